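"""Reduced-codon usage vectors, RMSD geometry and classical MDS."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from pyrmatch import (
    CodonUsageVector,
    DistanceMatrix,
    classical_mds,
    distance_matrix,
    standard_code_usage,
    standard_table,
    usage_rmsd,
    usage_vector,
    worst_to_best_shifts,
)
from pyrmatch.errors import ConfigError, InvalidSequenceError
from pyrmatch.genetic_code import ReducedCodon


def vector_from_values(label, values):
    table = standard_table()
    return CodonUsageVector(label, dict(zip(table.variable_classes, values)))


class TestUsageVector:
    def test_met_ser_ser_cds(self):
        u = usage_vector(["AUGUCUUCU"], "toy")
        assert u.fractions[ReducedCodon("S", 3)] == pytest.approx(1.0)
        assert sum(u.fractions.values()) == pytest.approx(1.0)

    def test_standard_code_baseline_proportional_to_multiplicity(self):
        u = standard_code_usage()
        leu2 = u.fractions[ReducedCodon("L", 2)]
        leu3 = u.fractions[ReducedCodon("L", 3)]
        assert leu2 == pytest.approx(2 * leu3)
        assert leu2 == pytest.approx(4 / 41)
        assert sum(u.fractions.values()) == pytest.approx(1.0)

    def test_per_residue_normalization(self):
        u = standard_code_usage(normalization="per_residue")
        assert u.fractions[ReducedCodon("L", 2)] == pytest.approx(4 / 6)
        assert u.fractions[ReducedCodon("S", 1)] == pytest.approx(1 / 3)

    def test_generated_frequencies_recovered(self, table):
        # back-translation with standard weights: class shares ~ multiplicities
        rng = np.random.default_rng(8)
        protein = "M" + "".join(rng.choice(list("LIVPTAGSR"), 6000))
        cds = table.back_translate(protein, rng)
        u = usage_vector([cds], "syn")
        within_aa = standard_code_usage(normalization="per_residue")
        for rc in table.variable_classes:
            # uniform residue draw over the 9 variable amino acids, then a
            # multiplicity-weighted class draw within the residue
            p = within_aa.fractions[rc] / 9
            sigma = np.sqrt(p * (1 - p) / 6000)
            assert abs(u.fractions[rc] - p) < 4 * sigma

    def test_no_variable_codons_is_error(self):
        with pytest.raises(InvalidSequenceError):
            usage_vector(["AUGAAAAAG"], "empty")


class TestUsageRmsd:
    def test_identity(self):
        u = standard_code_usage()
        assert usage_rmsd(u, u) == 0.0

    def test_single_coordinate_closed_form(self):
        base = np.full(20, 0.05)
        other = base.copy()
        other[3] += 0.12
        d = usage_rmsd(vector_from_values("a", base), vector_from_values("b", other))
        assert d == pytest.approx(0.12 / np.sqrt(20))

    def test_hand_summed_toy_vectors(self):
        a = np.linspace(0.01, 0.09, 20)
        b = a[::-1].copy()
        expected = np.sqrt(np.sum((a - b) ** 2) / 20)
        d = usage_rmsd(vector_from_values("a", a), vector_from_values("b", b))
        assert d == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        vs = [vector_from_values(f"v{i}", rng.dirichlet(np.ones(20))) for i in range(3)]
        d01 = usage_rmsd(vs[0], vs[1])
        d12 = usage_rmsd(vs[1], vs[2])
        d02 = usage_rmsd(vs[0], vs[2])
        assert d02 <= d01 + d12 + 1e-12
        assert d01 == pytest.approx(usage_rmsd(vs[1], vs[0]))


class TestClassicalMds:
    def test_two_points(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 5.0], [5.0, 0.0]]))
        coords, varfrac = classical_mds(dm, dims=1)
        assert abs(coords[0, 0] - coords[1, 0]) == pytest.approx(5.0)
        assert varfrac[-1] == pytest.approx(1.0)

    def test_exact_euclidean_recovery_in_3d(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords, varfrac = classical_mds(d, dims=3)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.max(np.abs(d - d2)) < 1e-9
        assert varfrac[-1] == pytest.approx(1.0, abs=1e-12)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, _ = classical_mds(d, dims=2)
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(d2 + np.eye(3), 1.0, atol=1e-12)

    def test_dims_truncated_with_warning(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.warns(UserWarning):
            coords, _ = classical_mds(dm, dims=3)
        assert coords.shape == (2, 1)

    def test_agrees_with_r_cmdscale(self, tmp_path):
        """Embedded distances match R's cmdscale on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.savetxt(tmp_path / "d.tsv", d, delimiter="\t")
        script = textwrap.dedent("""
            d <- as.matrix(read.table(commandArgs(TRUE)[1]))
            fit <- cmdscale(as.dist(d), k = 3)
            write.table(as.matrix(dist(fit)), commandArgs(TRUE)[2],
                        sep = "\\t", row.names = FALSE, col.names = FALSE)
        """)
        (tmp_path / "mds.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "mds.R"), str(tmp_path / "d.tsv"),
             str(tmp_path / "out.tsv")],
            check=True, capture_output=True,
        )
        r_dist = np.loadtxt(tmp_path / "out.tsv")
        coords, _ = classical_mds(d, dims=3)
        py_dist = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(py_dist, r_dist, atol=1e-8)


class TestShiftsAndIntegration:
    def test_identical_contexts_zero_deltas(self):
        u = standard_code_usage()
        out = worst_to_best_shifts(u, u)
        assert np.allclose(out["delta_frequency"], 0.0)

    def test_planted_isoleucine_shift_ranked_first(self):
        base = np.full(20, 0.05)
        table = standard_table()
        idx = {rc: i for i, rc in enumerate(table.variable_classes)}
        shifted = base.copy()
        shifted[idx[ReducedCodon("I", 2)]] += 0.05
        shifted[idx[ReducedCodon("I", 1)]] -= 0.03
        shifted[idx[ReducedCodon("T", 1)]] -= 0.02
        out = worst_to_best_shifts(
            vector_from_values("worst", base), vector_from_values("best", shifted)
        )
        assert out.iloc[0]["codon"] == "Ile2"
        assert out.iloc[0]["delta_frequency"] > 0

    def test_per_amino_acid_conservation_under_recoding(self, sweep50):
        """Recoding never changes amino-acid counts, so per-residue fraction
        sums agree between the best and worst usage contexts."""
        u_best = usage_vector(sweep50.table["best_cds"], "best")
        u_worst = usage_vector(sweep50.table["worst_cds"], "worst")
        out = worst_to_best_shifts(u_worst, u_best)
        per_aa = out.groupby("amino_acid")["delta_frequency"].sum()
        assert np.allclose(per_aa, 0.0, atol=1e-12)

    def test_distance_matrix_structure(self, sweep50, synthetic_pairs):
        vectors = [
            standard_code_usage(),
            usage_vector([p.cds for p in synthetic_pairs], "native"),
            usage_vector(sweep50.table["best_cds"], "best"),
            usage_vector(sweep50.table["worst_cds"], "worst"),
        ]
        dm = distance_matrix(vectors)
        v = dm.values
        assert np.allclose(v, v.T) and np.all(np.diag(v) == 0) and np.all(v >= 0)
        # steering pushes best and worst usage apart more than either is from native
        i = {l: k for k, l in enumerate(dm.labels)}
        assert v[i["best"], i["worst"]] > v[i["native"], i["best"]]

    def test_mismatched_codon_sets_rejected(self):
        u = standard_code_usage()
        table = standard_table()
        partial = dict(list(u.fractions.items())[:19])
        with pytest.raises(ConfigError):
            CodonUsageVector("bad", partial)
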