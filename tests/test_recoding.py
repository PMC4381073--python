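"""Steered and non-steered synonymous recoding: contracts and oracles."""

import numpy as np
import pytest
from scipy import stats

from pyrmatch import (
    RecodingConfig,
    SequencePair,
    eligible_positions,
    enumerate_assignments,
    native_r,
    nonsteered_r_values,
    nonsteered_recode,
    steer_to_target,
    steered_recode,
    transcriptome_sweep,
)
from pyrmatch.errors import ConfigError
from pyrmatch.genetic_code import standard_table
from pyrmatch.profiles import profile_pair, match_score
from pyrmatch.recoding import _Engine
from tests.conftest import make_toy_pair


def pair_from_protein(protein, seed=0, pair_id="p"):
    rng = np.random.default_rng(seed)
    cds = standard_table().back_translate(protein, rng)
    return SequencePair.from_sequences(pair_id, protein, cds + "UAA")


class TestEligiblePositions:
    def test_no_degenerate_residues(self):
        assert eligible_positions(pair_from_protein("M" + "KND" * 5)) == []

    def test_mixed_small_protein(self):
        assert eligible_positions(pair_from_protein("MSKS")) == [1, 3]

    def test_start_met_frozen_serine_body(self):
        pair = pair_from_protein("M" + "S" * 42)
        assert eligible_positions(pair) == list(range(1, 43))


class TestSteeredRecode:
    def test_zero_steps_returns_input(self, toy_pair, scale):
        res = steered_recode(toy_pair, scale, RecodingConfig(n_steps=0, seed=1))
        assert res.r_final == res.r_native
        assert res.final_cds == toy_pair.full_cds()

    def test_no_eligible_positions_warns_and_is_identity(self, scale):
        pair = pair_from_protein("M" + "KNDEQHWYFC" * 5)
        with pytest.warns(UserWarning):
            res = steered_recode(pair, scale, RecodingConfig(n_steps=100, seed=1))
        assert res.r_final == res.r_native
        assert res.final_cds == pair.full_cds()

    @pytest.mark.parametrize("direction", ["improve", "worsen"])
    def test_trajectory_monotone_and_extreme_ordering(self, toy_pair, scale, direction):
        res = steered_recode(
            toy_pair, scale, RecodingConfig(n_steps=3000, direction=direction, seed=5)
        )
        diffs = np.diff(np.concatenate(([res.r_native], res.trajectory)))
        if direction == "improve":
            assert np.all(diffs < 0) and res.r_final <= res.r_native
        else:
            assert np.all(diffs > 0) and res.r_final >= res.r_native
        assert res.n_accepted == res.trajectory.size <= 3000

    def test_translation_start_stop_preserved(self, toy_pair, scale):
        res = steered_recode(toy_pair, scale, RecodingConfig(n_steps=2000, seed=2))
        table = standard_table()
        assert table.translate(res.final_cds) == toy_pair.protein
        assert res.final_cds[:3] == toy_pair.cds[:3]
        assert res.final_cds[-3:] == toy_pair.stop_codon

    def test_deterministic_given_seed(self, toy_pair, scale):
        cfg = RecodingConfig(n_steps=1000, seed=42)
        a = steered_recode(toy_pair, scale, cfg)
        b = steered_recode(toy_pair, scale, cfg)
        assert a.final_cds == b.final_cds
        assert np.array_equal(a.trajectory, b.trajectory)

    def test_reaches_enumeration_optimum(self, toy_pair, scale):
        enum = enumerate_assignments(toy_pair, scale)
        best = enum["r"].min()
        res = steered_recode(toy_pair, scale, RecodingConfig(n_steps=10_000, seed=0))
        assert res.r_final == pytest.approx(best, abs=1e-12)

    def test_engine_score_matches_profile_pearson(self, toy_pair, scale):
        res = steered_recode(toy_pair, scale, RecodingConfig(n_steps=2000, seed=9))
        recomputed = match_score(profile_pair(res.final_pair, scale))
        assert res.r_final == pytest.approx(recomputed, abs=1e-12)

    def test_checkpoint_recording_is_monotone(self, toy_pair, scale):
        res = steered_recode(
            toy_pair, scale,
            RecodingConfig(n_steps=4000, direction="worsen", seed=3, record_every=500),
        )
        assert res.checkpoints is not None
        assert np.all(np.diff(res.checkpoints[:, 1]) >= 0)


class TestSteerToTarget:
    def test_target_at_native_needs_no_steps(self, toy_pair, scale):
        r0 = native_r(toy_pair, scale)
        res = steer_to_target(toy_pair, scale, r0, 0.01, RecodingConfig(seed=1))
        assert res.n_accepted == 0
        assert res.final_cds == toy_pair.full_cds()


class TestNonsteered:
    def test_no_eligible_positions_all_native(self):
        pair = pair_from_protein("M" + "KND" * 20)
        variants = nonsteered_recode(pair, RecodingConfig(seed=1), 5)
        assert variants == [pair.full_cds()] * 5

    def test_single_leucine_class_frequency(self):
        pair = pair_from_protein("MKL")
        variants = nonsteered_recode(pair, RecodingConfig(seed=7), 60_000)
        table = standard_table()
        n_leu2 = sum(v[6:9] in table.codons_of(table.reduce("CUA")) for v in variants)
        p, n = 4 / 6, 60_000
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(n_leu2 / n - p) < 3 * sigma

    def test_class_frequencies_chi_square(self):
        # one serine position, three equally weighted classes
        pair = pair_from_protein("MKS")
        table = standard_table()
        variants = nonsteered_recode(pair, RecodingConfig(seed=3), 10_000)
        counts = np.zeros(3)
        for v in variants:
            counts[table.reduce(v[6:9]).pyr_count - 1] += 1
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.001

    def test_translation_invariance_and_determinism(self, toy_pair):
        cfg = RecodingConfig(seed=13)
        a = nonsteered_recode(toy_pair, cfg, 50)
        b = nonsteered_recode(toy_pair, cfg, 50)
        assert a == b
        table = standard_table()
        for v in a:
            assert table.translate(v) == toy_pair.protein
            assert v[:3] == toy_pair.cds[:3] and v[-3:] == toy_pair.stop_codon

    def test_r_values_lie_in_enumerated_spectrum(self, scale):
        # single variable position -> R takes one of the enumerable values
        pair = pair_from_protein("M" + "K" * 30 + "S" + "N" * 20)
        enum = enumerate_assignments(pair, scale)
        spectrum = enum["r"].to_numpy()
        rvals = nonsteered_r_values(pair, scale, RecodingConfig(seed=5), 200)
        for r in rvals:
            assert np.min(np.abs(spectrum - r)) < 1e-12

    def test_variant_count_validation(self, toy_pair):
        with pytest.raises(ConfigError):
            nonsteered_recode(toy_pair, RecodingConfig(seed=1), 0)


class TestSweep:
    def test_single_pair_ordering_contract(self, toy_pair, scale):
        res = transcriptome_sweep([toy_pair], scale, RecodingConfig(n_steps=3000, seed=5))
        row = res.table.iloc[0]
        assert row.r_best <= row.r_native <= row.r_worst
        assert row.delta_r >= 0

    def test_sweep_skips_degenerate_pairs_without_aborting(self, toy_pair, scale):
        bad = pair_from_protein("M" * 50)  # constant protein profile
        res = transcriptome_sweep([bad, toy_pair], scale, RecodingConfig(n_steps=500, seed=1))
        assert len(res.table) == 1
        assert list(res.skipped["id"]) == ["p"]

    def test_sweep_median_ordering(self, sweep50):
        t = sweep50.table
        assert (t.r_best <= t.r_native + 1e-12).all()
        assert (t.r_native <= t.r_worst + 1e-12).all()
        s = sweep50.summary()
        assert s.loc["best", "median"] <= s.loc["native", "median"] <= s.loc["worst", "median"]

    def test_nonsteered_sweep_summaries(self, scale):
        pairs = [make_toy_pair(seed=s, pair_id=f"t{s}") for s in (1, 2, 3)]
        res = transcriptome_sweep(
            pairs, scale, RecodingConfig(direction="none", seed=4), n_variants=50
        )
        assert set(res.r_matrix) == {"t1", "t2", "t3"}
        assert all(v.size == 50 for v in res.r_matrix.values())
        assert {"r_native", "r_random_mean", "r_random_sigma"} <= set(res.table.columns)
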