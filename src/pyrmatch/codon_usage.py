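"""Codon-usage geometry in the reduced PUR/PYR alphabet.

A transcriptome context (native, best-matched, worst-matched, or the genetic
code itself) is summarized by the fractions of the 20 reduced codons of the
nine pyrimidine-degenerate amino acids.  Contexts are compared by the RMSD

    RMSD(j, k) = sqrt( sum_i (x_ij - x_ik)^2 / 20 )

over the 20 coordinates, and the resulting distance matrix is embedded by
classical (Torgerson) multidimensional scaling — double-center the squared
distances, eigendecompose, keep the top positive eigenvalues — as R's
``cmdscale`` does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidSequenceError
from .genetic_code import CodeTable, ReducedCodon, split_codons, standard_table

Normalization = Literal["pooled", "per_residue"]


@dataclass(frozen=True)
class CodonUsageVector:
    """Fractions of the 20 reduced codons in one usage context.

    ``pooled`` normalization: each entry is the codon's share of *all*
    variable-residue codons in the context (entries sum to 1).
    ``per_residue``: entries sum to 1 within each amino acid instead.
    """

    context_label: str
    fractions: Mapping[ReducedCodon, float]
    normalization: Normalization = "pooled"

    def __post_init__(self) -> None:
        table = standard_table()
        if set(self.fractions) != set(table.variable_classes):
            raise ConfigError(
                f"{self.context_label}: usage vector must cover exactly the "
                f"{len(table.variable_classes)} reduced codons"
            )
        for rc, f in self.fractions.items():
            if not 0.0 <= f <= 1.0 + 1e-12:
                raise ConfigError(f"{self.context_label}: fraction of {rc} = {f}")

    def as_series(self) -> pd.Series:
        table = standard_table()
        return pd.Series(
            [self.fractions[rc] for rc in table.variable_classes],
            index=[str(rc) for rc in table.variable_classes],
            name=self.context_label,
        )

    def values(self) -> np.ndarray:
        table = standard_table()
        return np.array([self.fractions[rc] for rc in table.variable_classes])


def usage_vector(
    cds_set: Iterable[str],
    label: str,
    normalization: Normalization = "pooled",
    table: Optional[CodeTable] = None,
) -> CodonUsageVector:
    """Reduced-codon usage of a set of CDS (stop codons ignored)."""
    table = table or standard_table()
    counts: dict[ReducedCodon, int] = {rc: 0 for rc in table.variable_classes}
    total = 0
    for cds in cds_set:
        for codon in split_codons(cds):
            if codon in table.stop_codons:
                continue
            if table.codon_to_aa[codon] in table.variable_amino_acids:
                counts[table.reduce(codon)] += 1
                total += 1
    if total == 0:
        raise InvalidSequenceError(
            f"{label}: no codons of the variable amino acids in the set"
        )
    if normalization == "pooled":
        fractions = {rc: c / total for rc, c in counts.items()}
    elif normalization == "per_residue":
        per_aa = {}
        for rc, c in counts.items():
            per_aa[rc.amino_acid] = per_aa.get(rc.amino_acid, 0) + c
        fractions = {
            rc: (c / per_aa[rc.amino_acid] if per_aa[rc.amino_acid] else 0.0)
            for rc, c in counts.items()
        }
    else:
        raise ConfigError(f"unknown normalization {normalization!r}")
    return CodonUsageVector(label, fractions, normalization)


def standard_code_usage(
    normalization: Normalization = "pooled",
    table: Optional[CodeTable] = None,
    label: str = "UGC",
) -> CodonUsageVector:
    """Expected usage dictated by the code table alone: fractions proportional
    to class multiplicities (4 of leucine's 6 codons carry 2 pyrimidines, so
    Leu2 gets 4/41 pooled or 4/6 per-residue)."""
    table = table or standard_table()
    mult = {rc: table.multiplicity(rc) for rc in table.variable_classes}
    if normalization == "pooled":
        total = sum(mult.values())
        fractions = {rc: m / total for rc, m in mult.items()}
    else:
        per_aa: dict[str, int] = {}
        for rc, m in mult.items():
            per_aa[rc.amino_acid] = per_aa.get(rc.amino_acid, 0) + m
        fractions = {rc: m / per_aa[rc.amino_acid] for rc, m in mult.items()}
    return CodonUsageVector(label, fractions, normalization)


def usage_rmsd(u: CodonUsageVector, v: CodonUsageVector) -> float:
    """RMSD between two usage vectors over the 20 reduced-codon coordinates."""
    if set(u.fractions) != set(v.fractions):
        raise ConfigError("usage vectors cover different codon sets")
    d = u.values() - v.values()
    return float(np.sqrt((d @ d) / d.size))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ConfigError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or np.any(v < 0) or np.any(np.diag(v) != 0):
            raise ConfigError("distance matrix must be symmetric, nonnegative, "
                              "zero-diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def distance_matrix(vectors: Sequence[CodonUsageVector]) -> DistanceMatrix:
    """Pairwise usage RMSDs of a set of contexts."""
    n = len(vectors)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = usage_rmsd(vectors[i], vectors[j])
    return DistanceMatrix(tuple(v.context_label for v in vectors), m)


def classical_mds(
    dm: DistanceMatrix | np.ndarray,
    dims: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Returns ``(coordinates, variance_fractions)``: an ``n x dims`` embedding
    (defined up to rotation/reflection) and the cumulative share of the
    positive eigenvalue mass captured by 1..dims dimensions.  Negative
    eigenvalues (non-Euclidean distances) are excluded from the variance
    denominator.  If fewer than ``dims`` positive eigenvalues exist, the
    embedding is truncated with a warning.
    """
    if dims < 1:
        raise ConfigError(f"dims must be >= 1, got {dims}")
    d = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.size else evals > 0
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ConfigError("no positive eigenvalues: degenerate distance matrix")
    k = min(dims, n_pos)
    if k < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; embedding truncated to {k} dims"
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    pos_mass = evals[pos].sum()
    variance_fractions = np.cumsum(evals[:k]) / pos_mass
    return coords, variance_fractions


def worst_to_best_shifts(
    u_worst: CodonUsageVector,
    u_best: CodonUsageVector,
) -> pd.DataFrame:
    """Per-codon usage change upon the worst-to-best transition.

    Signed change ``best − worst`` per reduced codon, ranked by magnitude;
    the head of the table names the codons that drive the transition.
    """
    if set(u_worst.fractions) != set(u_best.fractions):
        raise ConfigError("usage vectors cover different codon sets")
    rows = [
        {
            "codon": str(rc),
            "amino_acid": rc.amino_acid,
            "delta_frequency": u_best.fractions[rc] - u_worst.fractions[rc],
        }
        for rc in standard_table().variable_classes
    ]
    df = pd.DataFrame(rows)
    df["abs_delta"] = df["delta_frequency"].abs()
    return (
        df.sort_values(["abs_delta", "codon"], ascending=[False, True])
        .drop(columns="abs_delta")
        .reset_index(drop=True)
    )
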