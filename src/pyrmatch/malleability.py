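"""Per-protein malleability of mRNA-protein matching and its correlates.

Malleability is the span of matching a protein's mRNA can reach by synonymous
recoding alone: ΔR = R_worst − R_best.  ΔR near 0 means the protein sequence
pins the matching level; ΔR near 2 means recoding can swing it from perfect
matching to perfect anti-matching.  This module computes ΔR records, the 5%
distribution tails used for functional fingerprinting, the rank correlation
between native matching and malleability, and per-annotation-term ΔR
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, PyrmatchError


class IncompleteRecordError(PyrmatchError, ValueError):
    """A malleability record is missing one of its steered extremes."""


@dataclass(frozen=True)
class MalleabilityRecord:
    id: str
    r_native: float
    r_best: float
    r_worst: float

    @property
    def delta_r(self) -> float:
        return delta_r(self.r_worst, self.r_best)


def delta_r(r_worst: Optional[float], r_best: Optional[float]) -> float:
    """ΔR = R_worst − R_best, the malleability span (0 = none, 2 = full)."""
    if r_worst is None or r_best is None or np.isnan(r_worst) or np.isnan(r_best):
        raise IncompleteRecordError("both steered extremes are required for ΔR")
    return float(r_worst) - float(r_best)


def records_frame(records) -> pd.DataFrame:
    """Normalize sweep tables / record lists to a DataFrame with delta_r."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {"id": r.id, "r_native": r.r_native, "r_best": r.r_best,
                 "r_worst": r.r_worst}
                for r in records
            ]
        )
    if "id" not in df:
        raise IncompleteRecordError("records lack column 'id'")
    if "delta_r" not in df:
        for col in ("r_best", "r_worst"):
            if col not in df:
                raise IncompleteRecordError(f"records lack column {col!r}")
        df["delta_r"] = df["r_worst"] - df["r_best"]
    return df


def tail_sets(records, fraction: float = 0.05) -> tuple[list[str], list[str]]:
    """Ids of the bottom and top ``fraction`` of the ΔR distribution.

    Each tail holds ``floor(fraction * n)`` proteins; ties at the cutoff are
    broken deterministically by (ΔR, id).
    """
    if not 0 < fraction < 0.5:
        raise ConfigError(f"tail fraction must be in (0, 0.5), got {fraction}")
    df = records_frame(records).sort_values(["delta_r", "id"], kind="mergesort")
    k = int(np.floor(fraction * len(df)))
    low = df["id"].head(k).tolist()
    high = df["id"].tail(k).tolist()
    return low, high


def native_vs_malleability(records) -> tuple[float, float]:
    """Spearman ρ (and p) between native matching R and malleability ΔR."""
    df = records_frame(records)
    if "r_native" not in df:
        raise IncompleteRecordError("records lack column 'r_native'")
    if len(df) < 3:
        raise ConfigError(f"need >= 3 records, got {len(df)}")
    rho, p = stats.spearmanr(df["r_native"], df["delta_r"])
    if np.isnan(rho):
        raise ConfigError("Spearman rho undefined (all ranks tied)")
    return float(rho), float(p)


def per_term_mean_delta(
    records,
    annotations: pd.DataFrame,
    min_proteins: int = 100,
) -> pd.DataFrame:
    """Mean ΔR per annotation term, for terms with enough annotated proteins.

    ``annotations`` needs columns ``protein_id`` and ``term_id`` (a protein
    may carry many terms).  Terms annotating fewer than ``min_proteins`` of
    the recorded proteins are dropped.
    """
    df = records_frame(records)
    merged = annotations.merge(df[["id", "delta_r"]], left_on="protein_id",
                               right_on="id")
    # a protein annotated twice with the same term counts once
    merged = merged.drop_duplicates(["protein_id", "term_id"])
    grouped = merged.groupby("term_id")["delta_r"].agg(["size", "mean"])
    out = grouped[grouped["size"] >= min_proteins].reset_index()
    out.columns = ["term_id", "n_proteins", "mean_delta_r"]
    return out.sort_values("mean_delta_r").reset_index(drop=True)


def compare_term_distributions(
    records,
    annotations: pd.DataFrame,
    term_a: str,
    term_b: str,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of the ΔR distributions of two terms.

    Proteins carrying both terms are counted in both groups.  Exact null for
    small tie-free samples, normal approximation with tie correction
    otherwise.  Returns (U statistic of group a, p-value).
    """
    df = records_frame(records).set_index("id")
    groups = []
    for term in (term_a, term_b):
        ids = annotations.loc[annotations["term_id"] == term, "protein_id"].unique()
        vals = df.loc[df.index.intersection(ids), "delta_r"].to_numpy()
        if vals.size == 0:
            raise ConfigError(f"term {term!r} annotates no recorded protein")
        groups.append(vals)
    res = stats.mannwhitneyu(groups[0], groups[1], alternative=alternative,
                             method="auto")
    return float(res.statistic), float(res.pvalue)
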