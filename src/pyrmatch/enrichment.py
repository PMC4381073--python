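"""Annotation-term enrichment/depletion with the EASE-adjusted Fisher test.

For a protein subset against a background, each term's 2x2 contingency table
is tested one-sided with the hypergeometric (Fisher) tail.  The EASE
modification makes the test conservative for low-count terms: the subset hit
count is decremented by one before testing enrichment (incremented for
depletion).  P-values are Benjamini-Hochberg FDR adjusted, separately within
each direction, at a default significance cutoff of 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

Direction = Literal["enriched", "depleted"]


@dataclass(frozen=True)
class TermContingency:
    """Counts behind one term's 2x2 table."""

    term_id: str
    k_subset: int       # subset proteins carrying the term
    n_subset: int       # subset size
    K_background: int   # background proteins carrying the term
    N_background: int   # background size

    def __post_init__(self) -> None:
        if not (0 <= self.k_subset <= min(self.n_subset, self.K_background)):
            raise ConfigError(f"{self.term_id}: impossible count k={self.k_subset}")
        if self.N_background < self.n_subset:
            raise ConfigError(f"{self.term_id}: background smaller than subset")


def ease_adjust(k_subset: int, direction: Direction, n_subset: int | None = None) -> int:
    """EASE count adjustment: k-1 for enrichment (floored at 0), k+1 for
    depletion (capped at the subset size when given)."""
    if k_subset < 0:
        raise ConfigError(f"negative count {k_subset}")
    if direction == "enriched":
        return max(k_subset - 1, 0)
    if direction == "depleted":
        k = k_subset + 1
        return min(k, n_subset) if n_subset is not None else k
    raise ConfigError(f"unknown direction {direction!r}")


def fisher_one_sided(tc: TermContingency, direction: Direction) -> float:
    """One-sided Fisher (hypergeometric tail) p-value of a contingency table.

    Upper tail P[X >= k] for enrichment, lower tail P[X <= k] for depletion,
    with X ~ Hypergeom(N, K, n).  The table is used as given; apply
    :func:`ease_adjust` beforehand for EASE semantics.
    """
    hg = stats.hypergeom(tc.N_background, tc.K_background, tc.n_subset)
    if direction == "enriched":
        return float(hg.sf(tc.k_subset - 1))
    if direction == "depleted":
        return float(hg.cdf(tc.k_subset))
    raise ConfigError(f"unknown direction {direction!r}")


def fdr_correct(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def contingencies(
    subset_ids: Iterable[str],
    background_ids: Iterable[str],
    annotations: pd.DataFrame,
) -> list[TermContingency]:
    """Per-term counts of an annotation table restricted to the background."""
    subset = set(subset_ids)
    background = set(background_ids)
    if not subset <= background:
        raise ConfigError("subset must be contained in the background")
    ann = annotations.loc[
        annotations["protein_id"].isin(background), ["protein_id", "term_id"]
    ].drop_duplicates()
    out = []
    for term, grp in ann.groupby("term_id"):
        members = set(grp["protein_id"])
        out.append(
            TermContingency(
                term_id=str(term),
                k_subset=len(members & subset),
                n_subset=len(subset),
                K_background=len(members),
                N_background=len(background),
            )
        )
    return out


def enrich_report(
    subset_ids: Iterable[str],
    background_ids: Iterable[str],
    annotations: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """EASE-Fisher enrichment and depletion of every term in a subset.

    Both directions are tested for every term; BH-FDR is applied within each
    direction (the two one-sided families are distinct hypotheses).  Rows with
    ``p_fdr < alpha`` are flagged significant.
    """
    tcs = contingencies(subset_ids, background_ids, annotations)
    rows = []
    for direction in ("enriched", "depleted"):
        for tc in tcs:
            k_ease = ease_adjust(tc.k_subset, direction, tc.n_subset)
            # table feasibility: k can never exceed the term's background count
            k_ease = min(k_ease, tc.K_background)
            adj = TermContingency(
                tc.term_id, k_ease, tc.n_subset,
                tc.K_background, tc.N_background,
            )
            rows.append({
                "term_id": tc.term_id,
                "direction": direction,
                "k_subset": tc.k_subset,
                "k_ease": k_ease,
                "n_subset": tc.n_subset,
                "K_background": tc.K_background,
                "N_background": tc.N_background,
                "p_raw": fisher_one_sided(adj, direction),
            })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_fdr"] = np.nan
    for direction in ("enriched", "depleted"):
        mask = df["direction"] == direction
        df.loc[mask, "p_fdr"] = fdr_correct(df.loc[mask, "p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < alpha
    return df.sort_values(["direction", "p_fdr", "term_id"]).reset_index(drop=True)
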