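"""Synthetic transcriptomes with plantable structure for pipeline validation.

Generates proteome-scale sets of CDS/protein pairs with controllable
amino-acid composition, reduced-codon usage bias and — via target-steered
recoding — a plantable level of native mRNA/protein profile matching, plus
annotation tables with planted term effects (ΔR-linked terms, subset
enrichment, pure nulls).  Everything is driven by one seed, so every
downstream artifact is reproducible byte-for-byte.

The generator emulates the *statistical* structure the analysis assumes
(composition, codon bias, matching level, annotation multiplicity); it does
not emulate real gene architecture, GC isochores or phylogenetic structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genetic_code import AMINO_ACIDS, CodeTable, ReducedCodon, standard_table
from .profiles import (
    DEFAULT_WINDOW_PROTEIN,
    MIN_PROTEIN_LENGTH,
    PropensityScale,
    SequencePair,
)
from .recoding import RecodingConfig, steer_to_target

#: fixture propensity scale with documented, well-spread values; decouples
#: tests from any particular empirical amino-acid scale
FIXTURE_SCALE = PropensityScale(
    "fixture",
    {aa: 4.0 + 0.5 * i for i, aa in enumerate(AMINO_ACIDS)},
)

PlantedProperty = Literal["low_delta_r", "high_delta_r", "none"]


@dataclass(frozen=True)
class AnnotationTerm:
    """Plan entry for one synthetic annotation term.

    ``planted`` controls how member proteins are chosen: preferentially from
    the bottom (``low_delta_r``) or top (``high_delta_r``) of the ΔR ranking
    with ``odds``:1 preference, or uniformly (``none``).  Alternatively a
    ``subset_enrichment`` fraction pair plants straight subset-vs-background
    membership rates for enrichment tests.
    """

    term_id: str
    n_proteins: int
    planted: PlantedProperty = "none"
    odds: float = 20.0
    subset_enrichment: Optional[tuple[float, float]] = None  # (p_subset, p_bg)
    term_name: str = ""
    aspect: str = "F"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic transcriptome.

    Defaults give a 50-pair transcriptome of 120-300-residue proteins with
    uniform amino-acid composition and standard-code codon usage; lengths
    stay above the 42-residue analysis floor unless ``min_length`` is
    lowered deliberately to exercise the filter.
    """

    n_pairs: int = 50
    min_length: int = 120
    max_length: int = 300
    composition: Optional[Mapping[str, float]] = None  # default uniform
    class_frequencies: Optional[Mapping[ReducedCodon, float]] = None
    target_r: Optional[float] = None
    tolerance: float = 0.05
    steps_per_target: int = 20_000
    max_attempts: int = 8  # protein redraws when target_r is out of reach
    window_protein: int = DEFAULT_WINDOW_PROTEIN
    annotation_plan: Sequence[AnnotationTerm] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")
        if not 2 < self.min_length <= self.max_length:
            raise ConfigError("need 2 < min_length <= max_length")
        if self.target_r is not None and not -1 < self.target_r < 1:
            raise ConfigError("target_r must lie in (-1, 1)")

    def composition_vector(self) -> np.ndarray:
        if self.composition is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        v = np.array([float(self.composition.get(aa, 0.0)) for aa in AMINO_ACIDS])
        if v.sum() <= 0 or np.any(v < 0):
            raise ConfigError("composition must be nonnegative with positive sum")
        return v / v.sum()


def generate_protein(
    cfg: GeneratorConfig, rng: np.random.Generator, length: Optional[int] = None
) -> str:
    """Random protein from the composition; residue 1 is always Met (the
    start codon encodes it)."""
    if length is None:
        length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
    comp = cfg.composition_vector()
    body = rng.choice(len(AMINO_ACIDS), size=length - 1, p=comp)
    return "M" + "".join(AMINO_ACIDS[i] for i in body)


def generate_pair(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    pair_id: str = "syn0001",
    table: Optional[CodeTable] = None,
) -> SequencePair:
    """One random CDS/protein pair: protein from the composition, CDS
    back-translated with the configured class bias, random stop appended."""
    table = table or standard_table()
    protein = generate_protein(cfg, rng)
    cds = table.back_translate(protein, rng, cfg.class_frequencies)
    stop = sorted(table.stop_codons)[int(rng.integers(3))]
    return SequencePair.from_sequences(pair_id, protein, cds + stop, table)


def generate_matched_pair(
    cfg: GeneratorConfig,
    scale: PropensityScale,
    rng: np.random.Generator,
    pair_id: str = "syn0001",
    table: Optional[CodeTable] = None,
) -> tuple[SequencePair, bool]:
    """A pair whose native matching R is planted near ``cfg.target_r``.

    Starts from a random encoding and steers it toward the target (accepting
    moves that shrink |R − target|).  Not every protein can reach every
    target — the reachable R range depends on its composition — so draws for
    which steering stalls outside the tolerance are discarded and redrawn, up
    to ``cfg.max_attempts`` times.  Returns ``(pair, achieved)``; after
    exhausting the attempts the nearest achieved encoding is returned,
    flagged ``achieved=False`` (never silently).
    """
    if cfg.target_r is None:
        raise ConfigError("cfg.target_r is not set")
    best: Optional[SequencePair] = None
    best_gap = np.inf
    for _ in range(max(1, cfg.max_attempts)):
        start = generate_pair(cfg, rng, pair_id, table)
        res = steer_to_target(
            start,
            scale,
            cfg.target_r,
            cfg.tolerance,
            RecodingConfig(
                n_steps=cfg.steps_per_target,
                direction="none",
                seed=int(rng.integers(2**31)),
                frequencies=cfg.class_frequencies,
                window_protein=cfg.window_protein,
            ),
            table,
        )
        gap = abs(res.r_final - cfg.target_r)
        if gap < best_gap:
            best, best_gap = res.final_pair, gap
        if gap <= cfg.tolerance:
            return res.final_pair, True
    return best, False


def generate_pairs(
    cfg: GeneratorConfig,
    scale: Optional[PropensityScale] = None,
    table: Optional[CodeTable] = None,
) -> list[SequencePair]:
    """A full synthetic pair set; matched to ``cfg.target_r`` when set."""
    table = table or standard_table()
    rng = np.random.default_rng(cfg.seed)
    pairs = []
    for i in range(cfg.n_pairs):
        pid = f"syn{i + 1:04d}"
        if cfg.target_r is None:
            pairs.append(generate_pair(cfg, rng, pid, table))
        else:
            if scale is None:
                raise ConfigError("a scale is required to plant target_r")
            pair, _ = generate_matched_pair(cfg, scale, rng, pid, table)
            pairs.append(pair)
    return pairs


def generate_annotations(
    cfg: GeneratorConfig,
    records: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    subset_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Annotation table (protein_id, term_id, term_name, aspect) per plan.

    ΔR-linked terms need a ``delta_r`` column in ``records``;
    ``subset_enrichment`` terms need ``subset_ids``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ids = records["id"].to_numpy()
    n = ids.size
    rows = []
    for term in cfg.annotation_plan:
        if term.subset_enrichment is not None:
            if subset_ids is None:
                raise ConfigError(f"{term.term_id}: subset_enrichment needs subset_ids")
            p_in, p_out = term.subset_enrichment
            in_subset = np.isin(ids, np.asarray(subset_ids))
            draws = rng.random(n)
            members = ids[(in_subset & (draws < p_in)) | (~in_subset & (draws < p_out))]
        else:
            if term.n_proteins > n:
                raise ConfigError(
                    f"{term.term_id}: plan asks for {term.n_proteins} of {n} proteins"
                )
            if term.planted == "none":
                weights = np.ones(n)
            else:
                if "delta_r" not in records:
                    raise ConfigError(
                        f"{term.term_id}: records lack delta_r for planted term"
                    )
                ranks = records["delta_r"].rank(method="first").to_numpy()
                quantile = ranks / n
                if term.planted == "low_delta_r":
                    weights = np.where(quantile <= 0.25, term.odds, 1.0)
                else:
                    weights = np.where(quantile > 0.75, term.odds, 1.0)
            members = rng.choice(
                ids, size=term.n_proteins, replace=False, p=weights / weights.sum()
            )
        for pid in members:
            rows.append({
                "protein_id": pid,
                "term_id": term.term_id,
                "term_name": term.term_name or term.term_id,
                "aspect": term.aspect,
            })
    return pd.DataFrame(rows, columns=["protein_id", "term_id", "term_name", "aspect"])
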