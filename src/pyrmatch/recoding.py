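"""Synonymous recoding of coding sequences in the reduced PUR/PYR alphabet.

Two sampling regimes over the synonymous sequence space of a protein:

* **steered** recoding — a Monte-Carlo walk of ``n_steps`` single-codon
  reassignments.  Each step draws one eligible position (a residue of the nine
  pyrimidine-degenerate amino acids; the start codon is frozen), proposes a
  *different* reduced class for it with standard-code class weights, and
  accepts the move iff the Pearson R between the mRNA pyrimidine profile and
  the protein propensity profile strictly moves in the requested direction
  (down for ``improve`` = better matching, up for ``worsen``).  The walk ends
  at a best-matched (R_best) or worst-matched (R_worst) variant.

* **non-steered** recoding — every eligible position is independently
  resampled from the class weights (current class included), many times over,
  always restarting from the native mRNA; no score is consulted.

The engine keeps the pyrimidine count of each 63-nt window as an exact
integer and recomputes R from those integers at every step, so the score is
identical to a full profile recomputation and never drifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ZeroVarianceError
from .genetic_code import CodeTable, ReducedCodon, standard_table
from .profiles import (
    DEFAULT_WINDOW_PROTEIN,
    PropensityScale,
    SequencePair,
    codon_pyr_counts,
    propensity_profile,
    split_codons,
)

Direction = Literal["improve", "worsen", "none"]


@dataclass(frozen=True)
class RecodingConfig:
    """Parameters of a recoding run.

    ``frequencies`` optionally replaces the standard-code class multiplicities
    with organism-specific reduced-codon frequencies when drawing classes.
    """

    n_steps: int = 10_000
    direction: Direction = "improve"
    seed: int = 0
    frequencies: Optional[Mapping[ReducedCodon, float]] = None
    window_protein: int = DEFAULT_WINDOW_PROTEIN
    record_every: int = 0  # 0 = record accepted steps only

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ConfigError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.direction not in ("improve", "worsen", "none"):
            raise ConfigError(f"unknown direction {self.direction!r}")


@dataclass
class RecodingResult:
    """Outcome of steering one CDS."""

    pair: SequencePair
    direction: Direction
    r_native: float
    r_final: float
    final_pair: SequencePair
    trajectory: np.ndarray  # R after each accepted step
    n_accepted: int
    n_steps: int
    seed: int
    checkpoints: Optional[np.ndarray] = None  # (step, R) rows if record_every

    @property
    def final_cds(self) -> str:
        return self.final_pair.full_cds()


def eligible_positions(pair: SequencePair, table: Optional[CodeTable] = None) -> list[int]:
    """Codon indices where a synonymous change can alter pyrimidine content.

    Residues of the nine variable amino acids only; position 0 (the start
    codon) is always frozen, and the stop codon is not part of ``pair.cds``.
    """
    table = table or standard_table()
    return [
        i for i, aa in enumerate(pair.protein)
        if i > 0 and aa in table.variable_amino_acids
    ]


class _Engine:
    """Shared state for scoring synonymous variants of one pair.

    Window pyrimidine sums are int64; R is recomputed from them in full at
    each evaluation, so scores are exact functions of the integer state.
    """

    def __init__(
        self,
        pair: SequencePair,
        scale: PropensityScale,
        window_protein: int = DEFAULT_WINDOW_PROTEIN,
        frequencies: Optional[Mapping[ReducedCodon, float]] = None,
        table: Optional[CodeTable] = None,
    ):
        self.table = table or standard_table()
        self.pair = pair
        self.wc = window_protein
        self.codons = split_codons(pair.cds)
        self.n = len(self.codons)
        self.nw = self.n - self.wc + 1
        if self.nw < 3:
            raise ZeroVarianceError(
                f"{pair.id}: only {self.nw} profile windows; need >= 3"
            )
        y = propensity_profile(pair.protein, scale, window_protein)
        self.yc = y - y.mean()
        self.syy = float(self.yc @ self.yc)
        if self.syy == 0.0:
            raise ZeroVarianceError(f"{pair.id}: constant protein profile")

        self.c = codon_pyr_counts(pair.cds)  # int64, per codon
        cs = np.concatenate(([0], np.cumsum(self.c)))
        self.w = (cs[self.wc:] - cs[:-self.wc]).astype(np.int64)  # window sums

        self.eligible = np.array(eligible_positions(pair, self.table), dtype=np.int64)

        # per variable amino acid: class pyr counts, weights, and for each
        # current-class index the candidate classes + cumulative probabilities
        self._aa_info: dict[str, dict] = {}
        for aa in self.table.variable_amino_acids:
            classes = self.table.reduced_classes(aa)
            rcs = [rc for rc, _ in classes]
            pyr = np.array([rc.pyr_count for rc in rcs], dtype=np.int64)
            full = self.table.class_sampling_weights(aa, frequencies=frequencies)
            probs = np.array([full[rc] for rc in rcs])
            excl = []
            for cur in range(len(rcs)):
                cand = [k for k in range(len(rcs)) if k != cur]
                p = probs[cand]
                tot = p.sum()
                if tot <= 0:
                    raise ConfigError(
                        f"frequencies leave no alternative class for {aa}"
                    )
                excl.append((np.array(cand), np.cumsum(p / tot)))
            self._aa_info[aa] = {
                "classes": rcs,
                "pyr": pyr,
                "cum": np.cumsum(probs),
                "excl": excl,
            }

        # current class index per codon position (variable residues only)
        self.cls_idx = np.full(self.n, -1, dtype=np.int64)
        self.native_cls = {}
        for j in range(self.n):
            aa = pair.protein[j]
            if aa in self._aa_info:
                k = int(np.searchsorted(
                    self._aa_info[aa]["pyr"], self.c[j]
                ))
                self.cls_idx[j] = k
        self.native_cls_idx = self.cls_idx.copy()

    # -- scoring -----------------------------------------------------------

    def r_of_w(self, w: np.ndarray) -> Optional[float]:
        """Pearson R of the pyr profile implied by integer window sums ``w``
        against the protein profile; None when the pyr profile is constant."""
        sw = int(w.sum())
        sww = int(w @ w)
        var = sww - sw * sw / w.size
        if var <= 0:
            return None
        return float(w @ self.yc) / np.sqrt(var * self.syy)

    def current_r(self) -> Optional[float]:
        return self.r_of_w(self.w)

    def window_span(self, j: int) -> tuple[int, int]:
        """Half-open window-index range affected by codon ``j``."""
        return max(0, j - self.wc + 1), min(self.nw - 1, j) + 1

    # -- realization -------------------------------------------------------

    def realize(self, rng: np.random.Generator) -> SequencePair:
        """Concrete CDS for the current class assignment.

        Positions whose class equals the native class keep the native codon;
        changed classes get a uniform draw within the class.
        """
        out = list(self.codons)
        for j in self.eligible:
            if self.cls_idx[j] != self.native_cls_idx[j]:
                aa = self.pair.protein[j]
                rc = self._aa_info[aa]["classes"][self.cls_idx[j]]
                out[j] = self.table.concretize(rc, rng)
        return SequencePair(
            id=self.pair.id,
            protein=self.pair.protein,
            cds="".join(out),
            stop_codon=self.pair.stop_codon,
        )


def _steer(
    engine: _Engine,
    accept,  # callable (r_new, r_cur) -> bool
    n_steps: int,
    rng: np.random.Generator,
    record_every: int = 0,
    stop_when=None,  # callable (r_cur) -> bool, early exit
) -> tuple[list[float], int, Optional[np.ndarray], float]:
    """Run the accept/reject walk on an engine in place."""
    r_cur = engine.current_r()
    if r_cur is None:
        raise ZeroVarianceError(f"{engine.pair.id}: constant native pyrimidine profile")
    trajectory: list[float] = []
    checkpoints: list[tuple[int, float]] = []
    n_accepted = 0
    ne = engine.eligible.size
    if ne and n_steps:
        pos_draws = rng.integers(0, ne, size=n_steps)
        u_draws = rng.random(n_steps)
        for step in range(n_steps):
            if stop_when is not None and stop_when(r_cur):
                break
            j = int(engine.eligible[pos_draws[step]])
            aa = engine.pair.protein[j]
            info = engine._aa_info[aa]
            cand, cum = info["excl"][engine.cls_idx[j]]
            k_new = int(cand[np.searchsorted(cum, u_draws[step], side="right")])
            d = int(info["pyr"][k_new] - info["pyr"][engine.cls_idx[j]])
            lo, hi = engine.window_span(j)
            engine.w[lo:hi] += d
            r_new = engine.r_of_w(engine.w)
            if r_new is not None and accept(r_new, r_cur):
                engine.cls_idx[j] = k_new
                engine.c[j] += d
                r_cur = r_new
                trajectory.append(r_cur)
                n_accepted += 1
            else:
                engine.w[lo:hi] -= d
            if record_every and (step + 1) % record_every == 0:
                checkpoints.append((step + 1, r_cur))
    cp = np.array(checkpoints) if checkpoints else None
    return trajectory, n_accepted, cp, r_cur


def steered_recode(
    pair: SequencePair,
    scale: PropensityScale,
    cfg: RecodingConfig,
    table: Optional[CodeTable] = None,
) -> RecodingResult:
    """Steer one CDS toward best matching (``improve``) or worst (``worsen``).

    Only strictly improving/worsening moves are accepted; a rejected proposal
    is reverted and consumes one step.  With no eligible positions the input
    is returned unchanged (with a warning).
    """
    if cfg.direction not in ("improve", "worsen"):
        raise ConfigError(f"steered_recode needs direction improve/worsen, got {cfg.direction!r}")
    engine = _Engine(pair, scale, cfg.window_protein, cfg.frequencies, table)
    rng = np.random.default_rng(cfg.seed)
    r_native = engine.current_r()
    if r_native is None:
        raise ZeroVarianceError(f"{pair.id}: constant native pyrimidine profile")
    if engine.eligible.size == 0:
        warnings.warn(f"{pair.id}: no eligible positions; returning input unchanged")
    accept = (lambda rn, rc: rn < rc) if cfg.direction == "improve" else (lambda rn, rc: rn > rc)
    trajectory, n_accepted, cp, r_final = _steer(
        engine, accept, cfg.n_steps, rng, cfg.record_every
    )
    return RecodingResult(
        pair=pair,
        direction=cfg.direction,
        r_native=r_native,
        r_final=r_final,
        final_pair=engine.realize(rng),
        trajectory=np.array(trajectory),
        n_accepted=n_accepted,
        n_steps=cfg.n_steps,
        seed=cfg.seed,
        checkpoints=cp,
    )


def steer_to_target(
    pair: SequencePair,
    scale: PropensityScale,
    target_r: float,
    tolerance: float,
    cfg: RecodingConfig,
    table: Optional[CodeTable] = None,
) -> RecodingResult:
    """Steer a CDS toward a *target* R: accept moves that shrink |R - target|,
    stop as soon as R is within ``tolerance``.  Used to plant native matching
    levels in synthetic pairs."""
    engine = _Engine(pair, scale, cfg.window_protein, cfg.frequencies, table)
    rng = np.random.default_rng(cfg.seed)
    r_native = engine.current_r()
    if r_native is None:
        raise ZeroVarianceError(f"{pair.id}: constant native pyrimidine profile")
    accept = lambda rn, rc: abs(rn - target_r) < abs(rc - target_r)
    stop = lambda rc: abs(rc - target_r) <= tolerance
    trajectory, n_accepted, cp, r_final = _steer(
        engine, accept, cfg.n_steps, rng, cfg.record_every, stop_when=stop
    )
    return RecodingResult(
        pair=pair,
        direction="none",
        r_native=r_native,
        r_final=r_final,
        final_pair=engine.realize(rng),
        trajectory=np.array(trajectory),
        n_accepted=n_accepted,
        n_steps=cfg.n_steps,
        seed=cfg.seed,
        checkpoints=cp,
    )


def nonsteered_recode(
    pair: SequencePair,
    cfg: RecodingConfig,
    n_variants: int,
    table: Optional[CodeTable] = None,
) -> list[str]:
    """Independent full randomizations of all eligible codons.

    Each variant redraws every eligible position's reduced class from the
    class sampling weights (current class *included*) and a concrete codon
    uniformly within the drawn class; the native mRNA is the template every
    time.  Returns full CDS strings (stop codon restored).
    """
    if n_variants < 1:
        raise ConfigError(f"n_variants must be >= 1, got {n_variants}")
    table = table or standard_table()
    rng = np.random.default_rng(cfg.seed)
    elig = eligible_positions(pair, table)
    native = split_codons(pair.cds)
    stop = pair.stop_codon or ""
    if not elig:
        return [pair.full_cds()] * n_variants

    # per eligible position: flat codon list + class-weighted per-codon probs
    per_pos = []
    for j in elig:
        aa = pair.protein[j]
        weights = table.class_sampling_weights(aa, frequencies=cfg.frequencies)
        codons, probs = [], []
        for rc, p_class in weights.items():
            cl = table.codons_of(rc)
            codons.extend(cl)
            probs.extend([p_class / len(cl)] * len(cl))
        per_pos.append((j, np.array(codons, dtype=object), np.array(probs)))

    grid = np.array(native, dtype=object)[None, :].repeat(n_variants, axis=0)
    for j, codons, probs in per_pos:
        picks = rng.choice(codons.size, size=n_variants, p=probs)
        grid[:, j] = codons[picks]
    return ["".join(row) + stop for row in grid]


def nonsteered_r_values(
    pair: SequencePair,
    scale: PropensityScale,
    cfg: RecodingConfig,
    n_variants: int,
    table: Optional[CodeTable] = None,
) -> np.ndarray:
    """Pearson R of ``n_variants`` non-steered recodings of one pair.

    Vectorized over variants (classes are resampled, never concretized, since
    R depends only on per-codon pyrimidine counts).  Variants whose pyrimidine
    profile is constant get NaN.
    """
    table = table or standard_table()
    engine = _Engine(pair, scale, cfg.window_protein, cfg.frequencies, table)
    rng = np.random.default_rng(cfg.seed)
    counts = np.broadcast_to(engine.c, (n_variants, engine.n)).copy()
    for j in engine.eligible:
        aa = pair.protein[j]
        info = engine._aa_info[aa]
        probs = np.diff(np.concatenate(([0.0], info["cum"])))
        picks = rng.choice(info["pyr"].size, size=n_variants, p=probs)
        counts[:, j] = info["pyr"][picks]
    cs = np.concatenate(
        [np.zeros((n_variants, 1), dtype=np.int64), np.cumsum(counts, axis=1)], axis=1
    )
    w = cs[:, engine.wc:] - cs[:, :-engine.wc]
    sw = w.sum(axis=1)
    var = (w * w).sum(axis=1) - sw * sw / engine.nw
    num = w @ engine.yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / np.sqrt(var * engine.syy)
    r[var <= 0] = np.nan
    return r


@dataclass
class SweepResult:
    """Per-pair table and distribution summaries of a transcriptome sweep."""

    table: pd.DataFrame
    skipped: pd.DataFrame
    r_matrix: Optional[dict[str, np.ndarray]] = None  # id -> non-steered R values

    def summary(self) -> pd.DataFrame:
        """Mean, sigma and median of the native/best/worst R distributions."""
        rows = {}
        for col in ("r_native", "r_best", "r_worst"):
            if col in self.table:
                v = self.table[col].to_numpy()
                rows[col.removeprefix("r_")] = {
                    "mean": float(np.mean(v)),
                    "sigma": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
                    "median": float(np.median(v)),
                }
        return pd.DataFrame(rows).T


def transcriptome_sweep(
    pairs: Sequence[SequencePair],
    scale: PropensityScale,
    cfg: RecodingConfig,
    n_variants: int = 0,
    table: Optional[CodeTable] = None,
) -> SweepResult:
    """Recode every pair of a (synthetic) transcriptome.

    With ``cfg.direction`` in {improve, worsen} (or the default), *both*
    steered directions are run per pair, yielding R_native, R_best, R_worst
    and the malleability span ΔR = R_worst − R_best.  With direction
    ``"none"``, ``n_variants`` non-steered recodings are scored per pair
    instead.  Per-pair failures (e.g. constant profiles) are recorded in
    ``skipped`` and never abort the sweep.  Pair seeds are derived from
    ``cfg.seed`` and the pair index, so results are order-independent.
    """
    rows, skipped = [], []
    r_matrix: dict[str, np.ndarray] = {}
    for i, pair in enumerate(pairs):
        sub = np.random.SeedSequence(cfg.seed, spawn_key=(i,)).generate_state(2)
        try:
            if cfg.direction == "none":
                r = nonsteered_r_values(
                    pair, scale,
                    RecodingConfig(
                        n_steps=cfg.n_steps, direction="none",
                        seed=int(sub[0] % 2**31), frequencies=cfg.frequencies,
                        window_protein=cfg.window_protein,
                    ),
                    n_variants, table,
                )
                r_matrix[pair.id] = r
                from .profiles import native_r
                rows.append({
                    "id": pair.id,
                    "r_native": native_r(pair, scale, cfg.window_protein),
                    "r_random_mean": float(np.nanmean(r)),
                    "r_random_sigma": float(np.nanstd(r, ddof=1)),
                })
            else:
                res_b = steered_recode(pair, scale, RecodingConfig(
                    n_steps=cfg.n_steps, direction="improve",
                    seed=int(sub[0] % 2**31), frequencies=cfg.frequencies,
                    window_protein=cfg.window_protein,
                ), table)
                res_w = steered_recode(pair, scale, RecodingConfig(
                    n_steps=cfg.n_steps, direction="worsen",
                    seed=int(sub[1] % 2**31), frequencies=cfg.frequencies,
                    window_protein=cfg.window_protein,
                ), table)
                rows.append({
                    "id": pair.id,
                    "r_native": res_b.r_native,
                    "r_best": res_b.r_final,
                    "r_worst": res_w.r_final,
                    "delta_r": res_w.r_final - res_b.r_final,
                    "n_eligible": len(eligible_positions(pair, table)),
                    "best_cds": res_b.final_cds,
                    "worst_cds": res_w.final_cds,
                })
        except ZeroVarianceError as e:
            skipped.append({"id": pair.id, "reason": str(e)})
    return SweepResult(
        table=pd.DataFrame(rows),
        skipped=pd.DataFrame(skipped, columns=["id", "reason"]),
        r_matrix=r_matrix or None,
    )


def enumerate_assignments(
    pair: SequencePair,
    scale: PropensityScale,
    window_protein: int = DEFAULT_WINDOW_PROTEIN,
    max_states: int = 600_000,
    table: Optional[CodeTable] = None,
) -> pd.DataFrame:
    """Exhaustively score every reduced-class assignment of a small pair.

    Brute-force ground truth for the steered optimizer: enumerates the full
    product of class choices over eligible positions (capped at
    ``max_states``) and returns per-assignment R.  NaN rows mark assignments
    with a constant pyrimidine profile.
    """
    import itertools

    table = table or standard_table()
    engine = _Engine(pair, scale, window_protein, table=table)
    elig = list(engine.eligible)
    choices = []
    n_states = 1
    for j in elig:
        pyr = engine._aa_info[pair.protein[j]]["pyr"]
        choices.append([int(p) for p in pyr])
        n_states *= len(pyr)
    if n_states > max_states:
        raise ConfigError(f"{n_states} assignments exceed max_states={max_states}")
    base = engine.c.copy()
    records = []
    for combo in itertools.product(*choices) if elig else [()]:
        c = base.copy()
        for j, p in zip(elig, combo):
            c[j] = p
        cs = np.concatenate(([0], np.cumsum(c)))
        w = cs[engine.wc:] - cs[:-engine.wc]
        records.append((combo, engine.r_of_w(w)))
    return pd.DataFrame(records, columns=["assignment", "r"])
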