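# Methods

## The model

The package quantifies compositional complementarity between an mRNA coding
sequence and its cognate protein. Two aligned profiles are built per pair:

* the **mRNA pyrimidine-density profile** — the fraction of pyrimidine bases
  (C, U) in a sliding 63-nucleotide window of the CDS;
* the **protein propensity profile** — the sliding 21-residue mean of an
  amino-acid propensity scale, by default the polar requirement (PR).
  Low PR means high propensity to interact with pyrimidine mimetics.

The matching level is the Pearson correlation `R` between the two profiles;
because of the PR sign convention, `R < 0` indicates *matching* (pyrimidine-
rich mRNA stretches encode high-pyrimidine-affinity protein stretches) and
`R > 0` anti-matching.

**Window registration.** The mRNA window advances one codon (3 nt) per step
and window *i* covers exactly the 21 codons encoding protein window *i*.
This is the only registration that yields index-aligned, equal-length
vectors given the 63 = 3 × 21 window ratio, and it is adopted as a design
decision. Both profiles have length `L − 20` for a protein of length `L`;
proteins with `L ≤ 42` (twice the window) are excluded at validation.

## The reduced PUR/PYR alphabet

Synonymous codons that differ only within the purine (A/G) or pyrimidine
(C/U) letters have identical pyrimidine counts, so the recoding problem
lives in a reduced alphabet: an amino acid plus a pyrimidine count
(`Ser2`, `Arg0`, …). Exactly nine amino acids — Leu, Ile, Val, Pro, Thr,
Ala, Gly, Ser, Arg — possess synonymous codons with *different* pyrimidine
counts; they carry 41 of the 61 sense codons and collapse to 20 reduced
codons. The table is derived at import from Biopython's standard code table,
never typed in, and only the standard code is supported (other table ids are
rejected).

Class draws follow the **standard-code class multiplicities** (leucine's
2-pyrimidine class covers 4 of its 6 codons, so it is proposed with weight
4/6), optionally overridden by a user-supplied reduced-codon frequency table
(classes absent from the table keep their multiplicity weight). When a
reduced class must be realized as a concrete codon, the codon is drawn
uniformly within the class; the analysis itself is invariant to this choice
since `R` depends only on per-codon pyrimidine counts.

## Steered recoding

A Monte-Carlo walk of `n_steps` (default 10 000) single-codon moves:

1. draw one eligible position uniformly — a residue of the nine variable
   amino acids, excluding position 0 (the start codon stays fixed; the
   terminal stop codon is likewise never touched);
2. draw a *different* reduced class for it with the class weights
   (the current class is excluded, so a proposal always changes the
   pyrimidine count);
3. recompute `R`; accept iff `R` strictly moves in the requested direction
   (down toward `R_best`, up toward `R_worst`), otherwise revert.

A rejected proposal consumes one step and the next step redraws a fresh
position; ties (`ΔR = 0`) are rejected, which prevents drift along neutral
plateaus. Each accepted move's mRNA is the input of the next step. The
implementation keeps the pyrimidine count of every 63-nt window as an exact
integer and recomputes `R` from those integers at every evaluation — full
recomputation from exact state rather than incremental floating-point
updates, so the engine score agrees with an independent profile-level
Pearson computation to ~1e-15 (enforced by test). With a 45-codon toy pair
whose reduced-class space is exhaustively enumerable (≈ 3·10³–10⁴ states),
10⁴-step walks reach the global optimum in ≥ 95 % of seeds.

Positions whose final class equals the native class keep the native codon,
so a zero-step run returns the input byte-for-byte.

`steer_to_target` is the same walk with acceptance on `|R − target|`
shrinking, stopping when within tolerance; it is how the synthetic generator
plants native matching levels.

## Non-steered recoding

Each variant independently resamples *every* eligible position's reduced
class from the class weights (current class included — full randomization),
always restarting from the native mRNA; no score is consulted. Scoring many
variants is vectorized over the class draws, since `R` needs only pyrimidine
counts. Sampled class frequencies converge to the class weights (checked by
chi-square goodness of fit).

## Malleability and its statistics

`ΔR = R_worst − R_best` per protein (0 = matching pinned by the protein
sequence, 2 = full swing). The distribution tails used for functional
fingerprinting hold `floor(0.05·n)` proteins each, with ties at the cutoff
broken deterministically by `(ΔR, id)` — the tie rule is a package decision,
as is the floor. The native-matching/malleability association is the
Spearman rank correlation. Two terms' ΔR distributions are compared by the
Wilcoxon rank-sum test; scipy's `method="auto"` gives the exact permutation
null for small tie-free samples (a fully separated 5-vs-5 comparison yields
exactly 1/252 one-sided) and the tie-corrected normal approximation
otherwise. Proteins carrying both terms count in both groups.

## Enrichment

Per term, a 2×2 subset-vs-background table is tested one-sided with the
hypergeometric tail after the **EASE adjustment**: subtract 1 from the
subset hit count for enrichment (floored at 0), add 1 for depletion (capped
at the subset size and the term's background count so the table stays
feasible). This penalizes low-count terms. P-values are Benjamini–Hochberg
FDR adjusted separately within each direction — the two one-sided families
test distinct hypotheses — with a 0.01 significance cutoff. Annotations are
used exactly as given; no propagation up an ontology graph is performed.
Under null annotations (membership independent of the subset) the
FDR-significant fraction measured over 200 simulated datasets is far below
the nominal 1 %, as expected from the EASE penalty.

## Codon-usage geometry

A usage context (native, best, worst, or the code baseline) is the vector of
the 20 reduced-codon fractions. By default fractions are **pooled** — each
entry is the codon's share of all variable-residue codons, summing to 1
across the 20 entries; a per-residue normalization (summing to 1 within each
amino acid) is available by switch, since either reading of "fraction of a
given codon" is defensible. Contexts are compared by
`RMSD = sqrt(Σᵢ (x_{i,j} − x_{i,k})² / 20)`, a scaled Euclidean metric.
The code baseline uses class multiplicities (e.g. `Leu2 = 4/41` pooled).

Classical (Torgerson) MDS embeds the distance matrix: double-center the
squared distances, eigendecompose, keep the top positive eigenvalues;
variance fractions are cumulative shares of the positive eigenvalue mass
(negative eigenvalues, possible for non-Euclidean inputs, are excluded from
the denominator). It is implemented directly — scikit-learn's MDS is the
iterative SMACOF variant, not classical scaling — and cross-checked against
R's `cmdscale` in the test suite. Coordinates are defined up to rotation and
reflection, so tests compare distance matrices, never raw coordinates. On an
exactly 3-D Euclidean input the embedding reproduces all distances to 1e-9
with variance fraction 1.0.

## Synthetic data

The generator emulates what the analysis consumes: proteins drawn from a
configurable composition (default uniform over the 20 residues, residue 1
always Met), CDS back-translated with configurable reduced-class bias plus a
random stop codon, and annotation tables with planted effects. Default
transcriptome: 50 pairs of 120–300 residues — large enough for stable
distribution medians, small enough for fast suites; planted-matching runs
use 150-residue pairs with target `R* = −0.75` and tolerance 0.05.

Planting a native matching level reuses `steer_to_target` from a random
encoding. Not every protein can reach every target (the reachable `R` range
depends on composition), so draws whose steering stalls outside tolerance
are redrawn, up to 8 attempts; a persistent failure is returned flagged,
never silently. Annotation planting: ΔR-linked terms sample members with
20:1 odds toward the bottom (or top) ΔR quartile; subset-enrichment terms
annotate subset members with one rate and the rest with another; null terms
sample uniformly.

What the generator does *not* emulate: real gene architecture (introns,
UTRs), GC isochores, organism-specific amino-acid composition, or any
biological coupling between protein function and malleability. Passing
tests therefore demonstrate the pipeline's correctness and statistical
calibration on data with known structure — not any claim about real
proteomes.

## Numerical choices and degenerate inputs

* Pearson on a constant profile is undefined; such sequences raise a typed
  error and are excluded with a reason, never silently zeroed. A steered
  proposal that would make the pyrimidine profile constant is rejected.
* Window sums are exact integers; profile values are derived from them, so
  determinism is bitwise given a seed. Sweep pair seeds are spawned from the
  run seed and the pair index, making sweeps order-independent.
* Eligible-position and class draws are pre-generated per run from one
  `numpy` generator; rerunning with the same seed reproduces every output
  byte-for-byte.
* 5 % tails use `floor`, and empty per-term tables are results, not errors.

## Problem sizes

Default validation sizes: 50-pair sweeps at 10⁴ steps for distribution
structure; 100 seeds × 10⁴ steps for optimizer-vs-enumeration equivalence
on a 45-codon toy pair; 200 pairs for planted-target recovery; 200 null
datasets for type-I calibration; 10 usage contexts (code baseline + three
biased synthetic transcriptomes × native/best/worst) for the MDS geometry.

## Known limitations

* The packaged PR scale is the classical experimental polar requirement;
  variant (e.g. computationally derived) scales must be supplied as TSV.
* Only the standard genetic code is supported, by design.
* Greedy strict-improvement steering finds the global optimum reliably on
  desk-scale sequences but carries no optimality guarantee for very long
  CDS; the convergence-checkpoint facility (`record_every`) exposes the
  plateau behavior.
* Enrichment treats annotation terms independently; no multiple-term
  dependence structure or ontology-aware collapsing is modeled.
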