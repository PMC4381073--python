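"""Window-averaged mRNA pyrimidine-density and protein propensity profiles.

An mRNA coding sequence is summarized by the pyrimidine (C/U) fraction in a
sliding 63-nucleotide window; its cognate protein by the mean of an amino-acid
propensity scale (by default the polar requirement, PR) over a sliding
21-residue window.  The two windows are registered codon-wise: mRNA window *i*
covers exactly the 21 codons encoding protein window *i*, so both profiles
have length ``n_residues - 21 + 1`` and the Pearson correlation R between them
is well defined.  Low PR means high propensity to interact with pyrimidine
mimetics, so *negative* R indicates compositional matching between an mRNA and
its protein.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import InvalidSequenceError, ScaleError, ZeroVarianceError
from .genetic_code import (
    AMINO_ACIDS,
    CodeTable,
    pyrimidine_count,
    split_codons,
    standard_table,
    to_rna,
)

#: default sliding-window sizes (residues / nucleotides)
DEFAULT_WINDOW_PROTEIN = 21
DEFAULT_WINDOW_MRNA = 63

#: proteins of length <= 2 * window are excluded from analysis
MIN_PROTEIN_LENGTH = 2 * DEFAULT_WINDOW_PROTEIN + 1


@dataclass(frozen=True)
class PropensityScale:
    """An amino-acid propensity scale: residue -> value for all 20 residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ScaleError(f"scale {self.name!r} missing residues {sorted(missing)}")
        for aa, v in self.values.items():
            if not np.isfinite(v):
                raise ScaleError(f"scale {self.name!r}: non-finite value for {aa}")

    def __getitem__(self, residue: str) -> float:
        try:
            return float(self.values[residue])
        except KeyError:
            raise ScaleError(f"residue {residue!r} not in scale {self.name!r}") from None

    def encode(self, protein: str) -> np.ndarray:
        """Per-residue scale values as a float vector."""
        try:
            return np.array([self.values[aa] for aa in protein], dtype=float)
        except KeyError as e:
            raise ScaleError(f"residue {e.args[0]!r} not in scale {self.name!r}") from None

    @classmethod
    def from_tsv(cls, path, name: Optional[str] = None) -> "PropensityScale":
        """Read a two-column TSV (residue, value); '#' lines are comments."""
        values: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                aa, val = line.split("\t")[:2]
                values[aa.strip()] = float(val)
        return cls(name or str(path), values)

    @classmethod
    def polar_requirement(cls) -> "PropensityScale":
        """The packaged polar requirement (PR) scale.

        Classical experimental PR values (partitioning of amino acids with
        substituted pyridines); low PR = high pyrimidine-mimetic affinity.
        """
        ref = importlib.resources.files("pyrmatch") / "data" / "polar_requirement.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path, name="polar_requirement")


@dataclass(frozen=True)
class SequencePair:
    """A validated CDS/protein pair.

    ``cds`` is the RNA coding sequence *without* the terminal stop codon (kept
    separately in ``stop_codon`` for faithful round-trips); it starts with the
    start codon encoding residue 1 and translates exactly to ``protein``.
    """

    id: str
    protein: str
    cds: str
    stop_codon: Optional[str] = None

    @classmethod
    def from_sequences(
        cls,
        id: str,
        protein: str,
        cds: str,
        table: Optional[CodeTable] = None,
    ) -> "SequencePair":
        table = table or standard_table()
        protein = protein.upper().strip("*")
        bad = set(protein) - set(AMINO_ACIDS)
        if bad:
            raise InvalidSequenceError(
                f"{id}: non-canonical residue(s) {sorted(bad)} in protein"
            )
        codons = split_codons(cds)
        stop = None
        if codons and codons[-1] in table.stop_codons:
            stop = codons[-1]
            codons = codons[:-1]
        body = "".join(codons)
        translated = table.translate(body)
        if translated != protein:
            raise InvalidSequenceError(f"{id}: CDS translation does not match protein")
        return cls(id=id, protein=protein, cds=body, stop_codon=stop)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def full_cds(self) -> str:
        """CDS with the terminal stop codon restored (if one was present)."""
        return self.cds + (self.stop_codon or "")


def window_average(values: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window mean: element i is the mean of ``values[i:i+window]``."""
    values = np.asarray(values, dtype=float)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > values.size:
        raise ValueError(f"window {window} exceeds vector length {values.size}")
    c = np.concatenate(([0.0], np.cumsum(values)))
    return (c[window:] - c[:-window]) / window


def codon_pyr_counts(cds: str) -> np.ndarray:
    """Per-codon pyrimidine counts (ints 0..3) of an RNA CDS."""
    return np.array([pyrimidine_count(c) for c in split_codons(cds)], dtype=np.int64)


def pyr_profile(cds: str, window_mrna: int = DEFAULT_WINDOW_MRNA) -> np.ndarray:
    """Codon-registered sliding pyrimidine fraction of a CDS (stop trimmed).

    Windows advance one codon (3 nt) per step; value i is the pyrimidine
    fraction of the ``window_mrna``-nt block spanning codons
    i .. i + window_mrna/3 - 1.
    """
    if window_mrna % 3:
        raise ValueError(f"window_mrna must be a multiple of 3, got {window_mrna}")
    counts = codon_pyr_counts(cds)
    wc = window_mrna // 3
    if wc > counts.size:
        raise ValueError(
            f"window of {wc} codons exceeds CDS length of {counts.size} codons"
        )
    c = np.concatenate(([0], np.cumsum(counts)))
    return (c[wc:] - c[:-wc]) / float(window_mrna)


def propensity_profile(
    protein: str,
    scale: PropensityScale,
    window_protein: int = DEFAULT_WINDOW_PROTEIN,
) -> np.ndarray:
    """Sliding-window mean of the scale over a protein sequence."""
    return window_average(scale.encode(protein), window_protein)


@dataclass(frozen=True)
class ProfilePair:
    """Index-aligned mRNA pyrimidine-density and protein propensity profiles."""

    pyr_profile: np.ndarray
    prot_profile: np.ndarray
    window_protein: int = DEFAULT_WINDOW_PROTEIN
    window_mrna: int = DEFAULT_WINDOW_MRNA

    def __post_init__(self) -> None:
        if self.pyr_profile.shape != self.prot_profile.shape:
            raise InvalidSequenceError(
                f"profile length mismatch: {self.pyr_profile.shape} vs "
                f"{self.prot_profile.shape}"
            )

    def __len__(self) -> int:
        return self.pyr_profile.size


def profile_pair(
    pair: SequencePair,
    scale: PropensityScale,
    window_protein: int = DEFAULT_WINDOW_PROTEIN,
) -> ProfilePair:
    """Build the aligned profile pair for a validated sequence pair."""
    return ProfilePair(
        pyr_profile=pyr_profile(pair.cds, 3 * window_protein),
        prot_profile=propensity_profile(pair.protein, scale, window_protein),
        window_protein=window_protein,
        window_mrna=3 * window_protein,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with an explicit zero-variance error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidSequenceError("profiles differ in length")
    if x.size < 3:
        raise InvalidSequenceError(f"need >= 3 profile points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("constant profile: Pearson R undefined")
    return float(xc @ yc) / np.sqrt(sxx * syy)


def match_score(pp: ProfilePair) -> float:
    """Pearson R between the two profiles; negative R means matching."""
    return pearson(pp.pyr_profile, pp.prot_profile)


def native_r(
    pair: SequencePair,
    scale: PropensityScale,
    window_protein: int = DEFAULT_WINDOW_PROTEIN,
) -> float:
    """R of a pair's native CDS against its protein profile."""
    return match_score(profile_pair(pair, scale, window_protein))
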