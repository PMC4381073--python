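"""Standard genetic code in a reduced purine/pyrimidine (PUR/PYR) alphabet.

Synonymous codons that differ only in purine identity (A vs G) or pyrimidine
identity (C vs U) carry the same pyrimidine count, so for recoding purposes the
code collapses to *reduced codons*: an amino acid plus the number of pyrimidine
bases in the codon (``Ser2``, ``Arg0`` ...).  Nine amino acids — Leu, Ile, Val,
Pro, Thr, Ala, Gly, Ser and Arg — have synonymous codons with *different*
pyrimidine counts; only at their positions can synonymous recoding change the
pyrimidine-density profile of an mRNA.  Those nine residues contribute 41 of
the 61 sense codons and exactly 20 reduced codons.

The table is derived at import time from Biopython's standard RNA codon table,
so the combinatorics above are computed, not typed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable
from Bio.SeqUtils import seq3

from .errors import ConfigError, InvalidSequenceError, LogicError

PYRIMIDINES = frozenset("CU")
PURINES = frozenset("AG")
RNA_BASES = frozenset("ACGU")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def to_rna(seq: str) -> str:
    """Normalize a nucleotide string to uppercase RNA (T -> U).

    Raises :class:`InvalidSequenceError` on any base outside {A,C,G,T,U}.
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_BASES
    if bad:
        raise InvalidSequenceError(
            f"non-canonical nucleotide(s) {sorted(bad)} in sequence"
        )
    return s


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or not set(codon) <= RNA_BASES or codon != codon.upper():
        raise InvalidSequenceError(f"invalid codon {codon!r}: need 3 uppercase RNA bases")
    return codon


def pyrimidine_count(codon: str) -> int:
    """Number of pyrimidine bases (C or U) in a codon, 0..3."""
    _check_codon(codon)
    return sum(b in PYRIMIDINES for b in codon)


@dataclass(frozen=True, order=True)
class ReducedCodon:
    """An amino acid together with a codon pyrimidine count, e.g. ``Ser2``.

    The unit of synonymous recoding: all concrete codons of ``amino_acid``
    with ``pyr_count`` pyrimidines are interchangeable for profile purposes.
    """

    amino_acid: str
    pyr_count: int

    def __post_init__(self) -> None:
        if self.amino_acid not in AMINO_ACIDS:
            raise InvalidSequenceError(f"unknown residue {self.amino_acid!r}")
        if not 0 <= self.pyr_count <= 3:
            raise InvalidSequenceError(f"pyr_count {self.pyr_count} outside 0..3")

    @property
    def label(self) -> str:
        return f"{seq3(self.amino_acid)}{self.pyr_count}"

    def __str__(self) -> str:  # e.g. "Ser2"
        return self.label

    @classmethod
    def from_label(cls, label: str) -> "ReducedCodon":
        """Parse the three-letter notation, e.g. ``"Arg0"``."""
        name, digit = label[:3], label[3:]
        aa = _THREE_TO_ONE.get(name.capitalize())
        if aa is None or not digit.isdigit():
            raise InvalidSequenceError(f"cannot parse reduced codon label {label!r}")
        return cls(aa, int(digit))


_THREE_TO_ONE = {seq3(aa): aa for aa in AMINO_ACIDS}


class CodeTable:
    """The standard genetic code plus its reduced PUR/PYR class structure.

    Only the standard code (NCBI table 1) is supported; requesting any other
    table id raises :class:`ConfigError`.
    """

    def __init__(self, table_id: int = 1):
        if table_id != 1:
            raise ConfigError(
                f"only the standard genetic code (table 1) is supported, got {table_id}"
            )
        bio = _BioCodonTable.unambiguous_rna_by_id[1]
        self.codon_to_aa: dict[str, str] = dict(bio.forward_table)
        self.stop_codons: frozenset[str] = frozenset(bio.stop_codons)
        assert len(self.codon_to_aa) == 61 and len(self.stop_codons) == 3

        # class structure: aa -> {pyr_count -> tuple of concrete codons}
        by_aa: dict[str, dict[int, list[str]]] = {aa: {} for aa in AMINO_ACIDS}
        for codon, aa in self.codon_to_aa.items():
            by_aa[aa].setdefault(pyrimidine_count(codon), []).append(codon)
        self._classes: dict[str, tuple[tuple[ReducedCodon, tuple[str, ...]], ...]] = {
            aa: tuple(
                (ReducedCodon(aa, pc), tuple(sorted(codons)))
                for pc, codons in sorted(groups.items())
            )
            for aa, groups in by_aa.items()
        }
        self.variable_amino_acids: frozenset[str] = frozenset(
            aa for aa, cls in self._classes.items() if len(cls) >= 2
        )
        self.variable_classes: tuple[ReducedCodon, ...] = tuple(
            rc
            for aa in sorted(self.variable_amino_acids)
            for rc, _ in self._classes[aa]
        )

    # -- lookups -----------------------------------------------------------

    def translate_codon(self, codon: str) -> str:
        _check_codon(codon)
        if codon in self.stop_codons:
            raise InvalidSequenceError(f"stop codon {codon} has no residue")
        return self.codon_to_aa[codon]

    def translate(self, cds: str) -> str:
        """Translate an RNA CDS (no internal stops; terminal stop allowed)."""
        cds = to_rna(cds)
        if len(cds) % 3:
            raise InvalidSequenceError(f"CDS length {len(cds)} not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in self.stop_codons:
            codons = codons[:-1]
        out = []
        for i, c in enumerate(codons):
            if c in self.stop_codons:
                raise InvalidSequenceError(f"internal stop codon {c} at codon {i}")
            out.append(self.codon_to_aa[c])
        return "".join(out)

    def reduce(self, codon: str) -> ReducedCodon:
        """Map a concrete codon to its reduced class."""
        return ReducedCodon(self.translate_codon(codon), pyrimidine_count(codon))

    def codons_of(self, reduced: ReducedCodon) -> tuple[str, ...]:
        for rc, codons in self._classes[reduced.amino_acid]:
            if rc == reduced:
                return codons
        raise LogicError(f"no codon realizes class {reduced}")

    # -- the reduced-class combinatorics ----------------------------------

    def reduced_classes(self, amino_acid: str) -> list[tuple[ReducedCodon, int]]:
        """Classes of a residue with multiplicities, sorted by pyr_count."""
        if amino_acid not in AMINO_ACIDS:
            raise InvalidSequenceError(f"unknown residue {amino_acid!r}")
        return [(rc, len(codons)) for rc, codons in self._classes[amino_acid]]

    def multiplicity(self, reduced: ReducedCodon) -> int:
        return len(self.codons_of(reduced))

    def class_sampling_weights(
        self,
        amino_acid: str,
        exclude_class: Optional[ReducedCodon] = None,
        frequencies: Optional[Mapping[ReducedCodon, float]] = None,
    ) -> dict[ReducedCodon, float]:
        """Probability of drawing each reduced class of a residue.

        Weights follow the class multiplicities in the standard code (a class
        realized by 4 of a residue's 6 codons is drawn with probability 4/6),
        or a user ``frequencies`` table overriding them (classes absent from
        the table keep their multiplicity weight).  With ``exclude_class``
        the remaining weights are renormalized.
        """
        classes = self.reduced_classes(amino_acid)
        if exclude_class is not None and len(classes) < 2:
            raise LogicError(
                f"{amino_acid} has a single reduced class; cannot exclude it"
            )
        weights = {}
        for rc, mult in classes:
            if rc == exclude_class:
                continue
            w = float(frequencies.get(rc, mult)) if frequencies is not None else float(mult)
            if w < 0:
                raise ConfigError(f"negative frequency for {rc}")
            weights[rc] = w
        total = sum(weights.values())
        if total <= 0:
            raise ConfigError(f"all sampling weights vanish for {amino_acid}")
        return {rc: w / total for rc, w in weights.items()}

    def concretize(self, reduced: ReducedCodon, rng: np.random.Generator) -> str:
        """Draw a concrete codon of the class, uniformly within the class."""
        codons = self.codons_of(reduced)
        return codons[int(rng.integers(len(codons)))]

    # -- misc --------------------------------------------------------------

    def back_translate(
        self,
        protein: str,
        rng: np.random.Generator,
        class_frequencies: Optional[Mapping[ReducedCodon, float]] = None,
    ) -> str:
        """Random CDS for a protein: class drawn by sampling weights, concrete
        codon uniform within the class.  No stop codon appended."""
        out = []
        for aa in protein:
            weights = self.class_sampling_weights(aa, frequencies=class_frequencies)
            classes = list(weights)
            probs = np.fromiter(weights.values(), float)
            rc = classes[int(rng.choice(len(classes), p=probs))]
            out.append(self.concretize(rc, rng))
        return "".join(out)

    def to_frame(self):
        """Dump the code table as a DataFrame (codon, amino_acid, pyr_count)."""
        import pandas as pd

        rows = [
            (codon, aa, pyrimidine_count(codon))
            for codon, aa in sorted(self.codon_to_aa.items())
        ]
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "pyr_count"])


@lru_cache(maxsize=None)
def standard_table() -> CodeTable:
    """The shared standard-code table instance."""
    return CodeTable(1)


def split_codons(cds: str) -> list[str]:
    """Split an RNA CDS into codons; frame errors raise."""
    cds = to_rna(cds)
    if len(cds) % 3:
        raise InvalidSequenceError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
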