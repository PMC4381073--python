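"""File plumbing: FASTA pair validation, annotation tables, run manifests.

DNA or RNA FASTA is accepted for coding sequences (normalized to RNA); pairs
are matched by exact FASTA id (first whitespace-delimited token).  Validation
never drops a record silently — every input id lands either in the validated
set or in the exclusion report with a reason.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidSequenceError
from .genetic_code import AMINO_ACIDS, CodeTable, RNA_BASES, standard_table, to_rna
from .profiles import DEFAULT_WINDOW_PROTEIN, SequencePair


def read_fasta(path) -> dict[str, str]:
    """id -> sequence, id being the first whitespace-delimited token."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def validate_pairs(
    protein_fasta,
    cds_fasta,
    table: Optional[CodeTable] = None,
    window_protein: int = DEFAULT_WINDOW_PROTEIN,
) -> tuple[list[SequencePair], pd.DataFrame]:
    """Pair and validate protein/CDS FASTA files.

    Exclusion reasons: ``unpaired``, ``non-canonical``, ``frame``,
    ``translation mismatch``, ``too short`` (length ≤ 2x the protein window).
    Input record count always equals validated + excluded.
    """
    table = table or standard_table()
    proteins = read_fasta(protein_fasta)
    cdss = read_fasta(cds_fasta)
    min_len = 2 * window_protein  # proteins of length <= min_len are excluded
    pairs: list[SequencePair] = []
    excluded: list[dict] = []

    for rid in sorted(set(proteins) | set(cdss)):
        if rid not in proteins or rid not in cdss:
            excluded.append({"id": rid, "reason": "unpaired"})
            continue
        protein = proteins[rid].upper().strip("*")
        if set(protein) - set(AMINO_ACIDS):
            excluded.append({"id": rid, "reason": "non-canonical"})
            continue
        raw = cdss[rid].upper().replace("T", "U")
        if set(raw) - RNA_BASES:
            excluded.append({"id": rid, "reason": "non-canonical"})
            continue
        if len(raw) % 3:
            excluded.append({"id": rid, "reason": "frame"})
            continue
        try:
            pair = SequencePair.from_sequences(rid, protein, raw, table)
        except InvalidSequenceError:
            excluded.append({"id": rid, "reason": "translation mismatch"})
            continue
        if len(pair.protein) <= min_len:
            excluded.append({"id": rid, "reason": f"length <= 2x window ({min_len})"})
            continue
        pairs.append(pair)
    return pairs, pd.DataFrame(excluded, columns=["id", "reason"])


def read_annotations(path) -> pd.DataFrame:
    """Annotation table from plain TSV (protein_id, term_id[, ...]) or GAF 2.x.

    GAF is detected by the ``!gaf-version`` header; columns 2 and 5 (DB object
    id, GO id) are used.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                rows.append({
                    "protein_id": cols[1],
                    "term_id": cols[4],
                    "term_name": "",
                    "aspect": cols[8] if len(cols) > 8 else "",
                })
        return pd.DataFrame(rows, columns=["protein_id", "term_id", "term_name", "aspect"])
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if "protein_id" not in df or "term_id" not in df:
        raise InvalidSequenceError(
            f"{path}: annotation TSV needs protein_id and term_id columns"
        )
    for col in ("term_name", "aspect"):
        if col not in df:
            df[col] = ""
    return df[["protein_id", "term_id", "term_name", "aspect"]]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted by every CLI/pipeline run."""

    command: str
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: list = field(default_factory=list)
    timestamp: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        if not self.version:
            from . import __version__

            self.version = __version__

    def config_digest(self) -> str:
        blob = json.dumps(
            {"command": self.command, "config": self.config, "seed": self.seed,
             "inputs": self.inputs},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self) | {"config_digest": self.config_digest()},
                      fh, indent=2, default=str)
            fh.write("\n")
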