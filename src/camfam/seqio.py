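"""FASTA input and TSV output with validation on entry.

Protein records are restricted to the 20 canonical amino acids plus ``X``;
nucleotide records to ``ACGTN``. Sequences are uppercased on read, and a
trailing/embedded ``*`` stop symbol is stripped from protein sequences with
a warning (ORF translations exported from sequence databases frequently
carry one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from Bio import SeqIO

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

__all__ = [
    "ProteinRecord",
    "NucleotideRecord",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence flowing through the pipeline."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        for pos, ch in enumerate(self.seq):
            if ch not in PROTEIN_ALPHABET:
                raise ValueError(
                    f"protein {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NucleotideRecord:
    """A cDNA or genomic nucleotide sequence."""

    id: str
    seq: str
    kind: Literal["cdna", "genomic"] = field(default="cdna")

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("nucleotide record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        if self.kind not in ("cdna", "genomic"):
            raise ValueError(f"sequence {self.id!r}: kind must be 'cdna' or 'genomic'")
        for pos, ch in enumerate(self.seq):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: illegal character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(
    path: str | Path,
    alphabet: Literal["protein", "nucleotide"],
    kind: Literal["cdna", "genomic"] = "cdna",
) -> list[ProteinRecord] | list[NucleotideRecord]:
    """Read a FASTA file into validated records, preserving input order.

    Sequences are uppercased. Duplicate ids raise ``ValueError`` naming the
    offending id; illegal characters raise with the record id and position.
    For protein input, ``*`` symbols are stripped with a warning.
    """
    if alphabet not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "protein":
            if "*" in seq:
                warnings.warn(
                    f"protein {rec.id!r}: stripping {seq.count('*')} stop symbol(s)",
                    stacklevel=2,
                )
                seq = seq.replace("*", "")
            records.append(ProteinRecord(rec.id, seq))
        else:
            records.append(NucleotideRecord(rec.id, seq, kind=kind))
    return records


def write_fasta(records: Iterable[ProteinRecord | NucleotideRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write keyed rows as a TSV with a header, in input order.

    All rows must share one key set. Float values are serialized with two
    decimals (half-up), matching how percentages are reported throughout.
    """
    from ._util import fmt_pct

    rows = list(rows)
    path = Path(path)
    if not rows:
        path.write_text("")
        return
    keys = list(rows[0].keys())
    keyset = set(keys)
    for i, row in enumerate(rows):
        if set(row.keys()) != keyset:
            raise ValueError(f"row {i} has keys {sorted(row.keys())}, expected {sorted(keyset)}")

    def cell(v: object) -> str:
        if isinstance(v, bool):
            return "+" if v else "-"
        if isinstance(v, float):
            return fmt_pct(v)
        return str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(cell(row[k]) for k in keys) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a TSV written by :func:`write_table` back into string-valued rows."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        return []
    keys = lines[0].split("\t")
    return [dict(zip(keys, line.split("\t"))) for line in lines[1:]]
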