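"""Exon/intron inference by exact comparison of a cDNA with its genomic locus.

The model is deliberately simple, matching how curated cDNA/genomic pairs
from a single assembly behave: the genomic sequence decomposes exactly into
exons (which concatenate to the cDNA) separated by introns that start with
``GT`` and end with ``AG``. Only the plus strand is handled; callers orient
their input. Among multiple valid decompositions the chain with leftmost
exon starts (first point of difference) is returned, which is the chain the
depth-first search below finds first.

Intron positions are reported against the coding frame: an intron that
falls after ``u`` exonic nucleotides interrupts codon ``floor(u/3) + 1``
with phase ``u mod 3`` (phase 0 = between codons).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .seqio import NucleotideRecord

MIN_EXON = 10

__all__ = [
    "GeneModel",
    "IntronCodonHit",
    "StructureError",
    "infer_gene_structure",
    "orf_aa_length",
    "intron_codon_positions",
    "write_gff3",
]


class StructureError(ValueError):
    """Raised when no valid exon/intron chain explains the cDNA."""


@dataclass
class GeneModel:
    """Exon/intron coordinates of one gene on its genomic sequence."""

    gene_id: str
    exons: list[tuple[int, int]]  # 0-based half-open genomic intervals
    introns: list[tuple[int, int]]
    strand: str = "+"

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced(self, genomic_seq: str) -> str:
        """Concatenated exon sequence (the reconstructed cDNA)."""
        return "".join(genomic_seq[s:e] for s, e in self.exons)


@dataclass(frozen=True)
class IntronCodonHit:
    """Which codon an intron interrupts, and at which phase."""

    intron_index: int  # 0-based ordinal of the intron
    codon_index: int  # 1-based codon number interrupted (or abutted at phase 0)
    phase: int  # 0, 1 or 2: offset of the intron within the codon


def infer_gene_structure(
    cdna: NucleotideRecord,
    genomic: NucleotideRecord,
    min_exon: int = MIN_EXON,
) -> GeneModel:
    """Infer the exon/intron chain relating a cDNA to its genomic sequence.

    The genomic sequence must decompose as exon(, intron, exon)* with the
    exons concatenating exactly to the cDNA and every intron bounded by
    GT..AG. Exons shorter than ``min_exon`` are not considered (except when
    the gene is intronless). Raises :class:`StructureError` when no chain
    exists.
    """
    c, g = cdna.seq, genomic.seq
    if len(c) > len(g):
        raise StructureError(
            f"{cdna.id}: cDNA ({len(c)} nt) longer than genomic sequence ({len(g)} nt)"
        )
    if c == g:
        return GeneModel(cdna.id, exons=[(0, len(g))], introns=[])

    # Positions in g where an intron could end: j such that g[j-2:j] == "AG";
    # the next exon then starts at j.
    ag_ends = [j for j in range(2, len(g) + 1) if g[j - 2 : j] == "AG"]

    exon_chain: list[tuple[int, int]] = []

    def match_len(ci: int, gi: int) -> int:
        """Longest common extension of c[ci:] and g[gi:]."""
        n = 0
        while ci + n < len(c) and gi + n < len(g) and c[ci + n] == g[gi + n]:
            n += 1
        return n

    def search(ci: int, gi: int) -> bool:
        ext = match_len(ci, gi)
        # Final exon: consumes the rest of both sequences.
        if ci + ext == len(c) and gi + ext == len(g) and ext >= min_exon:
            exon_chain.append((gi, gi + ext))
            return True
        # Interior exon of length e, then an intron g[gi+e:j] with GT..AG.
        # Candidate next-exon starts j are tried in ascending order so the
        # first complete chain found has leftmost exon starts.
        for j in ag_ends:
            if j < gi + min_exon + 4:  # room for the exon plus a minimal GT..AG
                continue
            for e in range(min_exon, min(ext, j - gi - 4) + 1):
                donor = gi + e
                if g[donor : donor + 2] != "GT":
                    continue
                if j + (len(c) - ci - e) > len(g):
                    continue
                if search(ci + e, j):
                    exon_chain.append((gi, donor))
                    return True
        return False

    if not search(0, 0):
        raise StructureError(
            f"{cdna.id}: unresolvable structure (no exact GT..AG exon chain "
            f"explains the cDNA on {genomic.id})"
        )
    exons = sorted(exon_chain)
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    model = GeneModel(cdna.id, exons=exons, introns=introns)
    assert model.spliced(g) == c, "spliced exons must reproduce the cDNA"
    return model


def orf_aa_length(cds_len: int) -> int:
    """Residues encoded by a CDS of ``cds_len`` nucleotides.

    The terminal stop codon is part of the CDS but encodes no residue, so a
    450-nt CDS encodes 149 amino acids.
    """
    if cds_len < 3 or cds_len % 3 != 0:
        raise ValueError(f"CDS length {cds_len} is not a positive multiple of 3")
    return cds_len // 3 - 1


def intron_codon_positions(model: GeneModel) -> list[IntronCodonHit]:
    """Codon index and phase interrupted by each intron.

    Assumes the cDNA is a CDS starting at its first nucleotide. An intron
    after ``u`` exonic nucleotides has ``u // 3`` complete codons upstream,
    so it interrupts codon ``u // 3 + 1`` at phase ``u % 3``.
    """
    hits: list[IntronCodonHit] = []
    upstream = 0
    for idx, (exon, _intron) in enumerate(zip(model.exons, model.introns)):
        upstream += exon[1] - exon[0]
        hits.append(
            IntronCodonHit(
                intron_index=idx,
                codon_index=upstream // 3 + 1,
                phase=upstream % 3,
            )
        )
    return hits


def write_gff3(models: Sequence[GeneModel], seq_ids: Sequence[str], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive coordinates)."""
    if len(models) != len(seq_ids):
        raise ValueError("one genomic sequence id per model required")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model, seqid in zip(models, seq_ids):
            gene_start = model.exons[0][0] + 1
            gene_end = model.exons[-1][1]
            fh.write(
                f"{seqid}\tcamfam\tgene\t{gene_start}\t{gene_end}\t.\t{model.strand}\t.\t"
                f"ID={model.gene_id}\n"
            )
            for i, (s, e) in enumerate(model.exons, 1):
                fh.write(
                    f"{seqid}\tcamfam\texon\t{s + 1}\t{e}\t.\t{model.strand}\t.\t"
                    f"ID={model.gene_id}.exon{i};Parent={model.gene_id}\n"
                )
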