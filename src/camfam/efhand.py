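"""Detection, pairing and consensus statistics of EF-hand Ca2+-binding loops.

An EF-hand chelates Ca2+ through a 12-residue loop whose ligand positions
are conventionally labelled in Cartesian coordinates: +X (loop position 1),
+Y (3), +Z (5), -Y (7), -X (9) and -Z (12). The scanner encodes the loop as
a position-specific grammar distilled from conserved plant CaM/CML loops:

    canonical: pos1 == D; pos3 in {D,N,S}; pos5 in {D,N,S,T}; pos6 == G;
               pos9 in {T,D,S,N,G,E,Q}; pos12 in {E,D}
    relaxed:   as canonical but without the pos9 (-X) constraint

Position 6 is the invariant glycine of the loop turn; a -Z aspartate in
place of the canonical glutamate marks loops whose coordination geometry
favours Mg2+ and is flagged separately.

EF-hands function in pairs: two helix-loop-helix motifs separated by a
short linker. Pairing here is greedy left-to-right over adjacent loops
whose linker length falls within configurable bounds; unpaired loops are
reported as lone hands, which may bind Ca2+ weakly or not at all.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .seqio import ProteinRecord

LOOP_LEN = 12
#: Ligand positions of the 12-residue loop, 1-based, in Cartesian labels.
LIGAND_POSITIONS = {1: "+X", 3: "+Y", 5: "+Z", 7: "-Y", 9: "-X", 12: "-Z"}

#: Allowed residues per 1-based loop position (canonical grammar).
CANONICAL_GRAMMAR: dict[int, frozenset[str]] = {
    1: frozenset("D"),
    3: frozenset("DNS"),
    5: frozenset("DNST"),
    6: frozenset("G"),
    9: frozenset("TDSNGEQ"),
    12: frozenset("ED"),
}

MIN_LINKER = 8
MAX_LINKER = 30

__all__ = [
    "EFHandLoop",
    "LoopFrequencyTable",
    "LIGAND_POSITIONS",
    "CANONICAL_GRAMMAR",
    "MIN_LINKER",
    "MAX_LINKER",
    "loop_matches",
    "scan_ef_hands",
    "pair_ef_hands",
    "loop_frequency_table",
    "flag_z_position_substitutions",
]


@dataclass
class EFHandLoop:
    """One detected 12-residue Ca2+-binding loop."""

    protein_id: str
    start: int  # 0-based index of loop position 1
    residues: str
    paired_with: int | None = None  # index of partner loop within the scan result
    ligand_positions: dict[int, str] = field(default_factory=lambda: dict(LIGAND_POSITIONS))

    def __post_init__(self) -> None:
        if len(self.residues) != LOOP_LEN:
            raise ValueError(
                f"{self.protein_id}: loop at {self.start} has {len(self.residues)} residues, expected {LOOP_LEN}"
            )

    @property
    def end(self) -> int:
        """Half-open end coordinate of the loop."""
        return self.start + LOOP_LEN

    @property
    def z_residue(self) -> str:
        """Residue at the -Z coordination position (loop position 12)."""
        return self.residues[11]

    @property
    def is_paired(self) -> bool:
        return self.paired_with is not None


def loop_matches(window: str, strictness: Literal["canonical", "relaxed"] = "canonical") -> bool:
    """True if a 12-mer satisfies the loop grammar."""
    if len(window) != LOOP_LEN:
        return False
    for pos, allowed in CANONICAL_GRAMMAR.items():
        if strictness == "relaxed" and pos == 9:
            continue
        if window[pos - 1] not in allowed:
            return False
    return True


def scan_ef_hands(
    protein: ProteinRecord,
    strictness: Literal["canonical", "relaxed"] = "canonical",
) -> list[EFHandLoop]:
    """Scan a protein for EF-hand loops, left to right.

    Overlapping candidate windows are resolved by keeping the leftmost
    match and resuming the scan after its end, reflecting that two
    physical 12-residue loops cannot overlap. Proteins shorter than 12
    residues yield an empty result.
    """
    if strictness not in ("canonical", "relaxed"):
        raise ValueError(f"unknown strictness {strictness!r}")
    seq = protein.seq
    loops: list[EFHandLoop] = []
    i = 0
    while i + LOOP_LEN <= len(seq):
        window = seq[i : i + LOOP_LEN]
        if loop_matches(window, strictness):
            loops.append(EFHandLoop(protein.id, i, window))
            i += LOOP_LEN
        else:
            i += 1
    return loops


def pair_ef_hands(
    loops: Sequence[EFHandLoop],
    min_linker: int = MIN_LINKER,
    max_linker: int = MAX_LINKER,
) -> list[EFHandLoop]:
    """Fill pairing status by greedy left-to-right pairing of adjacent loops.

    Two consecutive loops pair when the linker between them (next.start -
    prev.end) lies within ``[min_linker, max_linker]``. Each loop joins at
    most one pair; leftovers stay lone. Input must be sorted by start and
    come from a single protein.
    """
    starts = [lp.start for lp in loops]
    if starts != sorted(starts):
        raise ValueError("loops must be sorted by start position")
    if len({lp.protein_id for lp in loops}) > 1:
        raise ValueError("loops must come from a single protein")
    out = [replace(lp, paired_with=None) for lp in loops]
    i = 0
    while i + 1 < len(out):
        gap = out[i + 1].start - out[i].end
        if min_linker <= gap <= max_linker:
            out[i].paired_with = i + 1
            out[i + 1].paired_with = i
            i += 2
        else:
            i += 1
    return out


@dataclass
class LoopFrequencyTable:
    """Per-position residue counts over a loop collection, with consensus.

    ``consensus`` has one slot per loop position: the most frequent residue,
    followed in brackets by alternative residues whose frequency reaches the
    alternative threshold, or ``'x'`` where no residue is notably frequent.
    """

    counts: dict[int, dict[str, int]]
    n_loops: int
    consensus: list[str]


def loop_frequency_table(
    loops: Iterable[EFHandLoop],
    alt_threshold: float = 0.15,
) -> LoopFrequencyTable:
    """Tally residue occurrences per loop position and derive the consensus.

    The consensus residue is the argmax (ties broken alphabetically);
    alternatives are the other residues with frequency >= ``alt_threshold``,
    rendered in brackets. A position renders ``'x'`` when its top frequency
    is below both 0.5 and ``alt_threshold``.
    """
    loops = list(loops)
    if not loops:
        raise ValueError("cannot build a frequency table from zero loops")
    counters: dict[int, Counter] = {pos: Counter() for pos in range(1, LOOP_LEN + 1)}
    for lp in loops:
        for pos in range(1, LOOP_LEN + 1):
            counters[pos][lp.residues[pos - 1]] += 1
    n = len(loops)
    consensus: list[str] = []
    for pos in range(1, LOOP_LEN + 1):
        counter = counters[pos]
        top_aa = min(aa for aa, c in counter.items() if c == max(counter.values()))
        top_freq = counter[top_aa] / n
        if top_freq < 0.5 and top_freq < alt_threshold:
            consensus.append("x")
            continue
        alts = sorted(
            aa for aa, c in counter.items() if aa != top_aa and c / n >= alt_threshold
        )
        consensus.append(top_aa + (f"[{''.join(alts)}]" if alts else ""))
    counts = {pos: dict(sorted(counters[pos].items())) for pos in counters}
    return LoopFrequencyTable(counts=counts, n_loops=n, consensus=consensus)


def flag_z_position_substitutions(
    loops: Iterable[EFHandLoop],
) -> list[tuple[str, int]]:
    """Return (protein_id, loop index) for loops with an aspartate at -Z.

    The loop index counts loops per protein in scan order. A -Z aspartate
    replaces the canonical bidentate glutamate and shifts the site's ion
    preference toward Mg2+.
    """
    flagged: list[tuple[str, int]] = []
    per_protein: Counter = Counter()
    for lp in loops:
        idx = per_protein[lp.protein_id]
        per_protein[lp.protein_id] += 1
        if lp.z_residue == "D":
            flagged.append((lp.protein_id, idx))
    return flagged
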