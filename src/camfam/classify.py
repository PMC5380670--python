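"""CaM / CML family classification and the per-protein feature report.

A retained protein is one with at least ``retention_threshold`` percent
identity (default 23.00) to the reference CaM and no functional domains
other than the Ca2+-binding EF-hands. Retained proteins with four EF-hands
and high identity to the reference (default >= 60.00, sitting in the wide
empirical gap between true CaMs and the most CaM-like CMLs) are called
CaM; the remainder are calmodulin-like (CML).

Annotation features mirror the hallmarks used to describe plant CaMs:

* methionine content (Met-rich surfaces mediate target binding),
* a Cys27-equivalent: cysteine at loop position 7 (-Y) of the first
  EF-hand, typical of plant CaMs,
* a Lys116-equivalent: lysine aligned to reference position 116, the
  site of regulatory trimethylation,
* a putative N-myristoylation site at the N-terminal glycine, predicted
  by a rule-based sequence pattern (advisory only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from ._util import round_half_up
from .efhand import EFHandLoop, pair_ef_hands, scan_ef_hands
from .identity import AlignParams, global_align, identity_matrix
from .seqio import ProteinRecord

RETENTION_THRESHOLD = 23.00
CAM_THRESHOLD = 60.00

#: Rule for N-terminal myristoylation: after removing the initiator Met the
#: sequence must begin with Gly, followed by G-[^EDRKHPFYW]-x-x-[STAGCN]-[^P].
_MYR_PATTERN = re.compile(r"^G[^EDRKHPFYW]..[STAGCN][^P]")

__all__ = [
    "FamilyAssignment",
    "ClassifyConfig",
    "met_percentage",
    "has_cys27_equivalent",
    "has_lys116_equivalent",
    "predict_myristoylation",
    "classify_family",
    "table2_report",
    "RETENTION_THRESHOLD",
    "CAM_THRESHOLD",
]


@dataclass(frozen=True)
class ClassifyConfig:
    retention_threshold: float = RETENTION_THRESHOLD
    cam_threshold: float = CAM_THRESHOLD
    lys_ref_position: int = 116
    align_params: AlignParams = AlignParams()


@dataclass
class FamilyAssignment:
    """Feature vector and family call for one protein."""

    protein_id: str
    aa_len: int
    n_ef_hands: int
    n_pairs: int
    met_pct: float
    identity_to_ref: float
    cys27: bool
    lys116: bool
    myristoylation: bool
    family: str  # "CaM" | "CML" | "excluded"


def met_percentage(protein: ProteinRecord) -> float:
    """Percentage of methionine residues, two decimals half-up."""
    return round_half_up(100.0 * protein.seq.count("M") / len(protein.seq))


def has_cys27_equivalent(protein: ProteinRecord, loops: Sequence[EFHandLoop]) -> bool:
    """Cysteine at position 7 (-Y) of the first EF-hand loop.

    This is the residue equivalent to Cys27 of typical plant CaMs. False
    when the protein has no detected loops.
    """
    if not loops:
        return False
    first = min(loops, key=lambda lp: lp.start)
    return first.residues[6] == "C"


def has_lys116_equivalent(
    protein: ProteinRecord,
    ref: ProteinRecord,
    ref_position: int = 116,
    params: AlignParams = AlignParams(),
) -> bool:
    """Lysine aligned to the reference's 1-based ``ref_position``.

    The protein is globally aligned to the reference; the column carrying
    reference residue ``ref_position`` is inspected. Gaps count as absence.
    """
    if len(ref.seq) < ref_position:
        raise ValueError(
            f"reference {ref.id!r} has {len(ref.seq)} residues, "
            f"shorter than position {ref_position}"
        )
    aln = global_align(protein, ref, params)
    ref_count = 0
    for a_char, r_char in zip(aln.a_aln, aln.b_aln):
        if r_char != "-":
            ref_count += 1
            if ref_count == ref_position:
                return a_char == "K"
    raise AssertionError("reference position not reached in alignment")


def predict_myristoylation(protein: ProteinRecord) -> bool:
    """Rule-based prediction of an N-terminal myristoylation site.

    Requires an initiator Met followed by Gly (the acceptor), with the six
    residues after the Met matching a PROSITE-style consensus. The flag is
    advisory; it approximates dedicated predictors.
    """
    seq = protein.seq
    if len(seq) < 7 or not seq.startswith("MG"):
        return False
    return bool(_MYR_PATTERN.match(seq[1:]))


def classify_family(
    records: Sequence[ProteinRecord],
    ref: ProteinRecord,
    config: ClassifyConfig = ClassifyConfig(),
    external_domains: Mapping[str, Sequence[str]] | None = None,
) -> list[FamilyAssignment]:
    """Build the per-protein feature vector and CaM/CML/excluded call.

    ``external_domains`` optionally maps protein ids to annotated non-EF-hand
    functional domains; any protein carrying one is excluded, mirroring the
    restriction of the family to proteins that possess only the Ca2+-binding
    domain.
    """
    external_domains = external_domains or {}
    identities = identity_matrix(list(records), ref, config.align_params)
    out: list[FamilyAssignment] = []
    for rec in records:
        loops = pair_ef_hands(scan_ef_hands(rec, "canonical"))
        n_hands = len(loops)
        n_pairs = sum(1 for lp in loops if lp.is_paired) // 2
        ident = identities[rec.id]
        if ident < config.retention_threshold or external_domains.get(rec.id):
            family = "excluded"
        elif ident >= config.cam_threshold and n_hands == 4:
            family = "CaM"
        else:
            family = "CML"
        out.append(
            FamilyAssignment(
                protein_id=rec.id,
                aa_len=len(rec.seq),
                n_ef_hands=n_hands,
                n_pairs=n_pairs,
                met_pct=met_percentage(rec),
                identity_to_ref=ident,
                cys27=has_cys27_equivalent(rec, loops),
                lys116=has_lys116_equivalent(
                    rec, ref, config.lys_ref_position, config.align_params
                ),
                myristoylation=predict_myristoylation(rec),
                family=family,
            )
        )
    return out


def table2_report(assignments: Iterable[FamilyAssignment]) -> list[dict[str, object]]:
    """Rows for the per-protein characteristics table (TSV-ready).

    Boolean features are encoded ``+`` / ``-`` as in the printed family
    censuses this report mirrors.
    """
    rows: list[dict[str, object]] = []
    for a in assignments:
        rows.append(
            {
                "name": a.protein_id,
                "aa_len": a.aa_len,
                "ef_hands": a.n_ef_hands,
                "met_pct": a.met_pct,
                "identity": a.identity_to_ref,
                "cys27": a.cys27,
                "lys116": a.lys116,
                "myristoylation": a.myristoylation,
                "family": a.family,
            }
        )
    return rows
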