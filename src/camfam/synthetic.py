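"""Seeded generators for every input the pipeline consumes, with ground truth.

The cohort generator emulates the composition of a legume CaM/CML family
census at desk scale:

* a 149-residue reference CaM with four canonical EF-hand loops arranged
  as two pairs, a Cys at loop-1 position 7 (the Cys27 hallmark), a Lys at
  residue 116 and ~6% methionine;
* CaM isoforms derived from the reference by exact substitution counts
  (and, for the longer isoforms, one insertion), so their percent identity
  to the reference is known in closed form;
* 19 CML-like proteins whose loop counts (summing to 55), lengths and
  target identities follow the published family census structure: one to
  four loops including lone hands and -Z aspartate substitutions,
  identities in the 23.91-42.45% band;
* decoy proteins below the 23% retention band with no canonical loops.

Background residues are drawn from an alphabet without aspartate, so no
window outside an implanted loop can satisfy the loop grammar (which
requires D at position 1): implanted-motif recovery is exact by
construction. The background also lacks C, K and M, so the Cys27, Lys116
and methionine features are controlled solely by where the generator
places them.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionAtlas, QPCRExperiment
from .gene_structure import GeneModel
from .identity import percent_identity_pair
from .seqio import NucleotideRecord, ProteinRecord

#: Background alphabet: no D (grammar anchor), no C/K/M (feature residues).
BACKGROUND = "AEFGHILNPQRSTVWY"

REF_LOOP_STARTS = (20, 44, 88, 112)
LOOP1_CAM = "DKDGDGCITTKE"  # Cys at loop position 7 -> Cys27 hallmark
LOOP1_CML = "DKDGDGTITTKE"  # the CML version lacks it
LOOP2 = "DKDGNGTIDFPE"
LOOP3 = "DKDGNGYISAAE"
LOOP4 = "DIDKDGQVNYEE"  # Lys at loop position 4 -> residue 116 when start=112
REF_LEN = 149
MET_POSITIONS = (2, 7, 34, 60, 70, 80, 104, 130, 140)
LYS116_INDEX = 115  # 0-based; inside loop 4

#: Per-CML plan mirroring a 19-member census: (n_loops, length, identity %,
#: z-substitution on the last loop, myristoylated).
CML_PLAN: list[tuple[int, int, float, bool, bool]] = [
    (4, 139, 42.45, False, False),
    (4, 158, 40.28, False, False),
    (4, 140, 40.00, False, False),
    (4, 217, 39.86, False, False),
    (4, 187, 39.86, False, False),
    (3, 199, 38.16, True, False),
    (2, 111, 35.71, False, False),
    (4, 138, 35.11, False, False),
    (3, 139, 34.56, True, False),
    (3, 140, 34.31, True, False),
    (2, 117, 32.10, False, False),
    (2, 115, 31.58, True, False),
    (3, 237, 31.51, False, False),
    (1, 187, 30.67, False, True),
    (3, 147, 30.61, True, False),
    (2, 181, 30.20, False, False),
    (3, 146, 28.17, True, False),
    (3, 134, 27.27, False, True),
    (1, 172, 23.91, False, False),
]

MYR_START = "MGQFASV"  # satisfies the myristoylation rule

__all__ = [
    "GeneratorConfig",
    "reference_cam",
    "mutate_background",
    "insert_residue",
    "make_cam_cohort",
    "make_gene_locus",
    "random_cds",
    "make_atlas",
    "make_qpcr",
    "CML_PLAN",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generator settings (defaults mirror the census scale)."""

    seed: int = 0
    cam_mismatch_counts: tuple[int, ...] = (2,)  # substitution-only isoforms
    cam_indel_counts: tuple[int, ...] = (31, 31)  # 150-aa isoforms: 1 insertion + k subs
    n_decoy: int = 3
    decoy_len: int = 120
    cml_plan: tuple = tuple(CML_PLAN)


def _loop_starts(n_loops: int, lone_only: bool = False) -> tuple[int, ...]:
    """Loop start offsets for an architecture with ``n_loops`` hands.

    1 loop: lone; 2 loops: a pair (or two lone hands if ``lone_only``);
    3 loops: a pair plus a lone C-terminal hand; 4 loops: two pairs.
    """
    if n_loops == 1:
        return (20,)
    if n_loops == 2:
        return (20, 88) if lone_only else (20, 44)
    if n_loops == 3:
        return (20, 44, 88)
    if n_loops == 4:
        return REF_LOOP_STARTS
    raise ValueError(f"unsupported loop count {n_loops}")


def reference_cam(rng: np.random.Generator, protein_id: str = "CaM1") -> ProteinRecord:
    """The synthetic two-pair reference CaM (149 aa, 4 canonical loops)."""
    seq = [str(rng.choice(list(BACKGROUND))) for _ in range(REF_LEN)]
    for start, loop in zip(REF_LOOP_STARTS, (LOOP1_CAM, LOOP2, LOOP3, LOOP4)):
        seq[start : start + 12] = list(loop)
    for pos in MET_POSITIONS:
        seq[pos] = "M"
    record = ProteinRecord(protein_id, "".join(seq))
    assert record.seq[LYS116_INDEX] == "K"
    return record


def _background_indices(length: int, loop_starts: Sequence[int]) -> list[int]:
    """Indices outside loops, the Lys116 site, Met sites and the N-terminal 7."""
    in_loop = set()
    for s in loop_starts:
        in_loop.update(range(s, s + 12))
    return [
        i
        for i in range(7, length)
        if i not in in_loop and i != LYS116_INDEX and i not in MET_POSITIONS
    ]


def mutate_background(
    record: ProteinRecord,
    k: int,
    rng: np.random.Generator,
    new_id: str,
    exclude: Sequence[int] = (),
) -> ProteinRecord:
    """Copy with exactly ``k`` substitutions at background positions.

    Substitutions avoid loops, feature residues and ``exclude``; each new
    residue is drawn from the background alphabet and differs from the
    original, so the mismatch count is exact.
    """
    candidates = [
        i for i in _background_indices(len(record.seq), REF_LOOP_STARTS)
        if i not in set(exclude)
    ]
    if k > len(candidates):
        raise ValueError(
            f"{new_id}: {k} mismatches requested but only {len(candidates)} "
            "background positions available"
        )
    seq = list(record.seq)
    for i in rng.choice(len(candidates), size=k, replace=False):
        pos = candidates[int(i)]
        choices = [c for c in BACKGROUND if c != seq[pos]]
        seq[pos] = str(rng.choice(choices))
    return ProteinRecord(new_id, "".join(seq))


def insert_residue(record: ProteinRecord, pos: int, residue: str, new_id: str) -> ProteinRecord:
    """Copy with one residue inserted before 0-based ``pos``."""
    return ProteinRecord(new_id, record.seq[:pos] + residue + record.seq[pos:])


def _make_cml(
    idx: int,
    plan: tuple[int, int, float, bool, bool],
    ref: ProteinRecord,
    rng: np.random.Generator,
) -> tuple[ProteinRecord, dict]:
    n_loops, length, target_pct, z_sub, myristoylated = plan
    lone_only = n_loops == 2 and z_sub  # the two-separate-hands architecture
    starts = _loop_starts(n_loops, lone_only=lone_only)
    templates = {20: LOOP1_CML, 44: LOOP2, 88: LOOP3, 112: LOOP4}

    len_shorter = min(length, REF_LEN)
    m_target = int(np.floor(target_pct * len_shorter / 100.0 + 0.5))
    # Identical columns contributed by loops vs the reference: each kept loop
    # matches its reference counterpart except loop-1 position 7 (no Cys) and
    # a -Z substitution if present.
    loop_identical = 12 * n_loops - 1 - (1 if z_sub else 0)
    # Lone-only architecture places hand 2 at 88 where the reference has
    # loop 3; the templates differ there (LOOP3 vs LOOP3) -- same template,
    # so no further correction is needed.
    n_conserved = m_target - loop_identical
    if n_conserved < 0:
        raise ValueError(f"CML{idx}: target identity below loop-only identity")

    # Conserved positions may copy neither the CML's own loops nor any
    # reference loop region: a reference loop copied piecewise into the
    # background could re-create a canonical loop the architecture does
    # not call for (the background alphabet supplies no aspartate, so
    # loops can arise only where reference loop residues are copied).
    off_limits = set()
    for s in set(starts) | set(REF_LOOP_STARTS):
        off_limits.update(range(s, s + 12))
    candidates = [
        i
        for i in range(7, min(length, REF_LEN))
        if i not in off_limits and i != LYS116_INDEX and i not in MET_POSITIONS
    ]
    if n_conserved > len(candidates):
        raise ValueError(f"CML{idx}: cannot conserve {n_conserved} positions")
    conserved = {
        candidates[int(i)]
        for i in rng.choice(len(candidates), size=n_conserved, replace=False)
    }

    seq: list[str] = []
    for i in range(length):
        if i < REF_LEN and i in conserved:
            seq.append(ref.seq[i])
        elif i < REF_LEN:
            # Differ from the reference so conserved count is exact.
            choices = [c for c in BACKGROUND if c != ref.seq[i]]
            seq.append(str(rng.choice(choices)))
        else:
            seq.append(str(rng.choice(list(BACKGROUND))))
    for s in starts:
        seq[s : s + 12] = list(templates[s])
    if z_sub:
        seq[starts[-1] + 11] = "D"
    if myristoylated:
        seq[: len(MYR_START)] = list(MYR_START)

    record = ProteinRecord(f"CML{idx}", "".join(seq))
    # Pairing truth follows the architecture: (20,44) and (88,112) pair,
    # a hand at 88 without 112 is lone, and the lone-only layout pairs none.
    paired: list[bool] = []
    for s in starts:
        if s == 20:
            paired.append(44 in starts)
        elif s == 44:
            paired.append(True)
        elif s == 88:
            paired.append(112 in starts and not lone_only)
        else:
            paired.append(True)
    if lone_only:
        paired = [False] * len(starts)
    truth = {
        "family": "CML",
        "loop_starts": list(starts),
        "paired": paired,
        "z_sub_loops": [len(starts) - 1] if z_sub else [],
        "target_identity": target_pct,
        "cys27": False,
        "lys116": 112 in starts,
        "myristoylation": myristoylated,
    }
    return record, truth


def make_cam_cohort(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[list[ProteinRecord], dict[str, dict]]:
    """Generate the full protein cohort plus a per-protein truth table.

    Returns records in order: reference CaM, CaM isoforms, CMLs, decoys.
    Truth records family, loop offsets, pairing, -Z substitutions and the
    annotation flags each protein was built to carry.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    truth: dict[str, dict] = {}

    ref = reference_cam(rng)
    records.append(ref)
    truth[ref.id] = {
        "family": "CaM",
        "loop_starts": list(REF_LOOP_STARTS),
        "paired": [True, True, True, True],
        "z_sub_loops": [],
        "target_identity": 100.0,
        "cys27": True,
        "lys116": True,
        "myristoylation": False,
        "is_reference": True,
    }

    iso = 2
    for k in config.cam_mismatch_counts:
        rec = mutate_background(ref, k, rng, f"CaM{iso}")
        records.append(rec)
        truth[rec.id] = {
            "family": "CaM",
            "loop_starts": list(REF_LOOP_STARTS),
            "paired": [True, True, True, True],
            "z_sub_loops": [],
            "n_mismatches": k,
            "target_identity": round(100.0 * (REF_LEN - k) / REF_LEN, 2),
            "cys27": True,
            "lys116": True,
            "myristoylation": False,
        }
        iso += 1
    for k in config.cam_indel_counts:
        # 150-aa isoform: one insertion in the C-terminal tail plus k
        # substitutions kept away from the insertion point, so the identity
        # to the reference is (149 - k) / 149.
        mutated = mutate_background(ref, k, rng, f"CaM{iso}", exclude=range(125, 136))
        rec = insert_residue(mutated, 130, "W", f"CaM{iso}")
        records.append(rec)
        truth[rec.id] = {
            "family": "CaM",
            "loop_starts": list(REF_LOOP_STARTS),
            "paired": [True, True, True, True],
            "z_sub_loops": [],
            "n_mismatches": k,
            "target_identity": round(100.0 * (REF_LEN - k) / REF_LEN, 2),
            "cys27": True,
            "lys116": True,
            "myristoylation": False,
        }
        iso += 1

    for i, plan in enumerate(config.cml_plan, start=1):
        rec, t = _make_cml(i, plan, ref, rng)
        records.append(rec)
        truth[rec.id] = t

    for d in range(1, config.n_decoy + 1):
        for _attempt in range(50):
            seq = "".join(
                str(rng.choice(list(BACKGROUND))) for _ in range(config.decoy_len)
            )
            rec = ProteinRecord(f"DECOY{d}", seq)
            if percent_identity_pair(rec, ref) < 23.0:
                break
        else:  # pragma: no cover - background decoys sit far below the band
            raise RuntimeError(f"could not sample decoy {d} below the retention band")
        records.append(rec)
        truth[rec.id] = {
            "family": "excluded",
            "loop_starts": [],
            "paired": [],
            "z_sub_loops": [],
            "cys27": False,
            "lys116": False,
            "myristoylation": False,
        }

    return records, truth


# ---------------------------------------------------------------------------
# Gene loci


_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(n_residues: int, rng: np.random.Generator, gene_id: str = "gene") -> NucleotideRecord:
    """A random CDS: ATG, ``n_residues - 1`` random sense codons, TAA stop."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    codons = ["ATG"] + [
        _CODONS[int(i)] for i in rng.integers(0, len(_CODONS), size=n_residues - 1)
    ] + ["TAA"]
    return NucleotideRecord(gene_id, "".join(codons), kind="cdna")


def make_gene_locus(
    cdna: NucleotideRecord,
    intron_specs: Sequence[tuple[int, int, int]],
    rng: np.random.Generator,
    min_exon: int = 10,
) -> tuple[NucleotideRecord, GeneModel]:
    """Interleave GT..AG introns into a cDNA at specified codon positions.

    ``intron_specs`` is a list of (codon_index, phase, intron_length):
    the intron is inserted after ``(codon_index - 1) * 3 + phase`` exonic
    nucleotides. Intron interiors are drawn from {C, T} only, so they can
    contain no internal GT or AG decoy boundaries. Returns the genomic
    record and the ground-truth gene model.
    """
    points = [(ci - 1) * 3 + ph for ci, ph, _ln in intron_specs]
    lengths = [ln for _ci, _ph, ln in intron_specs]
    if any(ln < 6 for ln in lengths):
        raise ValueError("intron length must be >= 6 (GT + interior + AG)")
    if sorted(points) != points or len(set(points)) != len(points):
        raise ValueError("intron specs must be sorted and non-overlapping")
    if any(p <= 0 or p >= len(cdna.seq) for p in points):
        raise ValueError("intron codon positions fall outside the CDS")
    bounds = [0] + points + [len(cdna.seq)]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
    if any(el < min_exon for el in exon_lens):
        raise ValueError(f"intron spacing leaves an exon shorter than {min_exon} nt")

    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    gpos = 0
    for i, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
        pieces.append(cdna.seq[start:end])
        exons.append((gpos, gpos + end - start))
        gpos += end - start
        if i < len(points):
            interior = "".join(
                "CT"[int(b)] for b in rng.integers(0, 2, size=lengths[i] - 4)
            )
            pieces.append("GT" + interior + "AG")
            introns.append((gpos, gpos + lengths[i]))
            gpos += lengths[i]
    genomic = NucleotideRecord(cdna.id + "_genomic", "".join(pieces), kind="genomic")
    model = GeneModel(cdna.id, exons=exons, introns=introns)
    assert model.spliced(genomic.seq) == cdna.seq
    return genomic, model


# ---------------------------------------------------------------------------
# Expression


def make_atlas(
    n_genes: int,
    organs: Sequence[str],
    planted: dict[str, str] | int,
    rng: np.random.Generator,
    effect: float = 10.0,
) -> tuple[ExpressionAtlas, dict[str, str]]:
    """Log-normal baseline atlas with planted organ-specific genes.

    ``planted`` maps gene ids to their specific organ, or is an integer
    count of genes to plant (assigned to organs round-robin). The planted
    organ's value is multiplied by ``effect`` (> 1).
    """
    if effect <= 1.0:
        raise ValueError("effect size must exceed 1")
    if len(organs) < 2:
        raise ValueError("need at least two organs")
    genes = [f"G{i + 1}" for i in range(n_genes)]
    if isinstance(planted, int):
        planted = {
            genes[i]: organs[i % len(organs)] for i in range(min(planted, n_genes))
        }
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in atlas: {sorted(unknown)}")
    values = rng.lognormal(mean=np.log(200.0), sigma=0.5, size=(n_genes, len(organs)))
    df = pd.DataFrame(values, index=genes, columns=list(organs))
    for gene, organ in planted.items():
        df.loc[gene, organ] *= effect
    return ExpressionAtlas(df), dict(planted)


def make_qpcr(
    fold: float,
    sigma: float,
    rng: np.random.Generator,
    n_bio: int = 3,
    n_tech: int = 3,
    target_baseline: float = 25.0,
    reference_baseline: float = 20.0,
) -> tuple[QPCRExperiment, float]:
    """Ct table for one target/reference pair with a known true fold change.

    Treated-condition target Ct values are shifted by -log2(fold) relative
    to control (one cycle less per doubling); Gaussian noise of standard
    deviation ``sigma`` is added per technical replicate. Returns the
    experiment and the true fold.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rows = []
    for condition in ("control", "treated"):
        shift = -np.log2(fold) if condition == "treated" else 0.0
        for gene, base in (("target", target_baseline + shift), ("reference", reference_baseline)):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct": base + float(rng.normal(0.0, sigma)) if sigma else base,
                        }
                    )
    exp = QPCRExperiment(pd.DataFrame(rows))
    return exp, fold
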