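"""Class I/II typing, catalytic-histidine-loop analysis, and pI profiling.

PET hydrolases fall into two sequence classes: class I enzymes (e.g. the
thermophilic cutinases TfH and LCC) lack the extra disulfide bond and the
extra residues that follow the gatekeeper serine in the catalytic
histidine loop, while class II enzymes (IsPETase, PE-H) carry both.  This
module decides the class from an alignment against a reference, extracts
the loop architecture around the catalytic histidine (insertion blocks
and the residue adjacent to His), and computes Henderson-Hasselbalch net
charge and isoelectric points from per-group pKa tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

from .sequence_core import (
    Alignment,
    InsertionBlock,
    ProteinRecord,
    SubstitutionMatrix,
    align_pair,
    _insertion_blocks,
)

__all__ = [
    "ClassCriteria",
    "ClassReport",
    "LoopReport",
    "PhysChemProfile",
    "PkaSet",
    "BJELLQVIST",
    "EMBOSS",
    "classify_type",
    "loop_architecture",
    "net_charge",
    "isoelectric_point",
    "physchem_profile",
]


# ---------------------------------------------------------------------------
# pKa tables


@dataclass(frozen=True)
class PkaSet:
    """Per-group pKa values for the simple titration charge model.

    Basic groups (positive below their pKa): K, R, H side chains and the
    N-terminal amine.  Acidic groups (negative above their pKa): D, E, C,
    Y side chains and the C-terminal carboxyl.
    """

    name: str
    n_term: float
    c_term: float
    side: dict[str, float]

    BASIC = frozenset({"K", "R", "H"})
    ACIDIC = frozenset({"D", "E", "C", "Y"})


#: Single-value Bjellqvist-style table (the convention behind the common
#: "theoretical pI" web calculators).
BJELLQVIST = PkaSet(
    name="bjellqvist",
    n_term=7.5,
    c_term=3.55,
    side={"K": 10.0, "R": 12.0, "H": 5.98, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
)

#: EMBOSS iep defaults.
EMBOSS = PkaSet(
    name="emboss",
    n_term=8.6,
    c_term=3.6,
    side={"K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
)


def net_charge(seq: str | ProteinRecord, pH: float, pka_set: PkaSet = BJELLQVIST) -> float:
    """Net charge (elementary charges) of a protein at a given pH.

    charge = sum over basic groups of 1/(1+10^(pH-pKa))
           - sum over acidic groups of 1/(1+10^(pKa-pH)),
    with the N-/C-termini always contributing.  Unknown residue letters
    contribute nothing (with a warning), so 'X' is tolerated.
    """
    if isinstance(seq, ProteinRecord):
        seq = seq.seq
    if not 0 <= pH <= 14:
        raise ValueError("pH must be in [0, 14]")
    if not seq:
        raise ValueError("empty sequence")
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka_set.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pka_set.c_term - pH))
    known = PkaSet.BASIC | PkaSet.ACIDIC
    unknown = set()
    for r in seq:
        if r in PkaSet.BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka_set.side[r]))
        elif r in PkaSet.ACIDIC:
            charge -= 1.0 / (1.0 + 10.0 ** (pka_set.side[r] - pH))
        elif r not in known and r not in "ACDEFGHIKLMNPQRSTVWY":
            unknown.add(r)
    if unknown:
        warnings.warn(f"residues {sorted(unknown)} are not ionizable and were ignored")
    return charge


def isoelectric_point(
    seq: str | ProteinRecord, pka_set: PkaSet = BJELLQVIST, tol: float = 1e-3
) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH and the termini
    guarantee a sign change on [0, 14], so the root exists and is unique.
    """
    f = lambda ph: net_charge(seq, ph, pka_set)
    return float(bisect(f, 0.0, 14.0, xtol=tol))


@dataclass(frozen=True)
class PhysChemProfile:
    """Length, pI, charge-vs-pH samples, and residue-class fractions."""

    candidate_id: str
    length: int
    pI: float
    charge_at: dict[float, float]
    acidic_fraction: float
    basic_fraction: float


def physchem_profile(
    record: ProteinRecord,
    pka_set: PkaSet = BJELLQVIST,
    ph_grid: tuple[float, ...] = (5.0, 6.0, 7.0, 7.5, 8.0, 9.0),
) -> PhysChemProfile:
    """Summary physicochemical profile of one sequence."""
    n = len(record)
    acidic = sum(record.seq.count(r) for r in "DE")
    basic = sum(record.seq.count(r) for r in "KRH")
    return PhysChemProfile(
        candidate_id=record.id,
        length=n,
        pI=round(isoelectric_point(record, pka_set), 2),
        charge_at={ph: net_charge(record, ph, pka_set) for ph in ph_grid},
        acidic_fraction=acidic / n,
        basic_fraction=basic / n,
    )


# ---------------------------------------------------------------------------
# Class I/II typing


@dataclass(frozen=True)
class ClassCriteria:
    """Alignment-anchored diagnostics separating class I from class II.

    All positions are 1-based on the reference (IsPETase full-length
    numbering by default): the gatekeeper serine S238 whose following
    columns are examined for extra loop residues, the catalytic His H237
    that must map for the candidate to be classifiable, and the two
    cysteines of the class-II extra disulfide (C203/C239).
    """

    gatekeeper_pos: int = 238
    his_pos: int = 237
    disulfide_pair: tuple[int, int] = (203, 239)
    insertion_window: int = 10
    reference_extra_residues: int = 3

    def __post_init__(self) -> None:
        if self.insertion_window < 1:
            raise ValueError("insertion_window must be >= 1")
        if min(self.gatekeeper_pos, self.his_pos, *self.disulfide_pair) < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.reference_extra_residues < 0:
            raise ValueError("reference_extra_residues must be >= 0")


@dataclass(frozen=True)
class ClassReport:
    candidate_id: str
    has_disulfide: bool
    extra_residue_count: int
    assigned_class: str  # "I" or "II"
    evidence: dict[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class LoopReport:
    """Catalytic-histidine-loop architecture of one candidate."""

    candidate_id: str
    his_pos_candidate: int
    adjacent_residue: str | None
    insertion_blocks: tuple[InsertionBlock, ...]


def _blocks_in_window(
    aln: Alignment, start_ref: int, end_ref: int
) -> list[InsertionBlock]:
    """Insertion blocks (candidate runs over reference gaps) anchored in a window."""
    return [
        b for b in _insertion_blocks(aln) if start_ref <= b.anchor <= end_ref
    ]


def classify_type(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    criteria: ClassCriteria = ClassCriteria(),
    matrix: SubstitutionMatrix | None = None,
) -> ClassReport:
    """Assign class I or II from disulfide and loop-insertion diagnostics.

    Class II iff the candidate has cysteines at both aligned disulfide
    positions AND at least one residue in the loop window after the
    gatekeeper beyond the canonical class-I loop length; class I
    otherwise.  The extra-residue count is measured relative to class I:
    ``criteria.reference_extra_residues`` states how many extras the
    alignment reference itself carries (3 for IsPETase, a class II
    enzyme; 0 for a class I reference), and candidate insertions add to /
    deletions subtract from that baseline within the window.  A candidate
    whose catalytic His does not map through the alignment is not
    classifiable.
    """
    if max(criteria.gatekeeper_pos, criteria.his_pos, *criteria.disulfide_pair) > len(
        reference
    ):
        raise ValueError("criteria positions exceed reference length")
    aln = align_pair(reference, candidate, matrix, mode="global")
    posmap = {pa: pb for pa, pb in aln.position_map() if pa is not None}

    his_cand = posmap.get(criteria.his_pos)
    if his_cand is None or candidate.residue(his_cand) != "H":
        raise ValueError(
            f"{candidate.id!r}: catalytic His at reference {criteria.his_pos} "
            "does not map to H; not classifiable"
        )

    cys_positions = {}
    has_disulfide = True
    for ref_pos in criteria.disulfide_pair:
        cand_pos = posmap.get(ref_pos)
        res = candidate.residue(cand_pos) if cand_pos is not None else None
        cys_positions[ref_pos] = (cand_pos, res)
        if res != "C":
            has_disulfide = False

    window_end = min(criteria.gatekeeper_pos + criteria.insertion_window, len(reference))
    blocks = _blocks_in_window(aln, criteria.gatekeeper_pos, window_end)
    inserted = sum(b.length for b in blocks)
    deleted = sum(
        1
        for pa, pb in aln.position_map()
        if pa is not None and pb is None and criteria.gatekeeper_pos < pa <= window_end
    )
    extra = max(0, criteria.reference_extra_residues + inserted - deleted)

    assigned = "II" if (has_disulfide and extra >= 1) else "I"
    return ClassReport(
        candidate_id=candidate.id,
        has_disulfide=has_disulfide,
        extra_residue_count=extra,
        assigned_class=assigned,
        evidence={
            "his_pos_candidate": his_cand,
            "disulfide": cys_positions,
            "insertion_blocks": blocks,
            "deleted_in_window": deleted,
            "window": (criteria.gatekeeper_pos, window_end),
        },
    )


def loop_architecture(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    his_anchor: int,
    window: int = 10,
    matrix: SubstitutionMatrix | None = None,
) -> LoopReport:
    """Map the catalytic His and find loop insertions after it.

    Insertion blocks are runs of candidate residues aligned to reference
    gaps whose anchor falls in ``[his_anchor, his_anchor + window]``
    reference columns; the residue adjacent to the candidate His (His+1)
    is reported because bulky residues there restrict loop mobility.
    """
    if not 1 <= his_anchor <= len(reference):
        raise ValueError("his_anchor outside reference")
    end = his_anchor + window
    if end > len(reference):
        warnings.warn("insertion window truncated at reference end")
        end = len(reference)
    aln = align_pair(reference, candidate, matrix, mode="global")
    posmap = {pa: pb for pa, pb in aln.position_map() if pa is not None}
    his_cand = posmap.get(his_anchor)
    if his_cand is None or candidate.residue(his_cand) != "H":
        raise ValueError(
            f"{candidate.id!r}: reference position {his_anchor} does not map to H"
        )
    adjacent = (
        candidate.residue(his_cand + 1) if his_cand + 1 <= len(candidate) else None
    )
    blocks = tuple(_blocks_in_window(aln, his_anchor, end))
    return LoopReport(
        candidate_id=candidate.id,
        his_pos_candidate=his_cand,
        adjacent_residue=adjacent,
        insertion_blocks=blocks,
    )
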