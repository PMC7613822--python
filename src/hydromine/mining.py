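"""Homolog retrieval and catalytic-triad mapping/filtering.

This stage emulates the front of a metagenomic serine-hydrolase discovery
workflow: score every sequence of a protein collection against a query
(either a single reference enzyme or a profile built from an alignment of
references), keep hits above a normalized-score threshold, then map the
reference catalytic anchors (Ser nucleophile, Asp/Glu acid, His base)
through a global alignment onto each hit and keep only candidates whose
triad is intact.

The profile is a plain log-odds position-specific scoring matrix (PSSM)
scanned gap-free — a deliberately simple surrogate for a full profile-HMM
search, with an explicit, configurable threshold instead of E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_core import (
    AMINO_ACIDS,
    Alignment,
    ProteinRecord,
    SubstitutionMatrix,
    align_pair,
)

SCORE_FLOOR = -20.0  # cap for log-odds of unseen residues at pseudocount -> 0

__all__ = [
    "TriadSpec",
    "Pssm",
    "HitList",
    "TriadMap",
    "build_pssm",
    "search_homologs",
    "map_triad",
    "filter_triad",
]


@dataclass(frozen=True)
class TriadSpec:
    """Catalytic-triad anchor positions on a full-length reference.

    Positions are 1-based and include any signal peptide, matching how
    residues such as S160/D206/H237 are numbered on IsPETase.  The acid
    position accepts Asp or Glu by default (``strict_asp`` narrows it to
    Asp only).
    """

    reference_id: str
    ser_pos: int
    asp_pos: int
    his_pos: int
    allowed_ser: frozenset[str] = frozenset({"S"})
    allowed_asp: frozenset[str] = frozenset({"D", "E"})
    allowed_his: frozenset[str] = frozenset({"H"})
    reference: ProteinRecord | None = None

    def __post_init__(self) -> None:
        if not self.ser_pos < self.asp_pos < self.his_pos:
            raise ValueError("triad positions must be strictly increasing (ser < asp < his)")
        if min(self.ser_pos, self.asp_pos, self.his_pos) < 1:
            raise ValueError("triad positions are 1-based and must be >= 1")
        if self.reference is not None:
            if self.reference.id != self.reference_id:
                raise ValueError("reference record id does not match reference_id")
            if self.his_pos > len(self.reference):
                raise ValueError("triad positions exceed reference length")
            for pos, allowed, name in (
                (self.ser_pos, self.allowed_ser, "ser"),
                (self.asp_pos, self.allowed_asp, "asp"),
                (self.his_pos, self.allowed_his, "his"),
            ):
                res = self.reference.residue(pos)
                if res not in allowed:
                    raise ValueError(
                        f"reference residue {res!r} at {name} position {pos} "
                        f"not in allowed set {sorted(allowed)}"
                    )

    def strict_asp(self) -> "TriadSpec":
        """Variant accepting only Asp (not Glu) at the acid position."""
        return TriadSpec(
            self.reference_id,
            self.ser_pos,
            self.asp_pos,
            self.his_pos,
            self.allowed_ser,
            frozenset({"D"}),
            self.allowed_his,
            self.reference,
        )


@dataclass(frozen=True)
class Pssm:
    """Log-odds position-specific scoring matrix over ungapped columns."""

    columns: tuple[dict[str, float], ...]
    background: dict[str, float]
    pseudocount: float

    def __post_init__(self) -> None:
        total = sum(self.background.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"background frequencies sum to {total}, expected 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return len(self.columns)

    def max_score(self) -> float:
        return sum(max(col.values()) for col in self.columns)

    def score_window(self, window: str) -> float:
        if len(window) != len(self.columns):
            raise ValueError("window length does not match PSSM length")
        return sum(col.get(r, SCORE_FLOOR) for col, r in zip(self.columns, window))

    def best_placement(self, seq: str) -> tuple[float, int]:
        """Best gap-free sliding-window score and its 1-based offset.

        Sequences shorter than the profile are scored once, padded
        conceptually with floor-scoring positions.
        """
        w = len(self.columns)
        if len(seq) < w:
            short = sum(
                col.get(r, SCORE_FLOOR) for col, r in zip(self.columns, seq)
            ) + SCORE_FLOOR * (w - len(seq))
            return short, 1
        best, best_off = -math.inf, 1
        for off in range(len(seq) - w + 1):
            s = self.score_window(seq[off : off + w])
            if s > best:
                best, best_off = s, off + 1
        return best, best_off


@dataclass(frozen=True)
class HitList:
    """Homolog hits ordered by descending normalized score."""

    query_id: str
    hits: tuple[tuple[str, float], ...]
    threshold: float

    def __post_init__(self) -> None:
        scores = [s for _, s in self.hits]
        if any(s < self.threshold for s in scores):
            raise ValueError("hit below threshold")
        if any(a < b for a, b in zip(scores[1:], scores)) and scores != sorted(
            scores, reverse=True
        ):
            raise ValueError("hits not sorted by descending score")

    def ids(self) -> list[str]:
        return [h for h, _ in self.hits]

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class TriadMap:
    """Where the reference triad anchors land on one candidate."""

    candidate_id: str
    ser_pos: int | None
    asp_pos: int | None
    his_pos: int | None
    ser_res: str | None
    asp_res: str | None
    his_res: str | None
    verdict: bool


def uniform_background() -> dict[str, float]:
    return {a: 1.0 / len(AMINO_ACIDS) for a in AMINO_ACIDS}


def build_pssm(
    reference_alignment: Sequence[str],
    pseudocount: float = 1.0,
    background: dict[str, float] | None = None,
    max_gap_fraction: float = 0.5,
) -> Pssm:
    """Build a log-odds PSSM from gapped, equal-length reference sequences.

    Column score for residue ``r`` is
    ``log2(((count_r + pc * bg_r) / (n_eff + pc)) / bg_r)`` where ``n_eff``
    is the number of non-gap residues in the column.  Columns with more
    than ``max_gap_fraction`` gaps are dropped.
    """
    if len(reference_alignment) < 2:
        raise ValueError("PSSM needs >= 2 aligned sequences; use a pairwise search for one")
    length = len(reference_alignment[0])
    if any(len(s) != length for s in reference_alignment):
        raise ValueError("aligned reference sequences differ in length")
    bg = background or uniform_background()
    columns: list[dict[str, float]] = []
    n = len(reference_alignment)
    for i in range(length):
        col = [s[i] for s in reference_alignment]
        gaps = col.count("-")
        if gaps / n > max_gap_fraction:
            continue
        residues = [r for r in col if r != "-"]
        n_eff = len(residues)
        scores: dict[str, float] = {}
        for r in AMINO_ACIDS:
            count = residues.count(r)
            p = (count + pseudocount * bg[r]) / (n_eff + pseudocount)
            scores[r] = max(math.log2(p / bg[r]), SCORE_FLOOR)
        columns.append(scores)
    return Pssm(tuple(columns), dict(bg), float(pseudocount))


def search_homologs(
    db: Sequence[ProteinRecord],
    query: Pssm | ProteinRecord,
    threshold: float = 0.25,
    matrix: SubstitutionMatrix | None = None,
) -> HitList:
    """Score every database sequence against the query; keep hits >= threshold.

    Sequence queries are scored by local alignment, normalized by the query
    self-alignment score (so the query itself scores exactly 1.0).  PSSM
    queries use the best gap-free placement, normalized by the profile's
    maximum attainable score.  Ties are broken by candidate id.
    """
    if not db:
        raise ValueError("database is empty")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    scored: list[tuple[str, float]] = []
    if isinstance(query, Pssm):
        qid = "pssm"
        denom = query.max_score()
        if denom <= 0:
            raise ValueError("degenerate PSSM: non-positive maximum score")
        for rec in db:
            s, _ = query.best_placement(rec.seq)
            scored.append((rec.id, s / denom))
    else:
        qid = query.id
        self_score = align_pair(query, query, matrix, mode="local").score
        if self_score <= 0:
            raise ValueError("query self-score is non-positive")
        for rec in db:
            s = align_pair(query, rec, matrix, mode="local").score
            scored.append((rec.id, s / self_score))
    hits = [(cid, s) for cid, s in scored if s >= threshold]
    hits.sort(key=lambda h: (-h[1], h[0]))
    return HitList(query_id=qid, hits=tuple(hits), threshold=threshold)


def map_triad(
    candidate: ProteinRecord,
    spec: TriadSpec,
    reference: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
) -> TriadMap:
    """Translate triad anchor positions onto a candidate through alignment.

    The candidate is globally aligned to the reference; each anchor is
    carried through the alignment columns to a 1-based candidate position
    (absent where the candidate has a gap).  The verdict is true iff all
    three anchors land on residues in their allowed sets.
    """
    if reference.id != spec.reference_id:
        raise ValueError("reference record does not match the triad spec")
    if spec.his_pos > len(reference):
        raise ValueError("triad positions exceed reference length")
    aln = align_pair(reference, candidate, matrix, mode="global")
    posmap = {pa: pb for pa, pb in aln.position_map() if pa is not None}

    def resolve(ref_pos: int, allowed: frozenset[str]):
        cand_pos = posmap.get(ref_pos)
        if cand_pos is None:
            return None, None, False
        res = candidate.residue(cand_pos)
        return cand_pos, res, res in allowed

    ser_pos, ser_res, ser_ok = resolve(spec.ser_pos, spec.allowed_ser)
    asp_pos, asp_res, asp_ok = resolve(spec.asp_pos, spec.allowed_asp)
    his_pos, his_res, his_ok = resolve(spec.his_pos, spec.allowed_his)
    return TriadMap(
        candidate_id=candidate.id,
        ser_pos=ser_pos,
        asp_pos=asp_pos,
        his_pos=his_pos,
        ser_res=ser_res,
        asp_res=asp_res,
        his_res=his_res,
        verdict=ser_ok and asp_ok and his_ok,
    )


def filter_triad(
    candidates: Iterable[ProteinRecord],
    spec: TriadSpec,
    reference: ProteinRecord,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Keep candidates with an intact triad; report every input.

    Returns the passing records (input order preserved) and a report table
    with one row per candidate: mapped positions, residues, verdict.
    """
    passing: list[ProteinRecord] = []
    rows: list[dict[str, object]] = []
    for cand in candidates:
        tm = map_triad(cand, spec, reference, matrix)
        rows.append(
            {
                "candidate_id": tm.candidate_id,
                "ser_pos": tm.ser_pos,
                "ser_res": tm.ser_res,
                "asp_pos": tm.asp_pos,
                "asp_res": tm.asp_res,
                "his_pos": tm.his_pos,
                "his_res": tm.his_res,
                "verdict": tm.verdict,
            }
        )
        if tm.verdict:
            passing.append(cand)
    report = pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "ser_pos",
            "ser_res",
            "asp_pos",
            "asp_res",
            "his_pos",
            "his_res",
            "verdict",
        ],
    )
    return passing, report
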