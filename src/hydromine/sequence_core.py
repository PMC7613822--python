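"""Protein records, substitution scoring, and pairwise/star alignment.

Everything downstream — homolog search, catalytic-triad mapping, similarity
networks, loop-architecture analysis — is anchored on the global affine-gap
alignments produced here.  Scoring follows the EMBOSS-needle convention:
a gap of length ``L`` costs ``gap_open + gap_extend * L`` with the default
BLOSUM62 / 10 / 0.5 parameters.

Identity is reported as identical columns over *all* alignment columns
(gapped columns count in the denominator); similarity as columns whose
residue pair has a strictly positive substitution score ("positives").
Both conventions are carried on every :class:`Alignment` so either figure
can be compared against external tools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "ProteinRecord",
    "SubstitutionMatrix",
    "Alignment",
    "StarAlignment",
    "InsertionBlock",
    "read_fasta",
    "write_fasta",
    "align_pair",
    "star_alignment",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with a provenance tag.

    ``source`` distinguishes reference enzymes (e.g. the IsPETase query),
    candidate sequences from a mined collection, and synthetic benchmark
    sequences.  Sequences are uppercase over the 20 canonical residues
    plus ``X`` (unknown).
    """

    id: str
    seq: str
    source: str = "candidate"
    meta: Mapping[str, object] = field(default_factory=dict)

    _SOURCES = frozenset({"reference", "candidate", "synthetic"})

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.source not in self._SOURCES:
            raise ValueError(
                f"record {self.id!r}: source {self.source!r} not in {sorted(self._SOURCES)}"
            )
        seq = self.seq
        allowed = set(ALPHABET)
        for pos, letter in enumerate(seq, start=1):
            if letter not in allowed:
                raise ValueError(
                    f"record {self.id!r}: illegal character {letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.seq):
            raise IndexError(f"position {pos} outside 1..{len(self.seq)}")
        return self.seq[pos - 1]


class SubstitutionMatrix:
    """Symmetric residue-pair scores with affine gap penalties.

    ``X`` scores 0 against everything, including itself; ambiguity codes
    (B/Z/U) are rejected upstream at parse time.
    """

    def __init__(
        self,
        name: str,
        scores: Mapping[tuple[str, str], float],
        gap_open: float = 10.0,
        gap_extend: float = 0.5,
    ) -> None:
        if gap_open < 0 or gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        self.name = name
        self.gap_open = float(gap_open)
        self.gap_extend = float(gap_extend)
        full: dict[tuple[str, str], float] = {}
        for a, b in itertools.product(ALPHABET, repeat=2):
            if a == "X" or b == "X":
                full[(a, b)] = 0.0
                continue
            if (a, b) in scores:
                val = scores[(a, b)]
            elif (b, a) in scores:
                val = scores[(b, a)]
            else:
                raise ValueError(f"matrix {name!r} missing pair ({a},{b})")
            if (b, a) in scores and scores[(b, a)] != val:
                raise ValueError(f"matrix {name!r} asymmetric at ({a},{b})")
            full[(a, b)] = float(val)
        self._scores = full

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"residue pair ({a!r},{b!r}) absent from matrix {self.name!r}")

    def __contains__(self, letter: str) -> bool:
        return letter in ALPHABET

    def to_biopython(self) -> substitution_matrices.Array:
        arr = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
        for (a, b), v in self._scores.items():
            arr[a, b] = v
        return arr

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 0.5) -> "SubstitutionMatrix":
        """The default scoring scheme: BLOSUM62 with needle-style gaps."""
        raw = substitution_matrices.load("BLOSUM62")
        scores = {
            (a, b): float(raw[a, b])
            for a, b in itertools.product(AMINO_ACIDS, repeat=2)
        }
        return cls("BLOSUM62", scores, gap_open, gap_extend)

    @classmethod
    def from_file(
        cls, path: str | Path, gap_open: float = 10.0, gap_extend: float = 0.5
    ) -> "SubstitutionMatrix":
        """Load an NCBI-format (BLAST-style) substitution matrix text file."""
        raw = substitution_matrices.read(str(path))
        missing = [a for a in AMINO_ACIDS if a not in raw.alphabet]
        if missing:
            raise ValueError(f"matrix file {path} lacks residues {missing}")
        scores = {
            (a, b): float(raw[a, b])
            for a, b in itertools.product(AMINO_ACIDS, repeat=2)
        }
        return cls(Path(path).stem, scores, gap_open, gap_extend)


@dataclass(frozen=True)
class Alignment:
    """A scored pairwise alignment with identity/similarity fractions."""

    a_id: str
    b_id: str
    a_aln: str
    b_aln: str
    score: float
    identity: float
    similarity: float
    mode: str

    def __post_init__(self) -> None:
        if len(self.a_aln) != len(self.b_aln):
            raise ValueError("aligned strings differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.a_aln, self.b_aln)):
            raise ValueError("column with gap in both sequences")

    def __len__(self) -> int:
        return len(self.a_aln)

    def columns(self) -> Iterator[tuple[str, str]]:
        return zip(self.a_aln, self.b_aln)

    def position_map(self) -> list[tuple[int | None, int | None]]:
        """Per-column (a_pos, b_pos), 1-based, ``None`` where gapped."""
        out: list[tuple[int | None, int | None]] = []
        ia = ib = 0
        for x, y in self.columns():
            pa = pb = None
            if x != "-":
                ia += 1
                pa = ia
            if y != "-":
                ib += 1
                pb = ib
            out.append((pa, pb))
        return out

    def map_a_to_b(self, pos: int) -> int | None:
        """Translate 1-based position on ``a`` to ``b`` (None if over a gap)."""
        for pa, pb in self.position_map():
            if pa == pos:
                return pb
        raise IndexError(f"position {pos} outside aligned range of {self.a_id!r}")


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path, source: str = "candidate") -> list[ProteinRecord]:
    """Parse a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, ``*`` stop marks stripped, wrapped lines
    joined.  Duplicate ids and illegal residues raise ``ValueError``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks).upper().replace("*", "")
        rid = header.split()[0] if header.split() else ""
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        records.append(ProteinRecord(rid, seq, source=source))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (default 60 columns)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pairwise alignment


def _make_aligner(m: SubstitutionMatrix, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = m.to_biopython()
    # Biopython charges open_gap_score for the first gap residue and
    # extend_gap_score for each subsequent one; shifting the open score by
    # one extension reproduces cost(L) = gap_open + gap_extend * L.
    aligner.open_gap_score = -(m.gap_open + m.gap_extend)
    aligner.extend_gap_score = -m.gap_extend
    aligner.mode = mode
    return aligner


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    m: SubstitutionMatrix | None = None,
    mode: str = "global",
) -> Alignment:
    """Optimal affine-gap pairwise alignment of two protein records.

    Parameters
    ----------
    m
        Scoring scheme; BLOSUM62/10/0.5 when omitted.
    mode
        ``"global"`` (Needleman-Wunsch, end gaps penalised) or ``"local"``
        (Smith-Waterman).
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    if m is None:
        m = SubstitutionMatrix.blosum62()
    for rec in (a, b):
        for letter in rec.seq:
            if letter not in m:
                raise KeyError(f"residue {letter!r} of {rec.id!r} absent from matrix")
    aligner = _make_aligner(m, mode)
    best = aligner.align(a.seq, b.seq)[0]
    a_aln, b_aln = str(best[0]), str(best[1])
    ncols = len(a_aln)
    ident = sum(1 for x, y in zip(a_aln, b_aln) if x == y and x != "-")
    pos = sum(
        1
        for x, y in zip(a_aln, b_aln)
        if x != "-" and y != "-" and m.score(x, y) > 0
    )
    return Alignment(
        a_id=a.id,
        b_id=b.id,
        a_aln=a_aln,
        b_aln=b_aln,
        score=float(best.score),
        identity=ident / ncols,
        similarity=pos / ncols,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Reference-anchored star alignment


@dataclass(frozen=True)
class InsertionBlock:
    """A run of residues in another sequence aligned to center gaps.

    ``anchor`` is the 1-based center position immediately preceding the
    block (0 for an N-terminal insertion); ``positions`` are the 1-based
    coordinates of the inserted residues on the other sequence.
    """

    seq_id: str
    anchor: int
    residues: str
    positions: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class StarAlignment:
    """Pairwise alignments of several sequences onto one center reference.

    ``columns[p]`` maps every other sequence id to the residue (or ``'-'``)
    aligned to center position ``p`` (1-based); insertions relative to the
    center are kept separately as :class:`InsertionBlock` runs so the
    center coordinate system stays intact.
    """

    center: ProteinRecord
    alignments: dict[str, Alignment]
    columns: dict[int, dict[str, str]]
    insertions: list[InsertionBlock]

    def insertions_for(self, seq_id: str) -> list[InsertionBlock]:
        return [b for b in self.insertions if b.seq_id == seq_id]


def _insertion_blocks(aln: Alignment) -> list[InsertionBlock]:
    """Runs of b-residues aligned to gaps in a (the center)."""
    blocks: list[InsertionBlock] = []
    run: list[tuple[int, str]] = []
    anchor = 0
    for (pa, pb), (x, y) in zip(aln.position_map(), aln.columns()):
        if pa is None:  # center gap, b residue inserted
            run.append((pb, y))
        else:
            if run:
                blocks.append(
                    InsertionBlock(
                        seq_id=aln.b_id,
                        anchor=anchor,
                        residues="".join(r for _, r in run),
                        positions=tuple(p for p, _ in run),
                    )
                )
                run = []
            anchor = pa
    if run:
        blocks.append(
            InsertionBlock(
                seq_id=aln.b_id,
                anchor=anchor,
                residues="".join(r for _, r in run),
                positions=tuple(p for p, _ in run),
            )
        )
    return blocks


def star_alignment(
    center: ProteinRecord,
    others: Sequence[ProteinRecord],
    m: SubstitutionMatrix | None = None,
) -> StarAlignment:
    """Align each sequence to a designated center reference.

    A light-weight stand-in for progressive MSA: sufficient for mapping
    catalytic anchors and detecting loop insertions, and exactly testable
    because every row is an independent optimal pairwise alignment.
    """
    if not others:
        raise ValueError("star_alignment needs at least one other sequence")
    if m is None:
        m = SubstitutionMatrix.blosum62()
    alignments: dict[str, Alignment] = {}
    columns: dict[int, dict[str, str]] = {p: {} for p in range(1, len(center) + 1)}
    insertions: list[InsertionBlock] = []
    for other in others:
        aln = align_pair(center, other, m, mode="global")
        alignments[other.id] = aln
        for (pa, _pb), (_x, y) in zip(aln.position_map(), aln.columns()):
            if pa is not None:
                columns[pa][other.id] = y
        insertions.extend(_insertion_blocks(aln))
    return StarAlignment(center, alignments, columns, insertions)
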