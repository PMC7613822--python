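import functools
import itertools

import pytest

from hydromine.sequence_core import ProteinRecord, SubstitutionMatrix


@pytest.fixture(scope="session")
def blosum():
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def ispetase():
    from hydromine.references import ispetase

    return ispetase()


@pytest.fixture(scope="session")
def ispetase_spec():
    from hydromine.references import ispetase_triad_spec

    return ispetase_triad_spec()


def make_record(seq: str, rid: str = "r") -> ProteinRecord:
    return ProteinRecord(rid, seq, source="synthetic")


# ---------------------------------------------------------------------------
# Independent brute-force global-alignment oracle (enumeration, not DP).


def _alignments(a: str, b: str):
    """Yield all gapped global alignments (no both-gap columns)."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for x, y in _alignments(a[1:], b[1:]):
            yield a[0] + x, b[0] + y
    if a:
        for x, y in _alignments(a[1:], b):
            yield a[0] + x, "-" + y
    if b:
        for x, y in _alignments(a, b[1:]):
            yield "-" + x, b[0] + y


def _gap_cost(row: str, gap_open: float, gap_extend: float) -> float:
    cost = 0.0
    run = 0
    for ch in row + "!":
        if ch == "-":
            run += 1
        elif run:
            cost += gap_open + gap_extend * run
            run = 0
    return cost


@functools.lru_cache(maxsize=None)
def _blosum_scores():
    m = SubstitutionMatrix.blosum62()
    return {(x, y): m.score(x, y) for x, y in itertools.product("ACDEFGHIKLMNPQRSTVWYX", repeat=2)}


def brute_force_global_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Maximum score over exhaustive enumeration of all global alignments."""
    scores = _blosum_scores()
    best = float("-inf")
    for ra, rb in _alignments(a, b):
        s = sum(scores[(x, y)] for x, y in zip(ra, rb) if x != "-" and y != "-")
        s -= _gap_cost(ra, gap_open, gap_extend) + _gap_cost(rb, gap_open, gap_extend)
        best = max(best, s)
    return best
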