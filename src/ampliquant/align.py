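"""Affine-gap Smith-Waterman local alignment against a reference window.

Each pooled read is aligned locally to the short (typically 53-nt)
classification window using the Gotoh three-state formulation (match/mismatch
state plus one state per gap type), with all states floored at zero.  Gap
costs follow the EMBOSS convention: a gap of length L costs
``gap_open + gap_extend * L``, i.e. the first gap base is charged
open+extend.  Both the read and its reverse complement are aligned and the
higher-scoring orientation is returned, so reads whose orientation was not
normalised upstream are still classified.

Determinism: ties are broken by preferring a diagonal step over a deletion
(gap in the read) over an insertion (gap in the reference), and among equal
best end cells the one with the smallest (ref_end, read_end) is chosen.
Indel placement within homopolymer runs depends on these rules and is
documented rather than biologically meaningful.

The O(m*n) fill and traceback are plain-loop kernels compiled with numba
when it is importable; the same code runs (slowly) as pure Python otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .locus import ReferenceWindow, revcomp

try:  # pragma: no cover - exercised implicitly by every alignment test
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


MATCH, MISMATCH, INSERTION, DELETION = "match", "mismatch", "insert", "delete"

# traceback step codes emitted by the kernel
_STEP_MATCH, _STEP_MISMATCH, _STEP_DEL, _STEP_INS = 0, 1, 2, 3

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; defaults are the cited aligner's classic defaults."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    def gap_cost(self, length: int) -> float:
        return self.gap_open + self.gap_extend * length if length else 0.0


@dataclass(frozen=True)
class AlignmentOp:
    """One run of identical alignment columns."""

    op: str  # match | mismatch | insert | delete
    length: int
    bases: str = ""  # read bases for insert runs

    def __post_init__(self) -> None:
        if self.op == INSERTION and len(self.bases) != self.length:
            raise ValueError("insert op must carry its read bases")


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment of one read (in ``strand_used`` orientation)
    against a reference window.

    ``read_start/read_end`` index into the oriented read (the reverse
    complement of the input when ``strand_used == 'rev'``); ``ref_*`` index
    into the window.  ``operations`` runs from alignment start to end.
    """

    score: float
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    operations: tuple[AlignmentOp, ...]
    strand_used: str  # 'fwd' | 'rev'
    read: str = field(default="", repr=False)  # oriented read sequence

    @property
    def ref_coverage(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def gap_count(self) -> int:
        return sum(1 for op in self.operations if op.op in (INSERTION, DELETION))

    def score_from_operations(self, scheme: ScoringScheme) -> float:
        """Recompute the score from the operation list (consistency check)."""
        total = 0.0
        for op in self.operations:
            if op.op == MATCH:
                total += scheme.match * op.length
            elif op.op == MISMATCH:
                total += scheme.mismatch * op.length
            else:
                total -= scheme.gap_cost(op.length)
        return total


@njit(cache=True)
def _gotoh_fill(q, r, match, mismatch, gap_open, gap_ext):
    """Fill the three Gotoh matrices; return best M cell and pointers.

    Pointer codes: 0 = alignment starts here, 1 = from M, 2 = from D
    (gap in read, consumes ref), 3 = from I (gap in ref, consumes read).
    """
    m, n = q.shape[0], r.shape[0]
    gap1 = gap_open + gap_ext
    M = np.zeros((m + 1, n + 1), dtype=np.float64)
    D = np.zeros((m + 1, n + 1), dtype=np.float64)
    I = np.zeros((m + 1, n + 1), dtype=np.float64)
    pM = np.zeros((m + 1, n + 1), dtype=np.int8)
    pD = np.zeros((m + 1, n + 1), dtype=np.int8)
    pI = np.zeros((m + 1, n + 1), dtype=np.int8)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            s = match if qi == r[j - 1] else mismatch
            # M: end in an aligned pair; tie preference M > D > I
            v, p = M[i - 1, j - 1], 1
            if D[i - 1, j - 1] > v:
                v, p = D[i - 1, j - 1], 2
            if I[i - 1, j - 1] > v:
                v, p = I[i - 1, j - 1], 3
            if v == 0.0:
                p = 0
            v += s
            if v <= 0.0:
                v, p = 0.0, 0
            M[i, j], pM[i, j] = v, p
            # D: gap in read (delete from ref), consumes j
            v, p = M[i, j - 1] - gap1, 1
            c = D[i, j - 1] - gap_ext
            if c > v:
                v, p = c, 2
            c = I[i, j - 1] - gap1
            if c > v:
                v, p = c, 3
            if v <= 0.0:
                v, p = 0.0, 0
            D[i, j], pD[i, j] = v, p
            # I: gap in ref (insertion in read), consumes i
            v, p = M[i - 1, j] - gap1, 1
            c = D[i - 1, j] - gap1
            if c > v:
                v, p = c, 2
            c = I[i - 1, j] - gap_ext
            if c > v:
                v, p = c, 3
            if v <= 0.0:
                v, p = 0.0, 0
            I[i, j], pI[i, j] = v, p
    # best M cell; smallest (ref_end, read_end) wins ties, and any alignment
    # ending in a gap is dominated by its gap-trimmed suffix
    best, bi, bj = 0.0, 0, 0
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j
    return best, bi, bj, pM, pD, pI


@njit(cache=True)
def _gotoh_traceback(q, r, bi, bj, pM, pD, pI):
    """Walk pointers from the best cell; return reversed step codes and the
    alignment start coordinates."""
    steps = np.empty(bi + bj, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 1  # start in M: alignments end in an aligned pair
    while True:
        if state == 1:
            steps[k] = _STEP_MATCH if q[i - 1] == r[j - 1] else _STEP_MISMATCH
            k += 1
            nxt = pM[i, j]
            i -= 1
            j -= 1
            if nxt == 0:
                break
            state = nxt
        elif state == 2:
            steps[k] = _STEP_DEL
            k += 1
            nxt = pD[i, j]
            j -= 1
            state = nxt
        else:
            steps[k] = _STEP_INS
            k += 1
            nxt = pI[i, j]
            i -= 1
            state = nxt
    return steps[:k], i, j


def _align_one_orientation(
    read: str, ref: str, scheme: ScoringScheme
) -> tuple[float, int, int, int, int, tuple[AlignmentOp, ...]]:
    q, r = _encode(read), _encode(ref)
    best, bi, bj, pM, pD, pI = _gotoh_fill(
        q, r, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, ()
    steps, i0, j0 = _gotoh_traceback(q, r, bi, bj, pM, pD, pI)
    codes = steps[::-1]  # start -> end
    ops: list[AlignmentOp] = []
    rpos = i0
    for code, grp in groupby(codes):
        length = len(list(grp))
        if code == _STEP_MATCH:
            ops.append(AlignmentOp(MATCH, length))
            rpos += length
        elif code == _STEP_MISMATCH:
            ops.append(AlignmentOp(MISMATCH, length))
            rpos += length
        elif code == _STEP_DEL:
            ops.append(AlignmentOp(DELETION, length))
        else:
            ops.append(AlignmentOp(INSERTION, length, read[rpos : rpos + length]))
            rpos += length
    return float(best), i0, bi, j0, bj, tuple(ops)


def smith_waterman(
    read: str, window: ReferenceWindow | str, scheme: ScoringScheme | None = None
) -> AlignmentResult:
    """Optimal affine-gap local alignment of a read against a window.

    Aligns both the read and its reverse complement; returns the
    higher-scoring orientation (forward wins ties).  A read with no
    positive-scoring local alignment yields an empty result with score 0.
    """
    scheme = scheme or ScoringScheme()
    ref = window.sequence if isinstance(window, ReferenceWindow) else str(window)
    if not ref:
        raise ValueError("reference window is empty")
    if not read:
        raise ValueError("read is empty")

    fwd = _align_one_orientation(read, ref, scheme)
    rc = revcomp(read)
    rev = _align_one_orientation(rc, ref, scheme)
    if rev[0] > fwd[0]:
        score, rs, re_, fs, fe, ops = rev
        oriented, strand = rc, "rev"
    else:
        score, rs, re_, fs, fe, ops = fwd
        oriented, strand = read, "fwd"
    return AlignmentResult(
        score=score,
        read_start=rs,
        read_end=re_,
        ref_start=fs,
        ref_end=fe,
        operations=ops,
        strand_used=strand,
        read=oriented,
    )


def alignment_ref_coverage(result: AlignmentResult, window: ReferenceWindow | str) -> int:
    """Number of reference nt covered by the alignment (53 = full window)."""
    return result.ref_end - result.ref_start


def cigar_string(result: AlignmentResult) -> str:
    """Compact operation string for debugging output (=, X, I, D runs)."""
    sym = {MATCH: "=", MISMATCH: "X", INSERTION: "I", DELETION: "D"}
    return "".join(f"{op.length}{sym[op.op]}" for op in result.operations) or "*"
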