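"""Pairwise global alignment used across the pipeline.

Two routes share one scoring scheme (match=+1, mismatch=-2, a gap of length
L costs gap_open + L * gap_extend):

* :func:`banded_global` — a NumPy Gotoh (affine-gap) aligner restricted to a
  diagonal band, written here because block refinement needs an aligner whose
  band can be chosen from the anchor geometry and re-anchored when exceeded.
* :func:`biopython_global` — Bio.Align.PairwiseAligner with the same scores,
  used for ordinary unbanded alignments and, in the tests, as the
  independent full-dynamic-programming oracle for the banded route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_GAP_OPEN = -6
DEFAULT_GAP_EXTEND = -1

_NEG_INF = -1e18


class BandExceededError(RuntimeError):
    """Optimal path may leave the band; caller should widen or re-anchor."""


@dataclass
class AlignmentResult:
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    def identity(self) -> float:
        """Identity over aligned non-gap columns (gap columns excluded)."""
        matches = 0
        cols = 0
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" or y == "-":
                continue
            cols += 1
            if x == y:
                matches += 1
        if cols == 0:
            raise ZeroDivisionError("no aligned non-gap columns")
        return matches / cols


def banded_global(
    a: str,
    b: str,
    band: int,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    check_band: bool = True,
) -> AlignmentResult:
    """Affine-gap global alignment restricted to a diagonal band.

    Cells with |j - i| > band + |len(a) - len(b)| are never filled, so the
    band must exceed the largest net indel on the optimal path.  When
    ``check_band`` is true and the traceback touches the band edge,
    :class:`BandExceededError` is raised so the caller can widen the band or
    re-anchor rather than silently truncate the alignment.
    """
    if band < 1:
        raise ValueError("band must be >= 1")
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        gap_len = max(n, m)
        score = (gap_open + gap_extend * gap_len) if gap_len else 0.0
        return AlignmentResult(score, a + "-" * m, "-" * n + b)

    half = band + abs(n - m)
    width = 2 * half + 1
    open1 = gap_open + gap_extend  # cost of the first base of a gap

    ea = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    eb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    # Three DP states per cell; column j of row i lives at offset j - i + half.
    M = np.full((n + 1, width), _NEG_INF)
    X = np.full((n + 1, width), _NEG_INF)  # gap in b (consumes a)
    Y = np.full((n + 1, width), _NEG_INF)  # gap in a (consumes b)

    M[0, half] = 0.0
    for j in range(1, min(m, half) + 1):
        Y[0, j + half] = gap_open + gap_extend * j
    for i in range(1, min(n, half) + 1):
        X[i, half - i] = gap_open + gap_extend * i

    for i in range(1, n + 1):
        jlo = max(1, i - half)
        jhi = min(m, i + half)
        if jlo > jhi:
            raise BandExceededError("band does not reach row %d" % i)
        js = np.arange(jlo, jhi + 1)
        offs = js - i + half

        # X[i, j] from (i-1, j): previous-row offset is offs + 1.
        poff = offs + 1
        ok = poff <= width - 1
        poff_c = np.minimum(poff, width - 1)
        pm = np.where(ok, M[i - 1, poff_c], _NEG_INF)
        px = np.where(ok, X[i - 1, poff_c], _NEG_INF)
        py = np.where(ok, Y[i - 1, poff_c], _NEG_INF)
        xrow = np.maximum.reduce([pm + open1, px + gap_extend, py + open1])
        X[i, offs] = np.maximum(X[i, offs], xrow)

        # M[i, j] from (i-1, j-1): same offset in the previous row.
        sub = np.where(ea[i - 1] == eb[js - 1], match, mismatch)
        M[i, offs] = (
            np.maximum.reduce([M[i - 1, offs], X[i - 1, offs], Y[i - 1, offs]]) + sub
        )

        # Y[i, j] from (i, j-1): a left-to-right scan within the row.
        off0 = offs[0] - 1
        prev_m = M[i, off0] if off0 >= 0 else _NEG_INF
        prev_x = X[i, off0] if off0 >= 0 else _NEG_INF
        prev_y = Y[i, off0] if off0 >= 0 else _NEG_INF
        mrow = M[i, offs]
        xrow_now = X[i, offs]
        yrow = np.empty(len(js))
        for t in range(len(js)):
            val = max(prev_m + open1, prev_x + open1, prev_y + gap_extend)
            yrow[t] = val
            prev_m, prev_x, prev_y = mrow[t], xrow_now[t], val
        Y[i, offs] = yrow

    end_off = m - n + half
    finals = (M[n, end_off], X[n, end_off], Y[n, end_off])
    score = max(finals)
    if score <= _NEG_INF / 2:
        raise BandExceededError("no alignment path within band")

    # Traceback.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = int(np.argmax(finals))
    touched_edge = False
    while i > 0 or j > 0:
        off = j - i + half
        if j < m and i < n and (off <= 0 or off >= width - 1):
            touched_edge = True
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, off] - (match if a[i - 1] == b[j - 1] else mismatch)
            prev = (M[i - 1, off], X[i - 1, off], Y[i - 1, off])
            state = int(np.argmax(np.isclose(prev, target)))
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            target = X[i, off]
            poff = off + 1
            pm = M[i - 1, poff] if poff <= width - 1 else _NEG_INF
            py = Y[i - 1, poff] if poff <= width - 1 else _NEG_INF
            if np.isclose(pm + open1, target):
                state = 0
            elif np.isclose(py + open1, target):
                state = 2
            else:
                state = 1
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Y[i, off]
            poff = off - 1
            pm = M[i, poff] if poff >= 0 else _NEG_INF
            px = X[i, poff] if poff >= 0 else _NEG_INF
            if np.isclose(pm + open1, target):
                state = 0
            elif np.isclose(px + open1, target):
                state = 1
            else:
                state = 2
            j -= 1
    if check_band and touched_edge:
        raise BandExceededError("optimal path touched the band edge")
    return AlignmentResult(float(score), "".join(reversed(out_a)), "".join(reversed(out_b)))


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def biopython_global(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Full-DP global affine alignment via Bio.Align.PairwiseAligner."""
    if len(a) == 0 or len(b) == 0:
        return banded_global(a, b, band=1)
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return AlignmentResult(float(aln.score), str(aln[0]), str(aln[1]))


def biopython_score(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    return float(aligner.score(a, b))


def align_global(a: str, b: str, band: int | None = None) -> AlignmentResult:
    """Dispatch: banded Gotoh when a band is given, else full DP.

    A banded result is only trusted when its score equals a fast score-only
    full-DP pass (a too-narrow band can hold an interior suboptimal path
    that no edge check can see); on mismatch the full-DP aligner recomputes
    the alignment — never a silent truncation.
    """
    if band is None:
        return biopython_global(a, b)
    current = band
    res: AlignmentResult | None = None
    for _ in range(3):
        try:
            res = banded_global(a, b, band=current)
            break
        except BandExceededError:
            current *= 4
    if res is not None and res.score == biopython_score(a, b):
        return res
    return biopython_global(a, b)
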