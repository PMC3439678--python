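"""Deterministic pairwise alignment (Gotoh affine-gap dynamic programming).

Two engines are provided: a global (Needleman-Wunsch) aligner used for the
star multiple alignment and the residue-mapping fallback, and a local
(Smith-Waterman) aligner used to compute the identity/coverage statistics
behind similarity-network edges.  Both use BLAST-like defaults (BLOSUM62,
gap open 11, gap extend 1, a gap of length k costing open + k*extend) and a
fixed traceback tie-break — diagonal, then up (gap in the second sequence),
then left — so results are bit-reproducible and checkable against a
brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import blosum

NEG = -(10**9)

# traceback pointer codes
_FROM_M, _FROM_X, _FROM_Y, _STOP = 0, 1, 2, 3


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment as a list of aligned index pairs.

    ``pairs`` holds 0-based indices into the two sequences; ``None`` marks a
    gap on that side.  For a local alignment the pairs cover only the
    aligned region.
    """

    score: int
    pairs: tuple

    def aligned_strings(self, a: str, b: str) -> tuple[str, str]:
        ra = "".join(a[i] if i is not None else "-" for i, _ in self.pairs)
        rb = "".join(b[j] if j is not None else "-" for _, j in self.pairs)
        return ra, rb


def identity_score(x: str, y: str) -> int:
    """Simple scoring for the mapping fallback: match +1, mismatch 0."""
    return 1 if x == y else 0


def _dp(a, b, score_fn, gap_open, gap_extend, local):
    """Gotoh three-state DP; returns (score, end cell, pointer matrices)."""
    n, m = len(a), len(b)
    go = gap_open + gap_extend  # cost of the first gap position

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b ("up")
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a ("left")
    pM = [[_STOP] * (m + 1) for _ in range(n + 1)]
    pX = [[_FROM_M] * (m + 1) for _ in range(n + 1)]
    pY = [[_FROM_M] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = -(gap_open + i * gap_extend)
            pX[i][0] = _FROM_X if i > 1 else _FROM_M
        for j in range(1, m + 1):
            Y[0][j] = -(gap_open + j * gap_extend)
            pY[0][j] = _FROM_Y if j > 1 else _FROM_M

    best = (0, 0, 0)  # score, i, j — used in local mode only
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        pMi, pXi, pYi = pM[i], pX[i], pY[i]
        if local:
            Mi[0] = 0
        for j in range(1, m + 1):
            # match state: tie-break diagonal source M > X > Y
            dm, dx, dy = Mi1[j - 1], Xi1[j - 1], Yi1[j - 1]
            src, ptr = dm, _FROM_M
            if dx > src:
                src, ptr = dx, _FROM_X
            if dy > src:
                src, ptr = dy, _FROM_Y
            if local and src <= 0:
                src, ptr = 0, _STOP  # fresh start beats a dead prefix
            s = src + score_fn(ai, b[j - 1]) if src > NEG // 2 else NEG
            if local:
                if s <= 0:
                    s, ptr = 0, _STOP
                if s > best[0]:
                    best = (s, i, j)
            Mi[j] = s
            pMi[j] = ptr

            # up: consume a[i-1] against a gap; open from M preferred
            op, ex = Mi1[j] - go, Xi1[j] - gap_extend
            if op >= ex:
                Xi[j], pXi[j] = op, _FROM_M
            else:
                Xi[j], pXi[j] = ex, _FROM_X

            # left: consume b[j-1] against a gap
            op, ex = Mi[j - 1] - go, Yi[j - 1] - gap_extend
            if op >= ex:
                Yi[j], pYi[j] = op, _FROM_M
            else:
                Yi[j], pYi[j] = ex, _FROM_Y

    if local:
        return best[0], (best[1], best[2], _FROM_M), (pM, pX, pY)
    # global: tie-break final state M > X > Y
    end_state = _FROM_M
    score = M[n][m]
    if X[n][m] > score:
        score, end_state = X[n][m], _FROM_X
    if Y[n][m] > score:
        score, end_state = Y[n][m], _FROM_Y
    return score, (n, m, end_state), (pM, pX, pY)


def _traceback(end, pointers):
    pM, pX, pY = pointers
    i, j, state = end
    pairs = []
    while i > 0 or j > 0:
        if state == _FROM_M:
            state = pM[i][j]
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif state == _FROM_X:
            pairs.append((i - 1, None))
            state = pX[i][j]
            i -= 1
        else:
            pairs.append((None, j - 1))
            state = pY[i][j]
            j -= 1
    return tuple(reversed(pairs))


def global_align(a: str, b: str, score_fn=blosum.score,
                 gap_open: int = 11, gap_extend: int = 1) -> Alignment:
    """Optimal global alignment of ``a`` and ``b``.

    Ties are broken deterministically (diagonal > up > left), so repeated
    calls and reversed-argument calls give mirror-image alignments.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    score, end, pointers = _dp(a, b, score_fn, gap_open, gap_extend, local=False)
    return Alignment(score=score, pairs=_traceback(end, pointers))


def local_align(a: str, b: str, score_fn=blosum.score,
                gap_open: int = 11, gap_extend: int = 1) -> Alignment:
    """Optimal local alignment (Smith-Waterman) of ``a`` and ``b``.

    Among equally scoring end cells the first in row-major order wins.
    An all-negative scoring region yields an empty alignment of score 0.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    score, end, pointers = _dp(a, b, score_fn, gap_open, gap_extend, local=True)
    if score <= 0:
        return Alignment(score=0, pairs=())
    pM, pX, pY = pointers
    i, j, _ = end
    pairs = []
    state = _FROM_M
    while True:
        if state == _FROM_M:
            ptr = pM[i][j]
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if ptr == _STOP:
                break
            state = ptr
        elif state == _FROM_X:
            pairs.append((i - 1, None))
            state = pX[i][j]
            i -= 1
        else:
            pairs.append((None, j - 1))
            state = pY[i][j]
            j -= 1
    return Alignment(score=score, pairs=tuple(reversed(pairs)))
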