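"""Numba kernel for local alignment with affine gaps.

The recurrence is the classic three-matrix formulation
(H = best ending in a pair, E = gap in the query, F = gap in the subject),
with a gap of length L costing ``gap_open + L * gap_extend``.  The kernel is
profile-based: sequence-sequence alignment passes a profile made of
substitution-matrix rows, PSSM search passes the PSSM scores directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)


@njit(cache=True)
def sw_fill(profile, subject, gap_open, gap_extend):
    """Fill H/E/F and locate the best cell (first occurrence in row-major order).

    profile : (m, A) int64 position scores
    subject : (n,) int64 indices into the profile's alphabet axis
    Returns (best, bi, bj, H, E, F) with 1-based bi/bj into the DP matrices.
    """
    m = profile.shape[0]
    n = subject.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    go_ge = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - go_ge
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - go_ge
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            v = H[i - 1, j - 1] + profile[i - 1, subject[j - 1]]
            if f > v:
                v = f
            if e > v:
                v = e
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj, H, E, F


@njit(cache=True)
def sw_traceback(H, E, F, profile, subject, bi, bj, gap_open, gap_extend):
    """Trace back from (bi, bj) to the alignment start.

    Ties are broken deterministically: diagonal, then gap-in-subject (F),
    then gap-in-query (E); inside a gap state, closing the gap is preferred
    over extending it.

    Returns (ops, q0, s0): ops is an int8 array in alignment order
    (0 = aligned pair, 1 = gap in subject / query residue consumed,
    2 = gap in query / subject residue consumed); q0/s0 are 1-based start
    coordinates.
    """
    go_ge = gap_open + gap_extend
    ops = np.empty(bi + bj, dtype=np.int8)
    k = ops.shape[0]
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = F, 2 = E
    while True:
        if state == 0:
            v = H[i, j]
            if v == 0:
                break
            if v == H[i - 1, j - 1] + profile[i - 1, subject[j - 1]]:
                k -= 1
                ops[k] = 0
                i -= 1
                j -= 1
            elif v == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = 1
            if F[i, j] == H[i - 1, j] - go_ge:
                state = 0
            i -= 1
        else:
            k -= 1
            ops[k] = 2
            if E[i, j] == H[i, j - 1] - go_ge:
                state = 0
            j -= 1
    return ops[k:], i + 1, j + 1
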