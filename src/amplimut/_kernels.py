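"""Numba kernels for the inner loops (overlap search, affine-gap DP).

Sequences are passed as uint8 arrays of base codes (A=0, C=1, G=2, T=3,
N=4); the wrappers in :mod:`amplimut.align` and :mod:`amplimut.merge` do the
encoding and input validation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e18

# move codes emitted by the traceback
MOVE_DIAG = 0   # consume one ref and one query base
MOVE_DEL = 1    # gap in query (consumes ref)
MOVE_INS = 2    # gap in ref (consumes query)


@njit(cache=True)
def best_overlap(a, b, min_overlap, max_mismatch_frac):
    """Best overlap length between mate-1 ``a`` and reverse-complemented
    mate-2 ``b``.

    The suffix of ``a`` is slid over the prefix of ``b``; the admissible
    overlap maximizing matches-minus-mismatches is returned.  Ties prefer
    the longer overlap.  Returns (-1, 0) when no admissible overlap exists.
    """
    la = a.shape[0]
    lb = b.shape[0]
    lim = la if la < lb else lb
    best_score = NEG_INF
    best_o = -1
    best_mm = 0
    for o in range(lim, min_overlap - 1, -1):
        if o <= 0:
            break
        mm = 0
        off = la - o
        for k in range(o):
            if a[off + k] != b[k]:
                mm += 1
        if mm > max_mismatch_frac * o:
            continue
        sc = float(o - 2 * mm)
        if sc > best_score:
            best_score = sc
            best_o = o
            best_mm = mm
    return best_o, best_mm


@njit(cache=True)
def merge_consensus(a, qa, b, qb, o):
    """Consensus sequence/quality for mates with overlap ``o``.

    In the overlap the higher-quality base wins (mate 1 on ties); the
    consensus quality is the max on agreement and ``|q1-q2|`` on conflict.
    """
    la = a.shape[0]
    lb = b.shape[0]
    n = la + lb - o
    seq = np.empty(n, np.uint8)
    qual = np.empty(n, np.uint8)
    head = la - o
    for i in range(head):
        seq[i] = a[i]
        qual[i] = qa[i]
    for k in range(o):
        i = head + k
        if a[i] == b[k]:
            seq[head + k] = a[i]
            qual[head + k] = qa[i] if qa[i] > qb[k] else qb[k]
        elif qa[i] >= qb[k]:
            seq[head + k] = a[i]
            qual[head + k] = qa[i] - qb[k]
        else:
            seq[head + k] = b[k]
            qual[head + k] = qb[k] - qa[i]
    for k in range(o, lb):
        seq[la + k - o] = b[k]
        qual[la + k - o] = qb[k]
    return seq, qual


@njit(cache=True)
def nw_affine(ref, qry, match, mismatch, gap_open, gap_extend, free_ends):
    """Needleman-Wunsch with affine gaps (gap of length L costs
    ``gap_open + L * gap_extend``) and optionally free end gaps.

    Tie-breaking is deterministic: diagonal is preferred, then gap-in-query,
    then gap-in-ref, which left-shifts indel placement during traceback.

    Returns ``(score, moves)`` where moves are MOVE_* codes in alignment
    order.
    """
    n = ref.shape[0]
    m = qry.shape[0]
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in query (vertical)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in ref (horizontal)
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_ends else -(gap_open + i * gap_extend)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_ends else -(gap_open + j * gap_extend)
        pY[0, j] = 0 if j == 1 else 2

    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == qry[j - 1] else mismatch
            # match/mismatch state, preference M > X > Y on ties
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p
            # gap in query
            best = M[i - 1, j] - open_cost
            p = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                p = 1
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                p = 2
            X[i, j] = best
            pX[i, j] = p
            # gap in ref
            best = M[i, j - 1] - open_cost
            p = 0
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                p = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                p = 2
            Y[i, j] = best
            pY[i, j] = p

    # termination: with free ends the trailing gap run costs nothing, so the
    # optimum may sit anywhere on the last row/column
    bi = n
    bj = m
    bstate = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        bstate = 1
    if Y[n, m] > best:
        best = Y[n, m]
        bstate = 2
    if free_ends:
        for i in range(n - 1, -1, -1):
            for st in range(3):
                v = M[i, m] if st == 0 else (X[i, m] if st == 1 else Y[i, m])
                if v > best:
                    best = v
                    bi = i
                    bj = m
                    bstate = st
        for j in range(m - 1, -1, -1):
            for st in range(3):
                v = M[n, j] if st == 0 else (X[n, j] if st == 1 else Y[n, j])
                if v > best:
                    best = v
                    bi = n
                    bj = j
                    bstate = st

    moves = np.empty(n + m, np.int8)
    k = 0
    for _ in range(n - bi):   # trailing free gap in query
        moves[k] = MOVE_DEL
        k += 1
    for _ in range(m - bj):   # trailing free gap in ref
        moves[k] = MOVE_INS
        k += 1
    i = bi
    j = bj
    st = bstate
    while i > 0 or j > 0:
        if st == 0:
            p = pM[i, j]
            moves[k] = MOVE_DIAG
            i -= 1
            j -= 1
        elif st == 1:
            p = pX[i, j]
            moves[k] = MOVE_DEL
            i -= 1
        else:
            p = pY[i, j]
            moves[k] = MOVE_INS
            j -= 1
        k += 1
        st = p
    return best, moves[:k][::-1].copy()


@njit(cache=True)
def apply_substitution_errors(mat, err_mask, offsets, n_mask):
    """In-place sequencing-error model on a batch of encoded reads.

    ``err_mask`` flips a base to one of the three alternatives chosen by
    ``offsets`` (values 1..3); ``n_mask`` overwrites with the N code (4).
    """
    rows, cols = mat.shape
    for i in range(rows):
        for j in range(cols):
            if err_mask[i, j]:
                mat[i, j] = (mat[i, j] + offsets[i, j]) % 4
            if n_mask[i, j]:
                mat[i, j] = 4
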