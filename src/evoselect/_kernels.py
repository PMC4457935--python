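"""Numba kernels for the inner loops of read merging and local alignment.

Sequences are passed as uint8 codes (A=0, C=1, G=2, T=3, anything else=4).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TOL = 1e-9


@njit(cache=False)
def best_overlap(f, rc, min_overlap, max_mismatch_frac):
    """Offset of the reverse-complemented mate on the forward read.

    Candidate offsets place the mate's first base at forward position
    ``o >= 0``; the overlap is the region both reads cover.  The offset with
    the lowest mismatch fraction wins, ties going to the larger overlap
    (i.e. the smaller offset, scanned first).  Positions where either base is
    not A/C/G/T are ignored.  Returns -1 when no overlap of at least
    ``min_overlap`` bases has a mismatch fraction <= ``max_mismatch_frac``.
    """
    nf = f.shape[0]
    nr = rc.shape[0]
    best_o = -1
    best_frac = 2.0
    for o in range(0, nf - min_overlap + 1):
        ov = min(nf - o, nr)
        if ov < min_overlap:
            break
        mm = 0
        informative = 0
        for k in range(ov):
            a = f[o + k]
            b = rc[k]
            if a < 4 and b < 4:
                informative += 1
                if a != b:
                    mm += 1
        if informative == 0:
            continue
        frac = mm / informative
        if frac <= max_mismatch_frac and frac < best_frac - _TOL:
            best_frac = frac
            best_o = o
            if mm == 0:
                break
    return best_o


@njit(cache=False)
def sw_align(q, r, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman local alignment with affine gaps.

    The first base of a gap scores ``gap_open`` and each further base
    ``gap_extend``.  Tie-breaking is deterministic: the optimal cell is the
    rightmost (largest reference column, then largest query row) maximal
    cell, and the traceback prefers diagonal over up (gap in reference) over
    left (gap in query), closing gaps as early as possible.

    Returns ``(score, q_start, q_end, r_start, r_end, q_idx, r_idx)`` with
    0-based inclusive spans and per-column 0-based indices (-1 marks a gap).
    """
    m = q.shape[0]
    n = r.shape[0]
    NEG = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] + gap_open
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            fv = H[i - 1, j] + gap_open
            f2 = F[i - 1, j] + gap_extend
            if f2 > fv:
                fv = f2
            F[i, j] = fv
            if qi == r[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            hv = H[i - 1, j - 1] + s
            if E[i, j] > hv:
                hv = E[i, j]
            if F[i, j] > hv:
                hv = F[i, j]
            if hv < 0.0:
                hv = 0.0
            H[i, j] = hv
            if hv > 0.0 and (
                hv > best + _TOL
                or (
                    hv > best - _TOL
                    and (j > bj or (j == bj and i > bi))
                )
            ):
                best = hv
                bi = i
                bj = j

    q_idx = np.empty(m + n + 2, dtype=np.int32)
    r_idx = np.empty(m + n + 2, dtype=np.int32)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = match/mismatch, 1 = gap in reference (up), 2 = gap in query (left)
    while True:
        if state == 0:
            if i == 0 or j == 0 or H[i, j] <= _TOL:
                break
            if q[i - 1] == r[j - 1] and q[i - 1] < 4:
                s = match
            else:
                s = mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) <= _TOL:
                q_idx[k] = i - 1
                r_idx[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif abs(H[i, j] - F[i, j]) <= _TOL:
                state = 1
            else:
                state = 2
        elif state == 1:
            q_idx[k] = i - 1
            r_idx[k] = -1
            k += 1
            if abs(F[i, j] - (H[i - 1, j] + gap_open)) <= _TOL:
                state = 0
            i -= 1
        else:
            q_idx[k] = -1
            r_idx[k] = j - 1
            k += 1
            if abs(E[i, j] - (H[i, j - 1] + gap_open)) <= _TOL:
                state = 0
            j -= 1

    q_out = q_idx[:k][::-1].copy()
    r_out = r_idx[:k][::-1].copy()
    return best, i, bi - 1, j, bj - 1, q_out, r_out
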