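"""Numba kernels for affine-gap Smith-Waterman local alignment.

Gap convention: a gap of length g costs gap_open + g * gap_extend (the
BLAST -11/-1 convention: a length-1 gap costs 12 with the defaults).

Two kernels: a score-only rolling-row pass (cheap, used to screen proteome
cross-products) and a full pass with pointer matrices and traceback (used
whenever identity/coverage are needed).
"""

import numpy as np
from numba import njit

_NEG = -(10**9)


@njit(cache=True, nogil=True)
def sw_score(q, s, sub, gap_open, gap_extend):
    """Optimal local alignment score only; O(n) memory."""
    m = q.shape[0]
    n = s.shape[0]
    oc = gap_open + gap_extend
    H = np.zeros(n + 1, np.int32)
    F = np.full(n + 1, _NEG, np.int32)
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        h_diag = 0  # H[i-1][0]
        h_left = 0  # H[i][j-1]
        e = _NEG
        for j in range(1, n + 1):
            f = H[j] - oc
            fe = F[j] - gap_extend
            if fe > f:
                f = fe
            F[j] = f
            e_open = h_left - oc
            e = e - gap_extend
            if e_open > e:
                e = e_open
            h = h_diag + sub[qi, s[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = 0
            h_diag = H[j]
            H[j] = h
            h_left = h
            if h > best:
                best = h
    return best


@njit(cache=True, nogil=True)
def sw_full(q, s, sub, gap_open, gap_extend):
    """Optimal local alignment with traceback.

    Returns (score, q_start, q_end, s_start, s_end, n_identical, n_columns),
    1-based inclusive coordinates; all zeros if the optimal score is 0.

    Traceback tie-breaking on equal cell scores: diagonal, then gap in the
    subject (query residue vs gap), then gap in the query.
    """
    m = q.shape[0]
    n = s.shape[0]
    oc = gap_open + gap_extend
    H = np.zeros((m + 1, n + 1), np.int32)
    # ptr codes for H: 0 stop, 1 diagonal, 2 from E (gap in query), 3 from F
    ptrH = np.zeros((m + 1, n + 1), np.uint8)
    openE = np.zeros((m + 1, n + 1), np.uint8)  # 1 if E[i][j] opened from H
    openF = np.zeros((m + 1, n + 1), np.uint8)
    F_col = np.full(n + 1, _NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        e = _NEG
        for j in range(1, n + 1):
            f_open = H[i - 1, j] - oc
            f_ext = F_col[j] - gap_extend
            if f_open >= f_ext:
                f = f_open
                openF[i, j] = 1
            else:
                f = f_ext
            F_col[j] = f

            e_open = H[i, j - 1] - oc
            e_ext = e - gap_extend
            if e_open >= e_ext:
                e = e_open
                openE[i, j] = 1
            else:
                e = e_ext

            h = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            p = 1
            if f > h:
                h = f
                p = 3
            if e > h:
                h = e
                p = 2
            if h <= 0:
                h = 0
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0

    i = bi
    j = bj
    n_id = 0
    n_col = 0
    state = 0  # 0=H, 1=E (gap in query, consumes subject), 2=F (consumes query)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            p = ptrH[i, j]
            if p == 1:
                n_col += 1
                if q[i - 1] == s[j - 1]:
                    n_id += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            n_col += 1
            opened = openE[i, j]
            j -= 1
            if opened:
                state = 0
        else:
            n_col += 1
            opened = openF[i, j]
            i -= 1
            if opened:
                state = 0
    return best, i + 1, bi, j + 1, bj, n_id, n_col
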