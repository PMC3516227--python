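"""Affine-gap local alignment (Smith-Waterman-Gotoh).

The BLAST-like search in :mod:`tehgt.harvest` uses exact-word seeding
to nominate subject windows and this kernel to produce the gapped
local alignment.  Scoring follows the package's BLASTN-style defaults:
match +1, mismatch -2, gap open -5, gap extend -2 (a gap of length L
costs open + (L-1) * extend).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# traceback codes
_STOP, _DIAG, _FROM_E, _FROM_F = 0, 1, 2, 3


@njit(cache=True)
def _fill(a, b, match, mismatch, gap_open, gap_ext):
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float32)
    E = np.full((n + 1, m + 1), -1e9, dtype=np.float32)  # gap in a (left)
    F = np.full((n + 1, m + 1), -1e9, dtype=np.float32)  # gap in b (up)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    eptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1=open, 2=extend
    fptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_ext
            if e_open >= e_ext:
                E[i, j] = e_open
                eptr[i, j] = 1
            else:
                E[i, j] = e_ext
                eptr[i, j] = 2
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_ext
            if f_open >= f_ext:
                F[i, j] = f_open
                fptr[i, j] = 1
            else:
                F[i, j] = f_ext
                fptr[i, j] = 2
            ai = a[i - 1]
            bj_ = b[j - 1]
            if ai == bj_ and ai < 4:  # code 4 = N, always a mismatch
                s = match
            else:
                s = mismatch
            diag = H[i - 1, j - 1] + s
            h = np.float32(0.0)
            p = _STOP
            if diag > h:
                h = diag
                p = _DIAG
            if E[i, j] > h:
                h = E[i, j]
                p = _FROM_E
            if F[i, j] > h:
                h = F[i, j]
                p = _FROM_F
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptr, eptr, fptr, best, bi, bj


def smith_waterman(
    a: np.ndarray,
    b: np.ndarray,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -5.0,
    gap_ext: float = -2.0,
) -> tuple[float, tuple[int, int], tuple[int, int], np.ndarray, np.ndarray]:
    """Best local alignment of integer-coded sequences (A..T=0..3, N=4).

    Returns (score, a-interval, b-interval, aligned a codes, aligned b
    codes) with 5 standing for a gap in the aligned code arrays.
    Intervals are 0-based half-open.
    """
    H, ptr, eptr, fptr, best, bi, bj = _fill(
        a.astype(np.int8), b.astype(np.int8),
        np.float32(match), np.float32(mismatch),
        np.float32(gap_open), np.float32(gap_ext),
    )
    if best <= 0:
        return 0.0, (0, 0), (0, 0), np.empty(0, np.int8), np.empty(0, np.int8)
    out_a: list[int] = []
    out_b: list[int] = []
    i, j = bi, bj
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            p = ptr[i, j]
            if p == _STOP:
                break
            if p == _DIAG:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif p == _FROM_E:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            out_a.append(5)
            out_b.append(b[j - 1])
            state = "H" if eptr[i, j] == 1 else "E"
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append(5)
            state = "H" if fptr[i, j] == 1 else "F"
            i -= 1
    out_a.reverse()
    out_b.reverse()
    return (
        float(best),
        (i, bi),
        (j, bj),
        np.array(out_a, np.int8),
        np.array(out_b, np.int8),
    )
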