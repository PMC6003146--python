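"""Numba-compiled dynamic-programming kernels.

All kernels work on uint8-encoded sequences (A=0, C=1, G=2, T=3, other=4+).
The DP matrix convention is H[i, j] with rows i = 0..l2 indexing the vertical
(shorter) sequence and columns j = 0..l1 the horizontal (longer) one.

Banded kernels take a lower and an upper diagonal extent (wp, wm): a cell is
in-band iff -wm <= i - j <= +wp.  The corner-anchored corridor band of
half-width w uses (wp, wm) = (w, w + l1 - l2); a band centred on the main
diagonal uses (w, w).

Traceback op codes: 0 = M (diagonal, aligned pair), 1 = D (horizontal move,
gap in the vertical sequence), 2 = I (vertical move, gap in the horizontal
sequence).  Tie-break during traceback prefers M, then D, then I.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Sentinel for out-of-band cells: far below any reachable score, but safe
# against int32 overflow when a gap penalty is added to it.
NEG = -(1 << 30)


@njit(cache=True)
def fill_full(a, b, m, mm, g, semiglobal):
    """Fill the full (l2+1) x (l1+1) score matrix."""
    l1 = a.size
    l2 = b.size
    H = np.empty((l2 + 1, l1 + 1), np.int32)
    H[0, 0] = 0
    for j in range(1, l1 + 1):
        H[0, j] = 0 if semiglobal else j * g
    for i in range(1, l2 + 1):
        H[i, 0] = 0 if semiglobal else i * g
        bi = b[i - 1]
        for j in range(1, l1 + 1):
            s = m if a[j - 1] == bi else mm
            best = H[i - 1, j - 1] + s
            t = H[i, j - 1] + g
            if t > best:
                best = t
            t = H[i - 1, j] + g
            if t > best:
                best = t
            H[i, j] = best
    return H


@njit(cache=True)
def end_cell_full(H, semiglobal):
    """Pick the traceback end cell: the corner for global mode, the maximum
    over the last row then last column for semi-global (first maximum wins)."""
    l2 = H.shape[0] - 1
    l1 = H.shape[1] - 1
    if not semiglobal:
        return l2, l1
    bi = l2
    bj = 0
    best = H[l2, 0]
    for j in range(1, l1 + 1):
        if H[l2, j] > best:
            best = H[l2, j]
            bi = l2
            bj = j
    for i in range(0, l2):
        if H[i, l1] > best:
            best = H[i, l1]
            bi = i
            bj = l1
    return bi, bj


@njit(cache=True)
def traceback_full(H, a, b, m, mm, g, semiglobal, ei, ej):
    """Trace back from (ei, ej); returns ops in path order plus start cell."""
    ops = np.empty(a.size + b.size, np.uint8)
    k = 0
    i = ei
    j = ej
    while i > 0 and j > 0:
        s = m if a[j - 1] == b[i - 1] else mm
        if H[i, j] == H[i - 1, j - 1] + s:
            ops[k] = 0
            i -= 1
            j -= 1
        elif H[i, j] == H[i, j - 1] + g:
            ops[k] = 1
            j -= 1
        else:
            ops[k] = 2
            i -= 1
        k += 1
    if not semiglobal:
        while j > 0:
            ops[k] = 1
            k += 1
            j -= 1
        while i > 0:
            ops[k] = 2
            k += 1
            i -= 1
    return ops[:k][::-1].copy(), i, j


@njit(cache=True)
def fill_banded(a, b, m, mm, g, wp, wm, semiglobal):
    """Fill the band in offset-indexed storage B[i, c], c = j - i + wp.

    In-band: -wm <= i - j <= +wp.  Storage width is wp + wm + 1;
    out-of-band entries hold the NEG sentinel.
    """
    l1 = a.size
    l2 = b.size
    W = wp + wm + 1
    B = np.full((l2 + 1, W), NEG, np.int32)
    hi0 = min(l1, wm)
    for j in range(0, hi0 + 1):
        B[0, j + wp] = 0 if semiglobal else j * g
    for i in range(1, l2 + 1):
        jlo = max(0, i - wp)
        jhi = min(l1, i + wm)
        bi = b[i - 1]
        for j in range(jlo, jhi + 1):
            c = j - i + wp
            if j == 0:
                B[i, c] = 0 if semiglobal else i * g
                continue
            s = m if a[j - 1] == bi else mm
            best = B[i - 1, c] + s  # diagonal predecessor (i-1, j-1)
            if c >= 1:
                t = B[i, c - 1] + g  # horizontal predecessor (i, j-1)
                if t > best:
                    best = t
            if c + 1 < W:
                t = B[i - 1, c + 1] + g  # vertical predecessor (i-1, j)
                if t > best:
                    best = t
            B[i, c] = best
    return B


@njit(cache=True)
def end_cell_banded(B, l1, l2, wp, wm, semiglobal):
    """End cell among in-band cells of the last row, then the last column;
    scan order matches end_cell_full so results agree when the band covers
    the whole matrix."""
    if not semiglobal:
        return l2, l1
    bi = -1
    bj = -1
    best = NEG
    for j in range(max(0, l2 - wp), min(l1, l2 + wm) + 1):
        v = B[l2, j - l2 + wp]
        if v > best:
            best = v
            bi = l2
            bj = j
    for i in range(max(0, l1 - wm), min(l2 - 1, l1 + wp) + 1):
        v = B[i, l1 - i + wp]
        if v > best:
            best = v
            bi = i
            bj = l1
    return bi, bj


@njit(cache=True)
def traceback_banded(B, a, b, m, mm, g, wp, wm, wp_edge, wm_edge,
                     semiglobal, ei, ej):
    """Trace back within the band from (ei, ej).

    (wp_edge, wm_edge) are the *requested* diagonal extents used for the
    edge-touch test; they can exceed the storage extents when the requested
    band spills past the matrix.  Returns (ops, start_i, start_j, touched).
    """
    l1 = a.size
    l2 = b.size
    W = wp + wm + 1
    ops = np.empty(l1 + l2, np.uint8)
    k = 0
    i = ei
    j = ej
    touched = (i - j == wp_edge) or (j - i == wm_edge)
    while i > 0 and j > 0:
        c = j - i + wp
        s = m if a[j - 1] == b[i - 1] else mm
        if B[i, c] == B[i - 1, c] + s:
            ops[k] = 0
            i -= 1
            j -= 1
        elif c >= 1 and B[i, c] == B[i, c - 1] + g:
            ops[k] = 1
            j -= 1
        else:
            ops[k] = 2
            i -= 1
        k += 1
        if (i - j == wp_edge) or (j - i == wm_edge):
            touched = True
    if not semiglobal:
        while j > 0:
            ops[k] = 1
            k += 1
            j -= 1
            if (i - j == wp_edge) or (j - i == wm_edge):
                touched = True
        while i > 0:
            ops[k] = 2
            k += 1
            i -= 1
            if (i - j == wp_edge) or (j - i == wm_edge):
                touched = True
    return ops[:k][::-1].copy(), i, j, touched


@njit(cache=True)
def max_abs_excursion(start_i, start_j, ops):
    """Signed diagonal offset i-j at the path index maximising |i-j|
    (earliest index on ties), scanning the path start cell included."""
    i = start_i
    j = start_j
    best = i - j
    for k in range(ops.size):
        op = ops[k]
        if op == 0:
            i += 1
            j += 1
        elif op == 1:
            j += 1
        else:
            i += 1
        s = i - j
        if abs(s) > abs(best):
            best = s
    return best
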