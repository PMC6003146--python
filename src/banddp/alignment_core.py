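"""Full-matrix and banded Needleman-Wunsch alignment with traceback.

Two alignment modes are supported:

* ``global`` -- the path is anchored at both corners of the DP matrix, cell
  (0, 0) to cell (l2, l1); every end gap is charged.
* ``semiglobal`` -- overlap alignment: leading and trailing gaps in *either*
  sequence are free (first row and column initialised to zero, the score is
  maximised over the last row and last column, traceback stops on row 0 or
  column 0).  This is the natural mode for read-versus-read overlaps.

Matrix convention: rows i = 0..l2 index the vertical (shorter) sequence,
columns j = 0..l1 the horizontal (longer) one.  When the first sequence is
the shorter one the pair is swapped internally and the reported alignment
swapped back, so l1 >= l2 always holds inside; the deterministic tie-breaks
below are defined on that oriented frame.

A band of half-width w can be centred two ways:

* ``corners`` (default) -- cell (i, j) is in-band iff
  -w - (l1 - l2) <= i - j <= +w: the band hugs the corner-to-corner
  corridor, so the structural offset l1 - l2 costs no width.
* ``main_diagonal`` -- in-band iff |i - j| <= w, the geometry under which
  the random-walk exit model P(|d| > w) applies directly.

CIGAR convention (stated here once, used everywhere): ``M`` consumes one
character of each sequence (match or mismatch), ``D`` consumes only the
horizontal sequence (a gap in the vertical one), ``I`` consumes only the
vertical sequence (a gap in the horizontal one).  Hence for a global
alignment #M + #D = l1 and #M + #I = l2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from . import _kernels

Mode = Literal["global", "semiglobal"]
Center = Literal["corners", "main_diagonal"]

_ENCODE = np.full(256, 255, np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i  # lowercase

_OP_CHARS = "MDI"


@dataclass(frozen=True)
class ScoringScheme:
    """Linear scoring: per-pair match/mismatch scores and a per-symbol gap
    penalty (no affine extension).  Defaults +3 / -1 / -2."""

    match: int = 3
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap > 0:
            raise ValueError("mismatch and gap scores must be <= 0")


@dataclass(frozen=True)
class Band:
    """Diagonal band of half-width ``w`` for an l2 x l1 matrix (l1 >= l2).

    With the default ``corners`` centering, cell (i, j) is in-band iff
    -w - (l1 - l2) <= i - j <= +w, and for w >= l2 the band covers the
    whole matrix; with ``main_diagonal`` centering the condition is
    |i - j| <= w.
    """

    w: int
    l1: int
    l2: int
    center: Center = "corners"

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("band half-width w must be non-negative")
        if self.l1 < self.l2:
            raise ValueError("Band expects l1 >= l2")

    @property
    def extents(self) -> tuple[int, int]:
        """(upper, lower) diagonal extents (wp, wm): in-band iff
        -wm <= i - j <= +wp."""
        if self.center == "corners":
            return self.w, self.w + self.l1 - self.l2
        return self.w, self.w

    @property
    def width(self) -> int:
        """Number of stored cells per row."""
        wp, wm = self.extents
        return wp + wm + 1

    def contains(self, i: int, j: int) -> bool:
        wp, wm = self.extents
        return -wm <= i - j <= wp

    def covers_matrix(self) -> bool:
        wp, wm = self.extents
        return wp >= self.l2 and wm >= self.l1


@dataclass
class AlignmentResult:
    """Outcome of a pairwise DP alignment.

    ``ops`` is the op-code array (0=M, 1=D, 2=I) from ``start`` to ``end``;
    ``path`` materialises the corresponding matrix cells.  Coordinates are
    0-based half-open internally; the TSV writer reports 1-based.
    """

    score: int
    mode: Mode
    seq_h: str
    seq_v: str
    ops: np.ndarray
    start: tuple[int, int]
    end: tuple[int, int]
    n_match: int
    n_mismatch: int
    n_gap: int
    touched_edge: bool = False
    band: Optional[Band] = None

    @property
    def path(self) -> list[tuple[int, int]]:
        cells = [self.start]
        i, j = self.start
        for op in self.ops:
            if op == 0:
                i, j = i + 1, j + 1
            elif op == 1:
                j += 1
            else:
                i += 1
            cells.append((i, j))
        return cells

    @property
    def cigar(self) -> str:
        if self.ops.size == 0:
            return ""
        parts = []
        run_op = self.ops[0]
        run = 0
        for op in self.ops:
            if op == run_op:
                run += 1
            else:
                parts.append(f"{run}{_OP_CHARS[run_op]}")
                run_op = op
                run = 1
        parts.append(f"{run}{_OP_CHARS[run_op]}")
        return "".join(parts)

    def aligned_strings(self) -> tuple[str, str]:
        """Gapped horizontal and vertical strings over the aligned region."""
        i, j = self.start
        top, bot = [], []
        for op in self.ops:
            if op == 0:
                top.append(self.seq_h[j])
                bot.append(self.seq_v[i])
                i, j = i + 1, j + 1
            elif op == 1:
                top.append(self.seq_h[j])
                bot.append("-")
                j += 1
            else:
                top.append("-")
                bot.append(self.seq_v[i])
                i += 1
        return "".join(top), "".join(bot)

    def rescore(self, scoring: ScoringScheme) -> int:
        """Recompute the score column by column from the path (end gaps in
        semiglobal mode lie outside the path and contribute nothing)."""
        total = 0
        i, j = self.start
        for op in self.ops:
            if op == 0:
                ch, cv = self.seq_h[j].upper(), self.seq_v[i].upper()
                total += scoring.match if ch == cv and ch in "ACGT" \
                    else scoring.mismatch
                i, j = i + 1, j + 1
            else:
                total += scoring.gap
                i, j = (i, j + 1) if op == 1 else (i + 1, j)
        return total


def encode(seq: str, role_code: int = 4) -> np.ndarray:
    """uint8-encode a sequence; non-ACGT letters get ``role_code`` so that
    they mismatch everything, including themselves, when the two sequences
    are given distinct role codes."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), np.uint8)].copy()
    arr[arr == 255] = role_code
    return arr


def _check_inputs(seq_h: str, seq_v: str, mode: str) -> None:
    if not seq_h or not seq_v:
        raise ValueError("sequences must be non-empty")
    if mode not in ("global", "semiglobal"):
        raise ValueError(f"unknown alignment mode: {mode!r}")


def _column_counts(ops: np.ndarray, a: np.ndarray, b: np.ndarray,
                   start: tuple[int, int]) -> tuple[int, int, int]:
    i, j = start
    n_match = n_mismatch = n_gap = 0
    for op in ops:
        if op == 0:
            if a[j] == b[i]:
                n_match += 1
            else:
                n_mismatch += 1
            i, j = i + 1, j + 1
        else:
            n_gap += 1
            i, j = (i, j + 1) if op == 1 else (i + 1, j)
    return n_match, n_mismatch, n_gap


def _unswap(ops: np.ndarray, si: int, sj: int, ei: int, ej: int):
    """Transpose a result computed on swapped sequences back to the
    caller's orientation: D and I exchange, coordinates flip."""
    ops = np.where(ops == 0, 0, np.where(ops == 1, 2, 1)).astype(np.uint8)
    return ops, sj, si, ej, ei


def full_dp_align(seq_h: str, seq_v: str,
                  scoring: ScoringScheme = ScoringScheme(),
                  mode: Mode = "semiglobal") -> AlignmentResult:
    """Align two sequences with the full O(l1*l2) DP matrix.

    Returns the maximum-score alignment for the requested mode, with a
    deterministic traceback (on the oriented frame, ties prefer M, then D,
    then I; the semiglobal end cell is the first maximum met scanning the
    last row left to right, then the last column top to bottom).
    """
    _check_inputs(seq_h, seq_v, mode)
    swapped = len(seq_h) < len(seq_v)
    h, v = (seq_v, seq_h) if swapped else (seq_h, seq_v)
    a = encode(h, 4)
    b = encode(v, 5)
    semiglobal = mode == "semiglobal"
    sc = scoring
    H = _kernels.fill_full(a, b, sc.match, sc.mismatch, sc.gap, semiglobal)
    ei, ej = _kernels.end_cell_full(H, semiglobal)
    score = int(H[ei, ej])
    ops, si, sj = _kernels.traceback_full(
        H, a, b, sc.match, sc.mismatch, sc.gap, semiglobal, ei, ej)
    if swapped:
        ops, si, sj, ei, ej = _unswap(ops, si, sj, ei, ej)
        a, b = b, a
    n_m, n_mm, n_g = _column_counts(ops, a, b, (si, sj))
    return AlignmentResult(
        score=score, mode=mode, seq_h=seq_h, seq_v=seq_v,
        ops=ops, start=(si, sj), end=(ei, ej),
        n_match=n_m, n_mismatch=n_mm, n_gap=n_g)


def banded_dp_align(seq_h: str, seq_v: str,
                    scoring: ScoringScheme = ScoringScheme(),
                    mode: Mode = "semiglobal",
                    band: Band | int = 0,
                    center: Center = "corners") -> AlignmentResult:
    """Align within a diagonal band of half-width w.

    ``band`` may be a :class:`Band` (whose centering wins) or a bare
    half-width.  Storage and time are proportional to
    (wp + wm + 1) * (l2 + 1), never l1 * l2.  ``touched_edge`` is set from
    the traceback path only: true iff some path cell sits on a band
    boundary offset.
    """
    _check_inputs(seq_h, seq_v, mode)
    swapped = len(seq_h) < len(seq_v)
    h, v = (seq_v, seq_h) if swapped else (seq_h, seq_v)
    l1, l2 = len(h), len(v)
    if isinstance(band, Band):
        if (band.l1, band.l2) != (l1, l2):
            raise ValueError("Band lengths do not match the (oriented) "
                             "sequences")
        band_obj = band
    else:
        band_obj = Band(int(band), l1, l2, center)
    wp_edge, wm_edge = band_obj.extents
    if mode == "global" and l2 - l1 < -wm_edge:
        raise ValueError("band does not admit any global path: the corner "
                         "cell lies outside it")

    a = encode(h, 4)
    b = encode(v, 5)
    semiglobal = mode == "semiglobal"
    sc = scoring
    wp = min(wp_edge, l2)   # wider extents add no reachable cells
    wm = min(wm_edge, l1)
    B = _kernels.fill_banded(a, b, sc.match, sc.mismatch, sc.gap,
                             wp, wm, semiglobal)
    ei, ej = _kernels.end_cell_banded(B, l1, l2, wp, wm, semiglobal)
    ops, si, sj, touched = _kernels.traceback_banded(
        B, a, b, sc.match, sc.mismatch, sc.gap, wp, wm,
        wp_edge, wm_edge, semiglobal, ei, ej)
    score = int(B[ei, ej - ei + wp])
    if swapped:
        ops, si, sj, ei, ej = _unswap(ops, si, sj, ei, ej)
        a, b = b, a
    n_m, n_mm, n_g = _column_counts(ops, a, b, (si, sj))
    return AlignmentResult(
        score=score, mode=mode, seq_h=seq_h, seq_v=seq_v,
        ops=ops, start=(si, sj), end=(ei, ej),
        n_match=n_m, n_mismatch=n_mm, n_gap=n_g,
        touched_edge=bool(touched), band=band_obj)


def path_deviation_stat(result: AlignmentResult) -> int:
    """Signed diagonal offset s_k = i_k - j_k at the path index with the
    largest |s_k| (earliest index on ties).

    This is the travelled distance of the alignment path seen as a 1-D
    random walk: each gap in the vertical sequence steps the path one
    column right (s decreases), each gap in the horizontal sequence one row
    down (s increases).  Over symmetric simulations its mean is ~0.
    """
    ops = np.asarray(result.ops, np.uint8)
    return int(_kernels.max_abs_excursion(result.start[0], result.start[1],
                                          ops))


def count_matches(result: AlignmentResult) -> int:
    """Number of aligned columns with identical characters (= n_match)."""
    return result.n_match
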