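"""Full and banded DP against a brute-force path-enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from banddp import (Band, ScoringScheme, banded_dp_align, count_matches,
                    full_dp_align, path_deviation_stat)
from banddp.alignment_core import AlignmentResult

DNA = st.text(alphabet="ACGT", min_size=1, max_size=24)
SMALL_DNA = st.text(alphabet="ACGT", min_size=1, max_size=5)

_BASES = np.array(list("ACGT"))


def random_dna(rng, n):
    return "".join(_BASES[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# Independent oracle: explicit enumeration of every alignment path.

def enumerate_global(seq_h, seq_v, sc):
    """Best global score by recursing over all M/D/I paths."""
    l1, l2 = len(seq_h), len(seq_v)
    best = [-10 ** 9]

    def rec(i, j, score):
        if i == l2 and j == l1:
            best[0] = max(best[0], score)
            return
        if i < l2 and j < l1:
            s = sc.match if seq_h[j] == seq_v[i] else sc.mismatch
            rec(i + 1, j + 1, score + s)
        if j < l1:
            rec(i, j + 1, score + sc.gap)
        if i < l2:
            rec(i + 1, j, score + sc.gap)

    rec(0, 0, 0)
    return best[0]


def enumerate_semiglobal(seq_h, seq_v, sc):
    """Best overlap score: start on row 0 or column 0, end on the last row
    or column, leading/trailing gaps free."""
    l1, l2 = len(seq_h), len(seq_v)
    best = [-10 ** 9]

    def rec(i, j, score):
        if i == l2 or j == l1:  # free trailing gaps from here
            best[0] = max(best[0], score)
        if i < l2 and j < l1:
            s = sc.match if seq_h[j] == seq_v[i] else sc.mismatch
            rec(i + 1, j + 1, score + s)
            rec(i, j + 1, score + sc.gap)
            rec(i + 1, j, score + sc.gap)

    starts = {(0, j) for j in range(l1 + 1)} | {(i, 0) for i in range(l2 + 1)}
    for i0, j0 in starts:
        rec(i0, j0, 0)
    return best[0]


def enumerate_banded_global(seq_h, seq_v, sc, w):
    """Best global score among paths that never leave the band (l1 >= l2)."""
    l1, l2 = len(seq_h), len(seq_v)
    assert l1 >= l2
    best = [-10 ** 9]

    def in_band(i, j):
        return -w - (l1 - l2) <= i - j <= w

    def rec(i, j, score):
        if i == l2 and j == l1:
            best[0] = max(best[0], score)
            return
        if i < l2 and j < l1 and in_band(i + 1, j + 1):
            s = sc.match if seq_h[j] == seq_v[i] else sc.mismatch
            rec(i + 1, j + 1, score + s)
        if j < l1 and in_band(i, j + 1):
            rec(i, j + 1, score + sc.gap)
        if i < l2 and in_band(i + 1, j):
            rec(i + 1, j, score + sc.gap)

    rec(0, 0, 0)
    return best[0]


# ---------------------------------------------------------------------------
# Worked examples.

def test_identical_sequences_global(scoring):
    res = full_dp_align("ACGT", "ACGT", scoring, "global")
    assert (res.score, res.cigar, res.n_match) == (12, "4M", 4)


def test_single_deletion_global(scoring):
    res = full_dp_align("ACGT", "AGT", scoring, "global")
    assert res.score == enumerate_global("ACGT", "AGT", scoring) == 7
    assert res.cigar == "1M1D2M"


def test_semiglobal_free_flanks(scoring):
    res = full_dp_align("GGGACGTGGG", "ACGT", scoring, "semiglobal")
    assert res.score == enumerate_semiglobal("GGGACGTGGG", "ACGT",
                                             scoring) == 12
    assert res.cigar == "4M"
    assert res.start == (0, 3) and res.end == (4, 7)


def test_empty_sequence_rejected(scoring):
    with pytest.raises(ValueError):
        full_dp_align("", "ACGT", scoring, "global")
    with pytest.raises(ValueError):
        banded_dp_align("ACGT", "", scoring, "global", 2)


def test_non_acgt_letters_always_mismatch(scoring):
    res = full_dp_align("ANNT", "ANNT", scoring, "global")
    assert res.n_match == 2 and res.n_mismatch == 2
    assert res.score == 2 * 3 + 2 * (-1)


def test_count_matches(scoring):
    res = full_dp_align("ACGT", "AGGT", scoring, "global")
    assert count_matches(res) == 3
    res10 = full_dp_align("ACGTACGTAC", "ACGTACGTAC", scoring, "global")
    assert count_matches(res10) == 10


def test_zero_width_band_on_identical_sequences(scoring):
    res = banded_dp_align("ACGT", "ACGT", scoring, "global", 0)
    assert res.score == 12 and res.cigar == "4M"


def test_negative_band_width_rejected(scoring):
    with pytest.raises(ValueError):
        banded_dp_align("ACGT", "ACG", scoring, "global", -1)
    with pytest.raises(ValueError):
        Band(-1, 4, 3)


def test_band_membership_condition():
    band = Band(3, 20, 12)
    assert band.contains(0, 0) and band.contains(12, 20)
    assert band.contains(4, 1)            # i - j = 3 = +w boundary
    assert not band.contains(5, 1)        # i - j = 4 > w
    assert band.contains(1, 12)           # i - j = -11 = -w-(l1-l2)
    assert not band.contains(1, 13)
    assert Band(12, 20, 12).covers_matrix()


# ---------------------------------------------------------------------------
# Path deviation statistic.

def test_deviation_zero_on_diagonal(scoring):
    res = full_dp_align("ACGTAC", "ACGTAC", scoring, "global")
    assert path_deviation_stat(res) == 0


def test_deviation_of_gap_run():
    # a path 2M 3I 2M: three consecutive vertical moves push i - j to +3
    res = AlignmentResult(
        score=0, mode="global", seq_h="ACGT", seq_v="ACTTTGT",
        ops=np.array([0, 0, 2, 2, 2, 0, 0], np.uint8),
        start=(0, 0), end=(7, 4), n_match=4, n_mismatch=0, n_gap=3)
    assert path_deviation_stat(res) == 3


def test_deviation_negates_when_roles_swap(scoring, rng):
    for _ in range(10):
        a = random_dna(rng, 30)
        b = random_dna(rng, 25)
        d1 = path_deviation_stat(full_dp_align(a, b, scoring, "global"))
        d2 = path_deviation_stat(full_dp_align(b, a, scoring, "global"))
        assert d1 == -d2


# ---------------------------------------------------------------------------
# Property tests against the enumeration oracle (small instances).

@settings(max_examples=60, deadline=None, derandomize=True)
@given(SMALL_DNA, SMALL_DNA)
def test_full_dp_matches_enumeration_global(a, b):
    sc = ScoringScheme()
    assert full_dp_align(a, b, sc, "global").score == \
        enumerate_global(a, b, sc)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(SMALL_DNA, SMALL_DNA)
def test_full_dp_matches_enumeration_semiglobal(a, b):
    sc = ScoringScheme()
    assert full_dp_align(a, b, sc, "semiglobal").score == \
        enumerate_semiglobal(a, b, sc)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(SMALL_DNA, SMALL_DNA, st.integers(0, 4))
def test_banded_dp_matches_banded_enumeration(a, b, w):
    sc = ScoringScheme()
    if len(a) < len(b):
        a, b = b, a
    res = banded_dp_align(a, b, sc, "global", w)
    assert res.score == enumerate_banded_global(a, b, sc, w)


# ---------------------------------------------------------------------------
# Structural invariants on larger random instances.

@settings(max_examples=80, deadline=None, derandomize=True)
@given(DNA, DNA, st.sampled_from(["global", "semiglobal"]))
def test_score_recomputes_from_path(a, b, mode):
    sc = ScoringScheme()
    res = full_dp_align(a, b, sc, mode)
    assert res.rescore(sc) == res.score


@settings(max_examples=80, deadline=None, derandomize=True)
@given(DNA, DNA)
def test_global_cigar_conservation(a, b):
    sc = ScoringScheme()
    res = full_dp_align(a, b, sc, "global")
    ops = res.ops
    n_m = int((ops == 0).sum())
    n_d = int((ops == 1).sum())
    n_i = int((ops == 2).sum())
    assert n_m + n_d == len(a)   # horizontal characters consumed
    assert n_m + n_i == len(b)   # vertical characters consumed
    assert res.n_match + res.n_mismatch == n_m
    assert res.n_gap == n_d + n_i


@settings(max_examples=60, deadline=None, derandomize=True)
@given(DNA, DNA, st.sampled_from(["global", "semiglobal"]),
       st.integers(0, 30))
def test_banded_score_bounded_and_monotone_in_w(a, b, mode, w):
    sc = ScoringScheme()
    full = full_dp_align(a, b, sc, mode)
    r1 = banded_dp_align(a, b, sc, mode, w)
    r2 = banded_dp_align(a, b, sc, mode, w + 3)
    assert r1.score <= r2.score <= full.score
    assert r1.rescore(sc) == r1.score


@settings(max_examples=80, deadline=None, derandomize=True)
@given(DNA, DNA, st.sampled_from(["global", "semiglobal"]))
def test_wide_band_equals_full_dp(a, b, mode):
    sc = ScoringScheme()
    full = full_dp_align(a, b, sc, mode)
    banded = banded_dp_align(a, b, sc, mode, max(len(a), len(b)))
    assert banded.score == full.score
    assert banded.cigar == full.cigar


@settings(max_examples=40, deadline=None, derandomize=True)
@given(DNA, DNA, st.integers(0, 10))
def test_band_equality_when_full_path_in_band(a, b, w):
    sc = ScoringScheme()
    full = full_dp_align(a, b, sc, "global")
    l1, l2 = max(len(a), len(b)), min(len(a), len(b))
    band = Band(w, l1, l2)
    path = full.path if len(a) >= len(b) else [(j, i) for i, j in full.path]
    if all(band.contains(i, j) for i, j in path):
        assert banded_dp_align(a, b, sc, "global", w).score == full.score


def test_banded_memory_contract(scoring, rng):
    """Band storage is (2w+1+(l1-l2)) * (l2+1) cells, never l1 * l2."""
    from banddp import _kernels
    a = np.zeros(3000, np.uint8)
    b = np.zeros(2800, np.uint8)
    B = _kernels.fill_banded(a, b, 3, -1, -2, 40, 40 + 200, True)
    assert B.shape == (2801, 2 * 40 + 1 + 200)
    assert B.shape[0] * B.shape[1] < a.size * b.size / 10
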