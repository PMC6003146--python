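"""Statistical model of the alignment-path excursion and band certification.

The diagonal deviation of an alignment path between two noisy copies of the
same molecule is modelled as a 1-D random walk: per aligned position the
path steps right with probability p_r, left with p_l, or stays.  Counting
r right steps and l left steps in a walk of length N (multinomial), the
travelled distance d = r - l has

    E(d)   = N (p_r - p_l)
    Var(d) = N p_r (1 - p_r) + N p_l (1 - p_l) + 2 N p_r p_l

which for the symmetric case p_r = p_l = p reduces to E(d) = 0 and
Var(d) = 2 N p.  The effective step probability is driven by the indel
rates of the two reads:

    p = 2 (p_d + p_i - p_d^2 - p_i^2)

(the quadratic terms remove indels that cancel at the same position; a
further small cross-term of order p_i*p_d is deliberately ignored, which
makes sigma_d a slight over-estimate -- conservative for band sizing).

Choosing the half-width w = 3 sigma_d leaves under a 0.3% chance that the
path exits the band, giving an O(N^(3/2)) alignment.  A cheaper staged
schedule widens the band only when needed: w = sigma_d, 2 sigma_d,
3 sigma_d, then doubling; with stage occupancies (0.68, 0.28, 0.04) the
expected cost is 3.52 sigma_d N, about half the one-shot 6 sigma_d N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .alignment_core import (AlignmentResult, Mode, ScoringScheme,
                             banded_dp_align, count_matches, full_dp_align)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base event probabilities of a sequencing technology:
    no modification (p_u), mismatch (p_m), insertion (p_i), deletion (p_d).
    Must sum to 1."""

    p_u: float
    p_m: float
    p_i: float
    p_d: float

    def __post_init__(self) -> None:
        probs = (self.p_u, self.p_m, self.p_i, self.p_d)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_u, self.p_m, self.p_i, self.p_d)


#: Error-rate sets used throughout the simulation studies
#: (p_u, p_m, p_i, p_d).
ERROR_SETS: dict[int, ErrorProfile] = {
    1: ErrorProfile(0.85, 0.03, 0.075, 0.045),
    2: ErrorProfile(0.93, 0.01, 0.04, 0.02),
    3: ErrorProfile(0.89, 0.02, 0.06, 0.03),
}

#: Typical PacBio long-read rates: 3% mismatches, 7% insertions, 4% deletions.
PACBIO = ErrorProfile(0.86, 0.03, 0.07, 0.04)


def step_probability(profile: ErrorProfile) -> float:
    """Effective symmetric step probability p = 2(p_d + p_i - p_d^2 - p_i^2)."""
    p_i, p_d = profile.p_i, profile.p_d
    return 2.0 * (p_d + p_i - p_d * p_d - p_i * p_i)


def sigma_d(profile: ErrorProfile, N: int) -> float:
    """Standard deviation of the path deviation d: sqrt(2 N p)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.sqrt(2.0 * N * step_probability(profile))


def walk_moments(p_r: float, p_l: float, N: int) -> tuple[float, float]:
    """Mean and variance of d = r - l for the general asymmetric walk.

    Internal derivation cross-check: reduces to (0, 2Np) when p_r = p_l = p.
    """
    mean = N * (p_r - p_l)
    var = N * p_r * (1 - p_r) + N * p_l * (1 - p_l) + 2 * N * p_r * p_l
    return mean, var


@dataclass(frozen=True)
class WalkModel:
    """Symmetric random-walk summary for a read pair of length N."""

    p: float
    N: int

    @property
    def sigma_d(self) -> float:
        return math.sqrt(2.0 * self.N * self.p)


def band_schedule(sigma: float, l1: int, l2: int) -> list[int]:
    """Staged half-width schedule: ceil(sigma), ceil(2 sigma), ceil(3 sigma),
    then doubling, each value capped at l2 (w >= l2 covers the whole
    matrix); strictly increasing."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    widths: list[int] = []
    for k in (1, 2, 3):
        w = min(math.ceil(k * sigma), l2)
        if not widths or w > widths[-1]:
            widths.append(w)
        if w >= l2:
            return widths
    while widths[-1] < l2:
        widths.append(min(2 * widths[-1], l2))
    return widths


def expected_cost_coefficient(stage_fractions: Sequence[float],
                              stage_multipliers: Optional[Sequence[int]] = None
                              ) -> float:
    """Coefficient of sigma_d * N in the expected cost of the staged
    schedule.

    A stage of half-width k*sigma costs 2*k*sigma*N cells; a pair settled
    at stage k has paid for every stage up to k.  With occupancies
    (0.68, 0.28, 0.04) over multipliers (1, 2, 3) this evaluates to 3.52.
    """
    fractions = list(stage_fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("stage fractions must sum to 1")
    mult = list(stage_multipliers) if stage_multipliers is not None \
        else list(range(1, len(fractions) + 1))
    if len(mult) != len(fractions):
        raise ValueError("need one multiplier per stage")
    total = 0.0
    cumulative = 0.0
    for frac, k in zip(fractions, mult):
        cumulative += 2.0 * k
        total += frac * cumulative
    return total


def band_exit_probability(k: float) -> float:
    """Normal-model probability that |d| exceeds k standard deviations:
    2 (1 - Phi(k)); about 0.0027 at k = 3."""
    return float(math.erfc(k / math.sqrt(2.0)))


class Reason(str, Enum):
    IN_BAND_CERTIFIED = "in_band_certified"
    EDGE_TOUCHED = "edge_touched"
    MATCH_COUNT_LOW = "match_count_low"
    GLOBAL_BOUND_CERTIFIED = "global_bound_certified"
    GLOBAL_BOUND_FAILED = "global_bound_failed"


_ACCEPT_REASONS = {Reason.IN_BAND_CERTIFIED, Reason.GLOBAL_BOUND_CERTIFIED}


@dataclass(frozen=True)
class CertificationDecision:
    accepted: bool
    reason: Reason
    threshold_used: Optional[float]

    def __post_init__(self) -> None:
        assert self.accepted == (self.reason in _ACCEPT_REASONS)


def best_out_score(w: int, l1: int, l2: int,
                   scoring: ScoringScheme) -> Optional[int]:
    """Upper bound on the score of any global path leaving the band:

        best_out = [2(w+1) - (l1-l2)] g + [l2 - (w+1)] m

    (w+1 gaps in the vertical sequence, w+1-(l1-l2) in the horizontal one,
    and at most l2-(w+1) aligned pairs, all generously scored as matches).
    Returns None when w + 1 > l2: no path can leave such a band.
    """
    if l1 < l2:
        raise ValueError("best_out_score expects l1 >= l2")
    if w + 1 > l2:
        return None
    g, m = scoring.gap, scoring.match
    return (2 * (w + 1) - (l1 - l2)) * g + (l2 - (w + 1)) * m


def certify_global(s_band: int, w: int, l1: int, l2: int,
                   scoring: ScoringScheme) -> CertificationDecision:
    """Global-mode certification: s_band >= best_out proves the banded score
    beats every path that exits the band, hence is optimal."""
    bound = best_out_score(w, l1, l2, scoring)
    if bound is None:
        return CertificationDecision(True, Reason.GLOBAL_BOUND_CERTIFIED, None)
    if s_band >= bound:
        return CertificationDecision(True, Reason.GLOBAL_BOUND_CERTIFIED,
                                     float(bound))
    return CertificationDecision(False, Reason.GLOBAL_BOUND_FAILED,
                                 float(bound))


def match_count_bounds(profile: ErrorProfile,
                       N: int) -> tuple[float, float, float]:
    """Mean, SD and lower 99%-confidence threshold of the match count N_m:
    E(N_m) = N p_u, Var(N_m) = N p_u (1 - p_u), threshold = mean - 3 SD."""
    if N < 1:
        raise ValueError("N must be >= 1")
    mean = N * profile.p_u
    sd = math.sqrt(N * profile.p_u * (1.0 - profile.p_u))
    return mean, sd, mean - 3.0 * sd


def certify_semiglobal(result: AlignmentResult, profile: ErrorProfile,
                       N: int) -> CertificationDecision:
    """Semi-global certification, two criteria in order:

    i)  the traceback path must not reach the band edge;
    ii) the match count must not fall below E(N_m) - 3 sigma_{N_m}
        (lower half of the 99% confidence interval).

    Either failure means the band is suspect and should be widened.
    """
    _, _, threshold = match_count_bounds(profile, N)
    if result.touched_edge:
        return CertificationDecision(False, Reason.EDGE_TOUCHED, threshold)
    if count_matches(result) < threshold:
        return CertificationDecision(False, Reason.MATCH_COUNT_LOW, threshold)
    return CertificationDecision(True, Reason.IN_BAND_CERTIFIED, threshold)


def align_adaptive(seq_h: str, seq_v: str, profile: ErrorProfile,
                   scoring: ScoringScheme = ScoringScheme(),
                   mode: Mode = "semiglobal"
                   ) -> tuple[AlignmentResult, CertificationDecision, list[int]]:
    """Staged banded alignment: walk the band schedule, certify each stage,
    return the first accepted result.

    The last scheduled width equals the shorter length, i.e. the full
    matrix, whose result is exact by construction; if even its
    certification fails (pathological inputs) the exact result is still
    returned, marked as certified because no path can leave a band that
    covers the matrix.  Returns (result, decision, widths tried).
    """
    l1, l2 = max(len(seq_h), len(seq_v)), min(len(seq_h), len(seq_v))
    N = l1  # reads are near-equal length; use the longer one
    sigma = sigma_d(profile, N)
    schedule = band_schedule(sigma if sigma > 0 else 1.0, l1, l2)
    stages_used: list[int] = []
    result: AlignmentResult
    decision: CertificationDecision
    for w in schedule:
        stages_used.append(w)
        result = banded_dp_align(seq_h, seq_v, scoring, mode, w)
        if mode == "global":
            decision = certify_global(result.score, w, l1, l2, scoring)
        else:
            decision = certify_semiglobal(result, profile, N)
        if decision.accepted:
            return result, decision, stages_used
    if schedule[-1] >= l2:
        # the last stage already spanned the matrix: its score is exact
        decision = CertificationDecision(
            True,
            Reason.GLOBAL_BOUND_CERTIFIED if mode == "global"
            else Reason.IN_BAND_CERTIFIED,
            decision.threshold_used)
        return result, decision, stages_used
    stages_used.append(l2)
    result = full_dp_align(seq_h, seq_v, scoring, mode)
    decision = CertificationDecision(
        True,
        Reason.GLOBAL_BOUND_CERTIFIED if mode == "global"
        else Reason.IN_BAND_CERTIFIED,
        None)
    return result, decision, stages_used
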