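"""Simulation studies validating the band model.

Two studies are provided, both on simulated read pairs:

* :func:`run_table1` -- does the analytic sigma_d = sqrt(2 N p) describe
  the spread of the measured path deviation d?  For each (length,
  error-set) cell it aligns ``n_pairs`` pairs with the full-matrix
  semi-global DP, measures d on every path, and reports the empirical
  mean/SD next to the analytic value.

* :func:`run_table2` -- how reliable are the two semi-global
  certification criteria at the cheapest band, w = ceil(sigma_d)?  Each
  banded alignment is cross-classified by whether its traceback touched
  the band edge (criterion i) and whether its score equals the full-matrix
  optimum; a second classification then adds the match-count test
  (criterion ii), which can only turn acceptances into rejections.

* :func:`run_band_exit` -- the fraction of full-DP paths whose deviation
  exceeds k sigma_d, next to the normal-model tail 2(1 - Phi(k)).

Runs are sized by ``n_pairs`` and ``lengths``; full-size replications are
available through the same parameters.  Binomial/SD standard errors are
reported so scaled-down runs state their uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_core import (ScoringScheme, banded_dp_align, full_dp_align,
                             path_deviation_stat)
from .band_model import (ERROR_SETS, ErrorProfile, band_exit_probability,
                         certify_semiglobal, sigma_d)
from .synthetic_data import Pairing, pair_stream

#: Scoring used throughout the studies.
DEFAULT_SCORING = ScoringScheme(match=3, mismatch=-1, gap=-2)


def _as_profile(error_set: "int | ErrorProfile") -> ErrorProfile:
    if isinstance(error_set, ErrorProfile):
        return error_set
    return ERROR_SETS[int(error_set)]


def _set_label(error_set: "int | ErrorProfile") -> str:
    return str(error_set) if not isinstance(error_set, ErrorProfile) \
        else "custom"


@dataclass(frozen=True)
class Table1Row:
    """One (length, error-set) cell of the sigma comparison."""

    N: int
    error_set: str
    n_pairs: int
    mean_d: float
    mean_d_se: float
    sigma_ex: float
    sigma_ex_se: float
    sigma_th: float


def run_table1(lengths: Sequence[int] = (2000, 3000, 4000, 6000),
               error_sets: Sequence["int | ErrorProfile"] = (1, 2, 3),
               n_pairs: int = 1000,
               seed: int = 0,
               pairing: Pairing = "both_mutated",
               scoring: ScoringScheme = DEFAULT_SCORING) -> pd.DataFrame:
    """Empirical vs analytic standard deviation of the path deviation d.

    Returns a DataFrame with one row per (error set, length) cell:
    empirical mean of d with its standard error (expected ~0 by symmetry),
    empirical SD with standard error sigma_ex / sqrt(2(n-1)), and the
    analytic sigma_th = sqrt(2 N p).
    """
    if n_pairs < 30:
        raise ValueError("n_pairs must be >= 30 for a meaningful SD")
    root = np.random.SeedSequence(seed)
    rows: list[Table1Row] = []
    for error_set in error_sets:
        profile = _as_profile(error_set)
        for N in lengths:
            cell_seed = root.spawn(1)[0]
            ds = np.empty(n_pairs)
            for idx, pair in enumerate(
                    pair_stream(N, profile, n_pairs, cell_seed, pairing)):
                res = full_dp_align(pair.seq_a, pair.seq_b, scoring,
                                    "semiglobal")
                ds[idx] = path_deviation_stat(res)
            sd = float(ds.std(ddof=1))
            rows.append(Table1Row(
                N=N, error_set=_set_label(error_set), n_pairs=n_pairs,
                mean_d=float(ds.mean()),
                mean_d_se=sd / math.sqrt(n_pairs),
                sigma_ex=sd,
                sigma_ex_se=sd / math.sqrt(2.0 * (n_pairs - 1)),
                sigma_th=sigma_d(profile, N)))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Table2Cell:
    reached_edge: bool
    optimal: bool
    count: int
    percentage: float


@dataclass
class Table2Report:
    """Cross-classification of banded semi-global alignments at w=ceil(sigma).

    ``cells`` holds the four (reached_edge, optimal) percentages from
    criterion i alone; ``adjusted_cells`` re-classifies with the full
    certification (criteria i + ii) as (rejected, optimal).  The two
    off-diagonal quantities of interest are exposed directly: the
    wrongly-accepted fraction (no edge touch / certification accepted, yet
    suboptimal) before and after criterion ii.
    """

    n: int
    cells: list[Table2Cell]
    adjusted_cells: list[Table2Cell]
    per_pair: pd.DataFrame = field(repr=False)

    def cell(self, reached_edge: bool, optimal: bool) -> Table2Cell:
        for c in self.cells:
            if c.reached_edge == reached_edge and c.optimal == optimal:
                return c
        raise KeyError((reached_edge, optimal))

    def adjusted_cell(self, rejected: bool, optimal: bool) -> Table2Cell:
        for c in self.adjusted_cells:
            if c.reached_edge == rejected and c.optimal == optimal:
                return c
        raise KeyError((rejected, optimal))

    @property
    def wrongly_accepted_before(self) -> float:
        """% not reaching the edge yet suboptimal (criterion i only)."""
        return self.cell(False, False).percentage

    @property
    def wrongly_accepted_after(self) -> float:
        """% accepted by criteria i+ii yet suboptimal."""
        return self.adjusted_cell(False, False).percentage

    def as_frame(self) -> pd.DataFrame:
        rows = [{"classification": "criterion_i",
                 "reached_edge_or_rejected": c.reached_edge,
                 "optimal": c.optimal, "count": c.count,
                 "percentage": c.percentage} for c in self.cells]
        rows += [{"classification": "criteria_i_and_ii",
                  "reached_edge_or_rejected": c.reached_edge,
                  "optimal": c.optimal, "count": c.count,
                  "percentage": c.percentage} for c in self.adjusted_cells]
        return pd.DataFrame(rows)


def run_table2(error_set: "int | ErrorProfile" = 3,
               lengths: Sequence[int] = (2000, 3000, 4000, 6000),
               n_pairs: int = 1000,
               w_policy=None,
               seed: int = 0,
               pairing: Pairing = "both_mutated",
               scoring: ScoringScheme = DEFAULT_SCORING,
               center: str = "main_diagonal") -> Table2Report:
    """Banded-vs-full cross-classification at the narrowest scheduled band.

    ``n_pairs`` pairs are generated per length and pooled.  For each pair
    the band half-width is ``w_policy(profile, N)`` (default
    ceil(sigma_d), with N the longer read length); the banded semi-global
    score is compared with the full-matrix semi-global optimum.

    The band is centred on the main diagonal by default: that is the
    geometry the random-walk exit model P(|d| > w) speaks about, d being
    the maximal |i - j| along the path.  The corner-anchored corridor band
    (``center="corners"``) additionally absorbs the read-length difference
    l1 - l2, so at the same nominal w it exits far more rarely.
    """
    profile = _as_profile(error_set)
    if w_policy is None:
        # w = ceil(sigma_d); floor of 1 because a zero-width band is
        # degenerate (every diagonal cell sits on both band edges)
        w_policy = lambda prof, N: max(1, math.ceil(sigma_d(prof, N)))
    root = np.random.SeedSequence(seed)
    records = []
    for N in lengths:
        cell_seed = root.spawn(1)[0]
        for idx, pair in enumerate(
                pair_stream(N, profile, n_pairs, cell_seed, pairing)):
            n_long = max(len(pair.seq_a), len(pair.seq_b))
            w = int(w_policy(profile, n_long))
            banded = banded_dp_align(pair.seq_a, pair.seq_b, scoring,
                                     "semiglobal", w, center=center)
            full = full_dp_align(pair.seq_a, pair.seq_b, scoring,
                                 "semiglobal")
            decision = certify_semiglobal(banded, profile, n_long)
            records.append({
                "N": N, "pair": idx, "w": w,
                "reached_edge": banded.touched_edge,
                "optimal": banded.score == full.score,
                "banded_score": banded.score, "full_score": full.score,
                "n_match": banded.n_match,
                "rejected": not decision.accepted,
                "reject_reason": decision.reason.value,
            })
    per_pair = pd.DataFrame(records)
    n = len(per_pair)

    def _grid(flag_col: str) -> list[Table2Cell]:
        cells = []
        for flag in (False, True):
            for optimal in (True, False):
                count = int(((per_pair[flag_col] == flag)
                             & (per_pair["optimal"] == optimal)).sum())
                cells.append(Table2Cell(flag, optimal, count,
                                        100.0 * count / n))
        return cells

    return Table2Report(n=n, cells=_grid("reached_edge"),
                        adjusted_cells=_grid("rejected"), per_pair=per_pair)


def run_band_exit(error_set: "int | ErrorProfile",
                  N: int,
                  k_values: Sequence[float] = (1, 2, 3),
                  n_pairs: int = 1000,
                  seed: int = 0,
                  pairing: Pairing = "both_mutated",
                  scoring: ScoringScheme = DEFAULT_SCORING) -> pd.DataFrame:
    """Fraction of full-DP paths with |d| > k sigma_d, per k.

    Also reports the analytic normal-model tail 2(1 - Phi(k)) and a
    binomial standard error for each measured fraction.
    """
    profile = _as_profile(error_set)
    sigma = sigma_d(profile, N)
    ds = np.empty(n_pairs)
    for idx, pair in enumerate(
            pair_stream(N, profile, n_pairs,
                        np.random.SeedSequence(seed), pairing)):
        res = full_dp_align(pair.seq_a, pair.seq_b, scoring, "semiglobal")
        ds[idx] = path_deviation_stat(res)
    rows = []
    for k in k_values:
        frac = float(np.mean(np.abs(ds) > k * sigma))
        rows.append({
            "k": k, "sigma_d": sigma, "N": N, "n_pairs": n_pairs,
            "exit_fraction": frac,
            "exit_fraction_se": math.sqrt(max(frac * (1 - frac), 0.0)
                                          / n_pairs),
            "analytic": band_exit_probability(k),
        })
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path) -> None:
    """Write any report DataFrame as TSV."""
    df.to_csv(path, sep="\t", index=False)
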