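"""Threshold aggregation and reliability statistics for adaptive runs.

Because the staircases are multiplicative, every mean over thresholds is
geometric and every spread is a sample SD (n-1) of log10 thresholds.  The
module covers: the clinical aggregation rule (three runs, plus a fourth when
the spread is too large), the required-number-of-runs calculation from
test-retest spread, run-ratio repeatability, the R ratio relating the fixed
IPD of the adaptive-frequency test to a listener's IPD threshold at 250 Hz,
Spearman rank correlation, and per-listener practice slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class AnalysisError(ValueError):
    pass


class InsufficientDataError(AnalysisError):
    pass


def _log10(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise AnalysisError("thresholds must be positive and finite")
    return np.log10(arr)


def geometric_mean(values: Sequence[float]) -> float:
    return float(10.0 ** np.mean(_log10(values)))


def sd_log10(values: Sequence[float]) -> float:
    """Sample SD (n-1 denominator) of log10 values."""
    return float(np.std(_log10(values), ddof=1))


@dataclass(frozen=True)
class ThresholdSet:
    """Ordered run thresholds for one listener at one test condition."""

    listener_id: str
    thresholds: tuple[float, ...]
    valid: tuple[bool, ...] = ()
    phi_deg: Optional[float] = None

    def __post_init__(self) -> None:
        _log10(self.thresholds)  # validates positivity
        if self.valid and len(self.valid) != len(self.thresholds):
            raise AnalysisError("valid flags must match thresholds in length")


@dataclass(frozen=True)
class AggregateResult:
    estimate: Optional[float]
    needs_extra_run: bool
    sd_log10_first3: float
    n_runs_used: int


def aggregate_runs(ts: ThresholdSet, sd_limit: float = 0.20) -> AggregateResult:
    """Final threshold from three (or four) runs.

    If the sample SD of log10 thresholds across the first three runs is
    <= ``sd_limit``, the estimate is their geometric mean.  Otherwise an extra
    run is required: with a fourth run present the estimate is the geometric
    mean of all four; without one the result is flagged ``needs_extra_run``
    with no estimate.
    """
    t = ts.thresholds
    if len(t) < 3:
        raise InsufficientDataError(f"need >= 3 runs, got {len(t)}")
    sd3 = sd_log10(t[:3])
    if sd3 <= sd_limit:
        return AggregateResult(geometric_mean(t[:3]), False, sd3, 3)
    if len(t) >= 4:
        return AggregateResult(geometric_mean(t[:4]), False, sd3, 4)
    return AggregateResult(None, True, sd3, 0)


def required_runs(sd_log: float, tolerance_factor: float = 1.3) -> tuple[float, int]:
    """Number of runs needed for 95% of n-run means to fall within a factor
    of ``tolerance_factor`` of the true threshold.

    With SE = SD/sqrt(n) and a +/-2 SE criterion on the log scale, the bound
    2*SD/sqrt(n) <= log10(tolerance_factor) gives

        n = (2 * sd_log / log10(tolerance_factor))^2

    Returns (real-valued n, nearest whole number of runs).
    """
    if sd_log < 0 or not math.isfinite(sd_log):
        raise AnalysisError("sd_log must be finite and >= 0")
    if tolerance_factor <= 1.0:
        raise AnalysisError("tolerance_factor must exceed 1")
    n = (2.0 * sd_log / math.log10(tolerance_factor)) ** 2
    return n, round(n)


def run_ratio(ts: ThresholdSet, first: int = 1, last: int = 3) -> float:
    """Ratio threshold[last] / threshold[first] (1-based run indices)."""
    for idx in (first, last):
        if not 1 <= idx <= len(ts.thresholds):
            raise InsufficientDataError(
                f"run {idx} missing (have {len(ts.thresholds)} runs)")
    return ts.thresholds[last - 1] / ts.thresholds[first - 1]


def cohort_run_ratio(sets: Sequence[ThresholdSet], first: int = 1,
                     last: int = 3) -> dict:
    """Run-ratio repeatability over a cohort: mean, SD, min, max."""
    ratios = np.array([run_ratio(ts, first, last) for ts in sets])
    if ratios.size == 0:
        raise InsufficientDataError("empty cohort")
    # the geometric mean is the unbiased center for ratios of log-normal
    # thresholds; the arithmetic mean is reported but sits above 1 even for
    # a perfectly stationary cohort
    return {"mean": float(ratios.mean()),
            "geomean": geometric_mean(ratios),
            "sd": float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0,
            "min": float(ratios.min()), "max": float(ratios.max()),
            "n": int(ratios.size)}


def ratio_R(phi_deg: float, tfslf_threshold_deg: float) -> float:
    """R = phi / (IPD threshold at 250 Hz).  Values below ~3 mark conditions
    where the adaptive-frequency test becomes unreliable: the fixed IPD is too
    close to what the listener can discriminate at all."""
    if phi_deg <= 0 or tfslf_threshold_deg <= 0:
        raise AnalysisError("phi and threshold must be positive")
    return phi_deg / tfslf_threshold_deg


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of mid-rank-transformed vectors.

    Returns the statistic only; no significance test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise AnalysisError("need two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise AnalysisError("rank correlation undefined for a constant vector")
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass(frozen=True)
class PracticeSlope:
    slope: float        # log10 units per block
    stderr: float
    intercept: float
    n_blocks: int


def practice_slope(thresholds: Sequence[float], block_size: int = 3) -> PracticeSlope:
    """OLS slope of mean log10 threshold per block against block index.

    Blocks group consecutive runs (default three per block, mirroring testing
    in blocks of three with breaks).  A slope indistinguishable from zero
    indicates no practice effect."""
    logs = _log10(thresholds)
    n_blocks = len(logs) // block_size
    if n_blocks < 2:
        raise InsufficientDataError("need >= 2 complete blocks")
    block_means = logs[: n_blocks * block_size].reshape(n_blocks, block_size).mean(axis=1)
    res = stats.linregress(np.arange(1, n_blocks + 1), block_means)
    return PracticeSlope(slope=float(res.slope), stderr=float(res.stderr),
                         intercept=float(res.intercept), n_blocks=n_blocks)


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-listener reliability summary over a session of repeated runs."""

    listener_id: str
    n_runs: int
    mean_log10: float          # mean of log10 thresholds ("mean_15" analog)
    sd_log10: float            # SD of log10 thresholds ("SD_15" analog)
    geometric_mean: float
    run_ratio_last_first: Optional[float]
    required_runs_exact: float
    required_runs_rounded: int

    def to_json(self) -> dict:
        return dict(self.__dict__)


def reliability_report(ts: ThresholdSet,
                       tolerance_factor: float = 1.3) -> ReliabilityReport:
    t = ts.thresholds
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 runs for a reliability report")
    logs = _log10(t)
    sd = float(np.std(logs, ddof=1))
    n_exact, n_round = required_runs(sd, tolerance_factor)
    return ReliabilityReport(
        listener_id=ts.listener_id, n_runs=len(t),
        mean_log10=float(np.mean(logs)), sd_log10=sd,
        geometric_mean=geometric_mean(t),
        run_ratio_last_first=run_ratio(ts, 1, len(t)),
        required_runs_exact=n_exact, required_runs_rounded=n_round)


def cohort_table_to_threshold_sets(df: pd.DataFrame) -> list[ThresholdSet]:
    """Convert a long-format cohort table (as produced by simulate_cohort or
    read back from its CSV) into per-listener ThresholdSets, ordered by run."""
    sets = []
    for lid, grp in df.groupby("listener_id", sort=True):
        grp = grp.sort_values("run_index")
        phi = grp["phi_deg"].iloc[0] if "phi_deg" in grp else None
        sets.append(ThresholdSet(
            listener_id=str(lid),
            thresholds=tuple(grp["threshold"].astype(float)),
            valid=tuple(grp["valid"].astype(bool)) if "valid" in grp else (),
            phi_deg=phi))
    return sets
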