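"""Transformed up-down adaptive staircases for the TFS-AF and TFS-LF tests.

Both tests use a two-interval forced-choice task with a transformed up-down
rule (Levitt): after ``n_correct_to_harden`` consecutive correct responses the
task is made one step harder; any incorrect response makes it one step easier.
With n = 2 the track converges on the 70.7% correct point of the psychometric
function (the value at which two consecutive correct responses are as likely
as not); n = 3 tracks 79.4%.

TFS-AF adaptively raises the tone *frequency* (harder = higher): steps are
multiplicative with factors 1.4 before the first reversal, 1.2 until the
second, and 1.1 thereafter, with a 30-Hz floor.  TFS-LF adaptively shrinks
the *IPD* at a fixed 250-Hz tone (harder = smaller phase), with factors
1.95 / 1.56 / 1.25 and a 180-deg ceiling.  A run terminates after eight
reversals; the threshold is the geometric mean of the values at the last six,
and the run is valid if the sample SD of their log10 values is <= 0.2.

Reversal bookkeeping: each executed step carries a logical direction (harder
or easier).  A reversal is recorded when that direction differs from the
previous step's direction; the first step only establishes direction.  The
reversal value is the stimulus value presented on the trial at which the
direction flipped (the track's extremum).  A step that is clamped at the
floor keeps its logical direction, so the tracker stays well-defined at the
bound; pinned trials are counted in the result.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

import numpy as np

HARDER, EASIER = "harder", "easier"


class StaircaseError(ValueError):
    pass


class IllegalStateError(StaircaseError):
    """Update requested on a terminated run."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive track.

    ``step_factors`` are indexed by the number of reversals already recorded:
    entry 0 applies until (and including) the step that produces the first
    reversal, entry 1 until the second, the last entry thereafter.
    """

    tracked_variable: Literal["frequency", "ipd"] = "frequency"
    harder_direction: Literal["increase", "decrease"] = "increase"
    n_correct_to_harden: int = 2
    step_factors: tuple[float, ...] = (1.4, 1.2, 1.1)
    start_value: float = 200.0
    floor: Optional[float] = 30.0
    ceiling: Optional[float] = None
    total_reversals: int = 8
    reversals_for_threshold: int = 6
    validity_sd_limit: float = 0.2
    max_trials: int = 400
    phi_deg: float = 180.0          # fixed IPD for TFS-AF
    fixed_frequency_hz: float = 250.0  # fixed frequency for TFS-LF

    def __post_init__(self) -> None:
        if any(f <= 1.0 for f in self.step_factors):
            raise StaircaseError("all step factors must exceed 1")
        if self.reversals_for_threshold > self.total_reversals:
            raise StaircaseError("reversals_for_threshold > total_reversals")
        if self.n_correct_to_harden < 1:
            raise StaircaseError("n_correct_to_harden must be >= 1")
        if self.floor is not None and self.start_value < self.floor:
            raise StaircaseError("start value below floor")
        if self.ceiling is not None and self.start_value > self.ceiling:
            raise StaircaseError("start value above ceiling")

    @classmethod
    def tfs_af(cls, phi_deg: float = 180.0, start_value: float = 200.0,
               **overrides) -> "StaircaseConfig":
        """Adaptive-frequency test: phi fixed, frequency tracked upward.

        ``start_value=100`` is the published fallback for listeners who cannot
        do the task at 200 Hz."""
        return cls(tracked_variable="frequency", harder_direction="increase",
                   step_factors=(1.4, 1.2, 1.1), start_value=start_value,
                   floor=30.0, ceiling=None, phi_deg=phi_deg, **overrides)

    @classmethod
    def tfs_lf(cls, fixed_frequency_hz: float = 250.0, **overrides) -> "StaircaseConfig":
        """Adaptive-IPD test at a fixed low frequency: IPD tracked downward."""
        return cls(tracked_variable="ipd", harder_direction="decrease",
                   step_factors=(1.95, 1.56, 1.25), start_value=180.0,
                   floor=None, ceiling=180.0,
                   fixed_frequency_hz=fixed_frequency_hz, **overrides)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class TrialRecord:
    trial: int
    value: float
    target_interval: int
    response_interval: int
    correct: bool
    reversal: bool
    factor: float


@dataclass
class StaircaseState:
    """Evolving state of one run; mutated only by :func:`update`."""

    cfg: StaircaseConfig
    value: float = field(init=False)
    n_consecutive_correct: int = 0
    last_direction: Optional[str] = None  # HARDER / EASIER / None
    reversal_values: list[float] = field(default_factory=list)
    trial_log: list[TrialRecord] = field(default_factory=list)
    clamped_at_floor: int = 0

    def __post_init__(self) -> None:
        self.value = self.cfg.start_value

    @property
    def terminated(self) -> bool:
        return len(self.reversal_values) >= self.cfg.total_reversals

    @property
    def n_trials(self) -> int:
        return len(self.trial_log)


def _step(value: float, factor: float, direction: str,
          cfg: StaircaseConfig) -> tuple[float, bool]:
    """Apply one multiplicative step in the given logical direction.

    Returns (new value, hit-floor flag)."""
    toward_harder = (direction == HARDER)
    multiply_is_harder = (cfg.harder_direction == "increase")
    if toward_harder == multiply_is_harder:
        new = value * factor
    else:
        new = value / factor
    hit_floor = cfg.floor is not None and new < cfg.floor
    if hit_floor:
        new = cfg.floor
    if cfg.ceiling is not None:
        new = min(new, cfg.ceiling)
    return new, hit_floor


def update(state: StaircaseState, correct: bool, *,
           target_interval: int = 0, response_interval: int = 0) -> StaircaseState:
    """Advance the staircase by one trial outcome (mutates and returns state).

    The presented value for this trial is ``state.value`` before the call.
    Interval bookkeeping is optional metadata for the trial log.
    """
    cfg = state.cfg
    if state.terminated:
        raise IllegalStateError("run already terminated (8 reversals reached)")

    presented = state.value
    direction: Optional[str] = None
    if correct:
        state.n_consecutive_correct += 1
        if state.n_consecutive_correct >= cfg.n_correct_to_harden:
            state.n_consecutive_correct = 0
            direction = HARDER
    else:
        state.n_consecutive_correct = 0
        direction = EASIER

    reversal = False
    n_rev_before = len(state.reversal_values)
    factor = cfg.step_factors[min(n_rev_before, len(cfg.step_factors) - 1)]
    if direction is not None:
        new_value, hit_floor = _step(presented, factor, direction, cfg)
        if hit_floor:
            state.clamped_at_floor += 1
        if state.last_direction is not None and direction != state.last_direction:
            reversal = True
            state.reversal_values.append(presented)
        state.last_direction = direction
        state.value = new_value

    state.trial_log.append(TrialRecord(
        trial=state.n_trials + 1, value=presented,
        target_interval=target_interval, response_interval=response_interval,
        correct=correct, reversal=reversal, factor=factor))
    return state


@dataclass(frozen=True)
class RunResult:
    """Outcome of one adaptive run."""

    threshold: Optional[float]
    reversal_values: tuple[float, ...]
    valid: bool
    n_trials: int
    trial_log: tuple[TrialRecord, ...]
    clamped_at_floor: int
    seed: Optional[int]
    config: StaircaseConfig
    aborted: bool = False
    abort_reason: Optional[str] = None

    @property
    def high_threshold_flag(self) -> bool:
        """Thresholds above 1500 Hz are implausibly high for IPD detection and
        usually reflect a streak of lucky guesses; flag them for review."""
        return (self.config.tracked_variable == "frequency"
                and self.threshold is not None and self.threshold > 1500.0)

    def to_json(self) -> dict:
        return {
            "threshold": self.threshold,
            "reversals": list(self.reversal_values),
            "valid": self.valid,
            "n_trials": self.n_trials,
            "clamped_at_floor": self.clamped_at_floor,
            "seed": self.seed,
            "aborted": self.aborted,
            "abort_reason": self.abort_reason,
            "high_threshold_flag": self.high_threshold_flag,
            "config_digest": self.config.digest(),
        }

    def write_log_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["trial", "value", "target", "response",
                        "correct", "reversal", "factor"])
            for r in self.trial_log:
                w.writerow([r.trial, repr(r.value), r.target_interval,
                            r.response_interval, int(r.correct),
                            int(r.reversal), r.factor])
        return path


def threshold_from_reversals(reversals: Sequence[float], k: int = 6) -> float:
    """Geometric mean of the final ``k`` reversal values."""
    if len(reversals) < k:
        raise StaircaseError(f"need >= {k} reversals, got {len(reversals)}")
    tail = np.asarray(reversals[-k:], dtype=float)
    if np.any(tail <= 0):
        raise StaircaseError("reversal values must be positive")
    return float(np.exp(np.mean(np.log(tail))))


def is_valid(reversals: Sequence[float], sd_limit: float = 0.2, k: int = 6) -> bool:
    """A run is valid if the sample SD (n-1) of log10 of the last ``k``
    reversal values is <= ``sd_limit``."""
    if len(reversals) < k:
        raise StaircaseError(f"need >= {k} reversals, got {len(reversals)}")
    tail = np.asarray(reversals[-k:], dtype=float)
    if np.any(tail <= 0):
        raise StaircaseError("reversal values must be positive")
    return float(np.std(np.log10(tail), ddof=1)) <= sd_limit


def run(cfg: StaircaseConfig,
        responder: Callable[[float], bool],
        rng: np.random.Generator | int | None = None) -> RunResult:
    """Drive a full adaptive run against a responder.

    ``responder(value) -> bool`` reports whether the simulated (or replayed)
    listener answered correctly at the presented value.  The target interval
    for each trial is drawn from ``rng`` and recorded in the log; the seed (if
    an int was given) is stored in the result for bit-reproducibility.

    Runs that exceed ``cfg.max_trials`` before reaching eight reversals are
    aborted and flagged invalid rather than silently truncated.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    state = StaircaseState(cfg)
    while not state.terminated:
        if state.n_trials >= cfg.max_trials:
            return RunResult(
                threshold=None, reversal_values=tuple(state.reversal_values),
                valid=False, n_trials=state.n_trials,
                trial_log=tuple(state.trial_log),
                clamped_at_floor=state.clamped_at_floor, seed=seed, config=cfg,
                aborted=True,
                abort_reason=f"safety cap of {cfg.max_trials} trials exceeded")
        target = int(gen.integers(1, 3))
        correct = bool(responder(state.value))
        response = target if correct else 3 - target
        update(state, correct, target_interval=target,
               response_interval=response)

    thr = threshold_from_reversals(state.reversal_values,
                                   cfg.reversals_for_threshold)
    valid = is_valid(state.reversal_values, cfg.validity_sd_limit,
                     cfg.reversals_for_threshold)
    return RunResult(
        threshold=thr, reversal_values=tuple(state.reversal_values),
        valid=valid, n_trials=state.n_trials, trial_log=tuple(state.trial_log),
        clamped_at_floor=state.clamped_at_floor, seed=seed, config=cfg)
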