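"""Parametric virtual listeners for closed-loop validation of the tests.

Sensitivity to interaural phase differences (IPD) of pure tones collapses
above a listener-specific limiting frequency, and performance at a fixed
frequency saturates for large IPDs (little gain above ~90 deg).  The observer
model here captures both facts with a logistic psychometric function in log
frequency whose midpoint saturates hyperbolically in phi:

    f_alpha(phi) = f_max * phi / (phi + phi_half)
    p(correct | f, phi) = 0.5 + (0.5 - lapse/2) * L(beta * (ln f_alpha - ln f))

where L is the standard logistic.  ``f_max`` is the large-phi asymptote of the
limiting frequency (Hz), ``beta`` the slope per natural-log-frequency unit,
``phi_half`` the IPD at which the limiting frequency is half its asymptote,
and ``lapse`` the stimulus-independent error rate that caps the upper
asymptote at 1 - lapse/2.  The form is chosen for closed-form invertibility
(the 70.7%-correct frequency a 2-up/1-down track targets has an explicit
expression), not as a physiological model.

The same model drives TFS-LF simulation: with f fixed at 250 Hz, p increases
with phi through f_alpha(phi), so shrinking the IPD makes the task harder.

A cohort generator draws listener parameters from log-normal / normal
distributions to emulate the wide between-listener spread of limiting
frequencies seen in real groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .staircase import StaircaseConfig, RunResult, run as run_staircase

P_TARGET_2UP = 0.5 ** 0.5   # 70.7% — 2-up/1-down convergence point
P_TARGET_3UP = 0.5 ** (1 / 3)  # 79.4% — 3-up/1-down


class ListenerError(ValueError):
    pass


@dataclass(frozen=True)
class ListenerModel:
    """One simulated observer of the 2I-2AFC IPD-discrimination task."""

    f_max: float = 1000.0     # Hz, large-phi limiting-frequency asymptote
    beta: float = 4.0         # slope per ln-frequency unit
    lapse: float = 0.0        # lambda in [0, 0.1]
    phi_half: float = 30.0    # deg, half-saturation IPD of f_alpha

    def __post_init__(self) -> None:
        if not (self.f_max > 0 and self.beta > 0 and self.phi_half > 0):
            raise ListenerError("f_max, beta, phi_half must be positive")
        if not 0.0 <= self.lapse <= 0.1:
            raise ListenerError("lapse must lie in [0, 0.1]")

    def f_alpha(self, phi_deg: float) -> float:
        """Limiting frequency (midpoint of the psychometric function) at phi."""
        return self.f_max * phi_deg / (phi_deg + self.phi_half)


def p_correct(model: ListenerModel, f_hz: float, phi_deg: float) -> float:
    """Probability of a correct 2I-2AFC response at (f, phi).

    Strictly decreasing in f, strictly increasing in phi; bounded in
    (0.5, 1 - lapse/2].
    """
    if not (f_hz > 0 and math.isfinite(f_hz)):
        raise ListenerError("f must be positive and finite")
    if not 0.0 < phi_deg <= 180.0:
        raise ListenerError("phi must lie in (0, 180] degrees")
    x = model.beta * (math.log(model.f_alpha(phi_deg)) - math.log(f_hz))
    logistic = 1.0 / (1.0 + math.exp(-x))
    return 0.5 + (0.5 - model.lapse / 2.0) * logistic


def p_target_frequency(model: ListenerModel, phi_deg: float,
                       p: float = P_TARGET_2UP) -> float:
    """Frequency at which p_correct equals ``p`` (closed-form inversion).

    Solving p = 0.5 + (0.5 - lapse/2) * L(x) for x = beta*(ln f_alpha - ln f):

        L = (p - 0.5) / (0.5 - lapse/2);  x = ln(L / (1 - L))
        f = f_alpha(phi) * exp(-x / beta)

    For lapse = 0 and p = 2^(-1/2) this reduces to
    f = f_alpha * exp(0.34657 / beta), since ln(0.41421/0.58579) = -0.34657.
    Raises if ``p`` is unattainable given the lapse rate.
    """
    upper = 1.0 - model.lapse / 2.0
    if not 0.5 < p < upper:
        raise ListenerError(
            f"p={p:.4f} unattainable: range is (0.5, {upper:.4f})")
    logistic = (p - 0.5) / (0.5 - model.lapse / 2.0)
    x = math.log(logistic / (1.0 - logistic))
    return model.f_alpha(phi_deg) * math.exp(-x / model.beta)


def p707_frequency(model: ListenerModel, phi_deg: float) -> float:
    """The 70.7%-correct frequency — the point a 2-up/1-down TFS-AF track
    converges to."""
    return p_target_frequency(model, phi_deg, P_TARGET_2UP)


def respond(model: ListenerModel, f_hz: float, phi_deg: float,
            rng: np.random.Generator) -> bool:
    """One Bernoulli(p_correct) draw."""
    return bool(rng.random() < p_correct(model, f_hz, phi_deg))


def af_responder(model: ListenerModel, phi_deg: float,
                 rng: np.random.Generator):
    """Responder closure for a TFS-AF staircase (value = frequency)."""
    return lambda f: respond(model, f, phi_deg, rng)


def lf_responder(model: ListenerModel, f_hz: float,
                 rng: np.random.Generator):
    """Responder closure for a TFS-LF staircase (value = IPD in degrees)."""
    return lambda phi: respond(model, f_hz, phi, rng)


def simulate_run(model: ListenerModel, cfg: StaircaseConfig,
                 rng: np.random.Generator | int | None = None) -> RunResult:
    """One full adaptive run of either test against the model."""
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if cfg.tracked_variable == "frequency":
        responder = af_responder(model, cfg.phi_deg, gen)
    else:
        responder = lf_responder(model, cfg.fixed_frequency_hz, gen)
    result = run_staircase(cfg, responder, gen)
    if seed is not None:
        result = RunResult(**{**result.__dict__, "seed": int(seed)})
    return result


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic listener population.

    ``f_max`` is log-normal (median in Hz, SD in log10 units) to emulate the
    roughly order-of-magnitude spread of limiting frequencies across real
    listeners; slope, lapse and phi_half are truncated normals.
    """

    n_listeners: int = 13
    f_max_median_hz: float = 1000.0
    f_max_sd_log10: float = 0.18
    beta_mean: float = 5.0
    beta_sd: float = 1.0
    lapse_mean: float = 0.01
    lapse_sd: float = 0.01
    phi_half_mean_deg: float = 30.0
    phi_half_sd_deg: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners < 0:
            raise ListenerError("n_listeners must be >= 0")
        for name in ("f_max_sd_log10", "beta_sd", "lapse_sd", "phi_half_sd_deg"):
            if getattr(self, name) < 0:
                raise ListenerError(f"{name} must be >= 0")

    def draw_listeners(self) -> list[ListenerModel]:
        rng = np.random.default_rng(self.seed)
        listeners = []
        for _ in range(self.n_listeners):
            f_max = 10.0 ** rng.normal(math.log10(self.f_max_median_hz),
                                       self.f_max_sd_log10)
            beta = max(0.5, rng.normal(self.beta_mean, self.beta_sd))
            lapse = float(np.clip(rng.normal(self.lapse_mean, self.lapse_sd),
                                  0.0, 0.1))
            phi_half = max(1.0, rng.normal(self.phi_half_mean_deg,
                                           self.phi_half_sd_deg))
            listeners.append(ListenerModel(f_max=f_max, beta=beta,
                                           lapse=lapse, phi_half=phi_half))
        return listeners


def simulate_cohort(spec: CohortSpec, test_cfg: StaircaseConfig,
                    runs_per_listener: int = 15) -> pd.DataFrame:
    """Run every listener of a synthetic cohort through the test.

    Returns a long-format table with one row per run: listener_id, run_index
    (1-based), phi_deg, threshold, valid, n_trials, seed.  Fully reproducible
    from ``spec.seed``.
    """
    rows = []
    root = np.random.SeedSequence(spec.seed)
    listeners = spec.draw_listeners()
    for lid, (model, ss) in enumerate(
            zip(listeners, root.spawn(max(spec.n_listeners, 1)))):
        run_seeds = ss.generate_state(runs_per_listener) % (2 ** 31)
        for ridx in range(runs_per_listener):
            res = simulate_run(model, test_cfg, int(run_seeds[ridx]))
            rows.append({
                "listener_id": lid,
                "run_index": ridx + 1,
                "phi_deg": test_cfg.phi_deg,
                "threshold": res.threshold,
                "valid": res.valid,
                "n_trials": res.n_trials,
                "seed": int(run_seeds[ridx]),
            })
    return pd.DataFrame(
        rows, columns=["listener_id", "run_index", "phi_deg", "threshold",
                       "valid", "n_trials", "seed"])
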