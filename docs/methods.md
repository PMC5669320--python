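# Methods

## The tests

Both tests measure sensitivity to interaural phase differences (IPDs) of
pure tones, the binaural expression of temporal-fine-structure (TFS) coding.
A 2I-2AFC trial contains two intervals of four 400-ms tones (20-ms
raised-cosine ramps), tones separated by 100 ms and intervals by 500 ms
(4.3 s nominal trial duration). The standard interval has IPD 0° in all
tones; the target interval carries IPD φ in tones 2 and 4 only, so the
percept alternates within the sequence.

The staircase is a transformed up-down rule: `n` consecutive correct
responses (default n = 2) harden the task one step, any error eases it one
step. The 2-up/1-down rule converges where the probability of two
consecutive correct responses is ½, i.e. p = 2^(−1/2) ≈ 0.707; 3-up/1-down
(supported via `n_correct_to_harden=3`) tracks 2^(−1/3) ≈ 0.794. Steps are
multiplicative — factors 1.4 / 1.2 / 1.1 for the adaptive-frequency test
(TFS-AF, harder = higher frequency, 30-Hz floor, 200-Hz start with a 100-Hz
fallback) and 1.95 / 1.56 / 1.25 for the adaptive-IPD test (TFS-LF at a
fixed 250 Hz, harder = smaller IPD, 180° start and ceiling) — switching
after the first and second reversals. A run terminates at eight reversals;
the threshold is the geometric mean of the last six reversal values and the
run is valid when the sample SD (n−1) of their log₁₀ values is ≤ 0.2.
Because steps are multiplicative, every aggregate in the package is
geometric and every spread is computed on log₁₀ values.

### Staircase bookkeeping choices

The published rules leave three details open; the engine fixes them as
follows (and an independently written transcription of the same statements,
`tests/reference_staircase.py`, is compared trial-for-trial in the tests):

- **Reversal detection** compares logical step directions (harder/easier);
  the first step only establishes direction. The reversal value is the value
  presented on the trial at which the direction flipped — the track's
  extremum, the standard convention for up-down staircases.
- **Floor/ceiling clamping** changes the value but not the logical
  direction, so the tracker remains well-defined while pinned at the 30-Hz
  floor; pinned steps are counted and reported (`clamped_at_floor`).
- **Step-factor switching** indexes the factor by the number of reversals
  recorded before the current step, so the step that produces a reversal
  still uses the earlier factor ("a factor of 1.4 until the first
  reversal", read inclusively).

Runs are capped at 400 trials as a safety net (an always-correct responder
never reverses); capped runs are returned flagged `aborted`, never silently
truncated. Each run draws target intervals from a single seeded generator
and records the seed, so every output is bit-reproducible.

## The virtual listener

No observer model is part of the published tests; the one here is a
validation device. It encodes two robust qualitative facts — IPD
discriminability collapses above a listener-specific limiting frequency,
and performance saturates for IPDs above ~90° — in a form invertible in
closed form:

    f_α(φ) = f_max · φ / (φ + φ_half)
    p(correct | f, φ) = 0.5 + (0.5 − λ/2) · L(β · (ln f_α(φ) − ln f))

with L the standard logistic. Parameters: `f_max` (Hz), the large-φ
asymptote of the limiting frequency (the spread of this parameter across
listeners is what cohort simulation varies, default median 1000 Hz,
SD 0.18 log₁₀ units — roughly the order-of-magnitude spread real groups
show); `β`, slope per natural-log-frequency unit (default 4–6; ≥ 4 counts
as "steep"); `λ ∈ [0, 0.1]`, lapse rate, capping the upper asymptote at
1 − λ/2; `φ_half` (deg), the IPD at which the limiting frequency is half
its asymptote (default 30°, which puts saturation above ~90°). The
70.7%-correct frequency has the closed form f = f_α(φ)·exp(0.34657/β) for
λ = 0 (verified in the tests against brute-force root finding on
p_correct). TFS-LF simulation reuses the same formula with f fixed at
250 Hz and φ as the staircase variable.

What the model does *not* emulate: practice and fatigue (run index has no
effect by construction), lapse streaks beyond the stationary λ, level
dependence, and any physiological binaural mechanism. Passing simulations
therefore validate the *procedure* — stepping rules, convergence,
aggregation — not claims about human listeners. Runs whose threshold
exceeds 1500 Hz (implausible for IPD detection; in practice produced by
lucky-guess streaks) carry a `high_threshold_flag`.

### Convergence accuracy

Simulating the full staircase against a steep listener (β = 6, λ = 0) and
evaluating p_correct at the resulting thresholds gives a mean tracked level
of ≈ 72.5% for 2-up/1-down (theory 70.7%) and ≈ 80.0% for 3-up/1-down
(theory 79.4%) at 1000 runs — the small excess is the familiar finite-run,
finite-step-size bias of up-down tracks. On the threshold scale the
geometric-mean estimate sits within ~3% of the true 70.7% frequency at
β = 6 (measured −2.6% over 1000 runs), with the bias growing as β shrinks
(≈ −8% at β = 4): a single 15-run session has Monte-Carlo error comparable
to these biases, which is why recovery tests average many sessions.

## Calibration

Audiometric thresholds (dB HL at the 11 standard audiometric frequencies,
125–8000 Hz) are converted to dB SPL by adding the minimum audible pressure
(MAP) interpolated linearly in dB against log₁₀ frequency. The
threshold-in-SPL curve is then interpolated the same way between measured
frequencies (so interpolation is exact at the knots), extrapolated linearly
below 125 Hz, and refused above the highest measured frequency. The
presentation level adds a fixed sensation level (default 30 dB). The
built-in MAP table (`builtin-2026a`) follows the shape of standard
normal-threshold data; any user table (CSV `frequency_hz, map_db_spl`)
takes precedence, and all tests use explicit synthetic tables so no result
depends on the built-in values. Pure-tone averages include every measured
frequency inside the inclusive band, averaged over both ears (so PTA
125–1000 Hz uses 125, 250, 500, 750 and 1000 Hz); this membership rule is
explicit because conventions differ across clinics.

## Stimulus numerics

48-kHz, 24-bit stereo; tone length is round(duration·sr/1000) samples. The
IPD is realized symmetrically (+φ/2 left, −φ/2 right) so neither ear leads
systematically and φ = 180° is an exact carrier negation; a one-ear
convention is available (`ipd_split="left"`). The carrier starts at sine
phase 0 at tone onset for bit-reproducibility (`start_phase_rad` overrides).
The envelope multiplies the carrier after the phase shift, so the envelope
is IPD-invariant. Digital level convention: a full-scale sine equals
100 dB SPL by default; the convention is recorded in every WAV's JSON
sidecar, and writes that would clip are refused with the required headroom.

## Analysis conventions

- Aggregation: geometric mean of the first three runs if their log₁₀ SD is
  ≤ 0.20, otherwise a fourth run is required and the estimate is the
  geometric mean of all four.
- Required runs: n = (2·SD / log₁₀ tolerance)², with tolerance factor 1.3
  (so the criterion half-width is log₁₀ 1.3 ≈ 0.114); quadratic in SD and
  independent of the threshold scale.
- Run ratios (e.g. run 3 / run 1) use raw run thresholds. The cohort
  summary reports both the arithmetic and the geometric mean of ratios; the
  geometric mean is the meaningful center (for log-normal thresholds the
  arithmetic mean of ratios exceeds 1 even with no practice effect).
- Rank correlation is Spearman's ρ computed as the Pearson correlation of
  mid-rank-transformed vectors; the statistic only — the package
  deliberately performs no significance testing, since its simulated
  cohorts would make p-values meaningless theater.
- Practice slopes regress mean log₁₀ threshold per block of three runs on
  block index (OLS, with standard error).

## Problem sizes

Simulation-backed tests use 200-seed rule-equivalence sweeps, 1000-run
convergence estimates, and cohorts of 20–300 listeners with 2–3 runs each;
the whole suite runs in a few seconds, and the acceptance script's 1000
runs in under a minute. These sizes hold Monte-Carlo standard errors
well inside each assertion's band.

## Known limitations

- The observer model is phenomenological; parameter values for demo cohorts
  are illustrative, not fits to human data.
- No audio playback, response hardware, headphone equalization or real-ear
  correction: `synth` produces calibrated files, not a test session.
- The MAP table ships as a convenience; clinical use requires a
  transducer-specific table.
- Reversal-value convention and SD convention (sample, n−1) are choices
  where the published rules are silent; both are configurable or documented
  above.
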