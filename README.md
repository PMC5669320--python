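# tfstest

Adaptive psychophysical tests of binaural temporal-fine-structure (TFS)
sensitivity — the ability to detect interaural phase differences (IPDs) of
low-frequency pure tones — implemented as a simulatable Python package for
hearing scientists and audiology tool-builders.

Two tests are provided:

- **TFS-AF** (adaptive frequency): the IPD φ is fixed (default 180°) and the
  tone frequency is adaptively raised; the threshold is the highest frequency
  at which the IPD remains detectable. Higher is better.
- **TFS-LF** (low frequency): the tone frequency is fixed (250 Hz) and the
  IPD is adaptively shrunk; the threshold is the smallest detectable IPD.
  Lower is better.

Both use a two-interval, two-alternative forced-choice (2I-2AFC) task. Each
trial presents two intervals of four 400-ms tones (20-ms raised-cosine ramps,
100-ms gaps, 500 ms between intervals; 4.3 s per trial). In the standard
interval all tones have IPD 0°; in the target interval tones 2 and 4 carry
IPD φ. A transformed up-down staircase (2-up/1-down, converging on the 70.7%
correct point) adjusts the tracked variable by factors 1.4/1.2/1.1 (TFS-AF)
or 1.95/1.56/1.25 (TFS-LF), switching at the first and second reversals. A
run ends after eight reversals; the threshold is the geometric mean of the
last six reversal values, valid when the sample SD of their log₁₀ values is
≤ 0.2. Frequencies are floored at 30 Hz; the IPD is capped at 180°.

The package covers:

- `tfstest.stimulus` — bit-reproducible stereo stimulus synthesis and 24-bit
  WAV export with JSON sidecars;
- `tfstest.calibration` — audiogram (dB HL) → presentation level (dB SPL) at
  30 dB sensation level, interpolated in dB vs log frequency, plus pure-tone
  averages;
- `tfstest.staircase` — the exact stepping, termination, threshold and
  validity rules;
- `tfstest.virtual_listener` — parametric simulated observers
  p(correct | f, φ) with lapse rate and φ-dependent limiting frequency, and a
  cohort generator, for closed-loop validation without human subjects;
- `tfstest.analysis` — geometric-mean aggregation (with the extra-run rule),
  test–retest reliability (required number of runs), run ratios, the R ratio
  (φ / IPD threshold at 250 Hz), Spearman rank correlation, practice slopes;
- `tfstest.cli` — the `tfstest simulate | synth | analyze` command line.

## Worked example

Simulate a three-run session against the default virtual listener and
analyze it:

```
$ tfstest simulate --runs 3 --seed 5 --out demo_session
wrote 3 run(s) to demo_session
$ tfstest analyze demo_session/run01_result.json \
                  demo_session/run02_result.json \
                  demo_session/run03_result.json
listener: n=3 geomean=908.2 sd_log10=0.091 required_runs=2.6 (-> 3)
```

The three run thresholds were 713.0, 1011.3 and 1039.0 Hz; their geometric
mean, 908.2 Hz, is the session's TFS-AF threshold estimate — the listener
can use binaural TFS cues up to roughly 900 Hz. The log₁₀ spread across
runs (0.091) feeds the reliability rule n = (2·SD / log₁₀ 1.3)², giving 2.6:
three runs suffice for 95% of session means to land within a factor of 1.3
of the true threshold.

Synthesize one calibrated trial for a measured audiogram:

```
$ tfstest synth --audiogram audiogram.csv -f 200 --phi 180 --out trial.wav
wrote trial.wav (4.3 s, levels L=57.5 R=57.5 dB SPL)
```

Levels are set 30 dB above the listener's threshold-in-SPL at the tone
frequency (here a flat 5 dB HL audiogram under the built-in minimum audible
pressure table).

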