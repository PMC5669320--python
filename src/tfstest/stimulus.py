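"""2I-2AFC stimulus synthesis for the TFS-AF / TFS-LF tests.

A trial contains two intervals of four 400-ms pure tones each (20-ms
raised-cosine on/off ramps), tones separated by 100 ms of silence and the
intervals by 500 ms.  In the standard interval all four tones carry an
interaural phase difference (IPD) of 0 deg; in the target interval tones 2 and
4 carry IPD phi while tones 1 and 3 stay at 0 deg.  A listener with access to
binaural temporal fine structure hears the target interval "move" inside the
head.

The IPD is realized symmetrically: +phi/2 on the left carrier phase and
-phi/2 on the right, which avoids a systematic lateral bias and makes the
phi = 180 deg case an exact carrier negation.  Levels are per-ear RMS levels
in dB SPL under a declared digital full-scale convention (default: a
full-scale sine corresponds to 100 dB SPL).
"""

from __future__ import annotations

import json
import math
import wave
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_SAMPLE_RATE = 48_000
DEFAULT_FULL_SCALE_DB_SPL = 100.0


class StimulusError(ValueError):
    pass


class ClippingError(StimulusError):
    """Samples exceed digital full scale; message names the required headroom."""


@dataclass(frozen=True)
class ToneSpec:
    """One pure tone of the sequence.

    ``level_db_spl`` maps to digital RMS via ``full_scale_db_spl``: a sine of
    peak amplitude 1.0 (RMS 1/sqrt(2)) is defined to be ``full_scale_db_spl``.
    """

    frequency_hz: float
    phi_deg: float = 0.0
    duration_ms: float = 400.0
    ramp_ms: float = 20.0
    level_db_spl: tuple[float, float] = (70.0, 70.0)  # (left, right)
    sample_rate: int = DEFAULT_SAMPLE_RATE
    full_scale_db_spl: float = DEFAULT_FULL_SCALE_DB_SPL
    ipd_split: str = "symmetric"  # or "left" (apply full phi to left channel)
    start_phase_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (self.frequency_hz > 0 and math.isfinite(self.frequency_hz)):
            raise StimulusError("frequency must be positive and finite")
        if self.frequency_hz >= self.sample_rate / 2:
            raise StimulusError(
                f"frequency {self.frequency_hz:g} Hz >= Nyquist "
                f"({self.sample_rate / 2:g} Hz)")
        if not 0.0 <= self.phi_deg <= 360.0:
            raise StimulusError("phi must lie in [0, 360] degrees")
        if self.duration_ms < 2 * self.ramp_ms:
            raise StimulusError("duration must be >= 2 * ramp duration")
        if self.ipd_split not in ("symmetric", "left"):
            raise StimulusError(f"unknown ipd_split {self.ipd_split!r}")

    @property
    def n_samples(self) -> int:
        return round(self.duration_ms * self.sample_rate / 1000.0)


def _raised_cosine_envelope(n: int, ramp_samples: int) -> np.ndarray:
    env = np.ones(n)
    if ramp_samples > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_samples) / ramp_samples))
        env[:ramp_samples] = ramp
        env[-ramp_samples:] = ramp[::-1]
    return env


def synth_tone(spec: ToneSpec) -> np.ndarray:
    """Synthesize one stereo tone; returns an (n_samples, 2) float64 array.

    The phase offset is applied to the carrier, not the envelope, so the
    per-channel envelope is identical regardless of phi.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    omega = 2.0 * np.pi * spec.frequency_hz
    phi = math.radians(spec.phi_deg)
    if spec.ipd_split == "symmetric":
        ph_left, ph_right = +phi / 2.0, -phi / 2.0
    else:
        ph_left, ph_right = phi, 0.0
    env = _raised_cosine_envelope(n, round(spec.ramp_ms * spec.sample_rate / 1000.0))
    out = np.empty((n, 2))
    for ch, (ph, level) in enumerate(
            zip((ph_left, ph_right), spec.level_db_spl)):
        amp = 10.0 ** ((level - spec.full_scale_db_spl) / 20.0)
        out[:, ch] = amp * env * np.sin(omega * t + spec.start_phase_rad + ph)
    return out


@dataclass(frozen=True)
class TrialStimulus:
    """One complete 2I-2AFC trial: samples plus the metadata needed to log it."""

    samples: np.ndarray  # (n, 2) float64
    target_interval: int  # 1 or 2
    frequency_hz: float
    phi_deg: float
    level_db_spl: tuple[float, float]
    sample_rate: int = DEFAULT_SAMPLE_RATE
    full_scale_db_spl: float = DEFAULT_FULL_SCALE_DB_SPL
    inter_tone_gap_ms: float = 100.0
    inter_interval_gap_ms: float = 500.0

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.sample_rate

    def metadata(self) -> dict:
        return {
            "frequency_hz": self.frequency_hz,
            "phi_deg": self.phi_deg,
            "target_interval": self.target_interval,
            "level_db_spl": {"left": self.level_db_spl[0],
                             "right": self.level_db_spl[1]},
            "full_scale_db_spl": self.full_scale_db_spl,
            "sample_rate_hz": self.sample_rate,
            "duration_s": self.duration_s,
        }


def _silence(ms: float, sr: int) -> np.ndarray:
    return np.zeros((round(ms * sr / 1000.0), 2))


def build_trial(
    frequency_hz: float,
    phi_deg: float,
    level_db_spl: tuple[float, float] = (70.0, 70.0),
    target_interval: int = 1,
    *,
    tone_duration_ms: float = 400.0,
    ramp_ms: float = 20.0,
    inter_tone_gap_ms: float = 100.0,
    inter_interval_gap_ms: float = 500.0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    full_scale_db_spl: float = DEFAULT_FULL_SCALE_DB_SPL,
) -> TrialStimulus:
    """Assemble the two-interval trial.

    Target-interval placement is the caller's job (the session layer draws it
    from its RNG); this function is fully deterministic.
    """
    if target_interval not in (1, 2):
        raise StimulusError("target_interval must be 1 or 2")

    def tone(phi: float) -> np.ndarray:
        return synth_tone(ToneSpec(
            frequency_hz=frequency_hz, phi_deg=phi,
            duration_ms=tone_duration_ms, ramp_ms=ramp_ms,
            level_db_spl=level_db_spl, sample_rate=sample_rate,
            full_scale_db_spl=full_scale_db_spl))

    gap = _silence(inter_tone_gap_ms, sample_rate)

    def interval(phis: list[float]) -> np.ndarray:
        parts: list[np.ndarray] = []
        for i, p in enumerate(phis):
            if i:
                parts.append(gap)
            parts.append(tone(p))
        return np.concatenate(parts)

    standard = interval([0.0, 0.0, 0.0, 0.0])
    target = interval([0.0, phi_deg, 0.0, phi_deg])
    big_gap = _silence(inter_interval_gap_ms, sample_rate)
    first, second = (target, standard) if target_interval == 1 else (standard, target)
    samples = np.concatenate([first, big_gap, second])
    return TrialStimulus(
        samples=samples, target_interval=target_interval,
        frequency_hz=frequency_hz, phi_deg=phi_deg,
        level_db_spl=tuple(level_db_spl), sample_rate=sample_rate,
        full_scale_db_spl=full_scale_db_spl,
        inter_tone_gap_ms=inter_tone_gap_ms,
        inter_interval_gap_ms=inter_interval_gap_ms)


_I24_MAX = 2 ** 23 - 1


def write_wav(stim: TrialStimulus, path: str | Path) -> Path:
    """Write a stereo 24-bit PCM WAV plus a JSON metadata sidecar.

    Refuses to write if any sample exceeds full scale, reporting the headroom
    (in dB) the levels would have to drop by.
    """
    path = Path(path)
    peak = float(np.max(np.abs(stim.samples))) if stim.samples.size else 0.0
    if peak > 1.0:
        need = 20.0 * math.log10(peak)
        raise ClippingError(
            f"stimulus peaks at {need:.2f} dB above full scale; "
            f"reduce levels by at least {need:.2f} dB")
    scaled = np.round(stim.samples * _I24_MAX).astype(np.int32)
    # int32 -> packed little-endian 3-byte frames, interleaved L/R
    flat = scaled.reshape(-1)
    raw = flat.astype("<i4").tobytes()
    frames = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(2)
        wf.setsampwidth(3)
        wf.setframerate(stim.sample_rate)
        wf.writeframes(frames)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(stim.metadata(), indent=2) + "\n")
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a stereo 24-bit PCM WAV back to float64 in [-1, 1]."""
    with wave.open(str(path), "rb") as wf:
        if wf.getsampwidth() != 3:
            raise StimulusError("expected 24-bit PCM")
        sr = wf.getframerate()
        nch = wf.getnchannels()
        raw = np.frombuffer(wf.readframes(wf.getnframes()), dtype=np.uint8)
    b = raw.reshape(-1, 3)
    padded = np.zeros((b.shape[0], 4), dtype=np.uint8)
    padded[:, :3] = b
    # sign-extend byte 3 from the 24-bit sign bit
    padded[:, 3] = np.where(b[:, 2] & 0x80, 0xFF, 0x00)
    ints = padded.view("<i4").reshape(-1, nch)
    return ints.astype(np.float64) / _I24_MAX, sr
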