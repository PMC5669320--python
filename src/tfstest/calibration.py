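"""Audiogram-referenced level calibration.

Binaural TFS tests present tones at a fixed sensation level (SL) — a fixed
number of dB above the listener's own detection threshold — so that audibility
is equated across listeners and frequencies.  Audiometric thresholds are
measured in dB HL at the standard audiometric frequencies; converting them to
dB SPL requires the minimum audible pressure (MAP), the SPL at threshold for
a median normal ear.  The presentation level at an arbitrary test frequency is
obtained by interpolating the threshold-in-SPL curve linearly in dB against
log frequency, then adding the sensation level (default 30 dB SL).

This module also computes pure-tone averages (PTA) over a frequency band,
averaged over both ears.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

AUDIOMETRIC_FREQUENCIES: tuple[float, ...] = (
    125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0,
    2000.0, 3000.0, 4000.0, 6000.0, 8000.0,
)

#: Built-in free-field-equivalent monaural minimum audible pressure (dB SPL at
#: normal threshold) at the audiometric frequencies.  Values follow the shape
#: of standard threshold-of-hearing data for otologically normal adults
#: (steeply falling below 1 kHz, shallow minimum in the 1-4 kHz region).
#: Version tag lets results cite which table they used; a user-supplied table
#: always takes precedence.
DEFAULT_MAP_VERSION = "builtin-2026a"
DEFAULT_MAP_TABLE: dict[float, float] = {
    125.0: 30.0,
    250.0: 19.0,
    500.0: 11.0,
    750.0: 8.0,
    1000.0: 6.5,
    1500.0: 6.0,
    2000.0: 6.0,
    3000.0: 6.0,
    4000.0: 7.5,
    6000.0: 11.0,
    8000.0: 13.0,
}


class CalibrationError(ValueError):
    """Invalid calibration input (non-finite value, empty range, ...)."""


class ExtrapolationError(CalibrationError):
    """Requested frequency lies above the measured audiogram range."""


def _check_strictly_increasing(freqs: Iterable[float], what: str) -> None:
    fs = list(freqs)
    if any(not math.isfinite(f) or f <= 0 for f in fs):
        raise CalibrationError(f"{what}: frequencies must be finite and positive")
    if any(b <= a for a, b in zip(fs, fs[1:])):
        raise CalibrationError(f"{what}: frequencies must be strictly increasing")


@dataclass(frozen=True)
class MapTable:
    """Minimum audible pressure: frequency (Hz) -> dB SPL at normal threshold."""

    values: Mapping[float, float]
    version: str = "user"

    def __post_init__(self) -> None:
        items = sorted((float(f), float(v)) for f, v in self.values.items())
        _check_strictly_increasing((f for f, _ in items), "MapTable")
        if any(not math.isfinite(v) for _, v in items):
            raise CalibrationError("MapTable: values must be finite")
        object.__setattr__(self, "values", dict(items))

    @property
    def frequencies(self) -> np.ndarray:
        return np.array(list(self.values.keys()))

    @property
    def spl(self) -> np.ndarray:
        return np.array(list(self.values.values()))

    @classmethod
    def default(cls) -> "MapTable":
        return cls(DEFAULT_MAP_TABLE, version=DEFAULT_MAP_VERSION)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MapTable":
        """Read a table from CSV with columns ``frequency_hz, map_db_spl``."""
        table: dict[float, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                table[float(row["frequency_hz"])] = float(row["map_db_spl"])
        return cls(table, version=str(path))


@dataclass(frozen=True)
class Audiogram:
    """Per-ear pure-tone thresholds in dB HL at measured frequencies."""

    left: Mapping[float, float]
    right: Mapping[float, float]

    def __post_init__(self) -> None:
        for name in ("left", "right"):
            ear = getattr(self, name)
            if not ear:
                raise CalibrationError(f"Audiogram: {name} ear has no thresholds")
            items = sorted((float(f), float(t)) for f, t in ear.items())
            _check_strictly_increasing((f for f, _ in items), f"Audiogram[{name}]")
            if any(not math.isfinite(t) for _, t in items):
                raise CalibrationError("Audiogram: thresholds must be finite")
            object.__setattr__(self, name, dict(items))

    def ear(self, which: str) -> Mapping[float, float]:
        if which not in ("left", "right"):
            raise CalibrationError(f"unknown ear {which!r}")
        return getattr(self, which)

    @classmethod
    def flat(cls, hl: float, frequencies: Iterable[float] = AUDIOMETRIC_FREQUENCIES) -> "Audiogram":
        table = {float(f): float(hl) for f in frequencies}
        return cls(left=dict(table), right=dict(table))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Audiogram":
        """Read from CSV with columns ``ear, frequency_hz, threshold_db_hl``."""
        ears: dict[str, dict[float, float]] = {"left": {}, "right": {}}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ear = row["ear"].strip().lower()
                if ear not in ears:
                    raise CalibrationError(f"unknown ear {ear!r} in {path}")
                ears[ear][float(row["frequency_hz"])] = float(row["threshold_db_hl"])
        return cls(left=ears["left"], right=ears["right"])


@dataclass(frozen=True)
class SensationLevelPolicy:
    """How presentation levels are derived from thresholds.

    ``sensation_level_db`` is added to the interpolated threshold-in-SPL;
    interpolation is linear in dB against log10 frequency, the convention for
    audiometric data.
    """

    sensation_level_db: float = 30.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.sensation_level_db) or self.sensation_level_db < 0:
            raise CalibrationError("sensation level must be finite and >= 0")


def _interp_log_freq(freq: float, xs: np.ndarray, ys: np.ndarray,
                     extrapolate_low: bool = True) -> float:
    """Linear interpolation of ys (dB) against log10(xs); linear extrapolation
    below the lowest knot using the first segment's slope."""
    lf = math.log10(freq)
    lxs = np.log10(xs)
    if lf < lxs[0]:
        if not extrapolate_low:
            raise ExtrapolationError(f"{freq} Hz below table span")
        if len(xs) < 2:
            return float(ys[0])
        slope = (ys[1] - ys[0]) / (lxs[1] - lxs[0])
        return float(ys[0] + slope * (lf - lxs[0]))
    return float(np.interp(lf, lxs, ys))


def hl_to_spl(freq: float, hl: float, map_table: MapTable | None = None) -> float:
    """Convert a dB HL threshold at ``freq`` to dB SPL by adding the MAP.

    The MAP is interpolated linearly in dB against log frequency; linear
    extrapolation is applied below the table's lowest frequency.  Frequencies
    above the table span raise :class:`ExtrapolationError`.
    """
    if map_table is None:
        map_table = MapTable.default()
    if not (math.isfinite(freq) and freq > 0 and math.isfinite(hl)):
        raise CalibrationError("hl_to_spl: inputs must be finite, freq > 0")
    xs, ys = map_table.frequencies, map_table.spl
    if freq > xs[-1]:
        raise ExtrapolationError(
            f"{freq} Hz above MAP table span ({xs[-1]:g} Hz)")
    return hl + _interp_log_freq(freq, xs, ys)


def presentation_level(
    audiogram: Audiogram,
    ear: str,
    freq: float,
    policy: SensationLevelPolicy | None = None,
    map_table: MapTable | None = None,
) -> float:
    """Per-ear presentation level in dB SPL at ``freq``.

    Each measured audiogram point is first converted to SPL at its own
    frequency via :func:`hl_to_spl`; the resulting threshold-in-SPL curve is
    interpolated linearly in dB vs log10 frequency and the sensation level is
    added.  Below the lowest measured frequency the curve is extrapolated
    linearly on the same scale; above the highest measured frequency an
    :class:`ExtrapolationError` is raised (the tests never need it).
    """
    if policy is None:
        policy = SensationLevelPolicy()
    if map_table is None:
        map_table = MapTable.default()
    if not (math.isfinite(freq) and freq > 0):
        raise CalibrationError("presentation_level: freq must be finite and > 0")
    thresholds = audiogram.ear(ear)
    if len(thresholds) < 2:
        raise CalibrationError("presentation_level: need >= 2 audiogram points")
    xs = np.array(list(thresholds.keys()))
    spl = np.array([hl_to_spl(f, t, map_table) for f, t in thresholds.items()])
    if freq > xs[-1]:
        raise ExtrapolationError(
            f"{freq} Hz above highest measured audiogram frequency ({xs[-1]:g} Hz)")
    return _interp_log_freq(freq, xs, spl) + policy.sensation_level_db


def pta(audiogram: Audiogram, f_lo: float, f_hi: float) -> float:
    """Pure-tone average: mean dB HL over both ears and every measured
    frequency in the inclusive range [f_lo, f_hi]."""
    if f_hi < f_lo:
        raise CalibrationError("pta: empty range")
    vals = [
        t
        for ear in (audiogram.left, audiogram.right)
        for f, t in ear.items()
        if f_lo <= f <= f_hi
    ]
    if not vals:
        raise CalibrationError(
            f"pta: no measured frequencies in [{f_lo}, {f_hi}]")
    return float(np.mean(vals))
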