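"""Session-level physiological and performance metrics.

Covers the three non-jump measurements of a monitored training session:
mean heart rate from a wrist monitor sampling every 5 s, total covered
distance from the GNSS track, and mean/maximum anaerobic power from a 30-s
all-out (Wingate) cycling trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "HeartRateSeries",
    "GnssTrack",
    "WingateTrial",
    "mean_heart_rate",
    "total_distance",
    "wingate_powers",
    "EARTH_RADIUS_M",
]

EARTH_RADIUS_M = 6_371_000.0

BPM_MIN, BPM_MAX = 25.0, 250.0


@dataclass
class HeartRateSeries:
    """Heart rate sampled at a fixed period (nominally 5 s).

    ``gaps`` optionally marks samples the monitor failed to estimate; they
    are omitted from averaging (no interpolation).
    """

    bpm: np.ndarray
    sample_period_s: float = 5.0
    gaps: Optional[np.ndarray] = None  # boolean, True = missing

    def __post_init__(self) -> None:
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.sample_period_s <= 0:
            raise ValueError("sample_period_s must be positive")
        present = self.bpm if self.gaps is None else self.bpm[~np.asarray(self.gaps)]
        if present.size and not ((present > BPM_MIN) & (present < BPM_MAX)).all():
            bad = present[(present <= BPM_MIN) | (present >= BPM_MAX)]
            raise ValueError(f"implausible heart-rate values: {bad[:5]}")


@dataclass
class GnssTrack:
    """Ordered (time_s, lat_deg, lon_deg) positions."""

    time_s: np.ndarray
    lat_deg: np.ndarray
    lon_deg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.lat_deg = np.asarray(self.lat_deg, dtype=float)
        self.lon_deg = np.asarray(self.lon_deg, dtype=float)
        if not (self.time_s.size == self.lat_deg.size == self.lon_deg.size):
            raise ValueError("time/lat/lon lengths differ")
        if self.time_s.size >= 2 and not (np.diff(self.time_s) > 0).all():
            i = int(np.flatnonzero(np.diff(self.time_s) <= 0)[0])
            raise ValueError(f"timestamps not strictly increasing at index {i + 1}")
        if np.abs(self.lat_deg).max(initial=0) > 90 or np.abs(self.lon_deg).max(initial=0) > 180:
            raise ValueError("coordinates out of range")


@dataclass
class WingateTrial:
    """Instantaneous power trace of a 30-s all-out cycling test."""

    power_w: np.ndarray
    fs_hz: float
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        self.power_w = np.asarray(self.power_w, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if (self.power_w < 0).any():
            raise ValueError("negative power samples")
        actual = self.power_w.size / self.fs_hz
        if abs(actual - self.duration_s) > 0.1 * self.duration_s:
            raise ValueError(
                f"trial length {actual:.1f} s deviates >10% from nominal "
                f"{self.duration_s} s"
            )


def mean_heart_rate(series: HeartRateSeries) -> float:
    """Arithmetic mean heart rate over all non-missing samples (bpm)."""
    bpm = series.bpm if series.gaps is None else series.bpm[~np.asarray(series.gaps)]
    if bpm.size == 0:
        raise ValueError("no heart-rate samples available")
    return float(np.mean(bpm))


def _haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance between coordinate arrays, in meters."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def total_distance(track: GnssTrack, max_speed_ms: Optional[float] = 12.0) -> float:
    """Total covered distance: sum of successive great-circle segments (m).

    Segments implying a speed above ``max_speed_ms`` are dropped as GNSS
    spikes (pass ``None`` to disable the gate).
    """
    if track.time_s.size < 2:
        raise ValueError("need at least 2 track points")
    seg = _haversine_m(
        track.lat_deg[:-1], track.lon_deg[:-1], track.lat_deg[1:], track.lon_deg[1:]
    )
    if max_speed_ms is not None:
        dt = np.diff(track.time_s)
        seg = seg[seg / dt <= max_speed_ms]
    return float(seg.sum())


def wingate_powers(trial: WingateTrial, peak_window_s: float = 1.0) -> tuple[float, float]:
    """(mean power, maximum power) of a Wingate trial, in watts.

    Mean is the time-average of the trace; maximum is the peak of a centred
    rolling mean of width ``peak_window_s`` — instantaneous maxima are
    noise-dominated, and peak anaerobic power is conventionally reported
    over a short window.
    """
    if peak_window_s < 1.0 / trial.fs_hz:
        raise ValueError("peak_window_s shorter than one sample period")
    n = trial.power_w.size
    w = int(round(peak_window_s * trial.fs_hz))
    if w > n:
        raise ValueError(f"window of {w} samples longer than trial of {n}")
    mean_p = float(np.mean(trial.power_w))
    kernel = np.ones(w) / w
    rolled = np.convolve(trial.power_w, kernel, mode="valid")
    # the whole trial is itself a window, so peak power is never below the mean
    return mean_p, max(float(rolled.max()), mean_p)
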