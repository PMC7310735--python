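"""Respiration: breath detection and breathing-rate features.

Breathing rate is estimated by counting chest rises: the displacement signal
is band-pass filtered to the physiological breathing band (0.1–0.4 Hz, i.e.
6–24 breaths per minute) and peaks are picked with a 2-second minimum
spacing — strictly below the 2.5 s period of the fastest plausible breathing
so regular fast breathing is not decimated by timing jitter.

These features are retained for completeness; the final models exclude the
respiration channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .ecg import normalized_difference_stats
from .session import Baseline, BiosignalRecord

__all__ = ["BreathSeries", "RspFeatures", "detect_breaths", "rsp_features"]

#: minimum spacing between breath peaks, seconds
MIN_BREATH_SPACING_S = 2.0


@dataclass(frozen=True)
class BreathSeries:
    """Chest-rise peak instants and successive breath intervals."""

    peak_times: np.ndarray  # s
    intervals: np.ndarray  # ms
    interval_end_times: np.ndarray  # s

    @classmethod
    def from_peaks(cls, peak_times: np.ndarray) -> "BreathSeries":
        peak_times = np.asarray(peak_times, dtype=np.float64)
        if len(peak_times) < 2:
            return cls(peak_times, np.empty(0), np.empty(0))
        return cls(peak_times, np.diff(peak_times) * 1000.0, peak_times[1:])

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        sel = (self.interval_end_times >= start) & (self.interval_end_times < end)
        return self.intervals[sel]

    def br_in(self, window: tuple[float, float]) -> np.ndarray:
        """Instantaneous breathing rate (breaths/min) for intervals ending in the window."""
        iv = self.in_window(window)
        return 60000.0 / iv if len(iv) else np.empty(0)

    def rate(self, window: tuple[float, float]) -> float:
        """Breaths per minute as peak count over window length."""
        start, end = window
        n = int(np.sum((self.peak_times >= start) & (self.peak_times < end)))
        return 60.0 * n / (end - start)


def detect_breaths(
    record: BiosignalRecord,
    *,
    prominence: float = 0.5,
    literal_upper_cutoff: bool = False,
) -> BreathSeries:
    """Breath peaks from the chest-displacement signal.

    ``literal_upper_cutoff=True`` widens the band to 0.1–24 Hz (audit flag);
    the default upper cutoff is 0.4 Hz, matching 24 breaths per minute.
    """
    if record.channel != "rsp":
        raise ValueError(f"detect_breaths needs an rsp record, got {record.channel!r}")
    fs = record.sampling_rate
    x = record.samples
    if len(x) < int(5 * fs) or np.ptp(x) == 0.0:
        return BreathSeries.from_peaks(np.empty(0))
    upper = 24.0 if literal_upper_cutoff else 0.4
    b, a = butter(2, [0.1, upper], btype="band", fs=fs)
    filtered = filtfilt(b, a, x)
    peaks, _ = find_peaks(
        filtered, distance=max(1, int(round(MIN_BREATH_SPACING_S * fs))), prominence=prominence
    )
    return BreathSeries.from_peaks(record.t0 + peaks / fs)


@dataclass(frozen=True)
class RspFeatures:
    Nmean: float = math.nan  # mean BR deviation from resting BR, breaths/min
    std: float = math.nan
    NFD: float = math.nan
    NSD: float = math.nan
    BRV: float = math.nan  # mean signed successive breath-interval difference, ms
    avNN: float = math.nan  # ms
    sdNN: float = math.nan  # ms
    missing: frozenset = frozenset()

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name)
                for name in ("Nmean", "std", "NFD", "NSD", "BRV", "avNN", "sdNN")}


def rsp_features(
    breaths: BreathSeries,
    window: tuple[float, float],
    baseline: Baseline,
) -> RspFeatures:
    """The seven respiration features of one window.

    Conventions mirror the ECG features, applied to the breath-interval and
    breathing-rate series with the resting breathing rate as reference.
    Short windows often contain fewer than three breaths; the interval
    statistics are then flagged missing rather than fabricated.
    """
    missing: set[str] = set()
    out: dict[str, float] = {}

    br_w = breaths.br_in(window)
    if len(br_w) >= 1 and np.isfinite(baseline.br_rest_mean):
        out["Nmean"] = float(np.mean(br_w - baseline.br_rest_mean))
    else:
        missing.add("Nmean")
    if len(br_w) >= 2:
        out["std"] = float(np.std(br_w, ddof=1))
    else:
        missing.add("std")
    nfd, nsd = normalized_difference_stats(br_w)
    if math.isnan(nfd):
        missing.add("NFD")
    else:
        out["NFD"] = nfd
    if math.isnan(nsd):
        missing.add("NSD")
    else:
        out["NSD"] = nsd

    iv = breaths.in_window(window)
    n = len(iv)
    if n >= 3:
        out["avNN"] = float(np.mean(iv))
        out["sdNN"] = float(np.std(iv, ddof=1))
        out["BRV"] = float(np.sum(np.diff(iv)) / n)
    else:
        missing |= {"avNN", "sdNN", "BRV"}

    return RspFeatures(**out, missing=frozenset(missing))
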