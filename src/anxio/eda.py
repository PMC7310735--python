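"""Electrodermal activity: tonic/phasic filtering, orienting responses, features.

The tonic pathway is a zero-phase second-order Butterworth low-pass at
1.5 Hz; the phasic pathway removes the slow skin-conductance level from the
denoised signal with a zero-phase second-order high-pass at 0.05 Hz.
Skin-conductance orienting responses (ORs) are local phasic maxima whose
rise from the preceding onset reaches 0.03 µS; the offset is the
half-recovery point (first sample after the peak at which the phasic signal
has fallen halfway back to the onset level, capped at 10 s).

Window features: range-corrected mean (Lykken normalization against the
resting-phase minimum/maximum), standard deviation, normalized first/second
difference means on the tonic signal, and the OR count / mean magnitude /
mean duration on the phasic signal.  Mean OR magnitude and duration are
*missing* (not zero) when no OR occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .ecg import normalized_difference_stats
from .session import Baseline, BiosignalRecord

__all__ = [
    "OR_THRESHOLD_US",
    "OrientingResponse",
    "EdaFeatures",
    "DegenerateBaselineError",
    "tonic_filter",
    "phasic_filter",
    "detect_orienting_responses",
    "eda_features",
]

#: minimum onset-to-peak rise for a detected orienting response, µS
OR_THRESHOLD_US = 0.03

#: cap on the half-recovery search after the peak, seconds
HALF_RECOVERY_CAP_S = 10.0

#: longest plausible onset-to-peak rise of a skin-conductance response, seconds
MAX_RISE_S = 5.0


class DegenerateBaselineError(ValueError):
    """Resting-phase EDA range is zero; range-corrected mean is undefined."""


@dataclass(frozen=True)
class OrientingResponse:
    """One skin-conductance orienting response (onset → peak → offset)."""

    onset_t: float
    peak_t: float
    offset_t: float
    magnitude: float  # peak − onset amplitude, µS
    duration: float  # offset − onset, s

    def __post_init__(self) -> None:
        if not (self.onset_t < self.peak_t <= self.offset_t):
            raise ValueError("orienting response requires onset < peak <= offset")
        if self.magnitude < OR_THRESHOLD_US - 1e-12:
            raise ValueError("orienting response below detection threshold")


def _check_eda(record: BiosignalRecord) -> None:
    if record.channel != "eda":
        raise ValueError(f"expected an eda record, got {record.channel!r}")


def tonic_filter(record: BiosignalRecord) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth low-pass at 1.5 Hz (length preserved)."""
    _check_eda(record)
    b, a = butter(2, 1.5, btype="low", fs=record.sampling_rate)
    return filtfilt(b, a, record.samples)


def phasic_filter(record: BiosignalRecord) -> np.ndarray:
    """Phasic signal: 0.05 Hz zero-phase high-pass of the denoised (tonic-filtered) EDA."""
    _check_eda(record)
    b, a = butter(2, 0.05, btype="high", fs=record.sampling_rate)
    return filtfilt(b, a, tonic_filter(record))


def detect_orienting_responses(
    phasic: np.ndarray,
    sampling_rate: float,
    window: Optional[tuple[float, float]] = None,
    *,
    t0: float = 0.0,
    threshold: float = OR_THRESHOLD_US,
    max_rise_s: float = MAX_RISE_S,
) -> list[OrientingResponse]:
    """Orienting responses whose peak falls inside ``window`` (half-open).

    An OR is a local maximum of the phasic signal preceded by an onset (the
    last local minimum, or the series start) such that the rise reaches
    ``threshold`` within a plausible rise time (``max_rise_s``; slower
    drifts, e.g. post-response filter rebound, are not responses).
    Overlapping responses are split at the intervening local minimum.  The
    offset is the half-recovery sample, capped at 10 s after the peak (or
    the end of the series).
    """
    phasic = np.asarray(phasic, dtype=np.float64)
    fs = sampling_rate
    n = len(phasic)
    if n < 3:
        return []
    if window is None:
        window = (t0, t0 + n / fs)
    start, end = window

    peaks, _ = find_peaks(phasic)
    if len(peaks) == 0:
        return []
    minima, _ = find_peaks(-phasic)

    peak_times = t0 + peaks / fs
    in_win = (peak_times >= start) & (peak_times < end)
    peaks = peaks[in_win]
    if len(peaks) == 0:
        return []

    # onset: last local minimum strictly before the peak (series start if none)
    if len(minima):
        pos = np.searchsorted(minima, peaks)
        onsets = np.where(pos > 0, minima[np.clip(pos - 1, 0, len(minima) - 1)], 0)
    else:
        onsets = np.zeros(len(peaks), dtype=int)

    cap = int(round(HALF_RECOVERY_CAP_S * fs))
    responses: list[OrientingResponse] = []
    max_rise = int(round(max_rise_s * fs))
    for p, o in zip(peaks, onsets):
        if p - o > max_rise:
            # measure the rise from the latest plausible onset instead
            o = p - max_rise + int(np.argmin(phasic[p - max_rise:p]))
        mag = float(phasic[p] - phasic[o])
        if mag < threshold:
            continue
        if phasic[p] < threshold / 2.0:
            # a response is a positive excursion of the detrended signal;
            # sub-zero "peaks" are recovery rebounds of the high-pass filter
            continue
        half_level = phasic[o] + 0.5 * mag
        hi = min(n, p + cap + 1)
        below = np.nonzero(phasic[p + 1 : hi] < half_level)[0]
        off = (p + 1 + below[0]) if len(below) else (hi - 1)
        responses.append(
            OrientingResponse(
                onset_t=t0 + o / fs,
                peak_t=t0 + p / fs,
                offset_t=t0 + off / fs,
                magnitude=mag,
                duration=(off - o) / fs,
            )
        )
    return responses


@dataclass(frozen=True)
class EdaFeatures:
    Nmean: float = math.nan  # range-corrected mean, dimensionless
    std: float = math.nan  # µS, on the tonic window
    NFD: float = math.nan
    NSD: float = math.nan
    nOR: float = math.nan  # count
    mmOR: float = math.nan  # mean OR magnitude, µS
    mdOR: float = math.nan  # mean OR duration, s
    missing: frozenset = frozenset()

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name)
                for name in ("Nmean", "std", "NFD", "NSD", "nOR", "mmOR", "mdOR")}


def eda_features(
    tonic: np.ndarray,
    phasic: np.ndarray,
    window: tuple[float, float],
    baseline: Baseline,
    sampling_rate: float,
    *,
    t0: float = 0.0,
) -> EdaFeatures:
    """The seven EDA features of one window.

    ``Nmean`` applies the Lykken range correction sample-wise against the
    resting-phase extrema; a zero resting range is a hard error.
    """
    rng = baseline.eda_rest_max - baseline.eda_rest_min
    if rng <= 0:
        raise DegenerateBaselineError(
            f"resting EDA range is zero for subject {baseline.subject_id}; "
            "range-corrected mean undefined"
        )
    fs = sampling_rate
    start, end = window
    i0 = max(0, int(math.ceil((start - t0) * fs - 1e-9)))
    i1 = min(len(tonic), int(math.ceil((end - t0) * fs - 1e-9)))
    seg = np.asarray(tonic[i0:i1], dtype=np.float64)

    missing: set[str] = set()
    out: dict[str, float] = {}
    if len(seg) >= 1:
        out["Nmean"] = float(np.mean((seg - baseline.eda_rest_min) / rng))
    else:
        missing.add("Nmean")
    if len(seg) >= 2:
        out["std"] = float(np.std(seg, ddof=1))
    else:
        missing.add("std")
    nfd, nsd = normalized_difference_stats(seg)
    if math.isnan(nfd):
        missing.add("NFD")
    else:
        out["NFD"] = nfd
    if math.isnan(nsd):
        missing.add("NSD")
    else:
        out["NSD"] = nsd

    responses = detect_orienting_responses(phasic, fs, window, t0=t0)
    out["nOR"] = float(len(responses))
    if responses:
        out["mmOR"] = float(np.mean([r.magnitude for r in responses]))
        out["mdOR"] = float(np.mean([r.duration for r in responses]))
    else:
        missing |= {"mmOR", "mdOR"}

    return EdaFeatures(**out, missing=frozenset(missing))
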