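"""ECG processing: QRS detection, heart rate, and time-domain HRV features.

R-peaks are found with the Pan–Tompkins algorithm (band-pass 5–12 Hz,
differentiation, squaring, moving-window integration, adaptive thresholding
with search-back).  Normal-to-normal intervals (NNI) are the gaps between
consecutive detected R-peaks after a physiological plausibility filter
(300–2000 ms); from them the eleven ECG features are computed per window:
Nmean, std, NFD, NSD on the beat-wise heart-rate series, and HRV, avNN,
sdNN, rMSSD, NN50, pNN50, pNN20 on the NNIs.

Note on HRV: the statistic implemented here is the mean of *signed*
successive NNI differences, which telescopes to ``(NNI_N − NNI_1)/N`` and
flips sign under time reversal.  That is a property of the definition this
package follows, kept deliberately; rMSSD is the conventional
sign-insensitive dispersion measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .session import Baseline, BiosignalRecord

__all__ = [
    "NNISeries",
    "HRSeries",
    "EcgFeatures",
    "detect_r_peaks",
    "instantaneous_hr",
    "ecg_features",
]

#: physiological plausibility bounds for a normal-to-normal interval, ms
NNI_BOUNDS_MS = (300.0, 2000.0)


@dataclass(frozen=True)
class NNISeries:
    """R-peak instants and plausibility-filtered normal-to-normal intervals."""

    peak_times: np.ndarray  # seconds
    nni: np.ndarray  # milliseconds
    nni_end_times: np.ndarray  # seconds; the interval's ending peak

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=np.float64))
        object.__setattr__(self, "nni", np.asarray(self.nni, dtype=np.float64))
        object.__setattr__(self, "nni_end_times", np.asarray(self.nni_end_times, dtype=np.float64))
        if len(self.nni) != len(self.nni_end_times):
            raise ValueError("nni and nni_end_times must align")
        if np.any(self.nni <= 0):
            raise ValueError("NNIs must be positive")

    @classmethod
    def from_peaks(cls, peak_times: np.ndarray) -> "NNISeries":
        peak_times = np.asarray(peak_times, dtype=np.float64)
        if len(peak_times) < 2:
            return cls(peak_times, np.empty(0), np.empty(0))
        raw = np.diff(peak_times) * 1000.0
        lo, hi = NNI_BOUNDS_MS
        keep = (raw >= lo) & (raw <= hi)
        return cls(peak_times, raw[keep], peak_times[1:][keep])

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        """NNIs whose ending peak lies in ``[start, end)``."""
        start, end = window
        sel = (self.nni_end_times >= start) & (self.nni_end_times < end)
        return self.nni[sel]


@dataclass(frozen=True)
class HRSeries:
    """Beat-wise instantaneous heart rate, bpm, stamped at the interval's end peak."""

    times: np.ndarray
    bpm: np.ndarray

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        start, end = window
        sel = (self.times >= start) & (self.times < end)
        return self.bpm[sel]


def _bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 2) -> np.ndarray:
    b, a = butter(order, [low, high], btype="band", fs=fs)
    return filtfilt(b, a, x)


def detect_r_peaks(
    record: BiosignalRecord,
    *,
    integration_window_s: float = 0.150,
    refractory_s: float = 0.200,
    searchback_factor: float = 1.66,
) -> NNISeries:
    """Pan–Tompkins QRS detection.

    Stages: band-pass 5–12 Hz, differentiation, squaring, moving-window
    integration (150 ms), adaptive signal/noise thresholds with 0.125/0.25
    update factors, a 200 ms refractory period (enforced through the
    candidate spacing), and search-back at ``searchback_factor`` times the
    running RR mean when a beat appears to have been missed.

    A flat or zero signal yields an empty series; input shorter than 5 s is
    an error.
    """
    if record.channel != "ecg":
        raise ValueError(f"detect_r_peaks needs an ecg record, got {record.channel!r}")
    if record.duration < 5.0:
        raise ValueError(f"ECG too short for QRS detection ({record.duration:.1f} s < 5 s)")
    fs = record.sampling_rate
    x = record.samples
    if np.ptp(x) == 0.0:
        return NNISeries.from_peaks(np.empty(0))

    filtered = _bandpass(x, fs, 5.0, 12.0)
    deriv = np.gradient(filtered)
    squared = deriv * deriv
    win = max(1, int(round(integration_window_s * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(refractory_s * fs)))
    candidates, _ = find_peaks(mwi, distance=refractory)
    if len(candidates) == 0:
        return NNISeries.from_peaks(np.empty(0))

    # adaptive thresholds initialized from the first two seconds
    head = mwi[: max(win, int(2 * fs))]
    spki = float(np.max(head)) / 3.0
    npki = float(np.mean(head)) / 2.0

    accepted: list[int] = []
    rejected: list[tuple[int, float]] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for idx in candidates:
        v = float(mwi[idx])
        if accepted:
            # running RR estimate; before any interval exists assume 1 s
            rr_mean = float(np.mean(rr_history[-8:])) if rr_history else fs
            gap = idx - accepted[-1]
            if gap > searchback_factor * rr_mean:
                # search-back: revisit rejected candidates in the gap at half threshold
                back = [(j, w) for j, w in rejected if accepted[-1] + refractory <= j <= idx - refractory]
                if back:
                    j, w = max(back, key=lambda t: t[1])
                    if w > 0.5 * threshold():
                        rr_history.append(j - accepted[-1])
                        accepted.append(j)
                        spki = 0.25 * w + 0.75 * spki
        if v > threshold():
            if accepted:
                rr_history.append(idx - accepted[-1])
            accepted.append(idx)
            spki = 0.125 * v + 0.875 * spki
        else:
            rejected.append((idx, v))
            npki = 0.125 * v + 0.875 * npki

    if not accepted:
        return NNISeries.from_peaks(np.empty(0))
    accepted.sort()

    # refine: the MWI peak trails the R wave; take the band-passed maximum in
    # the integration window preceding each accepted MWI peak
    half = int(round(0.050 * fs))
    peaks = []
    for idx in accepted:
        lo = max(0, idx - win)
        hi = min(len(filtered), idx + half + 1)
        peaks.append(lo + int(np.argmax(filtered[lo:hi])))
    peaks = np.unique(peaks)
    # enforce refractory spacing on refined peaks, keeping the larger deflection
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if filtered[p] > filtered[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    peak_times = record.t0 + np.asarray(kept, dtype=np.float64) / fs
    return NNISeries.from_peaks(peak_times)


def instantaneous_hr(nni: NNISeries, span: Optional[tuple[float, float]] = None) -> HRSeries:
    """Beat-wise heart rate ``60000/NNI`` stamped at each interval's end peak.

    Restricted to intervals ending inside ``span`` (half-open) when given;
    raises if the span contains no interval ends.
    """
    times, values = nni.nni_end_times, 60000.0 / nni.nni if len(nni.nni) else np.empty(0)
    if span is not None:
        sel = (times >= span[0]) & (times < span[1])
        times, values = times[sel], values[sel]
    if len(times) < 1:
        raise ValueError("span contains no normal-to-normal interval ends")
    return HRSeries(times=times, bpm=values)


@dataclass(frozen=True)
class EcgFeatures:
    """The eleven ECG features of one window.

    Missing entries (insufficient beats in the window) are NaN and listed in
    ``missing`` — they are never silently zero.
    """

    Nmean: float = math.nan  # mean HR deviation from resting HR, bpm
    std: float = math.nan  # HR standard deviation, bpm
    NFD: float = math.nan  # mean |first difference| of z-scored HR
    NSD: float = math.nan  # mean |second difference| of z-scored HR
    HRV: float = math.nan  # mean signed successive NNI difference, ms
    avNN: float = math.nan  # ms
    sdNN: float = math.nan  # ms
    rMSSD: float = math.nan  # ms
    NN50: float = math.nan  # count
    pNN50: float = math.nan  # fraction of successive differences
    pNN20: float = math.nan  # fraction of successive differences
    missing: frozenset = frozenset()

    def to_dict(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in ("Nmean", "std", "NFD", "NSD", "HRV", "avNN", "sdNN",
                         "rMSSD", "NN50", "pNN50", "pNN20")
        }


def _zscore(x: np.ndarray) -> Optional[np.ndarray]:
    if len(x) < 2:
        return None
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - mu) / sd


def normalized_difference_stats(x: np.ndarray) -> tuple[float, float]:
    """NFD and NSD: mean absolute first/second differences of the z-scored series.

    A zero-variance window is defined to have NFD = NSD = 0.  NaN is
    returned for series too short for the respective difference order.
    """
    z = _zscore(np.asarray(x, dtype=np.float64))
    if z is None:
        return math.nan, math.nan
    nfd = float(np.mean(np.abs(np.diff(z)))) if len(z) >= 2 else math.nan
    nsd = float(np.mean(np.abs(z[2:] - z[:-2]))) if len(z) >= 3 else math.nan
    return nfd, nsd


def nn_count(nni_ms: np.ndarray, threshold_ms: float, *, count_intervals: bool = False) -> int:
    """Count of successive NNI differences of magnitude at least ``threshold_ms``.

    The boundary case (a difference exactly at the threshold) counts as
    exceeding it.  ``count_intervals=True`` switches to the literal variant
    that counts intervals themselves above the threshold (audit only).
    """
    nni_ms = np.asarray(nni_ms, dtype=np.float64)
    if count_intervals:
        return int(np.sum(nni_ms >= threshold_ms))
    if len(nni_ms) < 2:
        return 0
    return int(np.sum(np.abs(np.diff(nni_ms)) >= threshold_ms))


def ecg_features(
    nni: NNISeries,
    hr: HRSeries,
    window: tuple[float, float],
    baseline: Baseline,
    *,
    count_intervals: bool = False,
) -> EcgFeatures:
    """Window features from the NNI series and the beat-wise HR series.

    ``Nmean`` is the mean deviation of window HR from the resting-phase mean;
    ``std`` the sample standard deviation of window HR; NFD/NSD operate on
    the within-window z-scored HR.  The NNI statistics need at least three
    intervals ending in the window; otherwise they are flagged missing.
    """
    missing: set[str] = set()
    out: dict[str, float] = {}

    hr_w = hr.in_window(window)
    if len(hr_w) >= 1:
        out["Nmean"] = float(np.mean(hr_w - baseline.hr_rest_mean))
    else:
        missing.add("Nmean")
    if len(hr_w) >= 2:
        out["std"] = float(np.std(hr_w, ddof=1))
    else:
        missing.add("std")
    nfd, nsd = normalized_difference_stats(hr_w)
    if math.isnan(nfd):
        missing.add("NFD")
    else:
        out["NFD"] = nfd
    if math.isnan(nsd):
        missing.add("NSD")
    else:
        out["NSD"] = nsd

    nni_w = nni.in_window(window)
    n = len(nni_w)
    if n >= 3:
        diffs = np.diff(nni_w)
        out["avNN"] = float(np.mean(nni_w))
        out["sdNN"] = float(np.std(nni_w, ddof=1))
        out["rMSSD"] = float(np.sqrt(np.sum(diffs**2) / (n - 1)))
        out["HRV"] = float(np.sum(diffs) / n)  # telescopes to (last-first)/n
        nn50 = nn_count(nni_w, 50.0, count_intervals=count_intervals)
        nn20 = nn_count(nni_w, 20.0, count_intervals=count_intervals)
        denom = n if count_intervals else n - 1
        out["NN50"] = float(nn50)
        out["pNN50"] = nn50 / denom
        out["pNN20"] = nn20 / denom
    else:
        missing |= {"avNN", "sdNN", "rMSSD", "HRV", "NN50", "pNN50", "pNN20"}

    return EcgFeatures(**out, missing=frozenset(missing))
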