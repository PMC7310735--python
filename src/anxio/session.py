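"""Session data model and file I/O.

A *session* is one wearable-sensor recording (biofeedback training or
video-clip exposure) made of uniformly sampled biosignal channels — ECG in
arbitrary voltage units, electrodermal activity (EDA) in microsiemens, and
respiration (RSP) as chest-displacement percentage, all nominally sampled at
100 Hz — together with a timed layout of rest / demo / clip segments and
subjective arousal ratings on a 1–4 scale.

Time coordinates are seconds from session start; segments are half-open
intervals ``[start, end)``.

On disk a session is a CSV file (``t,ecg,eda,rsp`` header, one row per
sample tick, full float precision) plus a JSON metadata sidecar with the
same stem.  OpenSignals-style text files (``#``-prefixed JSON header,
whitespace-separated columns) are supported read-only; the JSON sidecar is
still required for the layout.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHANNELS = ("ecg", "eda", "rsp")
ROLES = ("rest", "demo", "clip")

__all__ = [
    "CHANNELS",
    "BiosignalRecord",
    "Segment",
    "Rating",
    "SessionLayout",
    "SessionData",
    "SubjectDataset",
    "Baseline",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
    "compute_baseline",
]


class SessionFormatError(ValueError):
    """The file on disk is not a recognized session dialect."""


class SessionValidationError(ValueError):
    """The session content violates a structural invariant."""


@dataclass(frozen=True)
class BiosignalRecord:
    """One channel's uniformly sampled series.

    Parameters
    ----------
    channel : {"ecg", "eda", "rsp"}
    sampling_rate : float
        Hz, positive.  The study hardware sampled at 100 Hz per channel.
    samples : np.ndarray
        Raw sample values (ECG arbitrary voltage units, EDA µS, RSP %).
    t0 : float
        Offset of the first sample within the session, seconds.
    """

    channel: str
    samples: np.ndarray
    sampling_rate: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise SessionValidationError(f"unknown channel {self.channel!r}")
        if not self.sampling_rate > 0:
            raise SessionValidationError("sampling_rate must be > 0")
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.sampling_rate

    def index_range(self, start: float, end: float) -> tuple[int, int]:
        """Sample-index range covering session time ``[start, end)``."""
        fs = self.sampling_rate
        i0 = max(0, int(math.ceil((start - self.t0) * fs - 1e-9)))
        i1 = min(len(self.samples), int(math.ceil((end - self.t0) * fs - 1e-9)))
        return i0, max(i0, i1)

    def slice(self, start: float, end: float) -> np.ndarray:
        i0, i1 = self.index_range(start, end)
        return self.samples[i0:i1]

    def truncated(self, t: float) -> "BiosignalRecord":
        """Record containing only samples strictly before session time ``t``."""
        n = min(len(self.samples), max(0, int(math.ceil((t - self.t0) * self.sampling_rate - 1e-9))))
        return replace(self, samples=self.samples[:n])


@dataclass(frozen=True)
class Segment:
    role: str
    start: float
    end: float
    clip_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SessionValidationError(f"unknown segment role {self.role!r}")
        if not self.end > self.start:
            raise SessionValidationError(f"segment end {self.end} must exceed start {self.start}")
        if self.role == "clip":
            if self.clip_index is None or not 1 <= int(self.clip_index) <= 16:
                raise SessionValidationError("clip segments need clip_index in 1..16")
        elif self.clip_index is not None:
            raise SessionValidationError("only clip segments carry clip_index")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Rating:
    """Subjective arousal rating on the study's 4-point scale."""

    time: float
    after_clip_index: int
    value: int

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4):
            raise SessionValidationError(f"rating value {self.value} outside 1..4")


@dataclass(frozen=True)
class SessionLayout:
    """Timed segments and rating events; the coordinate frame for labeling."""

    session_kind: str
    segments: tuple[Segment, ...]
    ratings: tuple[Rating, ...] = ()

    def __post_init__(self) -> None:
        if self.session_kind not in ("training", "exposure"):
            raise SessionValidationError(f"unknown session kind {self.session_kind!r}")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "ratings", tuple(self.ratings))
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end - 1e-9:
                raise SessionValidationError(
                    f"segments overlap or are out of order: "
                    f"[{a.start}, {a.end}) then [{b.start}, {b.end})"
                )

    @property
    def duration(self) -> float:
        return self.segments[-1].end if self.segments else 0.0

    def rest_segment(self) -> Segment:
        for seg in self.segments:
            if seg.role == "rest":
                return seg
        raise SessionValidationError(f"{self.session_kind} session has no rest segment")

    def clip_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "clip"]

    def clip_segment(self, clip_index: int) -> Optional[Segment]:
        for s in self.segments:
            if s.role == "clip" and s.clip_index == clip_index:
                return s
        return None


@dataclass(frozen=True)
class SessionData:
    """A layout plus its per-channel records."""

    layout: SessionLayout
    records: Mapping[str, BiosignalRecord]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", dict(self.records))
        for name, rec in self.records.items():
            if rec.channel != name:
                raise SessionValidationError(f"record under key {name!r} has channel {rec.channel!r}")

    def record(self, channel: str) -> BiosignalRecord:
        try:
            return self.records[channel]
        except KeyError:
            raise SessionValidationError(
                f"required channel {channel!r} missing from {self.layout.session_kind} session"
            ) from None


@dataclass(frozen=True)
class SubjectDataset:
    """Both sessions of one subject.

    ECG and EDA are mandatory in each session; RSP is optional (the final
    models exclude it, mirroring the decision to drop the chest strap).
    """

    subject_id: str
    training: SessionData
    exposure: SessionData

    def __post_init__(self) -> None:
        for sess in (self.training, self.exposure):
            for ch in ("ecg", "eda"):
                if ch not in sess.records:
                    raise SessionValidationError(
                        f"subject {self.subject_id}: {sess.layout.session_kind} session "
                        f"is missing required channel {ch!r}"
                    )

    def session(self, kind: str) -> SessionData:
        if kind == "training":
            return self.training
        if kind == "exposure":
            return self.exposure
        raise KeyError(kind)


@dataclass(frozen=True)
class Baseline:
    """Resting-phase reference statistics used for feature normalization.

    Heart rate and breathing rate are referenced to their resting means;
    EDA is range-corrected (Lykken) against the resting minimum/maximum of
    the low-pass-filtered signal.
    """

    subject_id: str
    hr_rest_mean: float
    eda_rest_min: float
    eda_rest_max: float
    rest_window: tuple[float, float]
    br_rest_mean: float = float("nan")

    def __post_init__(self) -> None:
        if not (np.isfinite(self.hr_rest_mean) and np.isfinite(self.eda_rest_min) and np.isfinite(self.eda_rest_max)):
            raise SessionValidationError("baseline statistics must be finite")
        if self.eda_rest_max < self.eda_rest_min:
            raise SessionValidationError("eda_rest_max must be >= eda_rest_min")


# ---------------------------------------------------------------------------
# File I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _layout_to_dict(layout: SessionLayout) -> dict:
    return {
        "session_kind": layout.session_kind,
        "segments": [
            {k: v for k, v in
             dict(role=s.role, start=s.start, end=s.end, clip_index=s.clip_index).items()
             if v is not None}
            for s in layout.segments
        ],
        "ratings": [
            dict(time=r.time, after_clip_index=r.after_clip_index, value=r.value)
            for r in layout.ratings
        ],
    }


def _layout_from_dict(meta: dict) -> SessionLayout:
    segments = tuple(
        Segment(role=s["role"], start=float(s["start"]), end=float(s["end"]),
                clip_index=s.get("clip_index"))
        for s in meta.get("segments", [])
    )
    ratings = tuple(
        Rating(time=float(r["time"]), after_clip_index=int(r["after_clip_index"]),
               value=int(r["value"]))
        for r in meta.get("ratings", [])
    )
    return SessionLayout(session_kind=meta["session_kind"], segments=segments, ratings=ratings)


def write_session(layout: SessionLayout, records: Mapping[str, BiosignalRecord], path) -> Path:
    """Write a session as CSV + JSON sidecar.

    The CSV stores full float precision so that ``read_session`` round-trips
    samples bit-exactly.  All channels must share sampling rate, offset and
    length (one time column serves all).
    """
    path = Path(path)
    if not records:
        raise SessionValidationError("empty channel map")
    recs = dict(records)
    first = next(iter(recs.values()))
    for rec in recs.values():
        if rec.sampling_rate != first.sampling_rate or rec.t0 != first.t0 or len(rec.samples) != len(first.samples):
            raise SessionValidationError("CSV dialect requires aligned channels (same rate, t0, length)")
    try:
        cols = {"t": first.times}
        for ch in CHANNELS:
            if ch in recs:
                cols[ch] = recs[ch].samples
        frame = pd.DataFrame(cols)
        frame.to_csv(path, index=False, float_format="%.17g")
        meta = _layout_to_dict(layout)
        meta["sampling_rate"] = first.sampling_rate
        meta["t0"] = first.t0
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing session to {path}: {exc}") from exc
    return path


def _read_opensignals(path: Path) -> tuple[dict[str, np.ndarray], float]:
    """Minimal OpenSignals-style text reader (read-only convenience).

    Expects ``#``-prefixed header lines, one of which is a JSON object with
    ``sampling rate`` and channel ``labels``/``column`` names, then
    whitespace-separated numeric columns.
    """
    header: dict = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if body.startswith("{"):
                obj = json.loads(body)
                # device-keyed: {"mac": {...}} or flat {...}
                header = next(iter(obj.values())) if "sampling rate" not in obj else obj
    if not header:
        raise SessionFormatError(f"{path}: no JSON header line found in OpenSignals-style file")
    fs = float(header["sampling rate"])
    columns = header.get("column") or header.get("labels")
    if columns is None:
        raise SessionFormatError(f"{path}: OpenSignals header lacks column labels")
    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data[:, None]
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(columns):
        key = str(name).lower()
        for ch in CHANNELS:
            if ch in key:
                out[ch] = np.asarray(data[:, j], dtype=np.float64)
    if not out:
        raise SessionFormatError(f"{path}: no ecg/eda/rsp columns among {columns}")
    return out, fs


def read_session(path) -> tuple[SessionLayout, dict[str, BiosignalRecord]]:
    """Read a session written by :func:`write_session` (or OpenSignals text).

    The JSON sidecar (same stem, ``.json``) is mandatory and carries the
    layout, ratings, and nominal sampling rate.  If the signal file's header
    rate differs from the sidecar rate, channels are resampled to the
    sidecar rate (polyphase) when the ratio is rational, otherwise a format
    error is raised.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SessionFormatError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    layout = _layout_from_dict(meta)
    meta_fs = float(meta.get("sampling_rate", 100.0))
    t0 = float(meta.get("t0", 0.0))

    with open(path) as fh:
        first_char = fh.read(1)
    if first_char == "#":
        channels, file_fs = _read_opensignals(path)
    else:
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # noqa: BLE001 - normalized into format error
            raise SessionFormatError(f"{path}: unknown session dialect ({exc})") from exc
        if "t" not in frame.columns:
            raise SessionFormatError(f"{path}: CSV dialect requires a 't' column")
        channels = {ch: frame[ch].to_numpy(dtype=np.float64) for ch in CHANNELS if ch in frame.columns}
        if not channels:
            raise SessionFormatError(f"{path}: no ecg/eda/rsp columns present")
        file_fs = meta_fs
        if len(frame) > 1:
            dt = float(frame["t"].iloc[1] - frame["t"].iloc[0])
            if dt > 0:
                file_fs = 1.0 / dt

    if abs(file_fs - meta_fs) > 1e-6:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(meta_fs / file_fs).limit_denominator(1000)
        if abs(float(frac) - meta_fs / file_fs) > 1e-9:
            raise SessionFormatError(
                f"{path}: header rate {file_fs} Hz incompatible with metadata rate {meta_fs} Hz"
            )
        channels = {ch: resample_poly(x, frac.numerator, frac.denominator) for ch, x in channels.items()}
        logger.info("resampled %s from %g Hz to %g Hz", path, file_fs, meta_fs)

    records = {
        ch: BiosignalRecord(channel=ch, samples=x, sampling_rate=meta_fs, t0=t0)
        for ch, x in channels.items()
    }
    for ch in ("ecg", "eda"):
        if ch not in records:
            raise SessionValidationError(f"{path}: required channel {ch!r} missing")
    return layout, records


# ---------------------------------------------------------------------------
# Baselines

REST_SPANS = {"last_3min": 180.0, "full_5min": 300.0}


def compute_baseline(subject: SubjectDataset, rest_span: str = "full_5min") -> Baseline:
    """Resting-phase baseline from the biofeedback training session.

    ``rest_span`` selects the span the labeling approaches reference:
    ``"last_3min"`` (clip-based and subjective approaches) or
    ``"full_5min"`` (subject-based approaches).  The span is anchored at the
    end of the rest segment.
    """
    from . import ecg as _ecg
    from . import eda as _eda
    from . import rsp as _rsp

    if rest_span not in REST_SPANS:
        raise ValueError(f"rest_span must be one of {sorted(REST_SPANS)}")
    span = REST_SPANS[rest_span]
    rest = subject.training.layout.rest_segment()
    if rest.duration + 1e-9 < span:
        raise SessionValidationError(
            f"rest segment of {rest.duration:.0f} s shorter than requested {rest_span} span"
        )
    window = (rest.end - span, rest.end)

    ecg_rec = subject.training.record("ecg")
    nni = _ecg.detect_r_peaks(ecg_rec)
    if len(nni.peak_times) < 2:
        raise SessionValidationError("no detectable R-peaks in resting phase")
    hr = _ecg.instantaneous_hr(nni, span=window)
    hr_rest_mean = float(np.mean(hr.bpm))

    eda_rec = subject.training.record("eda")
    tonic = _eda.tonic_filter(eda_rec)
    i0, i1 = eda_rec.index_range(*window)
    rest_tonic = tonic[i0:i1]
    eda_rest_min = float(np.min(rest_tonic))
    eda_rest_max = float(np.max(rest_tonic))

    br_rest_mean = float("nan")
    if "rsp" in subject.training.records:
        breaths = _rsp.detect_breaths(subject.training.record("rsp"))
        sel = breaths.br_in(window)
        if len(sel) >= 2:
            br_rest_mean = float(np.mean(sel))

    return Baseline(
        subject_id=subject.subject_id,
        hr_rest_mean=hr_rest_mean,
        eda_rest_min=eda_rest_min,
        eda_rest_max=eda_rest_max,
        rest_window=window,
        br_rest_mean=br_rest_mean,
    )
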