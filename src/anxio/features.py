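"""Per-window feature vectors and design-matrix assembly.

Up to 25 named time-domain features per window — 11 from ECG, 7 from
respiration, 7 from EDA — in a fixed canonical column order.  The subset
the final models use is ``FINAL_SIX``.

Every window is computed *causally*: the records are truncated at the
window's end before any filtering or event detection, so a feature value
never depends on samples acquired after the window closes.  The on-line
playback engine calls the very same routine, which makes off-line and
on-line feature values identical by construction.

Structurally missing features (for example mean orienting-response
magnitude in a window with no orienting response, or breath-interval
statistics in a 10-second window with two breaths) are imputed as 0 in the
design matrix and flagged in a parallel boolean mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import ecg as _ecg
from . import eda as _eda
from . import rsp as _rsp
from .labeling import LabeledWindow
from .session import Baseline, BiosignalRecord, SubjectDataset

logger = logging.getLogger(__name__)

ECG_FEATURES = ("HRNmean", "HRstd", "HRNFD", "HRNSD", "HRV",
                "HRavNN", "HRsdNN", "HRrMSSD", "HRNN50", "HRpNN50", "HRpNN20")
RSP_FEATURES = ("BRNmean", "BRstd", "BRNFD", "BRNSD", "BRV", "BRavNN", "BRsdNN")
EDA_FEATURES = ("EDANmean", "EDAstd", "EDANFD", "EDANSD", "EDAnOR", "EDAmmOR", "EDAmdOR")
ALL_FEATURES = ECG_FEATURES + RSP_FEATURES + EDA_FEATURES

#: the minimal subset retained by the final models
FINAL_SIX = ("HRNmean", "HRstd", "EDANmean", "EDANFD", "EDAnOR", "EDAmmOR")

_PREFIX = {"ecg": "HR", "rsp": "BR", "eda": "EDA"}
_CHANNEL_COLUMNS = {
    "ecg": ECG_FEATURES,
    "rsp": RSP_FEATURES,
    "eda": EDA_FEATURES,
}

__all__ = [
    "ECG_FEATURES", "RSP_FEATURES", "EDA_FEATURES", "ALL_FEATURES", "FINAL_SIX",
    "DesignMatrix", "window_feature_vector", "extract_features", "feature_columns",
]


def feature_columns(channels: Sequence[str]) -> list[str]:
    """Canonical column order for a channel subset."""
    cols: list[str] = []
    for ch in ("ecg", "rsp", "eda"):
        if ch in channels:
            cols.extend(_CHANNEL_COLUMNS[ch])
    return cols


def _prefixed(channel: str, values: Mapping[str, float]) -> dict[str, float]:
    pre = _PREFIX[channel]
    out = {}
    for name, value in values.items():
        if name in ("HRV", "BRV"):
            out[name] = value
        elif channel == "ecg" and name in ("avNN", "sdNN", "rMSSD", "NN50", "pNN50", "pNN20"):
            out[pre + name] = value
        else:
            out[pre + name] = value
    return out


def window_feature_vector(
    records: Mapping[str, BiosignalRecord],
    window: tuple[float, float],
    baseline: Baseline,
    channels: Sequence[str] = ("ecg", "eda"),
) -> tuple[dict[str, float], set[str]]:
    """Feature values and missing-flags for one window.

    Records are truncated at ``window[1]`` first (causality); each channel's
    pipeline then runs on the truncated record and the window statistics are
    read off the interval ``[start, end)``.
    """
    start, end = window
    values: dict[str, float] = {}
    missing: set[str] = set()

    for ch in channels:
        if ch not in records:
            raise KeyError(f"requested channel {ch!r} not present in records")

    if "ecg" in channels:
        rec = records["ecg"].truncated(end)
        try:
            nni = _ecg.detect_r_peaks(rec)
            hr = _ecg.instantaneous_hr(nni)
            feats = _ecg.ecg_features(nni, hr, window, baseline)
            values.update(_prefixed("ecg", feats.to_dict()))
            missing |= {_PREFIX["ecg"] + m if m != "HRV" else m
                        for m in feats.missing}
        except ValueError:
            values.update({c: math.nan for c in ECG_FEATURES})
            missing |= set(ECG_FEATURES)

    if "rsp" in channels:
        rec = records["rsp"].truncated(end)
        breaths = _rsp.detect_breaths(rec)
        feats = _rsp.rsp_features(breaths, window, baseline)
        values.update(_prefixed("rsp", feats.to_dict()))
        missing |= {"BRV" if m == "BRV" else _PREFIX["rsp"] + m for m in feats.missing}

    if "eda" in channels:
        rec = records["eda"].truncated(end)
        tonic = _eda.tonic_filter(rec)
        phasic = _eda.phasic_filter(rec)
        feats = _eda.eda_features(tonic, phasic, window, baseline,
                                  rec.sampling_rate, t0=rec.t0)
        values.update(_prefixed("eda", feats.to_dict()))
        missing |= {_PREFIX["eda"] + m for m in feats.missing}

    cols = feature_columns(channels)
    values = {c: values.get(c, math.nan) for c in cols}
    for c in cols:
        if math.isnan(values[c]):
            missing.add(c)
    return values, missing & set(cols)


@dataclass(frozen=True)
class DesignMatrix:
    """Windows-by-features matrix with labels, missing flags and provenance.

    ``X`` holds imputed values (structural missing → 0); ``missing`` marks
    which entries were imputed; ``meta`` carries subject, session and window
    bounds per row.
    """

    X: pd.DataFrame
    y: pd.Series
    missing: pd.DataFrame
    meta: pd.DataFrame

    def __len__(self) -> int:
        return len(self.X)

    def select(self, columns: Sequence[str]) -> "DesignMatrix":
        return DesignMatrix(self.X[list(columns)], self.y,
                            self.missing[list(columns)], self.meta)

    def subset(self, mask) -> "DesignMatrix":
        mask = np.asarray(mask)
        return DesignMatrix(self.X[mask].reset_index(drop=True),
                            self.y[mask].reset_index(drop=True),
                            self.missing[mask].reset_index(drop=True),
                            self.meta[mask].reset_index(drop=True))

    def drop_label(self, label: str) -> "DesignMatrix":
        return self.subset((self.y != label).to_numpy())

    def to_csv(self, path) -> None:
        frame = self.X.copy()
        frame["label"] = self.y
        frame.to_csv(path, index=False)


def extract_features(
    subject: SubjectDataset,
    windows: Sequence[LabeledWindow],
    channels: Sequence[str] = ("ecg", "eda"),
    baseline: Optional[Baseline] = None,
) -> DesignMatrix:
    """One design-matrix row per labeled window, in deterministic order
    (session, window start).  Windows extending beyond the recording are
    dropped with a log entry."""
    from .session import compute_baseline
    from .labeling import rest_span_for

    if baseline is None and windows:
        baseline = compute_baseline(subject, rest_span_for(windows[0].config.approach))

    cols = feature_columns(channels)
    rows, flags, labels, meta = [], [], [], []
    for w in sorted(windows, key=lambda w: (w.session_kind, w.start)):
        session = subject.session(w.session_kind)
        records = session.records
        too_short = any(
            records[ch].t0 + records[ch].duration + 1e-9 < w.end
            for ch in channels if ch in records
        )
        if too_short:
            logger.warning("dropping window [%.1f, %.1f) of subject %s: outside recording",
                           w.start, w.end, subject.subject_id)
            continue
        values, missing = window_feature_vector(records, w.window, baseline, channels)
        rows.append([0.0 if c in missing else values[c] for c in cols])
        flags.append([c in missing for c in cols])
        labels.append(w.label)
        meta.append((subject.subject_id, w.session_kind, w.start, w.end))

    X = pd.DataFrame(rows, columns=cols, dtype=float)
    return DesignMatrix(
        X=X,
        y=pd.Series(labels, name="label", dtype=object),
        missing=pd.DataFrame(flags, columns=cols, dtype=bool),
        meta=pd.DataFrame(meta, columns=["subject", "session", "start", "end"]),
    )


def extract_cohort_features(
    cohort: Sequence[SubjectDataset],
    windows: Sequence[LabeledWindow],
    channels: Sequence[str] = ("ecg", "eda"),
    baselines: Optional[Mapping[str, Baseline]] = None,
) -> DesignMatrix:
    """Concatenate per-subject design matrices for a cohort."""
    parts = []
    by_subject: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        by_subject.setdefault(w.subject_id, []).append(w)
    for subject in cohort:
        sub_windows = by_subject.get(subject.subject_id, [])
        if not sub_windows:
            continue
        base = (baselines or {}).get(subject.subject_id)
        parts.append(extract_features(subject, sub_windows, channels, base))
    if not parts:
        empty = pd.DataFrame(columns=feature_columns(channels), dtype=float)
        return DesignMatrix(empty, pd.Series([], name="label", dtype=object),
                            empty.astype(bool),
                            pd.DataFrame(columns=["subject", "session", "start", "end"]))
    return DesignMatrix(
        X=pd.concat([p.X for p in parts], ignore_index=True),
        y=pd.concat([p.y for p in parts], ignore_index=True),
        missing=pd.concat([p.missing for p in parts], ignore_index=True),
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
    )
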