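"""On-line playback: emulated real-time prediction every 10 seconds.

The playback engine walks a recorded session in fixed update steps
(default 10 s).  At each tick ``t`` it computes the feature vector of the
window ``[t − update_s, t)`` using only samples acquired at or before ``t``
— the records are truncated at ``t`` before any processing, the same causal
code path batch feature extraction uses — and emits the trained model's
prediction with class scores.

If labeled windows are supplied, an event carries a true label only when
its full window lies inside one labeled span; windows straddling a label
boundary (or outside any labeled segment) count as unlabeled and are
excluded from the playback accuracy denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

from .features import window_feature_vector
from .labeling import LabeledWindow
from .models import FittedModel
from .session import Baseline, BiosignalRecord, SessionLayout

__all__ = ["PredictionEvent", "labeled_spans", "playback", "playback_accuracy"]


@dataclass(frozen=True)
class PredictionEvent:
    emit_time: float
    window: tuple[float, float]
    predicted: str
    scores: dict[str, float]
    true_label: Optional[str] = None
    features: Optional[dict[str, float]] = None


def labeled_spans(
    windows: Sequence[LabeledWindow], session_kind: str
) -> list[tuple[float, float, str]]:
    """Merge a session's labeled windows into maximal same-label spans."""
    wins = sorted((w for w in windows if w.session_kind == session_kind),
                  key=lambda w: w.start)
    spans: list[list] = []
    for w in wins:
        if spans and spans[-1][2] == w.label and abs(spans[-1][1] - w.start) < 1e-9:
            spans[-1][1] = w.end
        else:
            spans.append([w.start, w.end, w.label])
    return [tuple(s) for s in spans]


def _span_label(spans, start: float, end: float) -> Optional[str]:
    for s0, s1, label in spans:
        if start >= s0 - 1e-9 and end <= s1 + 1e-9:
            return label
    return None


def playback(
    layout: SessionLayout,
    records: Mapping[str, BiosignalRecord],
    model: FittedModel,
    baseline: Baseline,
    update_s: float = 10.0,
    labels: Optional[Sequence[LabeledWindow]] = None,
    channels: Sequence[str] = ("ecg", "eda"),
    keep_features: bool = False,
) -> Iterator[PredictionEvent]:
    """Stream one :class:`PredictionEvent` per update tick.

    The first event fires at ``t = update_s`` (a full first window); events
    are exactly ``update_s`` apart.  Missing baseline is an error because
    the normalized features are undefined without it.
    """
    if baseline is None:
        raise ValueError("playback requires a baseline (normalized features undefined)")
    for ch in channels:
        if ch not in records:
            raise KeyError(f"model requires channel {ch!r} absent from the session")
    duration = min(records[ch].t0 + records[ch].duration for ch in channels)
    spans = labeled_spans(labels, layout.session_kind) if labels else []

    n_events = int(math.floor(duration / update_s + 1e-9))
    for i in range(1, n_events + 1):
        t = i * update_s
        window = (t - update_s, t)
        values, missing = window_feature_vector(records, window, baseline, channels)
        x = np.array([[0.0 if name in missing else values[name]
                       for name in model.feature_names]])
        predicted = str(model.predict(x)[0])
        proba = model.predict_scores(x).iloc[0]
        yield PredictionEvent(
            emit_time=t,
            window=window,
            predicted=predicted,
            scores={c: float(proba[c]) for c in proba.index},
            true_label=_span_label(spans, *window),
            features=dict(values) if keep_features else None,
        )


def playback_accuracy(events: Iterable[PredictionEvent]) -> Optional[float]:
    """Agreement over events whose window lies inside a labeled span.

    Unlabeled events are excluded from the denominator; with no labeled
    event at all the accuracy is undefined and ``None`` is returned.
    """
    labeled = [e for e in events if e.true_label is not None]
    if not labeled:
        return None
    return float(np.mean([e.predicted == e.true_label for e in labeled]))
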