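"""Synthetic arousal-session simulator with known ground truth.

Generates cohorts of paired sessions that mirror the study protocol: a
biofeedback *training* session holding a 5-minute rest, and an *exposure*
session of a 1-minute demo clip, sixteen 1-minute spider-video clips with a
rating pause after every fourth clip, and a closing 5-minute rest.  Every
subject carries a latent arousal level per segment (rest = low, half the
clips high and half medium by default) that drives the signals:

* **ECG** — an RR-interval process (segment-dependent mean with AR(1)
  jitter; arousal raises heart rate and shrinks variability) rendered as
  Gaussian-bump QRS complexes plus baseline wander and sensor noise.
* **EDA** — a slowly drifting tonic level (raised slightly under arousal)
  with superposed biexponential skin-conductance responses at a
  state-dependent Poisson rate, plus noise.
* **RSP** — a sinusoidal chest-displacement signal whose rate rises with
  arousal, with phase jitter and noise.
* **Ratings** — the latent arousal of each pre-rating clip mapped onto the
  1–4 scale, optionally perturbed by one point with probability
  ``rating_noise``.

Ground truth (true R-peak instants, true SCR events, true breath peaks,
latent levels, ratings) is returned alongside the signals so every
detector and labeling stage can be validated without real recordings.
Output is fully determined by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .labeling import RATING_LABELS, LabeledWindow, LabelingConfig, segment_windows
from .session import (BiosignalRecord, Rating, Segment, SessionData,
                      SessionLayout, SubjectDataset)

__all__ = ["SimulationConfig", "GroundTruth", "generate_cohort", "generate_subject",
           "truth_labels", "training_layout", "exposure_layout"]

#: latent arousal weight per level — scales every arousal effect
LEVEL_WEIGHT = {"low": 0.0, "medium": 0.5, "high": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator settings; defaults encode the emulated study conditions."""

    n_subjects: int = 40
    seed: int = 0
    sampling_rate: float = 100.0

    # cardiac
    rest_hr: float = 65.0  # cohort-mean bpm at rest
    rest_hr_subject_sd: float = 3.0  # between-subject SD of resting HR, bpm
    hr_arousal_delta: float = 15.0  # bpm added at full (high) arousal
    hrv_rest: float = 40.0  # stationary SD of the AR(1) RR jitter, ms
    hrv_arousal_shrink: float = 0.6  # RR jitter SD multiplier at full arousal
    ar_coeff: float = 0.8  # AR(1) coefficient of the RR jitter

    # electrodermal
    scr_rate_rest: float = 2.0  # SCR events/min at rest
    scr_rate_high: float = 8.0  # SCR events/min at full arousal
    scr_amp_range: tuple[float, float] = (0.1, 0.6)  # µS
    tonic_base_range: tuple[float, float] = (2.0, 6.0)  # subject tonic level, µS
    tonic_drift: float = 0.05  # µS per minute
    tonic_wander: float = 0.05  # amplitude of a slow (120 s) tonic oscillation, µS
    tonic_arousal_rise: float = 0.3  # µS added to tonic at full arousal

    # respiratory
    br_rest: float = 12.0  # breaths/min at rest
    br_arousal_delta: float = 6.0  # breaths/min added at full arousal
    rsp_amp: float = 5.0  # chest displacement amplitude, %

    # protocol
    demo_s: float = 60.0
    clip_s: float = 60.0
    n_clips: int = 16
    rating_pause_s: float = 30.0
    rest_s: float = 300.0
    rating_noise: float = 0.1  # probability a rating deviates by ±1

    #: clips latently 'high' for every subject; None → random 8 per subject
    high_clips: Optional[tuple[int, ...]] = None
    n_high_clips: int = 8

    # sensor noise SDs
    ecg_noise: float = 0.02  # arbitrary units (R amplitude = 1)
    eda_noise: float = 0.01  # µS
    rsp_noise: float = 0.25  # %

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sampling_rate <= 0:
            raise ValueError("n_subjects and sampling_rate must be positive")
        if self.scr_rate_rest < 0 or self.scr_rate_high < 0 or self.br_rest <= 0:
            raise ValueError("rates must be positive")
        if self.high_clips is not None:
            if not all(1 <= c <= self.n_clips for c in self.high_clips):
                raise ValueError("high_clips must index clips 1..n_clips")


@dataclass
class GroundTruth:
    """Per-subject latent state and true events, consistent with the signals."""

    subject_id: str
    clip_levels: dict[int, str]  # clip index -> "high"/"medium"
    segment_levels: dict[str, list[tuple[float, float, str]]]  # session -> (start, end, level)
    r_peaks: dict[str, np.ndarray]  # session -> true R instants, s
    scr_events: dict[str, list[tuple[float, float]]]  # session -> (onset_t, amplitude µS)
    breath_peaks: dict[str, np.ndarray]  # session -> true chest-rise instants, s
    ratings: list[tuple[int, int]]  # (after_clip_index, value)


def training_layout(cfg: SimulationConfig) -> SessionLayout:
    return SessionLayout("training", (Segment("rest", 0.0, cfg.rest_s),))


def exposure_layout(cfg: SimulationConfig) -> SessionLayout:
    """Demo, sixteen clips with a rating pause after every fourth, final rest."""
    segments = [Segment("demo", 0.0, cfg.demo_s)]
    ratings = []
    t = cfg.demo_s
    for clip in range(1, cfg.n_clips + 1):
        segments.append(Segment("clip", t, t + cfg.clip_s, clip_index=clip))
        t += cfg.clip_s
        if clip % 4 == 0:
            ratings.append((t + cfg.rating_pause_s / 2, clip))
            t += cfg.rating_pause_s
    segments.append(Segment("rest", t, t + cfg.rest_s))
    return SessionLayout("exposure", tuple(segments),
                         tuple(Rating(time=rt, after_clip_index=ci, value=1)
                               for rt, ci in ratings))


def _level_pieces(layout: SessionLayout, clip_levels: dict[int, str]
                  ) -> list[tuple[float, float, str]]:
    """Piecewise-constant latent level covering [0, duration]; unscripted
    gaps (rating pauses) relax to 'low'."""
    pieces = []
    t = 0.0
    for seg in layout.segments:
        if seg.start > t + 1e-9:
            pieces.append((t, seg.start, "low"))
        if seg.role == "rest":
            level = "low"
        elif seg.role == "demo":
            level = "medium"
        else:
            level = clip_levels[seg.clip_index]
        pieces.append((seg.start, seg.end, level))
        t = seg.end
    return pieces


def _weight_profile(pieces) -> "callable":
    starts = np.array([p[0] for p in pieces])
    weights = np.array([LEVEL_WEIGHT[p[2]] for p in pieces])

    def w(t: float) -> float:
        i = int(np.searchsorted(starts, t, side="right")) - 1
        return float(weights[max(0, i)])

    return w


def _render_ecg(duration: float, w, cfg: SimulationConfig, rng: np.random.Generator,
                rest_hr: float) -> tuple[np.ndarray, np.ndarray]:
    fs = cfg.sampling_rate
    peaks = []
    t = 0.3 + 0.4 * rng.random()
    jitter = 0.0
    phi = cfg.ar_coeff
    while t < duration:
        wt = w(t)
        rr_mean = 60000.0 / (rest_hr + cfg.hr_arousal_delta * wt)
        sigma = cfg.hrv_rest * (cfg.hrv_arousal_shrink ** wt)
        jitter = phi * jitter + rng.normal(0.0, max(sigma, 1e-9) * math.sqrt(1 - phi * phi))
        rr = float(np.clip(rr_mean + jitter, 300.0, 2000.0))
        peaks.append(t)
        t += rr / 1000.0
    peaks = np.asarray(peaks)

    n = int(round(duration * fs))
    x = np.zeros(n)
    sigma_q = 0.012  # QRS bump width, s
    half = int(math.ceil(4 * sigma_q * fs))
    grid = np.arange(n) / fs
    for p in peaks:
        c = int(round(p * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        x[lo:hi] += np.exp(-0.5 * ((grid[lo:hi] - p) / sigma_q) ** 2)
    # baseline wander + sensor noise
    x += 0.05 * np.sin(2 * math.pi * 0.3 * grid + rng.uniform(0, 2 * math.pi))
    x += rng.normal(0.0, cfg.ecg_noise, size=n)
    return x, peaks


def _scr_kernel(amp: float, tau_rise: float, tau_decay: float, fs: float) -> np.ndarray:
    length = int(round((tau_rise + 6 * tau_decay) * fs))
    tau = np.arange(length) / fs
    shape = np.exp(-tau / tau_decay) - np.exp(-tau / tau_rise)
    peak = shape.max()
    return amp * shape / peak if peak > 0 else shape


def _render_eda(duration: float, pieces, cfg: SimulationConfig, rng: np.random.Generator,
                tonic_base: float) -> tuple[np.ndarray, list[tuple[float, float]]]:
    fs = cfg.sampling_rate
    n = int(round(duration * fs))
    grid = np.arange(n) / fs
    tonic = tonic_base + cfg.tonic_drift * grid / 60.0
    tonic += cfg.tonic_wander * np.sin(2 * math.pi * grid / 120.0 + rng.uniform(0, 2 * math.pi))
    # smoothed arousal rise of the tonic level (20 s ramp, no hard steps)
    rise = np.zeros(n)
    for (s, e, lvl) in pieces:
        i0, i1 = int(s * fs), min(n, int(e * fs))
        rise[i0:i1] = LEVEL_WEIGHT[lvl]
    ramp = int(20 * fs)
    if ramp > 1:
        kernel = np.ones(ramp) / ramp
        rise = np.convolve(rise, kernel, mode="same")
    x = tonic + cfg.tonic_arousal_rise * rise

    events: list[tuple[float, float]] = []
    for (s, e, lvl) in pieces:
        w_ = LEVEL_WEIGHT[lvl]
        rate = (cfg.scr_rate_rest + (cfg.scr_rate_high - cfg.scr_rate_rest) * w_) / 60.0
        count = rng.poisson(rate * (e - s))
        for onset in np.sort(rng.uniform(s, e, size=count)):
            amp = rng.uniform(*cfg.scr_amp_range)
            events.append((float(onset), float(amp)))
    for onset, amp in events:
        kern = _scr_kernel(amp, 0.75, rng.uniform(2.0, 6.0), fs)
        i0 = int(round(onset * fs))
        i1 = min(n, i0 + len(kern))
        x[i0:i1] += kern[: i1 - i0]
    x += rng.normal(0.0, cfg.eda_noise, size=n)
    return x, events


def _render_rsp(duration: float, w, cfg: SimulationConfig, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    fs = cfg.sampling_rate
    n = int(round(duration * fs))
    rates = np.array([(cfg.br_rest + cfg.br_arousal_delta * w(i / fs)) / 60.0
                      for i in range(n)])
    dphi = rates / fs + rng.normal(0.0, 2e-4, size=n)
    phase = np.cumsum(dphi)
    x = cfg.rsp_amp * np.sin(2 * math.pi * phase) + rng.normal(0.0, cfg.rsp_noise, size=n)
    # chest rises: phase passes quarter-cycle marks (sin maxima)
    marks = np.floor(phase - 0.25)
    peaks = (np.nonzero(np.diff(marks) > 0)[0] + 1) / fs
    return x, np.asarray(peaks, dtype=float)


def _simulate_session(layout: SessionLayout, clip_levels, cfg, rng, traits):
    """Render one session; ``traits`` are subject-level constants shared
    between the training and exposure sessions."""
    pieces = _level_pieces(layout, clip_levels)
    w = _weight_profile(pieces)
    duration = layout.duration
    ecg, r_peaks = _render_ecg(duration, w, cfg, rng, traits["rest_hr"])
    eda, scrs = _render_eda(duration, pieces, cfg, rng, traits["tonic_base"])
    rsp, breaths = _render_rsp(duration, w, cfg, rng)
    records = {
        "ecg": BiosignalRecord("ecg", ecg, cfg.sampling_rate),
        "eda": BiosignalRecord("eda", eda, cfg.sampling_rate),
        "rsp": BiosignalRecord("rsp", rsp, cfg.sampling_rate),
    }
    return records, pieces, r_peaks, scrs, breaths


def _simulate_ratings(clip_levels, cfg, rng) -> list[tuple[int, int]]:
    out = []
    for clip in range(4, cfg.n_clips + 1, 4):
        level = clip_levels[clip]
        value = int(rng.choice([3, 4])) if level == "high" else int(rng.choice([1, 2]))
        if rng.random() < cfg.rating_noise:
            value = int(np.clip(value + rng.choice([-1, 1]), 1, 4))
        out.append((clip, value))
    return out


def generate_subject(cfg: SimulationConfig, subject_id: str,
                     rng: np.random.Generator) -> tuple[SubjectDataset, GroundTruth]:
    if cfg.high_clips is not None:
        high = set(cfg.high_clips)
    else:
        high = set(rng.choice(np.arange(1, cfg.n_clips + 1), size=cfg.n_high_clips,
                              replace=False).tolist())
    clip_levels = {c: ("high" if c in high else "medium")
                   for c in range(1, cfg.n_clips + 1)}
    # subject-level physiological traits, constant across the two sessions
    traits = {
        "rest_hr": cfg.rest_hr + rng.normal(0.0, cfg.rest_hr_subject_sd),
        "tonic_base": rng.uniform(*cfg.tonic_base_range),
    }

    t_layout = training_layout(cfg)
    t_records, t_pieces, t_rpeaks, t_scrs, t_breaths = _simulate_session(
        t_layout, clip_levels, cfg, rng, traits)

    e_layout = exposure_layout(cfg)
    ratings = _simulate_ratings(clip_levels, cfg, rng)
    e_layout = SessionLayout(
        "exposure", e_layout.segments,
        tuple(Rating(time=r.time, after_clip_index=r.after_clip_index, value=v)
              for r, (_, v) in zip(e_layout.ratings, ratings)),
    )
    e_records, e_pieces, e_rpeaks, e_scrs, e_breaths = _simulate_session(
        e_layout, clip_levels, cfg, rng, traits)

    subject = SubjectDataset(
        subject_id=subject_id,
        training=SessionData(t_layout, t_records),
        exposure=SessionData(e_layout, e_records),
    )
    truth = GroundTruth(
        subject_id=subject_id,
        clip_levels=clip_levels,
        segment_levels={"training": t_pieces, "exposure": e_pieces},
        r_peaks={"training": t_rpeaks, "exposure": e_rpeaks},
        scr_events={"training": t_scrs, "exposure": e_scrs},
        breath_peaks={"training": t_breaths, "exposure": e_breaths},
        ratings=ratings,
    )
    return subject, truth


def generate_cohort(cfg: SimulationConfig
                    ) -> list[tuple[SubjectDataset, GroundTruth]]:
    """Simulate ``cfg.n_subjects`` subjects; byte-identical for a fixed seed."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    out = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        out.append(generate_subject(cfg, f"sim{i:03d}", rng))
    return out


# ---------------------------------------------------------------------------
# Oracle labels


def truth_labels(subject: SubjectDataset, truth: GroundTruth,
                 config: LabelingConfig) -> list[LabeledWindow]:
    """Labels derived directly from the latent arousal state, bypassing the
    signals — the oracle counterpart of the signal-driven labelers."""
    from .labeling import rest_span_for

    layout = subject.exposure.layout
    segments: list[tuple[float, float, str, str]] = []
    if config.approach == "SB":
        rated = dict(truth.ratings)
        for clip_index in range(4, 17, 4):
            seg = layout.clip_segment(clip_index)
            if seg is not None and clip_index in rated:
                segments.append((seg.start, seg.end,
                                 RATING_LABELS[rated[clip_index]], "exposure"))
    else:
        for seg in layout.clip_segments():
            segments.append((seg.start, seg.end,
                             truth.clip_levels[seg.clip_index], "exposure"))
    span = 300.0 if rest_span_for(config.approach) == "full_5min" else 180.0
    rest = subject.training.layout.rest_segment()
    segments.append((rest.end - span, rest.end, "low", "training"))

    tiles = segment_windows(segments, config.window_s)
    return [
        LabeledWindow(subject_id=subject.subject_id, session_kind=kind,
                      start=s, end=e, label=label, config=config)
        for s, e, label, kind in tiles
        if not (config.levels == 2 and label == "medium")
    ]
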