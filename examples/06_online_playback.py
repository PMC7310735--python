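"""On-line anxiety prediction: 10-second playback of a recorded session.

Trains a model on one subject's labeled windows, then replays the exposure
session emulating real-time acquisition — one causal prediction every 10
seconds — and reports the running agreement with the true labels.
"""

from anxio import (ClassifierConfig, LabelingConfig, SimulationConfig,
                   compute_baseline, extract_features, generate_cohort,
                   playback, playback_accuracy, subjective_labels, train)
from anxio.features import FINAL_SIX

cfg = SimulationConfig(n_subjects=1, seed=51, rating_noise=0.0)
[(subject, _)] = generate_cohort(cfg)
baseline = compute_baseline(subject, "last_3min")
labels = subjective_labels(subject, LabelingConfig("SB", 2, 10.0))

dm = extract_features(subject, labels, ("ecg", "eda"), baseline)
model = train(ClassifierConfig("bagged_trees", {"n_learners": 30}),
              dm.X[list(FINAL_SIX)], dm.y.to_numpy(), seed=0)

events = list(playback(subject.exposure.layout, subject.exposure.records,
                       model, baseline, update_s=10.0, labels=labels))
for event in events[:6]:
    truth = event.true_label or "-"
    print(f"t={event.emit_time:6.0f} s  predicted {event.predicted:5s}  true {truth}")
print(f"... {len(events)} events total; "
      f"agreement over labeled windows: {playback_accuracy(events):.2f}")
# Events without a true label fall outside (or straddle) labeled segments
# and are excluded from the agreement denominator.
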