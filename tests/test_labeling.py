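import numpy as np
import pytest

from anxio.labeling import (LabelingConfig, LabeledWindow, clip_based_labels,
                            clip_signal_means, segment_windows,
                            subject_based_labels, subjective_labels)
from anxio.session import compute_baseline
from anxio.synthetic import SimulationConfig, generate_cohort, truth_labels


def counts(windows):
    out = {"low": 0, "medium": 0, "high": 0}
    for w in windows:
        out[w.label] += 1
    return out


class TestSegmentWindows:
    @pytest.mark.parametrize("length,window,expected", [
        (60.0, 10.0, 6), (59.0, 60.0, 0), (180.0, 60.0, 3), (65.0, 10.0, 6),
    ])
    def test_tiling_arithmetic(self, length, window, expected):
        tiles = segment_windows([(0.0, length, "high", "exposure")], window)
        assert len(tiles) == expected
        for (s, e, _, _) in tiles:
            assert e - s == pytest.approx(window)

    def test_windows_never_cross_segments(self):
        tiles = segment_windows([(0.0, 60.0, "high", "exposure"),
                                 (65.0, 125.0, "low", "exposure")], 10.0)
        for s, e, _, _ in tiles:
            assert (e <= 60.0) or (s >= 65.0)


class TestClipBased:
    def test_window_counts_and_balance(self, small_cohort):
        cohort = [s for s, _ in small_cohort]
        wins3 = clip_based_labels(cohort, LabelingConfig("HR1", 3, 60.0))
        per_subject = [w for w in wins3 if w.subject_id == cohort[0].subject_id]
        assert counts(per_subject) == {"low": 3, "medium": 3, "high": 3}
        wins2 = clip_based_labels(cohort, LabelingConfig("HR1", 2, 10.0))
        per_subject2 = [w for w in wins2 if w.subject_id == cohort[0].subject_id]
        assert counts(per_subject2) == {"low": 18, "medium": 0, "high": 18}

    def test_label_map_shared_across_subjects(self, small_cohort):
        cohort = [s for s, _ in small_cohort]
        wins = clip_based_labels(cohort, LabelingConfig("EDA1", 3, 60.0))
        high_starts = {}
        for subj in cohort:
            layout = subj.exposure.layout
            highs = frozenset(
                seg.clip_index for seg in layout.clip_segments()
                if any(w.subject_id == subj.subject_id and w.label == "high"
                       and seg.start <= w.start < seg.end for w in wins)
            )
            high_starts[subj.subject_id] = highs
        assert len(set(high_starts.values())) == 1

    def test_label_map_invariant_to_subject_order(self, small_cohort):
        cohort = [s for s, _ in small_cohort]
        a = clip_signal_means(cohort, "hr")
        b = clip_signal_means(cohort[::-1], "hr")
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_designated_clips_rank_highest(self):
        # every subject aroused on the same three clips
        cfg = SimulationConfig(n_subjects=3, seed=31, high_clips=(5, 9, 12),
                               n_high_clips=3)
        cohort = [s for s, _ in generate_cohort(cfg)]
        means = clip_signal_means(cohort, "hr")
        top3 = set(np.argsort(means)[-3:] + 1)
        assert top3 == {5, 9, 12}

    def test_single_subject_equals_own_means(self, small_cohort):
        subject, _ = small_cohort[0]
        means = clip_signal_means([subject], "hr")
        assert means.shape == (16,)


class TestSubjectBased:
    def test_class_shares_38_38_24(self, strong_subject):
        subject, _ = strong_subject
        wins = subject_based_labels(subject, LabelingConfig("HR2", 3, 10.0))
        c = counts(wins)
        total = sum(c.values())
        assert c == {"high": 48, "medium": 48, "low": 30}
        assert c["high"] / total == pytest.approx(0.38, abs=0.005)
        assert c["low"] / total == pytest.approx(0.24, abs=0.005)

    def test_60s_window_count(self, strong_subject):
        subject, _ = strong_subject
        wins = subject_based_labels(subject, LabelingConfig("EDA2", 3, 60.0))
        assert len(wins) == 21  # 8 + 8 + 5 labeled minutes

    def test_agreement_with_latent_assignment(self, strong_subject):
        subject, truth = strong_subject
        wins = subject_based_labels(subject, LabelingConfig("HR2", 3, 60.0))
        oracle = truth_labels(subject, truth, LabelingConfig("HR2", 3, 60.0))
        labels = {(w.session_kind, w.start): w.label for w in wins}
        agree = [labels[(w.session_kind, w.start)] == w.label for w in oracle]
        assert np.mean(agree) >= 0.90

    def test_incomplete_exposure_rejected(self, strong_subject):
        import dataclasses
        from anxio.session import SessionData, SessionLayout, SessionValidationError
        subject, _ = strong_subject
        layout = subject.exposure.layout
        short = SessionLayout("exposure", tuple(
            s for s in layout.segments if s.role != "clip" or s.clip_index <= 8
        ), layout.ratings[:2])
        broken = dataclasses.replace(
            subject, exposure=SessionData(short, subject.exposure.records))
        with pytest.raises(SessionValidationError, match="8/8"):
            subject_based_labels(broken, LabelingConfig("HR2", 3, 10.0))


class TestSubjective:
    def test_rating_map(self, strong_subject):
        subject, truth = strong_subject
        wins = subjective_labels(subject, LabelingConfig("SB", 3, 60.0))
        rated = dict(truth.ratings)
        layout = subject.exposure.layout
        for clip_index, value in rated.items():
            seg = layout.clip_segment(clip_index)
            lab = next(w.label for w in wins
                       if w.session_kind == "exposure" and w.start == seg.start)
            assert lab == ("high" if value >= 3 else "medium")

    def test_window_budget_3level_60s(self, strong_subject):
        subject, _ = strong_subject
        wins = subjective_labels(subject, LabelingConfig("SB", 3, 60.0))
        c = counts(wins)
        assert c["low"] == 3 and c["medium"] + c["high"] == 4

    def test_two_level_has_no_medium(self, strong_subject):
        subject, _ = strong_subject
        wins = subjective_labels(subject, LabelingConfig("SB", 2, 10.0))
        assert all(w.label != "medium" for w in wins)

    def test_truth_labels_match_when_noise_free(self, strong_subject):
        subject, truth = strong_subject  # generated with rating_noise = 0
        sig = subjective_labels(subject, LabelingConfig("SB", 3, 10.0))
        orc = truth_labels(subject, truth, LabelingConfig("SB", 3, 10.0))
        assert {(w.session_kind, w.start, w.label) for w in sig} == \
               {(w.session_kind, w.start, w.label) for w in orc}


class TestConfigInvariants:
    def test_config_space(self):
        combos = [(a, l, w) for a in ("SB", "HR1", "HR2", "EDA1", "EDA2")
                  for l in (2, 3) for w in (10.0, 60.0)]
        assert len(combos) == 20
        for a, l, w in combos:
            LabelingConfig(a, l, w)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LabelingConfig("HR3", 3, 10.0)
        with pytest.raises(ValueError):
            LabelingConfig("SB", 4, 10.0)
        with pytest.raises(ValueError):
            LabeledWindow("s", "exposure", 0.0, 10.0, "medium",
                          LabelingConfig("SB", 2, 10.0))
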