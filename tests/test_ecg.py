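import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anxio.ecg import (EcgFeatures, HRSeries, NNISeries, detect_r_peaks,
                       ecg_features, instantaneous_hr)
from anxio.session import Baseline, BiosignalRecord
from anxio.synthetic import SimulationConfig, generate_cohort

import oracles


def nni_series(nni_ms, start=0.0):
    """Build an NNISeries from interval values, peaks 1 s apart notionally."""
    peak_times = np.concatenate([[start], start + np.cumsum(nni_ms) / 1000.0])
    return NNISeries.from_peaks(peak_times)


def hr_series(values, times=None):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values), dtype=float) if times is None else np.asarray(times)
    return HRSeries(times=times, bpm=values)


BASE = Baseline(subject_id="t", hr_rest_mean=70.0, eda_rest_min=2.0,
                eda_rest_max=4.0, rest_window=(0.0, 300.0))
WIDE = (0.0, 1e9)


class TestDetector:
    def test_flat_signal_yields_no_peaks(self):
        rec = BiosignalRecord("ecg", np.zeros(6000), 100.0)
        assert len(detect_r_peaks(rec).peak_times) == 0

    def test_too_short_input_rejected(self):
        rec = BiosignalRecord("ecg", np.zeros(100), 100.0)
        with pytest.raises(ValueError, match="short"):
            detect_r_peaks(rec)

    def test_constant_60bpm_clean(self):
        cfg = SimulationConfig(n_subjects=1, seed=7, rest_hr=60.0, hrv_rest=0.0,
                               rest_hr_subject_sd=0.0, rest_s=60.0, ecg_noise=0.005)
        [(subject, truth)] = generate_cohort(cfg)
        rec = subject.training.record("ecg")
        nni = detect_r_peaks(rec)
        true_peaks = truth.r_peaks["training"]
        assert 59 <= len(nni.peak_times) <= 61
        d = np.abs(nni.peak_times[:, None] - true_peaks[None, :]).min(axis=1)
        assert np.all(d < 0.020)

    def test_ar1_rr_mean_recovered(self):
        # RR process around 800 ms (75 bpm)
        cfg = SimulationConfig(n_subjects=1, seed=8, rest_hr=75.0, hrv_rest=40.0,
                               rest_hr_subject_sd=0.0)
        [(subject, truth)] = generate_cohort(cfg)
        nni = detect_r_peaks(subject.training.record("ecg"))
        true_mean = np.mean(np.diff(truth.r_peaks["training"])) * 1000.0
        assert np.mean(nni.nni) == pytest.approx(true_mean, abs=10.0)

    @pytest.mark.parametrize("hr", [50, 80, 120])
    def test_sensitivity_and_ppv_clean(self, hr):
        cfg = SimulationConfig(n_subjects=1, seed=40 + hr, rest_hr=float(hr),
                               hrv_rest=20.0, rest_s=120.0, ecg_noise=0.01)
        [(subject, truth)] = generate_cohort(cfg)
        det = detect_r_peaks(subject.training.record("ecg")).peak_times
        tru = truth.r_peaks["training"]
        d = np.abs(det[:, None] - tru[None, :])
        assert (d.min(axis=1) < 0.05).mean() >= 0.99  # positive predictivity
        assert (d.min(axis=0) < 0.05).mean() >= 0.99  # sensitivity

    def test_heavy_noise_degrades_gracefully(self):
        cfg = SimulationConfig(n_subjects=1, seed=9, rest_s=60.0, ecg_noise=1.5)
        [(subject, _)] = generate_cohort(cfg)
        detect_r_peaks(subject.training.record("ecg"))  # must not crash


class TestInstantaneousHR:
    def test_reciprocal_identity(self):
        hr = instantaneous_hr(nni_series([1000.0] * 10))
        np.testing.assert_allclose(hr.bpm, 60.0)

    def test_hand_values(self):
        hr = instantaneous_hr(nni_series([800.0, 1000.0]))
        np.testing.assert_allclose(hr.bpm, [75.0, 60.0])

    def test_empty_span_rejected(self):
        series = nni_series([1000.0] * 5)
        with pytest.raises(ValueError, match="no normal-to-normal"):
            instantaneous_hr(series, span=(100.0, 200.0))


class TestFeatureExamples:
    def test_worked_example_rmssd_and_pnn(self):
        nni = nni_series([800.0, 810.0, 790.0, 805.0])
        f = ecg_features(nni, instantaneous_hr(nni), WIDE, BASE)
        assert f.rMSSD == pytest.approx(15.546, abs=0.01)
        assert f.NN50 == 0
        assert f.pNN50 == 0
        assert f.pNN20 == pytest.approx(1 / 3)

    def test_constant_nni(self):
        nni = nni_series([800.0] * 6)
        f = ecg_features(nni, instantaneous_hr(nni), WIDE, BASE)
        assert f.avNN == pytest.approx(800.0)
        assert f.sdNN == pytest.approx(0.0, abs=1e-9)
        assert f.rMSSD == pytest.approx(0.0, abs=1e-9)
        assert f.HRV == pytest.approx(0.0, abs=1e-9)

    def test_nmean_from_baseline(self):
        f = ecg_features(nni_series([800.0] * 5),
                         hr_series([70.0, 72.0, 74.0]), WIDE, BASE)
        assert f.Nmean == pytest.approx(2.0)

    def test_insufficient_nnis_flagged_missing(self):
        nni = nni_series([800.0, 810.0])
        f = ecg_features(nni, instantaneous_hr(nni), WIDE, BASE)
        assert "rMSSD" in f.missing and math.isnan(f.rMSSD)
        assert "avNN" in f.missing

    def test_literal_interval_count_flag(self):
        nni = nni_series([800.0, 810.0, 790.0, 805.0])
        f = ecg_features(nni, instantaneous_hr(nni), WIDE, BASE, count_intervals=True)
        # every interval exceeds both thresholds under the printed literal reading
        assert f.NN50 == 4
        assert f.pNN50 == 1.0


class TestFeatureProperties:
    @pytest.mark.parametrize("trial", range(20))
    def test_oracle_equivalence_random_sequences(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = rng.integers(4, 30)
        vals = rng.uniform(500.0, 1200.0, size=n)
        nni = nni_series(vals)
        hr_vals = 60000.0 / nni.nni
        f = ecg_features(nni, instantaneous_hr(nni), WIDE, BASE)
        nlist = list(nni.nni)
        assert f.avNN == pytest.approx(oracles.av_nn(nlist), rel=1e-9)
        assert f.sdNN == pytest.approx(oracles.sd_nn(nlist), rel=1e-9)
        assert f.rMSSD == pytest.approx(oracles.rmssd(nlist), rel=1e-9)
        assert f.HRV == pytest.approx(oracles.hrv_signed(nlist), rel=1e-9, abs=1e-12)
        assert f.NN50 == oracles.nn_over(nlist, 50.0)
        assert f.pNN50 == pytest.approx(oracles.pnn(nlist, 50.0), rel=1e-9, abs=1e-12)
        assert f.pNN20 == pytest.approx(oracles.pnn(nlist, 20.0), rel=1e-9, abs=1e-12)
        hlist = list(hr_vals)
        assert f.Nmean == pytest.approx(oracles.nmean_reference(hlist, 70.0), rel=1e-9)
        assert f.std == pytest.approx(oracles.sample_std(hlist), rel=1e-9)
        assert f.NFD == pytest.approx(oracles.nfd(hlist), rel=1e-9)
        assert f.NSD == pytest.approx(oracles.nsd(hlist), rel=1e-9)

    @given(st.lists(st.floats(min_value=400.0, max_value=1500.0), min_size=4, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_invariants(self, vals):
        nni = nni_series(vals)
        f = ecg_features(nni, instantaneous_hr(nni), WIDE, BASE)
        rev = nni_series(vals[::-1])
        g = ecg_features(rev, instantaneous_hr(rev), WIDE, BASE)
        # order statistics are reversal-invariant; signed HRV flips sign
        assert g.rMSSD == pytest.approx(f.rMSSD, rel=1e-9, abs=1e-12)
        assert g.sdNN == pytest.approx(f.sdNN, rel=1e-9, abs=1e-12)
        assert g.HRV == pytest.approx(-f.HRV, rel=1e-9, abs=1e-12)
        assert f.pNN20 >= f.pNN50
        assert f.NN50 <= len(nni.nni) - 1

    def test_scaling_property(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(600.0, 1100.0, size=12)
        c = 1.5
        f = ecg_features(nni_series(vals), hr_series([70.0] * 5), WIDE, BASE)
        g = ecg_features(nni_series(c * vals), hr_series([70.0] * 5), WIDE, BASE)
        for name in ("avNN", "sdNN", "rMSSD"):
            assert getattr(g, name) == pytest.approx(c * getattr(f, name), rel=1e-9)

    def test_nni_plausibility_filter(self):
        peaks = np.array([0.0, 0.8, 0.9, 1.7, 4.5, 5.3])  # 100 ms and 2800 ms excluded
        series = NNISeries.from_peaks(peaks)
        np.testing.assert_allclose(series.nni, [800.0, 800.0, 800.0])
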