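import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capbio.ecg import (DetectionCounts, PreprocessConfig, RPeakTrain,
                        compute_rri, detect_rpeaks, detection_metrics,
                        estimate_threshold, full_detection, match_beats,
                        preprocess_ecg, round_display)
from capbio.signal_core import SignalError, TimeSeries

FS = 10_000.0


def _naive_chain(x, fs, cfg=PreprocessConfig()):
    """Independent sample-by-sample implementation of the preprocessing."""
    from scipy.signal import butter

    w = round(cfg.ma_window * fs)
    ma = np.empty_like(x)
    for n in range(x.size):  # centered moving average, truncated edges
        a = max(0, n - w // 2)
        b = min(x.size, a + w)
        ma[n] = np.mean(x[a:b])
    b_coef, a_coef = butter(cfg.filter_order, cfg.band, btype="bandpass", fs=fs)

    def direct_form(sig):
        y = np.zeros_like(sig)
        xs = np.zeros(len(b_coef))
        ys = np.zeros(len(a_coef) - 1)
        for n, v in enumerate(sig):
            xs = np.r_[v, xs[:-1]]
            y[n] = np.dot(b_coef, xs) - np.dot(a_coef[1:], ys)
            ys = np.r_[y[n], ys[:-1]]
        return y

    y = direct_form(ma)
    y = direct_form(y[::-1])[::-1]  # forward-backward = zero phase
    d = round(cfg.diff_interval * fs)
    out = np.zeros_like(y)
    out[d:] = y[d:] - y[:-d]
    return out


class TestPreprocess:
    def test_constant_input_gives_zero_output(self):
        ts = TimeSeries(np.full(20_000, 0.5), FS)
        out = preprocess_ecg(ts)
        assert np.max(np.abs(out.samples)) < 1e-9

    def test_passband_sinusoid_matches_naive_chain(self):
        fs = 500.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 15.0 * t)
        out = preprocess_ecg(TimeSeries(x, fs)).samples
        oracle = _naive_chain(x, fs)
        sl = slice(int(fs), int(3 * fs))  # central section, away from edges
        ratio = np.sqrt(np.mean(out[sl] ** 2) / np.mean(oracle[sl] ** 2))
        assert 10 ** (-3 / 20) < ratio < 10 ** (3 / 20)

    def test_out_of_band_sinusoid_attenuated(self):
        fs = 2000.0
        t = np.arange(int(8 * fs)) / fs
        sl = slice(int(2 * fs), int(6 * fs))

        def gain(f):
            out = preprocess_ecg(TimeSeries(np.sin(2 * np.pi * f * t), fs))
            return np.sqrt(np.mean(out.samples[sl] ** 2))

        assert gain(50.0) < gain(15.0) * 10 ** (-20 / 20)

    def test_band_outside_nyquist_rejected(self):
        ts = TimeSeries(np.zeros(1000), fs=30.0)
        with pytest.raises(SignalError):
            preprocess_ecg(ts, PreprocessConfig(band=(10.0, 20.0)))


def _spike_train(amps, spacing=1.0, fs=250.0, polarity=1.0):
    """Triangular spikes of given amplitudes, well separated."""
    n = int((len(amps) + 1) * spacing * fs)
    x = np.zeros(n)
    for k, a in enumerate(amps):
        i = int((k + 1) * spacing * fs)
        x[i - 2:i + 3] += polarity * a * np.array([0.3, 0.7, 1.0, 0.7, 0.3])
    return TimeSeries(x, fs)


class TestThreshold:
    def test_five_equal_negative_extrema(self):
        ts = _spike_train([1.0] * 5, polarity=-1.0)
        thr = estimate_threshold(ts)
        assert thr == pytest.approx(-0.8)

    def test_largest_mode_arithmetic(self):
        ts = _spike_train([1.0, 2.0, 3.0, 4.0, 5.0])
        thr = estimate_threshold(ts, n_waves=5, mode="largest")
        assert thr == pytest.approx(0.8 * 3.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_mode_threshold_detects_all_truth_beats(
            self, clean_ecg_session, seed):
        _, cecg, truth = clean_ecg_session
        train = full_detection(cecg, mode="random", seed=seed)
        counts = match_beats(train, truth)
        assert counts.n_fp == 0 and counts.n_fn == 0

    def test_too_few_candidates_rejected(self):
        ts = _spike_train([1.0, 2.0])
        with pytest.raises(SignalError):
            estimate_threshold(ts, n_waves=5)


class TestDetect:
    def test_no_crossing_gives_empty_train(self):
        ts = TimeSeries(np.zeros(1000), fs=100.0)
        assert len(detect_rpeaks(ts, threshold=0.5)) == 0

    def test_refractory_suppresses_close_crossings(self):
        fs = 1000.0
        x = np.zeros(2000)
        x[500:510] = 1.0
        x[600:610] = 0.8  # 0.1 s later
        train = detect_rpeaks(TimeSeries(x, fs), 0.5, refractory=0.25)
        assert len(train) == 1
        assert train.times[0] == pytest.approx(0.5, abs=0.01)

    def test_clean_synthetic_detection_count_exact(self, clean_ecg_session):
        _, cecg, truth = clean_ecg_session
        train = full_detection(cecg)
        assert len(train) == len(truth)
        # constant preprocessing delay cancels in RRI space; raw offsets small
        offsets = train.times - truth.times
        assert np.std(offsets) < 0.002

    def test_detection_invariant_to_gain_scaling(self, clean_ecg_session):
        _, cecg, _ = clean_ecg_session
        scaled = cecg.with_samples(cecg.samples * 10.0)
        t1 = full_detection(cecg)
        t2 = full_detection(scaled)
        assert np.array_equal(t1.times, t2.times)


class TestRRI:
    def test_unit_intervals(self):
        rri = compute_rri(RPeakTrain(np.array([1.0, 2.0, 3.0])))
        assert np.allclose(rri.intervals, [1.0, 1.0])
        assert np.allclose(rri.times, [2.0, 3.0])

    def test_single_beat_gives_empty_series(self):
        assert len(compute_rri(RPeakTrain(np.array([1.0])))) == 0

    def test_constant_hr_session_intervals(self):
        from capbio import synthetic as syn
        cfg = syn.ECGSimConfig(mean_hr=60.0, rr_sd=0.0, seed=0)
        beats = syn.simulate_rr_series(cfg, 30.0)
        rri = compute_rri(RPeakTrain(beats))
        assert np.allclose(rri.intervals, 1.0, atol=1e-4)


class TestMatchBeats:
    def test_identity_yields_k_minus_one_tp(self):
        t = RPeakTrain(np.arange(1.0, 11.0))
        c = match_beats(t, t)
        assert (c.n_tp, c.n_fp, c.n_fn) == (9, 0, 0)

    def test_empty_test_train_all_fn(self):
        ref = RPeakTrain(np.arange(1.0, 8.0))
        c = match_beats(RPeakTrain(np.empty(0)), ref)
        assert (c.n_tp, c.n_fp, c.n_fn) == (0, 0, 6)

    def test_single_shifted_beat_costs_two_fp_two_fn(self):
        ref = RPeakTrain(np.arange(1.0, 11.0))
        shifted = np.arange(1.0, 11.0)
        shifted[5] += 0.020  # both adjacent RRIs violate the ±10 ms rule
        c = match_beats(RPeakTrain(shifted), ref)
        assert (c.n_tp, c.n_fp, c.n_fn) == (7, 2, 2)

    def test_shift_within_tolerance_keeps_all_tp(self):
        ref = RPeakTrain(np.arange(1.0, 11.0))
        shifted = np.arange(1.0, 11.0)
        shifted[5] += 0.008
        c = match_beats(RPeakTrain(shifted), ref)
        assert (c.n_tp, c.n_fp, c.n_fn) == (9, 0, 0)

    @given(st.lists(st.floats(0.4, 1.6), min_size=0, max_size=30),
           st.lists(st.floats(0.4, 1.6), min_size=0, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_counts_conserve_rri_bearing_beats(self, rr_test, rr_ref):
        test = RPeakTrain(np.cumsum(rr_test))
        ref = RPeakTrain(np.cumsum(rr_ref))
        c = match_beats(test, ref)
        assert c.n_tp + c.n_fp == max(len(test) - 1, 0)
        assert c.n_tp + c.n_fn == max(len(ref) - 1, 0)

    def test_identity_is_perfect_for_any_train(self, rng):
        for _ in range(20):
            times = np.cumsum(rng.uniform(0.4, 1.5, size=rng.integers(2, 60)))
            t = RPeakTrain(times)
            c = match_beats(t, t)
            assert c.n_fp == 0 and c.n_fn == 0


class TestMetrics:
    def test_worst_case_subject_counts(self):
        m = detection_metrics(DetectionCounts(39, 154, 79)).rounded()
        assert (m.p_sns, m.p_acc, m.p_ppv) == (33.1, 14.3, 20.2)

    def test_perfect_detection(self):
        m = detection_metrics(DetectionCounts(163, 0, 0))
        assert (m.p_sns, m.p_acc, m.p_ppv) == (100.0, 100.0, 100.0)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = detection_metrics(DetectionCounts(0, 0, 5))
        assert m.p_sns == 0.0 and m.p_acc == 0.0 and m.p_ppv is None

    def test_display_rounding_half_away_from_zero(self):
        assert round_display(87.4625, 1) == 87.5
        assert round_display(33.05, 1) == 33.1
        assert round_display(-0.05, 1) == -0.1

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None)
    def test_accuracy_never_exceeds_sns_or_ppv(self, tp, fp, fn):
        m = detection_metrics(DetectionCounts(tp, fp, fn))
        if m.p_acc is not None:
            if m.p_sns is not None:
                assert m.p_acc <= m.p_sns + 1e-9
            if m.p_ppv is not None:
                assert m.p_acc <= m.p_ppv + 1e-9
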