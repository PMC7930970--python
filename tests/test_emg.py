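import numpy as np
import pytest

from capbio.emg import (CoughCycleSegment, EMGPreprocessConfig,
                        SegmentSelectionConfig, amplitude_spectrum,
                        compare_tsa, cough_tsa_analysis, envelope_stats,
                        extend_segments, locate_cough_segment, mean_duration,
                        preprocess_emg, select_resting_segments,
                        total_spectral_amplitude)
from capbio.signal_core import SignalError, TimeSeries

FS = 10_000.0


class TestPreprocess:
    def test_dc_removed(self):
        out = preprocess_emg(TimeSeries(np.ones(20_000), FS))
        assert np.max(np.abs(out.samples[1000:-1000])) < 1e-6

    @pytest.mark.parametrize("f,passes", [(100.0, True), (10.0, False)])
    def test_band_selectivity(self, f, passes):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * f * t)
        out = preprocess_emg(TimeSeries(x, FS)).samples
        sl = slice(int(FS), int(3 * FS))
        rms = np.sqrt(np.mean(out[sl] ** 2))
        ref = 1 / np.sqrt(2)
        if passes:
            assert rms > ref * 10 ** (-3 / 20)
        else:
            assert rms < ref * 10 ** (-20 / 20)


class TestSegmentLocation:
    def test_recovers_cycle_boundaries(self, cough_session):
        sess = cough_session
        cfg = SegmentSelectionConfig()
        emg = preprocess_emg(sess.emg_ref)
        stats = envelope_stats(emg, (0.0, 120.0), cfg)
        for i, (stamp, truth) in enumerate(zip(
                sess.annotations.times("two_cough"),
                sess.truth_cycle_windows)):
            seg = locate_cough_segment(emg, stamp, cfg, stats, i)
            assert abs(seg.start - truth[0]) <= cfg.envelope_window
            assert abs(seg.end - truth[1]) <= cfg.envelope_window

    def test_stamp_in_silent_rest_errors(self, cough_session):
        sess = cough_session
        cfg = SegmentSelectionConfig()
        emg = preprocess_emg(sess.emg_ref)
        stats = envelope_stats(emg, (0.0, 120.0), cfg)
        with pytest.raises(SignalError):
            locate_cough_segment(emg, 30.0, cfg, stats)

    def test_two_bursts_merge_into_one_segment(self):
        fs = 2000.0
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1e-5, int(30 * fs))
        for start in (20.0, 20.7):  # 0.3 s gap between 0.4 s bursts
            i = int(start * fs)
            x[i:i + int(0.4 * fs)] += rng.normal(0, 2e-4, int(0.4 * fs))
        ts = TimeSeries(x, fs)
        cfg = SegmentSelectionConfig(merge_span=0.5)
        stats = envelope_stats(ts, (0.0, 15.0), cfg)
        seg = locate_cough_segment(ts, 20.8, cfg, stats)
        assert seg.start == pytest.approx(20.0, abs=0.1)
        assert seg.end == pytest.approx(21.1, abs=0.1)


class TestDurations:
    def test_interior_mean(self):
        durs = [2.0, 2.2, 1.8, 2.1, 1.9, 2.0, 2.3]
        segs = [CoughCycleSegment(10.0 * i, 10.0 * i + d, i)
                for i, d in enumerate(durs)]
        assert mean_duration(segs) == pytest.approx(2.0)

    def test_equal_durations(self):
        segs = [CoughCycleSegment(5.0 * i, 5.0 * i + 1.5, i) for i in range(5)]
        assert mean_duration(segs) == pytest.approx(1.5)

    def test_too_few_segments_with_exclusion(self):
        segs = [CoughCycleSegment(0.0, 1.0), CoughCycleSegment(5.0, 6.0, 1)]
        with pytest.raises(SignalError):
            mean_duration(segs)


class TestExtension:
    def test_window_arithmetic(self):
        segs = [CoughCycleSegment(0.0, 1.0, 0),
                CoughCycleSegment(99.0, 101.0, 1),
                CoughCycleSegment(200.0, 201.0, 2)]
        out = extend_segments(segs, md=2.0, cfg=SegmentSelectionConfig())
        assert out == [(pytest.approx(98.8), pytest.approx(101.2))]

    def test_factor_one_equals_detected_segments(self):
        segs = [CoughCycleSegment(10.0 * i, 10.0 * i + 2.0, i)
                for i in range(5)]
        cfg = SegmentSelectionConfig(extension_factor=1.0)
        out = extend_segments(segs, md=2.0, cfg=cfg)
        for (a, b), s in zip(out, segs[1:-1]):
            assert a == pytest.approx(s.start) and b == pytest.approx(s.end)

    def test_seven_cycles_give_five_coughing_segments(self):
        segs = [CoughCycleSegment(10.0 * i, 10.0 * i + 2.0, i)
                for i in range(7)]
        assert len(extend_segments(segs, 2.0, SegmentSelectionConfig())) == 5

    def test_clipped_window_errors(self):
        segs = [CoughCycleSegment(float(i), i + 1.0, i) for i in range(3)]
        with pytest.raises(SignalError):
            extend_segments(segs, 10.0, SegmentSelectionConfig(),
                            record_span=(0.0, 5.0))


class TestRestingSelection:
    def test_silent_rest_returns_first_tiles(self):
        rng = np.random.default_rng(1)
        rest = TimeSeries(rng.normal(0, 1e-5, int(60 * 2000)), 2000.0)
        cfg = SegmentSelectionConfig()
        out = select_resting_segments(rest, 1.5, 5, cfg)
        assert out == [(pytest.approx(1.5 * i), pytest.approx(1.5 * (i + 1)))
                       for i in range(5)]

    def test_tiles_overlapping_injected_burst_are_skipped(self):
        rng = np.random.default_rng(2)
        fs = 2000.0
        x = rng.normal(0, 1e-5, int(60 * fs))
        x[int(2.0 * fs):int(2.4 * fs)] += rng.normal(0, 2e-4, int(0.4 * fs))
        rest = TimeSeries(x, fs)
        out = select_resting_segments(rest, 1.5, 5, SegmentSelectionConfig())
        burst_tile = (1.5, 3.0)
        assert burst_tile not in [(round(a, 6), round(b, 6)) for a, b in out]
        assert len(out) == 5

    def test_duration_longer_than_rest_errors(self):
        rest = TimeSeries(np.zeros(1000), 100.0)
        with pytest.raises(SignalError):
            select_resting_segments(rest, 20.0, 5, SegmentSelectionConfig())


class TestSpectrum:
    def test_unit_sinusoid_amplitude_one_at_its_bin(self):
        fs, f, n = 2000.0, 100.0, 2000  # integer number of periods
        t = np.arange(n) / fs
        freqs, amps = amplitude_spectrum(np.sin(2 * np.pi * f * t), fs)
        k = np.argmin(np.abs(freqs - f))
        assert amps[k] == pytest.approx(1.0, rel=1e-9)
        others = np.delete(amps, k)
        assert np.max(others) < 1e-9

    def test_zero_signal_zero_spectrum(self):
        _, amps = amplitude_spectrum(np.zeros(1024), 1000.0)
        assert np.all(amps == 0)

    @pytest.mark.parametrize("n", [1024, 1001])
    def test_parseval_energy_identity(self, rng, n):
        x = rng.normal(size=n)
        _, amps = amplitude_spectrum(x, 1000.0)
        energy = amps[0] ** 2 + np.sum(amps[1:] ** 2) / 2
        if n % 2 == 0:
            energy += amps[-1] ** 2 / 2  # Nyquist bin is not split
        assert energy == pytest.approx(np.mean(x ** 2), rel=1e-9)


class TestTSA:
    def test_in_band_sinusoid_tsa_equals_amplitude(self):
        fs, n = 2000.0, 2000
        t = np.arange(n) / fs
        freqs, amps = amplitude_spectrum(0.3 * np.sin(2 * np.pi * 100 * t), fs)
        assert total_spectral_amplitude(freqs, amps) == pytest.approx(0.3, rel=1e-6)

    def test_out_of_band_sinusoid_tsa_near_zero(self):
        fs, n = 2000.0, 2000
        t = np.arange(n) / fs
        freqs, amps = amplitude_spectrum(np.sin(2 * np.pi * 20 * t), fs)
        assert total_spectral_amplitude(freqs, amps) < 1e-9

    def test_band_partition_additivity(self, rng):
        freqs, amps = amplitude_spectrum(rng.normal(size=4096), 2000.0)
        whole = total_spectral_amplitude(freqs, amps, 40.0, 500.0)
        left = total_spectral_amplitude(freqs, amps, 40.0, 200.0)
        right = total_spectral_amplitude(freqs, amps,
                                         np.nextafter(200.0, np.inf), 500.0)
        assert whole == pytest.approx(left + right, rel=1e-12)


class TestComparison:
    def test_identical_groups_not_significant(self):
        vals = np.array([1.0, 1.2, 0.9, 1.1, 1.05])
        res = compare_tsa(vals, vals)
        assert res.p_value is None or res.p_value >= 0.05
        assert res.direction == "none"

    def test_swapping_groups_flips_direction(self, rng):
        rest = rng.uniform(1.0, 1.2, 5)
        cough = rest + rng.uniform(1.0, 2.0, 5)
        fwd = compare_tsa(rest, cough)
        rev = compare_tsa(cough, rest)
        assert fwd.direction == "coughing>resting"
        assert rev.direction == "resting>coughing"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SignalError):
            compare_tsa(np.ones(4), np.ones(5))


class TestEndToEnd:
    def test_cough_tsa_pipeline_on_synthetic_session(self, cough_session):
        sess = cough_session
        summary, comparison, detail = cough_tsa_analysis(
            sess.cemg, sess.annotations.times("two_cough"), (0.0, 120.0),
            boundary_channel=sess.emg_ref)
        assert len(summary.cough_tsas) == 5  # 7 cycles minus first and last
        assert len(summary.rest_tsas) == 5
        assert summary.mean_cough > summary.mean_rest
        assert comparison.direction == "coughing>resting"
        assert comparison.p_value < 0.05
        md = detail["mean_duration"]
        for a, b in detail["cough_windows"]:
            assert (b - a) == pytest.approx(1.2 * md, rel=1e-9)
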