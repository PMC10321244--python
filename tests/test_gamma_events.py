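import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from gammaloop import gamma_events, synth_data
from gammaloop.gamma_events import (
    BaselineStats,
    DegenerateBaselineError,
    DetectorConfig,
)
from gammaloop.lfp_io import ChannelMeta, Recording
from gammaloop.spectral import BandPowerSeries


def tiled_series(values, window_s=0.05):
    values = np.asarray(values, dtype=float)
    times = (np.arange(values.size) + 0.5) * window_s
    return BandPowerSeries(times_s=times, rms=values, window_s=window_s, step_s=window_s)


class TestPreprocess:
    def test_20khz_down_to_1250(self):
        rec = Recording(
            samples=np.random.default_rng(0).standard_normal((1, 20000 * 2)),
            sampling_rate_hz=20000.0,
            channels=[ChannelMeta("c")],
            gain_volts_per_count=1.0,
        )
        out = gamma_events.preprocess(rec, 1250.0)
        assert out.sampling_rate_hz == 1250.0
        assert out.n_samples == rec.n_samples // 16

    def test_identity_when_already_at_target(self):
        rec = Recording(
            samples=np.zeros((1, 100)),
            sampling_rate_hz=1250.0,
            channels=[ChannelMeta("c")],
            gain_volts_per_count=1.0,
        )
        assert gamma_events.preprocess(rec, 1250.0) is rec

    def test_sine_amplitude_preserved(self):
        fs = 20000.0
        t = np.arange(int(4 * fs)) / fs
        rec = Recording(
            samples=np.sin(2 * np.pi * 50 * t)[None, :],
            sampling_rate_hz=fs,
            channels=[ChannelMeta("c")],
            gain_volts_per_count=1.0,
        )
        out = gamma_events.preprocess(rec, 1250.0)
        interior = out.samples[0][100:-100]
        assert np.sqrt(2 * np.mean(interior**2)) == pytest.approx(1.0, rel=0.01)

    def test_rational_factor_resampling(self):
        rec = Recording(
            samples=np.zeros((1, 12500)),
            sampling_rate_hz=1250.0,
            channels=[ChannelMeta("c")],
            gain_volts_per_count=1.0,
        )
        out = gamma_events.preprocess(rec, 500.0)  # factor 2.5
        assert out.sampling_rate_hz == 500.0
        assert out.n_samples == 5000

    def test_upsampling_refused(self):
        rec = Recording(
            samples=np.zeros((1, 100)),
            sampling_rate_hz=500.0,
            channels=[ChannelMeta("c")],
            gain_volts_per_count=1.0,
        )
        with pytest.raises(ValueError):
            gamma_events.preprocess(rec, 1250.0)


class TestZeroPhaseFilter:
    def test_cross_correlation_peaks_at_lag_zero(self):
        fs = 1250.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 50 * t) * np.hanning(t.size)
        y = gamma_events.band_filter_zero_phase(x, fs)
        xc = np.correlate(y, x, mode="full")
        assert np.argmax(xc) - (x.size - 1) == 0

    def test_stop_band_attenuation(self):
        fs = 1250.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        y = gamma_events.band_filter_zero_phase(x, fs)
        assert np.sqrt(np.mean(y**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_impulse_response_time_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = gamma_events.band_filter_zero_phase(x, 1250.0)
        np.testing.assert_allclose(y, y[::-1], atol=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gamma_events.band_filter_zero_phase(np.zeros(100), 100.0, band_hz=(30.0, 80.0))


class TestSlidingRMS:
    def test_zero_signal(self):
        series = gamma_events.sliding_rms(np.zeros(1000), 1250.0)
        assert not series.rms.any()

    def test_unit_sine_windows_near_invsqrt2(self):
        fs = 1250.0
        t = np.arange(int(2 * fs)) / fs
        series = gamma_events.sliding_rms(np.sin(2 * np.pi * 50 * t), fs)
        np.testing.assert_allclose(series.rms, 1 / np.sqrt(2), rtol=0.02)

    def test_matches_naive_oracle_on_silence_then_sine(self):
        fs = 1000.0
        x = np.concatenate([np.zeros(1000), np.sin(2 * np.pi * 40 * np.arange(1000) / fs)])
        series = gamma_events.sliding_rms(x, fs, window_s=0.05, step_s=0.02)
        expected = oracles.windowed_rms(x, win=50, step=20)
        np.testing.assert_allclose(series.rms, expected, rtol=1e-9)
        # monotone step upward at the junction
        idx = np.searchsorted(series.times_s, 1.0)
        assert series.rms[idx - 2] < series.rms[idx + 2]

    def test_signal_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            gamma_events.sliding_rms(np.zeros(10), 1250.0, window_s=0.05)


class TestBaselineStats:
    def test_constant_series(self):
        stats = gamma_events.baseline_stats(tiled_series(np.full(50, 3.0)))
        assert stats.mean_rms == 3.0
        assert stats.sd_rms == 0.0
        assert stats.n_windows_used == stats.n_windows_total == 50

    def test_outliers_discarded(self):
        values = np.concatenate([np.ones(1000), np.full(10, 100.0)])
        stats = gamma_events.baseline_stats(tiled_series(values), outlier_k=4.0)
        assert stats.n_windows_used == 1000
        assert stats.mean_rms == pytest.approx(1.0)

    def test_no_op_trim_equals_untrimmed(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1.0, 2.0, 200)  # bounded: nothing beyond 4 SD
        stats = gamma_events.baseline_stats(tiled_series(values), outlier_k=4.0)
        assert stats.n_windows_used == 200
        assert stats.mean_rms == pytest.approx(values.mean())
        assert stats.sd_rms == pytest.approx(values.std())

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            gamma_events.baseline_stats(tiled_series(np.ones(5)))


class TestDetectEvents:
    def test_all_zero_series_no_events(self):
        base = BaselineStats(mean_rms=0.5, sd_rms=0.1, n_windows_total=100, n_windows_used=100)
        table = gamma_events.detect_events(tiled_series(np.zeros(100)), base)
        assert len(table) == 0

    def test_degenerate_baseline_rejected(self):
        base = BaselineStats(mean_rms=1.0, sd_rms=0.0, n_windows_total=100, n_windows_used=100)
        with pytest.raises(DegenerateBaselineError):
            gamma_events.detect_events(tiled_series(np.ones(100)), base)

    def test_amplitude_floor_rescues_degenerate_baseline(self):
        base = BaselineStats(mean_rms=1.0, sd_rms=0.0, n_windows_total=100, n_windows_used=100)
        cfg = DetectorConfig(amplitude_floor=2.0)
        values = np.ones(100)
        values[40:45] = 5.0
        table = gamma_events.detect_events(tiled_series(values), base, cfg)
        assert len(table) == 1

    def test_single_injected_burst_recovered(self, synth_rec_truth):
        rec, truth = synth_rec_truth
        cfg = truth.config
        burst = synth_data.BurstSpec(
            onset_s=30.0, duration_s=0.3, freq_hz=60.0, amplitude=10 * 0.35
        )
        rec1, _ = synth_data.generate_recording(
            synth_data.SynthConfig(duration_s=60.0, seed=21, artifact_rate_hz=0.0),
            bursts=[burst],
        )
        table, _, _ = gamma_events.detect_recording(rec1, "OB")
        assert len(table) == 1
        event = table.events[0]
        assert abs(event.onset_s - 30.0) <= 2 * 0.05
        assert abs(event.offset_s - 30.3) <= 2 * 0.05

    def test_two_separated_bursts_two_events(self):
        cfg = synth_data.SynthConfig(duration_s=60.0, seed=22, artifact_rate_hz=0.0)
        sigma = 0.35
        bursts = [
            synth_data.BurstSpec(onset_s=20.0, duration_s=0.3, freq_hz=55.0, amplitude=10 * sigma),
            synth_data.BurstSpec(onset_s=21.3, duration_s=0.3, freq_hz=65.0, amplitude=10 * sigma),
        ]
        rec, _ = synth_data.generate_recording(cfg, bursts=bursts)
        table, _, _ = gamma_events.detect_recording(rec, "OB")
        assert len(table) == 2
        first, second = table.events
        assert first.offset_s < second.onset_s

    def test_event_fields_consistent(self, synth_rec_truth):
        rec, _ = synth_rec_truth
        table, _, _ = gamma_events.detect_recording(rec, "OB")
        cfg = DetectorConfig()
        # realized step: 50 ms quantized to whole samples at 1250 Hz
        step_real = round(cfg.step_s * cfg.target_rate_hz) / cfg.target_rate_hz
        for e in table.events:
            assert e.offset_s - e.onset_s >= cfg.min_consecutive * step_real - 1e-9
            assert e.peak_rms >= e.mean_rms > 0


class TestDetectorProperties:
    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_on_random_series(self, data):
        """Vectorized detection equals brute-force threshold-run enumeration."""
        n = data.draw(st.integers(30, 400))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        values = np.abs(rng.standard_normal(n)) + rng.choice(
            [0.0, 4.0], size=n, p=[0.9, 0.1]
        )
        mean, sd = float(values.mean()), float(values.std() or 1.0)
        min_consec = data.draw(st.integers(1, 4))
        core_k = data.draw(st.floats(0.5, 3.0))
        boundary_k = core_k - data.draw(st.floats(0.1, 1.5))
        cfg = DetectorConfig(core_k=core_k, boundary_k=boundary_k, min_consecutive=min_consec)
        base = BaselineStats(mean, sd, n, n)
        table = gamma_events.detect_events(tiled_series(values), base, cfg)
        expected = oracles.threshold_run_events(
            values, mean, sd, core_k, boundary_k, min_consec
        )
        assert oracles.events_to_spans(table, 0.05, 0.05) == expected

    def test_raising_core_k_never_increases_event_count(self):
        rng = np.random.default_rng(7)
        values = np.abs(rng.standard_normal(500)) + rng.choice([0, 5], 500, p=[0.92, 0.08])
        base = BaselineStats(float(values.mean()), float(values.std()), 500, 500)
        counts = []
        for core_k in (1.5, 2.0, 2.5, 3.0, 4.0):
            cfg = DetectorConfig(core_k=core_k, boundary_k=1.0)
            counts.append(len(gamma_events.detect_events(tiled_series(values), base, cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_lowering_boundary_k_never_shortens_events(self):
        rng = np.random.default_rng(8)
        values = np.abs(rng.standard_normal(500)) + rng.choice([0, 5], 500, p=[0.92, 0.08])
        base = BaselineStats(float(values.mean()), float(values.std()), 500, 500)
        hi = gamma_events.detect_events(
            tiled_series(values), base, DetectorConfig(boundary_k=2.5)
        )
        lo = gamma_events.detect_events(
            tiled_series(values), base, DetectorConfig(boundary_k=1.0)
        )
        # every high-boundary event is contained in some low-boundary event
        for e in hi.events:
            assert any(
                f.onset_s <= e.onset_s and f.offset_s >= e.offset_s for f in lo.events
            )

    def test_scale_equivariance(self):
        cfg = synth_data.SynthConfig(duration_s=60.0, seed=23, artifact_rate_hz=0.0)
        rec, _ = synth_data.generate_recording(cfg)
        table1, _, _ = gamma_events.detect_recording(rec, "OB")
        scaled = Recording(
            samples=rec.samples * 3.0,
            sampling_rate_hz=rec.sampling_rate_hz,
            channels=list(rec.channels),
            gain_volts_per_count=rec.gain_volts_per_count,
        )
        table2, _, _ = gamma_events.detect_recording(scaled, "OB")
        assert len(table1) == len(table2) > 0
        for e1, e2 in zip(table1.events, table2.events):
            assert e1.onset_s == pytest.approx(e2.onset_s, abs=1e-9)
            assert e1.offset_s == pytest.approx(e2.offset_s, abs=1e-9)
            assert e2.peak_rms == pytest.approx(3.0 * e1.peak_rms, rel=1e-9)


class TestSummarizeEvents:
    def make_table(self, onsets, peaks):
        from gammaloop.lfp_io import EventTable, GammaEvent

        return EventTable(
            events=[
                GammaEvent(o, o + 0.2, peak_rms=p, mean_rms=p / 2) for o, p in zip(onsets, peaks)
            ]
        )

    def test_incidence_count_over_masked_minutes(self):
        table = self.make_table([10, 20, 30, 70, 80, 90], [1] * 6)
        median, incidence = gamma_events.summarize_events(
            table, [(0.0, 60.0), (60.0, 180.0)], 200.0
        )
        assert incidence == pytest.approx(6 / 3.0)

    def test_median_peak(self):
        table = self.make_table([1, 2, 3], [1.0, 2.0, 9.0])
        median, _ = gamma_events.summarize_events(table, [(0.0, 60.0)], 100.0)
        assert median == 2.0

    def test_mask_excluding_all_events(self):
        table = self.make_table([1, 2], [1.0, 2.0])
        median, incidence = gamma_events.summarize_events(table, [(30.0, 90.0)], 100.0)
        assert incidence == 0.0
        assert median is None

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            gamma_events.summarize_events(self.make_table([1], [1.0]), [], 100.0)

    def test_overlapping_mask_rejected(self):
        with pytest.raises(ValueError):
            gamma_events.summarize_events(
                self.make_table([1], [1.0]), [(0.0, 50.0), (40.0, 90.0)], 100.0
            )


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(core_k=2.0, boundary_k=2.5)
    with pytest.raises(ValueError):
        DetectorConfig(min_consecutive=0)
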