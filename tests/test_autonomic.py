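"""ECG filtering, R-peak detection, NN cleaning, HRV metrics, EDA/RSP."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from pupilclust.autonomic import (
    NNSeries, filter_ecg, detect_r_peaks, clean_nn, hrv_time, hrv_freq,
    segment_hrv, scr_metrics, rsp_metrics, slice_nn, total_power,
)
from pupilclust.synthetic import rr_series, render_ecg, default_archetypes

FS = 250.0


def hrv_time_oracle(nn_ms):
    """Independent one-line recomputation of the time-domain metrics."""
    nn = np.asarray(nn_ms, dtype=float)
    return (nn.mean(), nn.std(ddof=1), np.sqrt(np.mean(np.diff(nn) ** 2)))


class TestFilterECG:
    def test_dc_offset_removed(self):
        out = filter_ecg(np.full(2500, 3.7), FS)
        assert np.abs(out[200:-200]).max() < 1e-6

    def test_50hz_attenuated(self):
        # steady-state interior: the narrow notch has a long edge transient
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 50 * t)
        out = filter_ecg(x, FS)
        core = out[int(10 * FS):-int(10 * FS)]
        assert np.sqrt(np.mean(core**2)) < 0.05 * np.sqrt(0.5)

    def test_10hz_passband_preserved(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        out = filter_ecg(x, FS)
        rms_in = np.sqrt(np.mean(x[250:-250] ** 2))
        rms_out = np.sqrt(np.mean(out[250:-250] ** 2))
        assert abs(rms_out - rms_in) < 0.05 * rms_in

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            filter_ecg(np.zeros(1000), fs=80.0)


class TestDetectRPeaks:
    def test_flat_signal_no_peaks(self):
        nn = detect_r_peaks(np.zeros(2500), FS)
        assert len(nn.peak_times_s) == 0

    def test_two_beats_one_second_apart(self):
        sig, _ = render_ecg(np.array([1000.0]), fs=FS)
        nn = detect_r_peaks(filter_ecg(sig, FS), FS)
        assert len(nn.peak_times_s) == 2
        assert nn.nn_ms[0] == pytest.approx(1000.0, abs=2 / FS * 1000)

    def test_precision_recall_at_20db(self, rng):
        arch = default_archetypes()[0]
        rr = rr_series(arch, 300, rng)
        sig, truth = render_ecg(rr, fs=FS)
        snr_noise_sd = np.sqrt(np.mean(sig**2)) / 10**(20 / 20)
        noisy = sig + rng.normal(0, snr_noise_sd, size=len(sig))
        nn = detect_r_peaks(filter_ecg(noisy, FS), FS)
        det = np.round(nn.peak_times_s * FS).astype(int)
        tol = int(0.05 * FS)
        recall = np.mean([np.min(np.abs(det - t)) <= tol for t in truth])
        precision = np.mean([np.min(np.abs(truth - d)) <= tol for d in det])
        assert recall >= 0.99 and precision >= 0.99

    def test_refractory_suppresses_close_duplicates(self):
        # two templates 100 ms apart: only the larger survives
        t = np.arange(0, 2, 1 / FS)
        sig = (np.exp(-0.5 * ((t - 1.0) / 0.012) ** 2)
               + 0.6 * np.exp(-0.5 * ((t - 1.1) / 0.012) ** 2))
        nn = detect_r_peaks(sig, FS)
        assert len(nn.peak_times_s) == 1
        assert nn.peak_times_s[0] == pytest.approx(1.0, abs=0.02)


class TestCleanNN:
    def test_clean_series_nothing_flagged(self, rng):
        nn = NNSeries.from_peak_times(np.cumsum(rng.normal(0.8, 0.01, 100)))
        assert clean_nn(nn).artifact_mask.sum() == 0

    def test_isolated_long_interval_flagged(self):
        nn_ms = np.full(50, 800.0)
        nn_ms[25] = 2000.0
        times = np.concatenate([[0.0], np.cumsum(nn_ms) / 1000.0])
        cleaned = clean_nn(NNSeries.from_peak_times(times))
        assert cleaned.artifact_mask[25]
        assert cleaned.artifact_mask.sum() == 1

    def test_infinite_tolerance_is_identity(self, rng):
        nn = NNSeries.from_peak_times(np.cumsum(rng.uniform(0.5, 1.2, 60)))
        assert clean_nn(nn, rel_tol=np.inf).artifact_mask.sum() == 0

    def test_unusable_segment_rejected(self):
        nn_ms = np.tile([400.0, 1200.0], 25)
        times = np.concatenate([[0.0], np.cumsum(nn_ms) / 1000.0])
        with pytest.raises(ValueError, match="unusable"):
            clean_nn(NNSeries.from_peak_times(times))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            clean_nn(NNSeries.from_peak_times([0.0, 0.8]))


class TestHRVTime:
    def test_hand_checked_values(self):
        nn = NNSeries(np.array([0, .8, 1.61, 2.4, 3.205]),
                      np.array([800.0, 810.0, 790.0, 805.0]),
                      np.zeros(4, dtype=bool))
        mean_nn, sdnn, rmssd = hrv_time(nn)
        assert mean_nn == pytest.approx(801.25)
        assert sdnn == pytest.approx(8.539, abs=1e-3)
        assert rmssd == pytest.approx(15.546, abs=1e-3)

    def test_constant_series_zero_variability(self):
        times = np.arange(10) * 0.85
        mean_nn, sdnn, rmssd = hrv_time(NNSeries.from_peak_times(times))
        assert sdnn == pytest.approx(0.0) and rmssd == pytest.approx(0.0)

    def test_shift_invariance_of_sdnn_rmssd(self, rng):
        nn_ms = rng.uniform(600, 1000, 50)
        mk = lambda x: NNSeries(np.concatenate([[0], np.cumsum(x) / 1000]),
                                x, np.zeros(len(x), dtype=bool))
        _, sd_a, rm_a = hrv_time(mk(nn_ms))
        _, sd_b, rm_b = hrv_time(mk(nn_ms + 200.0))
        assert sd_a == pytest.approx(sd_b) and rm_a == pytest.approx(rm_b)

    def test_matches_oracle_on_random_series(self, rng):
        for _ in range(1000):
            nn_ms = rng.uniform(400, 1400, rng.integers(3, 40))
            nn = NNSeries(np.concatenate([[0], np.cumsum(nn_ms) / 1000]),
                          nn_ms, np.zeros(len(nn_ms), dtype=bool))
            np.testing.assert_allclose(hrv_time(nn), hrv_time_oracle(nn_ms),
                                       rtol=1e-12)

    def test_artifact_exclusion(self):
        nn_ms = np.full(20, 800.0)
        nn_ms[10] = 2000.0
        mask = np.zeros(20, dtype=bool)
        mask[10] = True
        nn = NNSeries(np.concatenate([[0], np.cumsum(nn_ms) / 1000]), nn_ms, mask)
        mean_nn, sdnn, _ = hrv_time(nn)
        assert mean_nn == pytest.approx(800.0) and sdnn == pytest.approx(0.0)


class TestHRVFreq:
    def _nn_from(self, arch, seed=0, jitter=0.0):
        rr = rr_series(arch, 300, np.random.default_rng(seed), jitter_sd_ms=jitter)
        return NNSeries.from_peak_times(0.5 + np.concatenate([[0], np.cumsum(rr) / 1000]))

    def test_hf_only_modulation(self):
        arch = dataclasses.replace(default_archetypes()[0], lf_mod_amp=0.0, hf_mod_amp=25.0)
        lf, hf, _ = hrv_freq(self._nn_from(arch))
        assert hf > 10 * lf

    def test_lf_only_modulation(self):
        arch = dataclasses.replace(default_archetypes()[0], lf_mod_amp=25.0, hf_mod_amp=0.0)
        lf, hf, ratio = hrv_freq(self._nn_from(arch))
        assert ratio > 1

    def test_unmodulated_series_negligible_power(self):
        base = dataclasses.replace(default_archetypes()[0], lf_mod_amp=0.0, hf_mod_amp=0.0)
        mod = dataclasses.replace(default_archetypes()[0], lf_mod_amp=0.0, hf_mod_amp=25.0)
        lf0, hf0, _ = hrv_freq(self._nn_from(base))
        _, hf_ref, _ = hrv_freq(self._nn_from(mod))
        assert hf0 < 1e-8 * hf_ref and lf0 < 1e-8 * hf_ref

    def test_short_segment_missing(self):
        nn = NNSeries.from_peak_times(np.arange(0, 30, 0.8))
        assert np.isnan(hrv_freq(nn)).all()

    def test_total_power_bounds_band_sum(self, rng):
        arch = default_archetypes()[0]
        nn = self._nn_from(arch, seed=3, jitter=20.0)
        lf, hf, _ = hrv_freq(nn)
        assert total_power(nn) >= lf + hf


class TestSegmentHRV:
    def _spans(self, n_levels=3, span_s=70.0):
        return pd.DataFrame({
            "block": [1] * n_levels, "level": list(range(1, n_levels + 1)),
            "t_start_s": np.arange(n_levels) * span_s,
            "t_end_s": (np.arange(n_levels) + 1) * span_s,
        })

    def test_stationary_rr_equal_across_levels(self):
        nn = NNSeries.from_peak_times(np.arange(0, 220, 0.8))
        rows = segment_hrv(nn, self._spans())
        level_means = [m.mean_nn_ms for m in rows if len(m.segment) == 2]
        np.testing.assert_allclose(level_means, 800.0, atol=1e-9)

    def test_archetype_ordering_in_every_window(self):
        arch0, arch1 = default_archetypes()
        rows = {}
        for arch in (arch0, arch1):
            rr = rr_series(arch, 220, np.random.default_rng(0), jitter_sd_ms=0.0)
            nn = NNSeries.from_peak_times(np.concatenate([[0], np.cumsum(rr) / 1000]))
            rows[arch.label] = [m.mean_nn_ms for m in segment_hrv(nn, self._spans())]
        assert all(a > b for a, b in zip(rows[0], rows[1]))

    def test_short_window_time_only(self):
        nn = NNSeries.from_peak_times(np.arange(0, 220, 0.8))
        spans = self._spans(n_levels=1, span_s=40.0)
        (level_row, block_row) = segment_hrv(nn, spans)
        assert np.isfinite(level_row.mean_nn_ms)
        assert np.isnan(level_row.lf_power) and np.isnan(level_row.hf_power)

    def test_empty_window_missing_row(self):
        nn = NNSeries.from_peak_times(np.arange(0, 50, 0.8))
        spans = self._spans(n_levels=2, span_s=100.0)   # second window empty
        rows = segment_hrv(nn, spans)
        assert np.isnan(rows[1].mean_nn_ms)


class TestSCR:
    def test_flat_trace_no_peaks(self):
        count, amp = scr_metrics(np.full(5000, 2.0), fs=50.0)
        assert count == 0

    def test_injected_events_counted(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        sig = np.full_like(t, 2.0)
        for t0 in (10, 30, 50, 70, 90):
            rel = np.maximum(t - t0, 0)
            sig += 0.4 * (1 - np.exp(-rel / 0.3)) * np.exp(-rel / 3.0) * (t >= t0)
        count, amp = scr_metrics(sig, fs)
        assert count == 5
        assert amp > 0.05

    def test_subthreshold_events_ignored(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        sig = np.full_like(t, 2.0)
        for t0 in (20, 60, 100):
            rel = np.maximum(t - t0, 0)
            sig += 0.02 * (1 - np.exp(-rel / 0.3)) * np.exp(-rel / 3.0) * (t >= t0)
        count, _ = scr_metrics(sig, fs)
        assert count == 0


class TestRSP:
    def test_pure_sinusoid_rate_and_symmetry(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        pm = rsp_metrics(np.sin(2 * np.pi * t / 4.0), fs)
        assert pm.rsp_rate_mean_bpm == pytest.approx(15.0, abs=0.2)
        assert pm.rsp_phase_ratio == pytest.approx(1.0, abs=0.05)

    def test_asymmetric_sawtooth_phase_ratio(self):
        from scipy.signal import sawtooth
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        # rise 1 s, fall 3 s within a 4 s cycle
        sig = sawtooth(2 * np.pi * t / 4.0, width=0.25)
        pm = rsp_metrics(sig, fs)
        assert pm.rsp_phase_ratio == pytest.approx(1 / 3, abs=0.1)

    def test_amplitude_peak_to_trough(self):
        fs = 50.0
        t = np.arange(0, 120, 1 / fs)
        pm = rsp_metrics(2.0 * np.sin(2 * np.pi * t / 4.0), fs)
        assert pm.rsp_amp_mean == pytest.approx(4.0, abs=0.1)

    def test_too_few_cycles_missing(self):
        pm = rsp_metrics(np.sin(np.linspace(0, np.pi, 500)), fs=50.0)
        assert np.isnan(pm.rsp_rate_mean_bpm)
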