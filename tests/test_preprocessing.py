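"""R-peak detection, RR/amplitude extraction, artifact cleaning, windowing."""

import numpy as np
import pytest

from apnea_st.errors import ConfigError, SparseBeatsError
from apnea_st.io_formats import ECGRecord, MinuteLabels
from apnea_st.preprocessing import (
    BeatSeries,
    build_windows,
    clean_rr,
    detect_r_peaks,
    extract_beat_series,
    fit_normalization,
    apply_normalization,
    resample_window,
    running_median,
    WindowSet,
)
from apnea_st.synthetic import _qrs_template


def _match(true_times, det_times, tol=0.05):
    used = np.zeros(len(det_times), dtype=bool)
    n = 0
    for bt in true_times:
        d = np.abs(det_times - bt)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] <= tol:
            used[i] = True
            n += 1
    return n


class TestDetectRPeaks:
    def test_recovers_generator_beats(self, sim_record):
        """Noise-free synthetic ECG: sensitivity and PPV >= 0.99 at +/-50 ms."""
        _, truth, ecg = sim_record
        peaks = detect_r_peaks(ecg)
        matched = _match(truth.beat_times, peaks / ecg.fs)
        assert matched / len(truth.beat_times) >= 0.99
        assert matched / len(peaks) >= 0.99

    def test_all_zero_signal_yields_no_peaks(self):
        ecg = ECGRecord("z", 100.0, np.zeros(6000))
        assert len(detect_r_peaks(ecg)) == 0

    def test_single_qrs_template_found_at_argmax(self):
        template = _qrs_template(100.0)
        sig = np.zeros(1000)
        half = len(template) // 2
        sig[500 - half : 500 + half + 1] = template
        peaks = detect_r_peaks(ECGRecord("one", 100.0, sig))
        assert len(peaks) == 1
        assert peaks[0] == int(np.argmax(sig)) == 500

    def test_requires_one_second_of_signal(self):
        with pytest.raises(ValueError):
            detect_r_peaks(ECGRecord("short", 100.0, np.zeros(50)))


class TestExtractBeatSeries:
    def test_constant_spacing(self):
        ecg = ECGRecord("c", 100.0, np.arange(400, dtype=float))
        s = extract_beat_series(ecg, np.array([100, 200, 300]))
        assert np.allclose(s.times, [1.0, 2.0, 3.0])
        assert np.allclose(s.rr, [1.0, 1.0])
        assert np.allclose(s.amp, [100.0, 200.0, 300.0])

    def test_single_peak_degenerate(self):
        ecg = ECGRecord("c", 100.0, np.ones(400))
        s = extract_beat_series(ecg, np.array([42]))
        assert len(s.rr) == 0
        assert len(s.amp) == 1

    def test_rr_equals_pairwise_differences(self):
        rng = np.random.default_rng(3)
        peaks = np.unique(rng.integers(0, 50_000, size=200))
        ecg = ECGRecord("r", 100.0, rng.normal(size=50_000))
        s = extract_beat_series(ecg, peaks)
        assert np.allclose(s.rr, np.diff(peaks) / 100.0)

    def test_non_ascending_peaks_rejected(self):
        ecg = ECGRecord("c", 100.0, np.ones(400))
        with pytest.raises(ValueError):
            extract_beat_series(ecg, np.array([200, 100]))


def _series_from_rr(rr, amp=None):
    times = np.concatenate([[0.0], np.cumsum(rr)])
    amp = np.ones(len(times)) if amp is None else amp
    return BeatSeries(times=times, rr=np.asarray(rr, dtype=float), amp=amp)


class TestCleanRR:
    def test_physiological_series_unchanged(self):
        rng = np.random.default_rng(0)
        rr = rng.uniform(0.78, 0.82, size=100)
        s = _series_from_rr(rr)
        out = clean_rr(s)
        assert np.array_equal(out.rr, rr)
        assert np.array_equal(out.amp, s.amp)

    def test_spike_replaced_by_running_median(self):
        rr = np.full(20, 0.8)
        rr[10] = 3.0
        out = clean_rr(_series_from_rr(rr))
        # independent oracle: median over the raw 5-point neighborhood
        expected = np.median(rr[8:13])
        assert out.rr[10] == expected
        assert np.array_equal(np.delete(out.rr, 10), np.delete(rr, 10))

    def test_amplitude_of_flagged_beat_cleaned(self):
        rr = np.full(20, 0.8)
        rr[10] = 3.0
        amp = np.ones(21)
        amp[11] = 9.0  # rr[10] ends at beat 11
        out = clean_rr(_series_from_rr(rr, amp))
        assert out.amp[11] == np.median(amp[9:14])

    def test_empty_series(self):
        s = BeatSeries(times=np.zeros(0), rr=np.zeros(0), amp=np.zeros(0))
        assert len(clean_rr(s).rr) == 0

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigError):
            clean_rr(_series_from_rr([0.8, 0.8]), lo_s=2.0, hi_s=0.4)

    def test_idempotent_on_random_series(self):
        """Cleaning twice equals cleaning once (100 seeded artifact patterns)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rr = rng.normal(0.85, 0.04, size=120).clip(0.5, 1.4)
            # sporadic isolated artifacts, at least median_k apart
            for pos in range(5, 115, 25):
                rr[pos] = rng.choice([0.2, 3.0, rr[pos] * 1.6])
            once = clean_rr(_series_from_rr(rr))
            twice = clean_rr(once)
            assert np.array_equal(once.rr, twice.rr)
            assert np.array_equal(once.amp, twice.amp)


class TestResampleWindow:
    def test_both_channels_have_900_points(self, dense_beats):
        s = BeatSeries(dense_beats, np.diff(dense_beats), np.ones(len(dense_beats)))
        rr_ch, amp_ch = resample_window(s, 0.0, 300.0)
        assert len(rr_ch) == 900 and len(amp_ch) == 900

    def test_constant_series_resamples_to_constant(self, dense_beats):
        s = BeatSeries(dense_beats, np.full(len(dense_beats) - 1, 1.0), np.ones(len(dense_beats)))
        rr_ch, _ = resample_window(s, 0.0, 300.0)
        assert np.max(np.abs(rr_ch - 1.0)) < 1e-9

    def test_affine_series_resamples_exactly(self, dense_beats):
        a, b = 0.7, 3e-4
        rr = a + b * dense_beats[1:]
        s = BeatSeries(dense_beats, rr, np.ones(len(dense_beats)))
        rr_ch, _ = resample_window(s, 0.0, 300.0)
        grid = 300.0 * np.arange(900) / 900
        expected = a + b * np.clip(grid, dense_beats[1], dense_beats[dense_beats <= 300].max())
        assert np.max(np.abs(rr_ch - expected)) < 1e-6

    def test_sparse_window_rejected(self):
        times = np.array([0.0, 1.0, 2.0, 400.0, 401.0])
        s = BeatSeries(times, np.diff(times), np.ones(5))
        with pytest.raises(SparseBeatsError):
            resample_window(s, 100.0, 400.0)


class TestBuildWindows:
    def _dense_series(self, n_minutes):
        times = np.arange(0.4, 60.0 * n_minutes, 0.8)
        return BeatSeries(times, np.diff(times), np.ones(len(times)))

    def test_edge_minutes_dropped(self):
        labels = MinuteLabels("r", np.zeros(10, dtype=int))
        wins = build_windows(self._dense_series(10), labels)
        assert [w.center_minute for w in wins] == [2, 3, 4, 5, 6, 7]

    def test_five_minutes_single_window(self):
        labels = MinuteLabels("r", np.zeros(5, dtype=int))
        wins = build_windows(self._dense_series(5), labels)
        assert len(wins) == 1 and wins[0].center_minute == 2

    def test_window_label_matches_center_minute(self):
        rng = np.random.default_rng(9)
        lab = rng.integers(0, 2, size=12)
        labels = MinuteLabels("r", lab)
        wins = build_windows(self._dense_series(12), labels)
        assert wins, "expected windows from a dense series"
        for w in wins:
            assert w.label == lab[w.center_minute]
            assert len(w.rr_channel) == 900 and len(w.amp_channel) == 900


class TestWindowSetAndNormalization:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        ws = WindowSet(
            X=rng.normal(size=(4, 900, 2)),
            y=np.array([0, 1, 1, 0]),
            record_ids=["a", "a", "b", "b"],
            center_minutes=np.array([2, 3, 2, 3]),
        )
        ws.save(tmp_path / "w")
        back = WindowSet.load(tmp_path / "w")
        assert np.array_equal(back.X, ws.X)
        assert np.array_equal(back.y, ws.y)
        assert back.record_ids == ws.record_ids

    def test_zscore_normalization(self):
        rng = np.random.default_rng(2)
        ws = WindowSet(X=rng.normal(2.0, 3.0, size=(6, 900, 2)), y=np.zeros(6, dtype=int))
        mean, sd = fit_normalization(ws)
        normed = apply_normalization(ws, mean, sd)
        flat = normed.X.reshape(-1, 2)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-12)


def test_running_median_matches_direct_computation():
    rng = np.random.default_rng(5)
    x = rng.normal(size=50)
    k, h = 7, 3
    xp = np.concatenate([np.full(h, x[0]), x, np.full(h, x[-1])])
    expected = [np.median(xp[i : i + k]) for i in range(len(x))]
    assert np.allclose(running_median(x, k), expected)
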