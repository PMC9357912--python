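import numpy as np
import pytest

from hrvstress import (DetectionResult, DetectorConfig, ECGRecord, InputError,
                       RAnnotation, detect, find_candidates, match_annotations,
                       reconcile, select_start)
from hrvstress.rpeak import WindowCandidates
from hrvstress.synth import SynthConfig, mixed_noise, simulate_record


class TestSelectStart:
    def _record(self, first_max, second_max, fs=360, t=300):
        x = np.zeros(4 * t) + 0.001
        x[t // 2] = first_max
        x[t + t // 2] = second_max
        return ECGRecord(x, fs=fs)

    def test_start_skips_when_opening_on_r_wave(self):
        cfg = DetectorConfig(t_init=300 / 360.0)
        rec = self._record(2.0, 1.0)
        assert select_start(rec, cfg) == 600  # 2.0 > 1.8 * 1.0

    def test_start_zero_for_balanced_segments(self):
        cfg = DetectorConfig(t_init=300 / 360.0)
        rec = self._record(1.0, 1.0)
        assert select_start(rec, cfg) == 0

    def test_too_short_signal(self):
        with pytest.raises(InputError):
            select_start(ECGRecord(np.zeros(100) + 0.01, fs=360))


class TestFindCandidates:
    def test_symmetric_gaussian_agrees(self):
        t = np.arange(101)
        w = np.exp(-0.5 * ((t - 40) / 4.0) ** 2)
        c = find_candidates(w)
        assert c.r1 == 40 and c.r_prime == 40 and c.agree

    def test_monotone_ramp_degenerate_bracket(self):
        w = np.linspace(0, 1, 50)
        c = find_candidates(w)
        assert c.r1 == 49
        lo, hi = min(c.t_max, c.t_min), max(c.t_max, c.t_min)
        assert lo <= c.r_prime <= hi
        assert not c.agree

    def test_window_too_short(self):
        with pytest.raises(InputError):
            find_candidates(np.array([1.0, 2.0]))

    def test_matches_exhaustive_scan_oracle(self, rng):
        """Candidates equal a brute-force argmax/argmin scan on 1,000 windows."""
        for _ in range(1000):
            n = int(rng.integers(3, 120))
            w = rng.normal(size=n)
            c = find_candidates(w)
            # oracle: plain linear scans, first occurrence wins
            r1 = max(range(n), key=lambda i: (w[i], -i))
            dif = [w[i + 1] - w[i] for i in range(n - 1)]
            t_max = max(range(n - 1), key=lambda i: (dif[i], -i))
            t_min = min(range(n - 1), key=lambda i: (dif[i], i))
            lo, hi = min(t_max, t_min), max(t_max, t_min)
            r_prime = max(range(lo, hi + 1), key=lambda i: (w[i], -i))
            assert (c.r1, c.t_max, c.t_min, c.r_prime) == (r1, t_max, t_min, r_prime)


class TestReconcile:
    def test_agreement(self):
        c = WindowCandidates(r1=120, t_max=115, t_min=125, r_prime=120)
        assert reconcile(c, 0) == 120

    def test_first_beat_takes_smaller(self):
        c = WindowCandidates(r1=150, t_max=80, t_min=100, r_prime=90)
        assert reconcile(c, 0) == 90

    def test_rr_history_prefers_closer_interval(self):
        # prev R at 0, prev RR 288 samples; implied RRs 310 vs 260
        c = WindowCandidates(r1=310, t_max=250, t_min=270, r_prime=260)
        assert reconcile(c, 0, prev_r=0, prev_rr_samples=288.0) == 310

    def test_same_peak_tolerance_resolves_to_amplitude_max(self):
        c = WindowCandidates(r1=100, t_max=96, t_min=104, r_prime=104)
        assert reconcile(c, 0, prev_r=0, prev_rr_samples=105.0, same_peak_tol=9) == 100


class TestDetect:
    def test_constant_60bpm_recovers_every_beat(self):
        cfg = SynthConfig(seed=11, mean_hr=60.0, rr_sd=0.0, duration=300.0)
        record, truth = simulate_record(cfg)
        det = detect(record)
        assert len(det) == len(truth)
        assert np.max(np.abs(det.r_indices - truth.indices)) <= 1

    def test_all_zero_signal_is_empty_with_warning(self):
        det = detect(ECGRecord(np.zeros(3600), fs=360))
        assert len(det) == 0
        assert det.status != "ok"

    def test_noisy_10db_rate_above_99(self):
        cfg = SynthConfig(seed=21, noise=mixed_noise(10.0))
        record, truth = simulate_record(cfg)
        stats = match_annotations(detect(record), truth)
        assert stats.recognition_rate >= 99.0

    def test_detections_increasing_and_refractory(self, clean_record):
        record, _ = clean_record
        det = detect(record)
        assert np.all(np.diff(det.r_indices) > 0)
        assert np.all(det.rr_intervals > DetectorConfig().refractory_T1)

    def test_scale_and_offset_invariance(self, short_clean_record):
        record, _ = short_clean_record
        base = detect(record).r_indices
        scaled = ECGRecord(record.samples * 7.3 + 4.2, fs=record.fs)
        np.testing.assert_array_equal(detect(scaled).r_indices, base)

    def test_too_short_record_rejected(self):
        with pytest.raises(InputError):
            detect(ECGRecord(np.zeros(360), fs=360))

    def test_bandpass_variant_still_detects(self, short_clean_record):
        record, truth = short_clean_record
        det = detect(record, DetectorConfig(bandpass=True))
        stats = match_annotations(det, truth)
        assert stats.recognition_rate == 100.0

    def test_rr_intervals_match_indices(self, short_clean_record):
        record, _ = short_clean_record
        det = detect(record)
        np.testing.assert_allclose(det.rr_intervals,
                                   np.diff(det.r_indices) / record.fs)


class TestMatchAnnotations:
    def _det(self, idx, fs=360):
        return DetectionResult(np.asarray(idx, dtype=np.int64), fs)

    def _ref(self, idx, fs=360):
        return RAnnotation(np.asarray(idx, dtype=np.int64), fs)

    def test_identity(self):
        idx = np.arange(10) * 300
        s = match_annotations(self._det(idx), self._ref(idx))
        assert (s.missed, s.false_pos, s.recognition_rate) == (0, 0, 100.0)

    def test_one_missed(self):
        ref = np.arange(10) * 300
        s = match_annotations(self._det(ref[:9]), self._ref(ref))
        assert (s.missed, s.false_pos) == (1, 0)
        assert s.recognition_rate == pytest.approx(90.0)

    def test_error_count_rate_formula(self):
        # 2,273 reference beats, one false detection and no misses
        ref = np.arange(2273) * 300
        det = np.sort(np.append(ref, [150]))
        s = match_annotations(self._det(det), self._ref(ref))
        assert (s.missed, s.false_pos) == (0, 1)
        assert s.recognition_rate == pytest.approx(100 * 2272 / 2273)
        assert s.recognition_rate == pytest.approx(99.956, abs=1e-3)

    def test_swap_symmetry(self, rng):
        for _ in range(50):
            a = np.unique(rng.integers(0, 100000, size=rng.integers(5, 80)))
            b = np.unique(rng.integers(0, 100000, size=rng.integers(5, 80)))
            if len(a) < 1 or len(b) < 1:
                continue
            s1 = match_annotations(self._det(a), self._ref(b))
            s2 = match_annotations(self._det(b), self._ref(a))
            assert (s1.missed, s1.false_pos) == (s2.false_pos, s2.missed)

    def test_fs_mismatch_rejected(self):
        with pytest.raises(InputError):
            match_annotations(self._det([1, 400], fs=360), self._ref([1, 400], fs=250))
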