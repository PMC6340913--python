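"""Spectral RR candidates, fusion, smoothing, availability, full pipeline."""

import numpy as np
import pytest

from ppgresp import (
    ModalityCandidate,
    PipelineConfig,
    RREstimate,
    SimulationConfig,
    availability,
    estimate_modality_rr,
    estimate_record,
    fuse,
    simulate_ppg,
    smooth,
)


def _tone(freq_hz, dur_s=120.0, fs=4.0, amp=1.0, phase=0.3):
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


def _cand(modality, rr, valid=True, ratio=0.5):
    return ModalityCandidate(modality, rr, ratio, valid)


class TestModalityRR:
    def test_pure_tone_recovered(self):
        c = estimate_modality_rr(_tone(0.25), 4.0)
        assert c.valid
        assert c.rr_bpm == pytest.approx(15.0, abs=1.0)

    def test_stronger_of_two_tones_wins(self):
        series = _tone(0.40, amp=1.0) + _tone(0.20, amp=0.3)
        c = estimate_modality_rr(series, 4.0)
        assert c.valid
        assert c.rr_bpm == pytest.approx(24.0, abs=1.0)

    def test_all_zero_series_invalid(self):
        c = estimate_modality_rr(np.zeros(480), 4.0)
        assert not c.valid

    def test_low_coverage_invalid(self):
        mask = np.zeros(480, dtype=bool)
        mask[:200] = True
        c = estimate_modality_rr(_tone(0.25), 4.0, valid_mask=mask)
        assert not c.valid

    def test_welch_argmax_matches_brute_force_dft(self):
        """Oracle equivalence on 50 random tonal surrogates (one-bin slack)."""
        rng = np.random.default_rng(99)
        nfft = 1 << 16
        for _ in range(50):
            f0 = rng.uniform(0.09, 0.95)
            series = _tone(f0, phase=rng.uniform(0, 2 * np.pi))
            series += rng.uniform(0, 0.4) * rng.standard_normal(series.size)
            c = estimate_modality_rr(series, 4.0)
            f = np.fft.rfftfreq(nfft, 1 / 4.0)
            p = np.abs(np.fft.rfft(series - series.mean(), nfft)) ** 2
            band = (f >= 4 / 60) & (f <= 1.0)
            f_dft = f[band][np.argmax(p[band])]
            assert c.valid
            assert abs(c.rr_bpm - 60 * f_dft) <= 1.0


class TestFuse:
    def test_agreeing_candidates_average(self):
        rr = fuse([_cand("fm", 15.0), _cand("am", 15.5), _cand("bm", 15.2)], 0.9)
        assert rr == pytest.approx((15.0 + 15.5 + 15.2) / 3)

    def test_wide_spread_rejected(self):
        assert fuse([_cand("fm", 10.0), _cand("am", 20.0), _cand("bm", 30.0)], 0.9) is None

    def test_single_candidate_needs_quality(self):
        cands = [_cand("fm", 18.0, valid=False), _cand("am", 18.0), _cand("bm", 0, valid=False)]
        assert fuse(cands, 0.9) == pytest.approx(18.0)
        assert fuse(cands, 0.5) is None

    def test_af_excludes_fm_candidate(self):
        cands = [_cand("fm", 30.0), _cand("am", 15.0), _cand("bm", 15.4)]
        rr = fuse(cands, 0.9, ibi_cv=0.2)
        assert rr == pytest.approx(15.2)

    def test_majority_subset_outvotes_outlier(self):
        cands = [_cand("fm", 24.0), _cand("am", 15.1), _cand("bm", 15.3)]
        assert fuse(cands, 0.9) == pytest.approx(15.2)

    def test_mirror_image_of_baseline_candidate_dropped(self):
        # beat rate 60 bpm: fm at 60-40=20 is the folded image of bm at 40
        cands = [_cand("fm", 20.0), _cand("am", 20.3, valid=False), _cand("bm", 40.0)]
        rr = fuse(cands, 0.9, f_beat=1.0)
        assert rr == pytest.approx(40.0)


def _est(t, rr, sqi=0.9):
    return RREstimate(
        t=t,
        rr_fused=rr,
        candidates=[],
        window_sqi=sqi,
        available=rr is not None,
    )


class TestSmoothAndAvailability:
    def test_constant_input_constant_trend(self):
        ests = [_est(120.0 * k, 22.0) for k in range(1, 8)]
        trend = smooth(ests, 600.0)
        np.testing.assert_allclose(trend.rr_smoothed, 22.0)

    def test_step_response_is_partial_average(self):
        ests = [_est(60.0 * k, 12.0 if 60.0 * k <= 600 else 24.0) for k in range(1, 16)]
        trend = smooth(ests, 600.0)
        at = dict(zip(trend.times, trend.rr_smoothed))
        # 300 s past the step the 10-min window holds 5 new and 5 old points
        assert at[900.0] == pytest.approx(18.0, abs=1.5)

    def test_all_unavailable_gives_empty_trend(self):
        ests = [_est(120.0 * k, None) for k in range(1, 5)]
        assert smooth(ests, 600.0).times.size == 0

    def test_trend_bounded_by_window_inputs(self):
        rng = np.random.default_rng(0)
        ests = [_est(30.0 * k, float(rng.uniform(10, 30))) for k in range(1, 40)]
        trend = smooth(ests, 600.0)
        vals = {e.t: e.rr_fused for e in ests}
        for t, s in zip(trend.times, trend.rr_smoothed):
            inside = [v for tt, v in vals.items() if t - 600.0 < tt <= t]
            assert min(inside) - 1e-12 <= s <= max(inside) + 1e-12

    @pytest.mark.parametrize(
        "rates,expected",
        [([22.0] * 19 + [None], 0.95), ([22.0] * 4, 1.0), ([None] * 4, 0.0)],
    )
    def test_availability_counts(self, rates, expected):
        ests = [_est(120.0 * (k + 1), v) for k, v in enumerate(rates)]
        assert availability(ests) == pytest.approx(expected)

    def test_availability_empty_errors(self):
        with pytest.raises(ValueError):
            availability([])


class TestEstimateRecord:
    def test_clean_simulation_recovers_truth(self, noisy_sim):
        rec, gt = noisy_sim
        _, _, mean_rr = estimate_record(rec)
        assert mean_rr == pytest.approx(gt.rr_bpm, abs=1.0)

    def test_band_containment(self, noisy_sim):
        """Every reported rate lies in the configured respiratory band."""
        rec, _ = noisy_sim
        estimates, trend, _ = estimate_record(rec)
        for e in estimates:
            if e.available:
                assert 4.0 <= e.rr_fused <= 60.0
            for c in e.candidates:
                if c.valid:
                    assert 4.0 <= c.rr_bpm <= 60.0
        assert np.all((trend.rr_smoothed >= 4.0) & (trend.rr_smoothed <= 60.0))

    def test_fully_corrupted_record_unavailable(self):
        rng = np.random.default_rng(8)
        from ppgresp import PPGRecord

        rec = PPGRecord(samples=rng.standard_normal(125 * 150) * 5.0, fs=125.0)
        _, _, mean_rr = estimate_record(rec)
        assert mean_rr is None

    def test_pipeline_is_deterministic(self, noisy_sim):
        rec, _ = noisy_sim
        e1, t1, m1 = estimate_record(rec)
        e2, t2, m2 = estimate_record(rec)
        assert m1 == m2
        assert [e.rr_fused for e in e1] == [e.rr_fused for e in e2]
        np.testing.assert_array_equal(t1.rr_smoothed, t2.rr_smoothed)

    def test_error_grows_as_snr_falls(self):
        """Mean absolute error is non-decreasing from 30 dB down to 5 dB."""
        maes = []
        for snr in (30.0, 20.0, 10.0, 5.0):
            errs = []
            for seed in (1, 2, 3):
                cfg = SimulationConfig(
                    hr_bpm=80.0, rr_bpm=18.0, snr_db=snr, duration_s=150.0, seed=seed
                )
                rec, _ = simulate_ppg(cfg)
                _, _, m = estimate_record(rec)
                errs.append(abs(m - 18.0) if m is not None else 5.0)
            maes.append(np.mean(errs))
        assert all(a <= b + 1e-12 for a, b in zip(maes, maes[1:]))
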