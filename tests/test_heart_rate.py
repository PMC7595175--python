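"""Window geometry and the four per-window heart-rate estimators."""

import numpy as np
import pytest

from camvitals.beats import BeatRecord
from camvitals.heart_rate import (AllPolesCancelledError, ark_cancel, fit_ar,
                                  hr_ar_pole, hr_ark, hr_beat_count, hr_fft,
                                  windows)
from camvitals.quality import QualityFlags

FPS = 15.0


def tone(freqs_amps_phases, n=225, fps=FPS, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fps
    x = np.zeros(n)
    for f, a, ph in freqs_amps_phases:
        x += a * np.cos(2 * np.pi * f * t + ph)
    if noise:
        x += rng.normal(0, noise, n)
    return x


def scored_beat(onset, next_onset, sqi=1.0):
    return BeatRecord(onset=onset, next_onset=next_onset,
                      hr_inst=60.0 * FPS / (next_onset - onset),
                      sqi=QualityFlags(sqi_dtw=sqi))


class TestWindows:
    @pytest.mark.parametrize("seconds,expected", [(30, 16), (15, 1), (14, 0)])
    def test_window_count(self, seconds, expected):
        assert len(windows(int(seconds * FPS), FPS)) == expected

    def test_half_open_non_overlapping_starts(self):
        wins = windows(int(30 * FPS), FPS)
        assert wins[0].start == 0 and wins[0].stop == 225
        assert wins[1].start == 15


class TestBeatCount:
    def test_sixteen_onsets_at_sixty(self):
        beats = [scored_beat(int(k * FPS), int((k + 1) * FPS)) for k in range(16)]
        assert hr_beat_count(beats, FPS, slice(0, 16 * 15)) == pytest.approx(60.0)

    def test_two_onsets_half_second(self):
        beats = [scored_beat(0, 7), scored_beat(7, 15)]
        # onsets at 0 and 7 samples ~ 0.467 s -> ~128 beats/min
        hr = hr_beat_count(beats[:1] + beats[1:], FPS, slice(0, 225))
        assert hr == pytest.approx(60.0 / (7 / FPS), rel=1e-9)

    def test_out_of_range_rate_rejected(self):
        beats = [scored_beat(0, 3), scored_beat(3, 6)]  # 300 beats/min
        assert hr_beat_count(beats, FPS, slice(0, 225)) is None

    def test_rejected_beats_do_not_count(self):
        beats = [scored_beat(int(k * FPS), int((k + 1) * FPS), sqi=0.0)
                 for k in range(16)]
        assert hr_beat_count(beats, FPS, slice(0, 240)) is None

    def test_count_convention_switch(self):
        beats = [scored_beat(int(k * FPS), int((k + 1) * FPS)) for k in range(16)]
        n_over = hr_beat_count(beats, FPS, slice(0, 240), use_intervals=False)
        assert n_over == pytest.approx(60.0 * 16 / 15)


class TestFFT:
    def test_pure_tone(self):
        x = tone([(1.2, 1.0, 0.3)])
        assert hr_fft(x, FPS) == pytest.approx(72.0, abs=0.5)

    def test_argmax_semantics_with_two_tones(self):
        x = tone([(1.0, 2.0, 0.0), (1.5, 1.0, 0.0)])
        assert hr_fft(x, FPS) == pytest.approx(60.0, abs=0.5)

    def test_band_restriction(self):
        x = tone([(5.0, 3.0, 0.0), (1.2, 0.5, 0.0)])
        assert hr_fft(x, FPS) == pytest.approx(72.0, abs=0.5)


class TestARFit:
    def test_known_ar2_pole_recovery(self):
        rng = np.random.default_rng(0)
        r, th = 0.95, 0.5
        a1, a2 = 2 * r * np.cos(th), -(r ** 2)
        x = np.zeros(4000)
        e = rng.normal(size=4000)
        for t in range(2, 4000):
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
        model = fit_ar(x[500:], FPS, order=2)
        angles = np.abs(np.angle(model.poles))
        assert np.min(np.abs(angles - th)) < 0.02

    def test_conjugate_pole_pairs(self):
        model = fit_ar(tone([(1.2, 1.0, 0.1)], noise=0.05), FPS)
        poles = model.poles
        for p in poles[np.abs(poles.imag) > 1e-9]:
            assert np.min(np.abs(poles - np.conj(p))) < 1e-9

    def test_residual_variance_bounded_by_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 2.0, 500)
        model = fit_ar(x, FPS)
        assert model.noise_variance <= np.var(x) * 1.001

    def test_constant_window_rejected(self):
        with pytest.raises(ValueError):
            fit_ar(np.full(225, 3.0), FPS)


class TestARPole:
    def test_clean_tone(self):
        model = fit_ar(tone([(1.2, 1.0, 0.2)], noise=0.02, seed=3), FPS)
        assert hr_ar_pole(model) == pytest.approx(72.0, abs=1.0)

    def test_real_axis_only_no_estimate(self):
        from camvitals.heart_rate import ARModel
        model = ARModel(order=2, coefficients=np.array([0.5, 0.1]),
                        poles=np.array([0.9, -0.3]), fps=FPS)
        assert hr_ar_pole(model) is None


class TestARk:
    def flicker(self, seed):
        rng = np.random.default_rng(seed)
        ph = rng.uniform(0, 2 * np.pi, 3)
        return [(2.0, 3.0, ph[1]), (4.0, 3.0, ph[2])], ph[0]

    def test_cancellation_recovers_cardiac_peak(self):
        hits = 0
        for seed in range(20):
            fl, ph0 = self.flicker(seed)
            subj = tone([(1.2, 1.0, ph0)] + fl, noise=0.05, seed=seed)
            bg = tone(fl, noise=0.05, seed=1000 + seed)
            hr = hr_ark(subj, bg, FPS)
            hits += hr is not None and abs(hr - 72.0) < 2.0
        assert hits >= 19

    def test_identical_series_all_cancelled(self):
        x = tone([(1.2, 1.0, 0.0), (2.0, 1.0, 0.5)], noise=0.01, seed=9)
        m = fit_ar(x, FPS)
        with pytest.raises(AllPolesCancelledError):
            ark_cancel(m, m)

    def test_distant_background_preserves_cardiac_pole(self):
        subj = fit_ar(tone([(1.2, 1.0, 0.0)], noise=0.02, seed=5), FPS)
        bg = fit_ar(tone([(3.5, 1.0, 0.0)], noise=0.02, seed=6), FPS)
        reduced = ark_cancel(subj, bg)
        freqs = reduced.pole_freqs_hz()
        assert np.min(np.abs(freqs[freqs > 0] - 1.2)) < 0.1

    def test_never_cancels_distant_poles(self):
        subj = fit_ar(tone([(1.2, 1.0, 0.0), (3.0, 1.0, 1.0)], noise=0.05, seed=7), FPS)
        bg = fit_ar(tone([(3.0, 1.0, 1.0)], noise=0.05, seed=8), FPS)
        reduced = ark_cancel(subj, bg)
        tol = np.deg2rad(2.0)
        bg_angles = np.angle(bg.poles)
        for p in subj.poles:
            if not np.any(np.isclose(reduced.poles, p)):
                d = np.abs(np.angle(p) - bg_angles)
                assert np.min(np.minimum(d, 2 * np.pi - d)) <= tol

    def test_matches_ar_pole_without_flicker(self):
        for seed in range(5):
            subj = tone([(1.2, 1.0, 0.7)], noise=0.05, seed=seed)
            bg = tone([], noise=0.05, seed=100 + seed)
            a = hr_ark(subj, bg, FPS)
            b = hr_ar_pole(fit_ar(subj, FPS))
            assert a is not None and b is not None
            assert abs(a - b) < 1.0


def test_estimators_agree_on_clean_window(clean_beats):
    """All four estimators within 3 beats/min of each other on clean data."""
    x, beats, _ = clean_beats
    w = slice(int(30 * FPS), int(45 * FPS))
    for b in beats:
        b.sqi = QualityFlags(sqi_dtw=1.0)
    in_win = [b for b in beats if w.start <= b.onset < w.stop]
    rng = np.random.default_rng(0)
    estimates = [
        hr_beat_count(in_win, FPS, w),
        hr_fft(x[w], FPS),
        hr_ar_pole(fit_ar(x[w], FPS)),
        hr_ark(x[w], rng.normal(0, 0.05, w.stop - w.start), FPS),
    ]
    assert all(e is not None for e in estimates)
    assert max(estimates) - min(estimates) < 3.0
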