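"""RIAV extraction, PCA selection, spectral purity and RR estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camvitals.beats import BeatRecord, detect_beats
from camvitals.preprocessing import band_limit
from camvitals.respiration import (RespSignal, dominant_frequency, pca_components,
                                   resp_sqi, riav_extract, rr_estimate,
                                   rr_from_window, spectral_purity,
                                   torso_candidates)
from camvitals.synthetic import SyntheticConfig, generate_session, generate_torso_session

from conftest import make_pulse


def pulse_train_beats(amps, fps=15.0):
    pulse = make_pulse()
    L = len(pulse)
    x = np.concatenate([a * pulse for a in amps])
    beats = []
    pk = int(np.argmax(pulse))
    for k in range(len(amps) - 1):
        beats.append(BeatRecord(onset=k * L, peak=k * L + pk, next_onset=(k + 1) * L,
                                hr_inst=60.0))
    return x, beats


class TestRIAV:
    def test_constant_amplitudes_give_constant_series(self):
        x, beats = pulse_train_beats(np.ones(40))
        resp = riav_extract(beats, x, 15.0)
        assert resp is not None
        assert np.std(resp.samples) < 1e-9

    def test_modulation_recovered_at_respiratory_frequency(self):
        cfg = SyntheticConfig(duration_s=120.0, hr_trace=72.0, rr_trace=15.0,
                              riav_depth=0.3, noise_sd=0.02, seed=1, n_rois=1)
        session, _ = generate_session(cfg)
        x = band_limit(session.subject_series[(1, "green")], cfg.fps)
        resp = riav_extract(detect_beats(x, cfg.fps), x, cfg.fps, duration_s=120.0)
        assert dominant_frequency(resp.samples, resp.fs) == pytest.approx(0.25, abs=0.02)

    def test_depth_scales_respiratory_peak_to_peak(self):
        # the depth enters the respiratory-band content linearly; the
        # broadband frame-quantisation jitter floor is filtered out first
        from scipy import signal as sg

        def ptp(depth, seed=2):
            cfg = SyntheticConfig(duration_s=90.0, hr_trace=72.0, rr_trace=15.0,
                                  riav_depth=depth, noise_sd=0.0, seed=seed, n_rois=1)
            session, _ = generate_session(cfg)
            x = band_limit(session.subject_series[(1, "green")], cfg.fps)
            resp = riav_extract(detect_beats(x, cfg.fps), x, cfg.fps, duration_s=90.0)
            b, a = sg.butter(4, [0.1 / 2.0, 0.4 / 2.0], btype="band")
            f = sg.filtfilt(b, a, resp.samples - resp.samples.mean())
            return np.ptp(f[40:-40])

        assert ptp(0.4) / ptp(0.2) == pytest.approx(2.0, rel=0.1)

    def test_too_few_beats_returns_none(self):
        x, beats = pulse_train_beats(np.ones(4))
        assert riav_extract(beats[:3], x, 15.0) is None


class TestPCA:
    def grid(self, n=480, fs=4.0):
        return np.arange(n) / fs

    def test_shared_sinusoid_concentrates_in_first_component(self):
        t = self.grid()
        rng = np.random.default_rng(3)
        base = np.sin(2 * np.pi * 0.25 * t)
        cands = [RespSignal(base * rng.uniform(0.5, 2.0) + rng.normal(0, 0.05, len(t)),
                            4.0, "face") for _ in range(10)]
        comps = pca_components(cands)
        assert comps[0].pca_rank == 0
        assert comps[0].variance_explained > 0.9
        assert comps[0].dominant_freq == pytest.approx(0.25, abs=0.02)

    def test_components_are_orthogonal(self):
        t = self.grid()
        rng = np.random.default_rng(4)
        cands = [RespSignal(np.sin(2 * np.pi * 0.2 * t + k) + rng.normal(0, 0.3, len(t)),
                            4.0, "face") for k in range(6)]
        comps = pca_components(cands)
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                a, b = comps[i].samples, comps[j].samples
                cos = abs(np.dot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b))
                assert cos < 1e-8

    def test_out_of_band_source_excluded(self):
        t = self.grid()
        rng = np.random.default_rng(5)
        fast = np.sin(2 * np.pi * 1.5 * t)     # outside 0.1-0.7 Hz
        slow = np.sin(2 * np.pi * 0.3 * t)
        cands = [RespSignal(3 * fast + rng.normal(0, 0.01, len(t)), 4.0, "face")
                 for _ in range(3)]
        cands += [RespSignal(slow + rng.normal(0, 0.01, len(t)), 4.0, "face")
                  for _ in range(3)]
        comps = pca_components(cands)
        for c in comps:
            assert 0.1 <= c.dominant_freq <= 0.7

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            pca_components([RespSignal(np.zeros(100), 4.0, "face")])


class TestSpectralPurity:
    def test_session_length_sinusoid_is_pure(self):
        t = np.arange(480) / 4.0
        assert spectral_purity(np.sin(2 * np.pi * 0.25 * t), 4.0).spi >= 0.99

    def test_white_noise_far_from_pure(self):
        rng = np.random.default_rng(6)
        spis = [spectral_purity(rng.normal(0, 1, 120), 4.0).spi for _ in range(100)]
        # flat-spectrum SPI concentrates near its analytic value 5/9
        assert np.median(spis) == pytest.approx(5.0 / 9.0, abs=0.05)
        assert max(spis) < 0.8

    def test_amplitude_invariance(self):
        t = np.arange(240) / 4.0
        x = np.sin(2 * np.pi * 0.3 * t) + 0.1 * np.sin(2 * np.pi * 0.6 * t)
        assert spectral_purity(x, 4.0).spi == pytest.approx(
            spectral_purity(37.0 * x, 4.0).spi, rel=1e-9)

    def test_zero_window_scored_zero(self):
        assert spectral_purity(np.zeros(120), 4.0).spi == 0.0

    @given(st.integers(0, 1000))
    @settings(max_examples=40, deadline=None)
    def test_cauchy_schwarz_bound(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 120) + rng.uniform(0, 2) * np.sin(
            2 * np.pi * rng.uniform(0.05, 1.5) * np.arange(120) / 4.0)
        assert spectral_purity(x, 4.0).spi <= 1.0 + 1e-12


class TestRespSqi:
    def component(self, freq, var=0.9, n=480):
        t = np.arange(n) / 4.0
        return RespSignal(np.sin(2 * np.pi * freq * t), 4.0, "face",
                          variance_explained=var)

    def test_pure_in_band_component_scores_spi(self):
        c = self.component(0.25)
        s = resp_sqi(c)
        assert s == pytest.approx(spectral_purity(c.samples, 4.0).spi)
        assert s > 0.99

    def test_out_of_band_peak_zeroed(self):
        assert resp_sqi(self.component(0.05)) == 0.0

    def test_low_variance_component_zeroed(self):
        assert resp_sqi(self.component(0.25, var=0.2)) == 0.0

    def test_low_snr_zeroed(self):
        t = np.arange(480) / 4.0
        rng = np.random.default_rng(7)
        noisy = 0.2 * np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 1.0, 480)
        c = RespSignal(noisy, 4.0, "face", variance_explained=0.9)
        assert resp_sqi(c) == 0.0


class TestRREstimation:
    def test_torso_stream_tracks_truth(self):
        cfg = SyntheticConfig(duration_s=180.0, rr_trace=15.0, noise_sd=0.05,
                              seed=8, n_rois=4)
        torso = generate_torso_session(cfg)
        grey = {k: v for k, v in torso.subject_series.items() if k[1] == "grey"}
        comps = pca_components(torso_candidates(grey, cfg.fps))
        ests = rr_estimate(comps, "torso")
        assert len(ests) > 10
        vals = np.array([e.value for e in ests])
        assert np.mean(np.abs(vals - 15.0)) < 1.0

    def test_estimates_confined_to_band(self):
        cfg = SyntheticConfig(duration_s=120.0, rr_trace=40.0, noise_sd=0.1,
                              seed=9, n_rois=4)
        torso = generate_torso_session(cfg)
        grey = {k: v for k, v in torso.subject_series.items() if k[1] == "grey"}
        comps = pca_components(torso_candidates(grey, cfg.fps))
        for e in rr_estimate(comps, "torso"):
            assert 6.0 <= e.value <= 42.0

    def test_window_pole_matches_sinusoid(self):
        t = np.arange(120) / 4.0
        rng = np.random.default_rng(10)
        x = np.sin(2 * np.pi * 0.25 * t) + rng.normal(0, 0.05, 120)
        assert rr_from_window(x, 4.0) == pytest.approx(15.0, abs=0.8)

    def test_no_components_no_estimates(self):
        assert rr_estimate([], "face") == []
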