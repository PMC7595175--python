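"""Pulse templates, multi-scale DTW and the six-component beat SQI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from camvitals.beats import BeatRecord
from camvitals.quality import (QualityFlags, build_template, clipped_fraction,
                               dtw_score, multiscale_dtw, rotate_normalise,
                               score_beat, window_sqi)
from conftest import make_pulse


def beats_from_pulse_train(pulse, n_beats, amp=None):
    """Tile one pulse into a waveform and matching BeatRecords."""
    L = len(pulse)
    amp = amp if amp is not None else np.ones(n_beats)
    x = np.concatenate([a * pulse for a in amp])
    beats = []
    pk = int(np.argmax(pulse))
    for k in range(n_beats - 1):
        beats.append(BeatRecord(onset=k * L, peak=k * L + pk, next_onset=(k + 1) * L,
                                hr_inst=60.0 * 15.0 / L))
    return x, beats


class TestDTW:
    def brute_force(self, x, y):
        xb, yt = rotate_normalise(x), rotate_normalise(y)
        dx, dy = np.diff(xb), np.diff(yt)
        C = np.abs(dx[:, None] - dy[None, :])
        acc = np.full(C.shape, np.inf)
        acc[0, 0] = C[0, 0]
        for i in range(C.shape[0]):
            for j in range(C.shape[1]):
                if i == 0 and j == 0:
                    continue
                prev = min(
                    acc[i - 1, j] if i > 0 else np.inf,
                    acc[i, j - 1] if j > 0 else np.inf,
                    acc[i - 1, j - 1] if (i > 0 and j > 0) else np.inf,
                )
                acc[i, j] = C[i, j] + prev
        return acc[-1, -1]

    def test_identical_series_zero_cost(self):
        pulse = make_pulse()
        res = multiscale_dtw(pulse, pulse.copy())
        assert res.cost == 0.0
        assert res.path[0] == (0, 0)

    def test_degenerate_beat_max_cost(self):
        res = multiscale_dtw(np.full(20, 1.0), make_pulse())
        assert res.degenerate
        assert res.cost == 100.0
        assert dtw_score(res.cost) == 0.0

    def test_unlimited_band_equals_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n, m = rng.integers(8, 41, 2)
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, m)
            assert multiscale_dtw(x, y, band=None).cost == pytest.approx(
                self.brute_force(x, y), abs=1e-12)

    def test_banded_cost_bounded_below_by_oracle(self):
        rng = np.random.default_rng(2)
        equal = 0
        trials = 50
        for _ in range(trials):
            n, m = rng.integers(8, 41, 2)
            x, y = rng.normal(0, 1, n), rng.normal(0, 1, m)
            oracle = self.brute_force(x, y)
            banded = multiscale_dtw(x, y, band=2, min_scale_len=16).cost
            assert banded >= oracle - 1e-12
            equal += abs(banded - oracle) < 1e-12
        assert equal >= 0.9 * trials  # band +-2 recovers the exact path almost always

    def test_symmetric_cost(self):
        x = np.sin(np.arange(30) * 0.3)
        y = np.cos(np.arange(24) * 0.4)
        assert multiscale_dtw(x, y, band=None).cost == pytest.approx(
            multiscale_dtw(y, x, band=None).cost)

    def test_path_monotone_boundary_to_boundary(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 25), rng.normal(0, 1, 30)
        res = multiscale_dtw(x, y, band=None)
        path = np.asarray(res.path)
        assert tuple(path[0]) == (0, 0)
        assert tuple(path[-1]) == (len(x) - 2, len(y) - 2)  # slope sequences
        steps = np.diff(path, axis=0)
        assert (steps >= 0).all() and (steps.sum(axis=1) >= 1).all()


class TestTemplate:
    def test_identical_beats_reproduce_the_pulse(self):
        pulse = make_pulse()
        x, beats = beats_from_pulse_train(pulse, 10)
        tpl = build_template(beats, x)
        assert tpl.valid
        assert tpl.length == len(pulse)
        assert np.max(np.abs(tpl.samples - pulse)) < 1e-9

    def test_amplitude_outlier_excluded_at_stage3(self):
        pulse = make_pulse()
        amp = np.ones(11)
        amp[5] = 5.0
        x, beats = beats_from_pulse_train(pulse, 11, amp)
        tpl = build_template(beats, x)
        assert tpl.valid
        assert 5 not in tpl.retained
        assert np.max(np.abs(tpl.samples - pulse)) < 0.02 * np.ptp(pulse)

    def test_majority_out_of_range_invalidates_window(self):
        pulse = make_pulse()
        x, beats = beats_from_pulse_train(pulse, 12)
        for b in beats[:7]:  # >50% outside the physiological band
            b.hr_inst = 300.0
        tpl = build_template(beats, x)
        assert not tpl.valid
        assert tpl.stage_reached == 1

    def test_fewer_than_two_beats_invalid(self):
        pulse = make_pulse()
        x, beats = beats_from_pulse_train(pulse, 2)
        assert not build_template(beats[:1], x).valid

    def test_rebuild_from_retained_is_idempotent(self):
        pulse = make_pulse()
        amp = np.ones(12)
        amp[3] = 4.0
        x, beats = beats_from_pulse_train(pulse, 12, amp)
        tpl = build_template(beats, x)
        again = build_template([beats[k] for k in tpl.retained], x)
        assert again.valid
        assert np.allclose(tpl.samples, again.samples, atol=1e-12)


class TestScoring:
    @pytest.mark.parametrize("cost,expected", [(3.58, 0.9642), (28.10, 0.719),
                                               (0.0, 1.0), (150.0, 0.0)])
    def test_dtw_score_formula(self, cost, expected):
        assert dtw_score(cost) == pytest.approx(expected, abs=1e-12)

    def test_combined_sqi_is_product(self):
        q = QualityFlags(sqi_act=1, sqi_cp=1, sqi_freq=1, sqi_amp=1, sqi_clip=1,
                         sqi_dtw=0.9642)
        assert q.sqi_beat == pytest.approx(0.9642)
        q.sqi_freq = 0
        assert q.sqi_beat == 0.0

    def _context(self, n_beats=12):
        pulse = make_pulse()
        x, beats = beats_from_pulse_train(pulse, n_beats)
        tpl = build_template(beats, x)
        act = np.ones(len(x), dtype=np.uint8)
        step_prob = np.zeros(len(x))
        return x, beats, tpl, act, step_prob

    def test_clean_beat_scores_near_one(self):
        x, beats, tpl, act, step_prob = self._context()
        q = score_beat(beats[5], x, tpl, act, step_prob, slice(0, len(x)))
        assert q.sqi_act == q.sqi_cp == q.sqi_freq == q.sqi_amp == q.sqi_clip == 1
        assert q.sqi_beat > 0.95

    def test_motion_frame_rejects_beat(self):
        x, beats, tpl, act, step_prob = self._context()
        act[beats[5].onset + 2] = 0
        q = score_beat(beats[5], x, tpl, act, step_prob, slice(0, len(x)))
        assert q.sqi_act == 0 and q.sqi_beat == 0.0

    def test_step_probability_rejects_beat(self):
        x, beats, tpl, act, step_prob = self._context()
        step_prob[beats[5].onset + 1] = 0.9
        q = score_beat(beats[5], x, tpl, act, step_prob, slice(0, len(x)))
        assert q.sqi_cp == 0 and q.sqi_beat == 0.0

    def test_bradycardic_rate_rejects_beat(self):
        x, beats, tpl, act, step_prob = self._context()
        beats[5].hr_inst = 30.0
        q = score_beat(beats[5], x, tpl, act, step_prob, slice(0, len(x)))
        assert q.sqi_freq == 0 and q.sqi_beat == 0.0

    def test_amplitude_spike_rejects_beat(self):
        x, beats, tpl, act, step_prob = self._context()
        x = x.copy()
        x[beats[5].onset + 3] += 10.0 * np.ptp(x)
        q = score_beat(beats[5], x, tpl, act, step_prob, slice(0, len(x)))
        assert q.sqi_amp == 0 and q.sqi_beat == 0.0

    def test_missing_template_rejects_beat(self):
        x, beats, _, act, step_prob = self._context()
        from camvitals.quality import PulseTemplate
        invalid = PulseTemplate(None, 0, 0, stage_reached=1, valid=False)
        q = score_beat(beats[5], x, invalid, act, step_prob, slice(0, len(x)))
        assert q.sqi_beat == 0.0

    def test_saturated_beat_flagged_as_clipped(self):
        pulse = make_pulse()
        x, beats = beats_from_pulse_train(pulse, 12)
        x = np.minimum(x, 0.25 * pulse.max())  # hard saturation
        frac = clipped_fraction(x[beats[5].onset : beats[5].next_onset],
                                x[: len(x)])
        assert frac > 1.0 / 3.0
        clean, cb = beats_from_pulse_train(pulse, 12)
        frac_clean = clipped_fraction(clean[cb[5].onset : cb[5].next_onset], clean)
        assert frac_clean <= 1.0 / 3.0


class TestWindowSqi:
    def test_mean_of_beat_scores(self):
        mk = lambda v: BeatRecord(onset=0, sqi=QualityFlags(sqi_dtw=v))
        assert window_sqi([mk(1.0), mk(1.0)]) == 1.0
        assert window_sqi([mk(1.0), mk(0.0)]) == 0.5
        assert window_sqi([]) == 0.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_bounded_and_monotone(self, scores):
        mk = lambda v: BeatRecord(onset=0, sqi=QualityFlags(sqi_dtw=v))
        beats = [mk(v) for v in scores]
        s = window_sqi(beats)
        assert 0.0 <= s <= 1.0
        worse = beats + [mk(0.0)]
        assert window_sqi(worse) <= s
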