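"""Synthetic PPGi session generator with full ground truth.

The clinical videos behind the method are not distributable, so sessions
with the same statistical structure are generated here instead: a pulsatile
skin-colour carrier at a configurable (possibly time-varying) heart rate,
amplitude-modulated by respiration (RIAV), plus the nuisance processes the
pipeline is built to survive -- frame-rate-aliased flicker tones from mains
lighting shared with a background ROI, illumination step changes, sensor
noise, amplitude clipping and motion gaps. Every injected component is
recorded in a :class:`SyntheticGroundTruth` so estimator error can be
measured exactly.

The pulse shape is a piecewise raised cosine with a fast upslope (170 ms at
60 beats/min, scaled with the beat period) and a slower raised-cosine decay,
matching the slope-sum assumptions of the beat detector. Flicker is written
with identical amplitude and phase into the background series and every
subject ROI before any subject-only component is added, so the subject and
background share the aliased artefact exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .session import SessionSignals, GRAY_WEIGHTS

Trace = float | Callable[[np.ndarray], np.ndarray] | Sequence[tuple[float, float]]

#: relative pulsatile strength of each colour channel (green carries most
#: of the PPG signal)
CHANNEL_GAINS = {"red": 0.5, "green": 1.0, "blue": 0.3}

#: fraction of the beat period spent on the upslope at 60 beats/min
UPSLOPE_S_AT_60 = 0.170


def alias_frequency(f_source_hz: float, fps: float) -> float:
    """Frequency to which a tone folds when sampled at ``fps``.

    A 100 Hz mains flicker sampled at 15 frames/s appears at 5 Hz.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if f_source_hz < 0:
        raise ValueError("source frequency must be non-negative")
    r = f_source_hz % fps
    return min(r, fps - r)


def as_trace(trace: Trace) -> Callable[[np.ndarray], np.ndarray]:
    """Normalise a scalar / breakpoint-list / callable into a callable."""
    if callable(trace):
        return trace
    if np.isscalar(trace):
        value = float(trace)  # type: ignore[arg-type]
        return lambda t: np.full_like(np.asarray(t, dtype=float), value)
    pts = np.asarray(trace, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("breakpoint trace must be a sequence of (time, value)")
    return lambda t: np.interp(np.asarray(t, dtype=float), pts[:, 0], pts[:, 1])


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic session."""

    duration_s: float = 120.0
    fps: float = 15.0
    hr_trace: Trace = 72.0            # beats/min, within [36, 240]
    rr_trace: Trace = 15.0            # breaths/min, within [6, 42]
    riav_depth: float = 0.3           # fractional amplitude modulation [0, 1)
    flicker_source_hz: Sequence[float] = field(default_factory=list)
    flicker_amp_ratio: float = 1.0    # artefact/cardiac amplitude ratio
    noise_sd: float = 0.05            # intensity units
    step_changes: Sequence[tuple[float, float]] = field(default_factory=list)
    clip_intervals: Sequence[tuple[float, float]] = field(default_factory=list)
    motion_intervals: Sequence[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    # layout / amplitude conditions (the paper reports the pulsatile
    # amplitude only as "very small" relative to the 8-bit intensity range)
    n_rois: int = 9
    pulse_amp: float = 1.0
    baseline: float = 100.0
    background_baseline: float = 90.0
    clip_margin: float = 0.3          # ceiling above baseline, in pulse amps

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not (0 <= self.riav_depth < 1):
            raise ValueError("riav_depth must be in [0, 1)")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        t = np.linspace(0.0, self.duration_s, 257)
        hr = as_trace(self.hr_trace)(t)
        if np.any(hr < 36.0) or np.any(hr > 240.0):
            raise ValueError("hr_trace must stay within [36, 240] beats/min")
        rr = as_trace(self.rr_trace)(t)
        if np.any(rr < 6.0) or np.any(rr > 42.0):
            raise ValueError("rr_trace must stay within [6, 42] breaths/min")
        for lo, hi in list(self.clip_intervals) + list(self.motion_intervals):
            if hi <= lo:
                raise ValueError("intervals must have positive length")


@dataclass
class SyntheticGroundTruth:
    """Everything injected into a synthetic session."""

    beat_onset_times: np.ndarray
    beat_peak_times: np.ndarray
    hr_at: Callable[[np.ndarray], np.ndarray]
    rr_at: Callable[[np.ndarray], np.ndarray]
    alias_freqs_hz: list[float]
    step_change_samples: list[int]
    invalid_intervals: list[tuple[float, float]]
    clip_intervals: list[tuple[float, float]]

    def __post_init__(self) -> None:
        onsets = np.asarray(self.beat_onset_times, dtype=float)
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("beat onsets must be strictly increasing")


def _beat_onsets(hr_at, duration_s: float, fps: float) -> np.ndarray:
    """Onset times where the integrated cardiac phase crosses integers."""
    dt = 1.0 / (8.0 * fps)
    t = np.arange(0.0, duration_s + 2.0, dt)
    rate = np.asarray(hr_at(t), dtype=float) / 60.0  # beats per second
    phase = np.concatenate(([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)))
    n_beats = int(np.floor(phase[-1]))
    # invert phase -> time by interpolation; phase is strictly increasing
    return np.interp(np.arange(n_beats + 1, dtype=float), phase, t)


def _pulse_waveform(times: np.ndarray, onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise raised-cosine pulse train; returns (waveform, peak_times).

    Each beat rises 0→1 over ``0.170 * period`` seconds and decays 1→0 over
    the remainder of the period. Zero outside [first onset, last onset).
    """
    wave = np.zeros_like(times, dtype=float)
    periods = np.diff(onsets)
    peak_times = onsets[:-1] + UPSLOPE_S_AT_60 * periods
    idx = np.searchsorted(onsets, times, side="right") - 1
    inside = (idx >= 0) & (idx < len(periods))
    k = idx[inside]
    s = times[inside] - onsets[k]
    u = UPSLOPE_S_AT_60 * periods[k]
    d = periods[k] - u
    rising = s <= u
    w = np.empty_like(s)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * s[rising] / u[rising]))
    w[~rising] = 0.5 * (1.0 + np.cos(np.pi * (s[~rising] - u[~rising]) / d[~rising]))
    wave[inside] = w
    return wave, peak_times


def _interval_mask(times: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros_like(times, dtype=bool)
    for lo, hi in intervals:
        mask |= (times >= lo) & (times < hi)
    return mask


def generate_session(config: SyntheticConfig) -> tuple[SessionSignals, SyntheticGroundTruth]:
    """Generate one synthetic face-ROI session plus ground truth.

    Randomness is drawn from a single generator seeded once; sub-streams
    (flicker phases, per-ROI gains, noise per series) are consumed in a
    fixed order, so identical configs give bit-identical sessions.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fps = config.fps
    n = int(round(config.duration_s * fps))
    t = np.arange(n) / fps

    hr_at = as_trace(config.hr_trace)
    rr_at = as_trace(config.rr_trace)

    onsets = _beat_onsets(hr_at, config.duration_s, fps)
    pulse, peak_times = _pulse_waveform(t, onsets)

    # respiratory amplitude modulation (RIAV)
    dt = 1.0 / fps
    resp_rate = np.asarray(rr_at(t), dtype=float) / 60.0
    resp_phase = np.concatenate(
        ([0.0], np.cumsum(0.5 * (resp_rate[1:] + resp_rate[:-1]) * dt))
    )
    modulation = 1.0 + config.riav_depth * np.sin(2.0 * np.pi * resp_phase)
    cardiac = config.pulse_amp * modulation * pulse

    # shared aliased flicker: identical amplitude and phase everywhere
    alias_freqs = [alias_frequency(f, fps) for f in config.flicker_source_hz]
    flicker_phases = rng.uniform(0.0, 2.0 * np.pi, size=len(alias_freqs))
    flicker = np.zeros(n)
    flicker_amp = config.flicker_amp_ratio * config.pulse_amp
    for fa, ph in zip(alias_freqs, flicker_phases):
        flicker += flicker_amp * np.cos(2.0 * np.pi * fa * t + ph)

    # illumination step changes (global: all ROIs and background)
    steps = np.zeros(n)
    step_samples = []
    for when, jump in config.step_changes:
        i = int(round(when * fps))
        if 0 <= i < n:
            steps[i:] += jump
            step_samples.append(i)

    # transient baseline swing during motion (in addition to centroid jumps)
    motion_swing = np.zeros(n)
    for lo, hi in config.motion_intervals:
        mask = (t >= lo) & (t < hi)
        m = int(mask.sum())
        if m:
            motion_swing[mask] += 5.0 * config.pulse_amp * np.hanning(m)

    roi_gains = rng.uniform(0.8, 1.2, size=config.n_rois)
    clip_mask = _interval_mask(t, config.clip_intervals)

    subject: dict[tuple[int, str], np.ndarray] = {}
    for r in range(config.n_rois):
        rgb = {}
        for ch in ("red", "green", "blue"):
            x = (
                config.baseline
                + CHANNEL_GAINS[ch] * roi_gains[r] * (cardiac + motion_swing)
                + flicker
                + steps
            )
            if config.noise_sd > 0:
                x = x + rng.normal(0.0, config.noise_sd, size=n)
            if clip_mask.any():
                ceiling = config.baseline + config.clip_margin * config.pulse_amp
                x = np.where(clip_mask, np.minimum(x, ceiling), x)
            rgb[ch] = x
        grey = (
            GRAY_WEIGHTS[0] * rgb["red"]
            + GRAY_WEIGHTS[1] * rgb["green"]
            + GRAY_WEIGHTS[2] * rgb["blue"]
        )
        for ch in ("red", "green", "blue"):
            subject[(r + 1, ch)] = rgb[ch]
        subject[(r + 1, "grey")] = grey

    background: dict[str, np.ndarray] = {}
    bg_rgb = {}
    for ch in ("red", "green", "blue"):
        x = config.background_baseline + flicker + steps
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=n)
        bg_rgb[ch] = x
    bg_rgb["grey"] = (
        GRAY_WEIGHTS[0] * bg_rgb["red"]
        + GRAY_WEIGHTS[1] * bg_rgb["green"]
        + GRAY_WEIGHTS[2] * bg_rgb["blue"]
    )
    background.update(bg_rgb)

    # centroid trace: constant except >100 px jumps inside motion intervals
    centroids = np.tile([1224.0, 1024.0], (n, 1))
    motion_mask = _interval_mask(t, config.motion_intervals)
    frames = np.flatnonzero(motion_mask)
    centroids[frames, 0] += np.where(frames % 2 == 0, 150.0, -150.0)

    session = SessionSignals(
        fps=fps,
        subject_series=subject,
        background_series=background,
        centroids=centroids,
        meta={"kind": "synthetic_face", "seed": config.seed},
    )
    truth = SyntheticGroundTruth(
        beat_onset_times=onsets,
        beat_peak_times=peak_times,
        hr_at=hr_at,
        rr_at=rr_at,
        alias_freqs_hz=alias_freqs,
        step_change_samples=step_samples,
        invalid_intervals=list(config.motion_intervals),
        clip_intervals=list(config.clip_intervals),
    )
    return session, truth


def generate_torso_session(config: SyntheticConfig) -> SessionSignals:
    """Grey-scale upper-torso session: respiratory motion, no cardiac pulse.

    Each ROI carries a sinusoid at the respiratory rate (clothing motion
    around the thorax) plus Gaussian noise; all ROIs share the respiratory
    phase, with per-ROI amplitude spread.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    fps = config.fps
    n = int(round(config.duration_s * fps))
    t = np.arange(n) / fps

    rr_at = as_trace(config.rr_trace)
    dt = 1.0 / fps
    rate = np.asarray(rr_at(t), dtype=float) / 60.0
    phase = np.concatenate(([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)))
    resp = np.sin(2.0 * np.pi * phase)

    amp = 2.0 * config.pulse_amp
    gains = rng.uniform(0.8, 1.2, size=config.n_rois)
    subject: dict[tuple[int, str], np.ndarray] = {}
    for r in range(config.n_rois):
        x = config.baseline + amp * gains[r] * resp
        if config.noise_sd > 0:
            x = x + rng.normal(0.0, config.noise_sd, size=n)
        subject[(r + 1, "grey")] = x

    bg = np.full(n, config.background_baseline, dtype=float)
    if config.noise_sd > 0:
        bg = bg + rng.normal(0.0, config.noise_sd, size=n)
    centroids = np.tile([1224.0, 1024.0], (n, 1))
    return SessionSignals(
        fps=fps,
        subject_series=subject,
        background_series={"grey": bg},
        centroids=centroids,
        meta={"kind": "synthetic_torso", "seed": config.seed},
    )
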