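"""Per-window heart-rate estimators: beat count, FFT, AR pole, ARk.

Four estimators run on 15-s windows advanced by 1 s:

* beat counting over the detected onsets,
* the peak of the Hamming-tapered magnitude spectrum in the cardiac band,
* the angle of the dominant (largest-radius) pole of an autoregressive
  model of the window, and
* ARk -- the same AR model after *pole cancellation*: any subject-ROI pole
  lying within two angular degrees of a background-ROI pole is treated as a
  frame-rate-aliased lighting artefact and removed from the transfer
  function denominator; the heart rate is then the peak of the power
  spectrum reconstructed from the surviving poles. This removes aliased
  mains flicker without knowing its frequency in advance.

AR models are fitted with Burg's method (stable on short windows); order 8
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg

from .beats import BeatRecord


@dataclass
class ARModel:
    """All-pole autoregressive model ``x_t = sum a_i x_{t-i} + e_t``."""

    order: int
    coefficients: np.ndarray    # a_1 .. a_p
    poles: np.ndarray           # roots of z^p - a_1 z^{p-1} - ... - a_p
    fps: float
    fit_method: str = "burg"
    noise_variance: float | None = None  # driving-noise variance of the fit

    def pole_freqs_hz(self) -> np.ndarray:
        """Frequency of each pole (signed, Hz)."""
        return np.angle(self.poles) / (2.0 * np.pi) * self.fps

    def power_spectrum(self, n_grid: int = 4096) -> tuple[np.ndarray, np.ndarray]:
        """|H(e^{jw})|^2 on a dense grid over [0, Nyquist].

        The numerator gain is irrelevant for peak location and is kept at 1.
        """
        freqs = np.linspace(0.0, self.fps / 2.0, n_grid)
        z = np.exp(1j * 2.0 * np.pi * freqs / self.fps)
        denom = np.ones_like(z)
        for p in self.poles:
            denom = denom * (z - p)
        mag = np.abs(denom)
        mag = np.maximum(mag, 1e-12)
        return freqs, 1.0 / (mag * mag)


@dataclass
class VitalEstimate:
    """One timestamped heart-rate or respiratory-rate estimate."""

    time_s: float
    value: float
    sqi: float
    method: str
    source: str


def windows(n_samples: int, fps: float, window_s: float = 15.0, step_s: float = 1.0):
    """Half-open running windows ``[start, start+len)`` in samples."""
    wlen = int(round(window_s * fps))
    step = max(1, int(round(step_s * fps)))
    return [slice(s, s + wlen) for s in range(0, n_samples - wlen + 1, step)]


def hr_beat_count(
    beats: list[BeatRecord],
    fps: float,
    window: slice,
    hr_band: tuple[float, float] = (36.0, 240.0),
    use_intervals: bool = True,
) -> float | None:
    """Beats/min from the onset count over the first-to-last onset span.

    Only beats with a positive combined SQI contribute. With
    ``use_intervals`` (default) the numerator is the number of
    inter-onset intervals, N-1; the literal N/dt reading is selectable.
    """
    onsets = [b.onset for b in beats
              if window.start <= b.onset < window.stop and b.sqi_beat > 0]
    if len(onsets) < 2:
        return None
    span_s = (onsets[-1] - onsets[0]) / fps
    if span_s <= 0:
        return None
    n = len(onsets) - 1 if use_intervals else len(onsets)
    hr = 60.0 * n / span_s
    return hr if hr_band[0] <= hr <= hr_band[1] else None


def hr_fft(
    x: np.ndarray,
    fps: float,
    band_hz: tuple[float, float] = (0.6, 4.0),
    zero_pad_factor: int = 8,
) -> float | None:
    """Beats/min from the band-restricted peak of the magnitude spectrum."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(max(zero_pad_factor * n, 2))))
    spec = np.abs(np.fft.rfft(x * np.hamming(n), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fps)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        return None
    k = np.flatnonzero(in_band)[np.argmax(spec[in_band])]
    return float(freqs[k] * 60.0)


def fit_ar(x: np.ndarray, fps: float, order: int = 8) -> ARModel:
    """Fit an AR model by Burg's method and locate its poles."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4 * order:
        raise ValueError("window too short for the AR order")
    if np.ptp(x) == 0:
        raise ValueError("constant window: AR fit is singular")
    coefs, sigma2 = burg(x, order=order, demean=True)
    poles = np.roots(np.concatenate(([1.0], -coefs)))
    return ARModel(order=order, coefficients=np.asarray(coefs), poles=poles, fps=fps,
                   noise_variance=float(sigma2))


def hr_ar_pole(
    model: ARModel,
    band_hz: tuple[float, float] = (0.6, 4.0),
) -> float | None:
    """Beats/min from the dominant in-band pole of the AR model.

    Among poles whose positive frequency falls in the cardiac band, the one
    with the largest radius wins; conjugate pairs count once through the
    positive-frequency convention. Real-axis-only models give no estimate.
    """
    freqs = model.pole_freqs_hz()
    radii = np.abs(model.poles)
    mask = (freqs > 0) & (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not mask.any():
        return None
    k = np.flatnonzero(mask)[np.argmax(radii[mask])]
    return float(freqs[k] * 60.0)


class AllPolesCancelledError(ValueError):
    """Raised when pole cancellation leaves no physiological component."""


def ark_cancel(
    subject_model: ARModel,
    background_model: ARModel,
    tol_deg: float = 2.0,
    bg_min_radius: float = 0.8,
    radius_tol: float = 0.1,
) -> ARModel:
    """Remove subject poles shared with the background model.

    A subject pole is cancelled when its angle lies within ``tol_deg``
    angular degrees of a background pole that represents a genuine shared
    component: either a dominant background pole (radius at least
    ``bg_min_radius`` -- an artefact tone is a strong narrowband component
    of the background model) or a pole whose radius also agrees within
    ``radius_tol`` (the same pole fitted in both models). Without the
    dominance requirement a weak background *noise* pole that happens to
    fall near the cardiac angle would cancel the pulse itself. Conjugate
    pairs cancel pairwise since angles are compared with their signs. The
    reduced model keeps the surviving poles (numerator order follows
    along; only peak location is used downstream).
    """
    if subject_model.order != background_model.order:
        raise ValueError("models must share the same order")
    if subject_model.fps != background_model.fps:
        raise ValueError("models must share the same sampling rate")
    tol = np.deg2rad(tol_deg)
    bg_angles = np.angle(background_model.poles)
    bg_radii = np.abs(background_model.poles)
    keep = []
    for p in subject_model.poles:
        diff = np.abs(np.angle(p) - bg_angles)
        diff = np.minimum(diff, 2.0 * np.pi - diff)
        shared = (diff <= tol) & (
            (bg_radii >= bg_min_radius) | (np.abs(bg_radii - np.abs(p)) <= radius_tol)
        )
        if not shared.any():
            keep.append(p)
    if not keep:
        raise AllPolesCancelledError(
            "all subject poles cancelled: no physiological component found"
        )
    kept = np.asarray(keep)
    coefs = -np.poly(kept)[1:]
    return ARModel(
        order=len(kept),
        coefficients=np.real_if_close(coefs),
        poles=kept,
        fps=subject_model.fps,
        fit_method=subject_model.fit_method + "+ark",
    )


def hr_ark(
    subject_window: np.ndarray,
    background_window: np.ndarray,
    fps: float,
    order: int = 8,
    tol_deg: float = 2.0,
    band_hz: tuple[float, float] = (0.6, 4.0),
    n_grid: int = 4096,
    bg_min_radius: float = 0.8,
    radius_tol: float = 0.1,
) -> float | None:
    """Beats/min via AR pole cancellation against the background ROI.

    Fits order-8 AR models to the paired subject and background windows,
    cancels shared poles, and reads the heart rate off the band-restricted
    peak of the reconstructed power spectrum. Returns None when
    cancellation removes everything or no in-band peak remains.
    """
    try:
        subject = fit_ar(subject_window, fps, order)
        background = fit_ar(background_window, fps, order)
        reduced = ark_cancel(subject, background, tol_deg, bg_min_radius, radius_tol)
    except (ValueError, np.linalg.LinAlgError):
        return None
    freqs, power = reduced.power_spectrum(n_grid)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        return None
    k = np.flatnonzero(in_band)[np.argmax(power[in_band])]
    return float(freqs[k] * 60.0)
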