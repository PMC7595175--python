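"""Respiratory-rate estimation from face PPGi and torso motion signals.

Two physical sources carry the breathing signal: the amplitude of the
cardiac pulse in facial PPGi is modulated by respiration (RIAV --
respiratory-induced amplitude variation), and clothing over the upper
torso moves with the thorax. Candidate respiratory series from many
ROIs are reduced by PCA to at most five components with in-band frequency
content (6-42 breaths/min), gated by a quality rule combining the
Spectral Purity Index, the variance explained and an in-band SNR, and the
surviving components are tracked per 30-s window (5-s step) with an
order-8 AR model and fused across components with the residual-weighted
Kalman scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from sklearn.decomposition import PCA

from .beats import BeatRecord
from .heart_rate import VitalEstimate, fit_ar
from .fusion import fuse_kalman_nd


@dataclass
class RespSignal:
    """One candidate or principal-component respiratory series at 4 Hz."""

    samples: np.ndarray
    fs: float
    source: str                  # "face" or "torso"
    pca_rank: int = -1
    variance_explained: float = 1.0
    dominant_freq: float | None = None
    t0: float = 0.0              # session time of the first sample, seconds


@dataclass
class SpectralPurity:
    """SPI and the spectral moments it is built from."""

    spi: float
    w0: float
    w2: float
    w4: float


def _refine_extremum(x: np.ndarray, i: int) -> float:
    """Parabolic (sub-sample) estimate of the extremum value at sample i."""
    if i < 1 or i > len(x) - 2:
        return float(x[i])
    a, b, c = x[i - 1], x[i], x[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return float(b)
    delta = 0.5 * (a - c) / denom
    if not (-1.0 < delta < 1.0):
        return float(b)
    return float(b - 0.25 * (a - c) * delta)


def riav_extract(
    beats: list[BeatRecord],
    ppgi: np.ndarray,
    fps: float,
    resample_hz: float = 4.0,
    duration_s: float | None = None,
    min_beats: int = 4,
    edge_guard_s: float = 2.0,
) -> RespSignal | None:
    """Beat-amplitude series resampled to a uniform grid.

    The amplitude of each pulse (peak value minus onset value) is placed at
    the peak time and linearly interpolated onto a uniform ``resample_hz``
    grid. Beats within ``edge_guard_s`` of the series edges are skipped
    (zero-phase filtering leaves transients there that corrupt the
    amplitudes). Fewer than ``min_beats`` usable beats yield no signal.
    """
    x = np.asarray(ppgi, dtype=float)
    guard = int(round(edge_guard_s * fps))
    t_amp, amp = [], []
    for b in beats:
        if b.peak is None:
            continue
        end = b.next_onset if b.next_onset is not None else b.peak
        if b.onset < guard or end > len(x) - guard:
            continue
        t_amp.append(b.peak / fps)
        # sub-sample refinement: sampled extremum values alternate
        # beat-to-beat when the pulse period is a non-integer number of
        # frames, planting a spurious tone at half the beat rate
        amp.append(_refine_extremum(x, b.peak) - _refine_extremum(x, b.onset))
    if len(amp) < min_beats:
        return None
    if duration_s is None:
        duration_s = len(x) / fps
    grid = np.arange(edge_guard_s, duration_s - edge_guard_s, 1.0 / resample_hz)
    if len(grid) == 0:
        return None
    series = np.interp(grid, np.asarray(t_amp), np.asarray(amp))
    return RespSignal(samples=series, fs=resample_hz, source="face", t0=float(grid[0]))


def dominant_frequency(x: np.ndarray, fs: float, zero_pad_factor: int = 4) -> float | None:
    """FFT peak frequency of a mean-removed series."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return None
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(max(zero_pad_factor * n, 2))))
    spec = np.abs(np.fft.rfft(x * np.hanning(n), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    spec[0] = 0.0
    return float(freqs[np.argmax(spec)])


def smooth_resp(x: np.ndarray, fs: float, lowpass_hz: float = 1.0) -> np.ndarray:
    """Detrend and low-pass a candidate respiratory series.

    Only the respiratory band carries information in these series
    (beat-amplitude noise is broadband, torso series leak cardiac motion);
    the zero-phase low-pass keeps the spectral-purity gate meaningful.
    """
    x = sig.detrend(np.asarray(x, dtype=float), type="linear")
    b, a = sig.butter(4, lowpass_hz / (fs / 2.0))
    return sig.filtfilt(b, a, x)


def pca_components(
    candidates: list[RespSignal],
    k: int = 5,
    band_hz: tuple[float, float] = (0.1, 0.7),
) -> list[RespSignal]:
    """First in-band principal components of the candidate series.

    Candidates are mean-centred and decomposed with PCA; components are
    scanned in descending-variance order and kept (up to ``k``) when their
    dominant frequency falls inside the respiratory band.
    """
    if len(candidates) < 2:
        raise ValueError("PCA selection needs at least two candidate series")
    fs = candidates[0].fs
    source = candidates[0].source
    data = np.column_stack([c.samples for c in candidates])
    data = data - data.mean(axis=0)
    pca = PCA(n_components=min(data.shape))
    scores = pca.fit_transform(data)
    out: list[RespSignal] = []
    for rank in range(scores.shape[1]):
        if len(out) >= k:
            break
        comp = scores[:, rank]
        f = dominant_frequency(comp, fs)
        if f is None or not (band_hz[0] <= f <= band_hz[1]):
            continue
        out.append(
            RespSignal(
                samples=comp,
                fs=fs,
                source=source,
                pca_rank=rank,
                variance_explained=float(pca.explained_variance_ratio_[rank]),
                dominant_freq=f,
                t0=candidates[0].t0,
            )
        )
    return out


def spectral_purity(x: np.ndarray, fs: float, zero_pad_factor: int = 4) -> SpectralPurity:
    """Spectral Purity Index: ``w2^2 / (w0 * w4)`` over spectral moments.

    Moments are discrete sums of the Hann-tapered periodogram against
    powers of the normalised angular frequency; the index tends to 1 for a
    single noise-free sinusoid and falls towards 0 as bandwidth grows. A
    zero-power window is undefined and scored 0.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if np.allclose(x, 0.0):
        return SpectralPurity(spi=0.0, w0=0.0, w2=0.0, w4=0.0)
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(max(zero_pad_factor * n, 2))))
    spec = np.abs(np.fft.rfft(x * np.hanning(n), nfft)) ** 2
    omega = 2.0 * np.pi * np.fft.rfftfreq(nfft)  # rad/sample in [0, pi]
    w0 = float(np.sum(spec))
    w2 = float(np.sum(omega**2 * spec))
    w4 = float(np.sum(omega**4 * spec))
    spi = w2 * w2 / (w0 * w4) if w0 > 0 and w4 > 0 else 0.0
    return SpectralPurity(spi=spi, w0=w0, w2=w2, w4=w4)


def resp_sqi(
    component: RespSignal,
    window: np.ndarray | None = None,
    band_hz: tuple[float, float] = (0.1, 0.7),
    var_explained_min: float = 0.3,
    snr_min: float = 1.0,
    snr_peak_halfwidth_hz: float = 0.05,
) -> float:
    """Window quality for one PCA component: SPI gated by three rules.

    The score equals the SPI when the FFT peak is inside the respiratory
    band, the component explains more than 30% of the total variance, and
    the in-band SNR (power within ±0.05 Hz of the peak over the remaining
    in-band power) exceeds 1; otherwise 0.
    """
    x = component.samples if window is None else np.asarray(window, dtype=float)
    fs = component.fs
    f_peak = dominant_frequency(x, fs)
    if f_peak is None or not (band_hz[0] <= f_peak <= band_hz[1]):
        return 0.0
    if component.variance_explained <= var_explained_min:
        return 0.0
    # in-band SNR around the peak
    xm = x - x.mean()
    n = len(xm)
    nfft = int(2 ** np.ceil(np.log2(max(4 * n, 2))))
    spec = np.abs(np.fft.rfft(xm * np.hanning(n), nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    near_peak = in_band & (np.abs(freqs - f_peak) <= snr_peak_halfwidth_hz)
    rest = in_band & ~near_peak
    rest_power = float(spec[rest].sum())
    peak_power = float(spec[near_peak].sum())
    snr = peak_power / rest_power if rest_power > 0 else np.inf
    if snr <= snr_min:
        return 0.0
    return spectral_purity(x, fs).spi


def rr_from_window(
    window: np.ndarray,
    fs: float,
    order: int = 8,
    band_hz: tuple[float, float] = (0.1, 0.7),
    support_fraction: float = 0.25,
) -> float | None:
    """Breaths/min from the dominant in-band AR pole of one window.

    Pole radius alone is fragile when a weak but perfectly narrowband
    artefact line shares the band with the (modulation-broadened)
    respiratory peak, so candidate poles must also carry periodogram
    support: at least ``support_fraction`` of the in-band spectral maximum
    at the pole's frequency. Among supported in-band poles the
    largest-radius one wins.
    """
    x = np.asarray(window, dtype=float)
    try:
        model = fit_ar(x, fs, order)
    except (ValueError, np.linalg.LinAlgError):
        return None
    freqs = model.pole_freqs_hz()
    radii = np.abs(model.poles)
    mask = (freqs > 0) & (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not mask.any():
        return None
    xm = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(max(4 * len(xm), 2))))
    spec = np.abs(np.fft.rfft(xm * np.hanning(len(xm)), nfft)) ** 2
    grid = np.fft.rfftfreq(nfft, 1.0 / fs)
    in_band = (grid >= band_hz[0]) & (grid <= band_hz[1])
    ref = float(spec[in_band].max()) if in_band.any() else 0.0
    cands = []
    for k in np.flatnonzero(mask):
        support = float(np.interp(freqs[k], grid, spec))
        if ref <= 0 or support >= support_fraction * ref:
            cands.append(k)
    if not cands:
        return None
    k = cands[int(np.argmax(radii[cands]))]
    return float(freqs[k] * 60.0)


def rr_estimate(
    components: list[RespSignal],
    group: str,
    window_s: float = 30.0,
    step_s: float = 5.0,
    order: int = 8,
    band_hz: tuple[float, float] = (0.1, 0.7),
    var_explained_min: float = 0.3,
    snr_min: float = 1.0,
    kalman_kwargs: dict | None = None,
) -> list[VitalEstimate]:
    """Respiratory-rate stream for one component group.

    Each gated component contributes a per-window AR rate; the component
    streams are fused with the residual/SQI-weighted Kalman scheme and the
    estimates timestamped at window centres, every ``step_s`` seconds.
    """
    if not components:
        return []
    fs = components[0].fs
    n = min(len(c.samples) for c in components)
    wlen = int(round(window_s * fs))
    step = max(1, int(round(step_s * fs)))
    if n < wlen:
        return []
    starts = list(range(0, n - wlen + 1, step))
    t0 = components[0].t0
    times = np.asarray([t0 + (s + wlen / 2.0) / fs for s in starts])

    streams: dict[str, list[float | None]] = {}
    sqis: dict[str, list[float]] = {}
    rr_band = (band_hz[0] * 60.0, band_hz[1] * 60.0)
    for ci, comp in enumerate(components):
        vals: list[float | None] = []
        qs: list[float] = []
        for s in starts:
            win = comp.samples[s : s + wlen]
            q = resp_sqi(comp, window=win, band_hz=band_hz,
                         var_explained_min=var_explained_min, snr_min=snr_min)
            rr = rr_from_window(win, fs, order, band_hz) if q > 0 else None
            if rr is not None and not (rr_band[0] <= rr <= rr_band[1]):
                rr = None
            vals.append(rr)
            qs.append(q if rr is not None else 0.0)
        streams[f"{group}:{ci}"] = vals
        sqis[f"{group}:{ci}"] = qs

    fused = fuse_kalman_nd(times, streams, sqis, kalman_kwargs=kalman_kwargs)
    for est in fused:
        est.method = "kalmanNd"
        est.source = group
    return fused


def torso_candidates(
    series: dict,
    fps: float,
    lowpass_hz: float = 1.0,
    resample_hz: float = 4.0,
    edge_guard_s: float = 2.0,
) -> list[RespSignal]:
    """Prepare torso grey-ROI series for PCA selection.

    Each series is linearly detrended, low-passed (to stop any cardiac
    leakage) and resampled to the common 4-Hz respiratory grid; the edges
    are cropped to match the face RIAV grid.
    """
    out = []
    guard = int(round(edge_guard_s * resample_hz))
    for key in sorted(series):
        x = smooth_resp(series[key], fps, lowpass_hz)
        x4 = sig.resample_poly(x, int(resample_hz), int(fps))
        if guard > 0:
            x4 = x4[guard:-guard] if len(x4) > 2 * guard else x4
        out.append(RespSignal(samples=x4, fs=resample_hz, source="torso",
                              t0=edge_guard_s))
    return out
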