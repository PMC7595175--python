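"""ROI layout, activity index and band-limited PPGi extraction.

The face box is tiled into a 9x9 grid of subject ROIs; per-frame mean
intensities from each tile form the raw PPGi series. Patient motion is
quantified from the frame-to-frame displacement of the face centroid and
thresholded into a binary activity index; sessions that are stable for less
than one-third of their length are discarded outright. Raw series are
linearly detrended and band-passed to the cardiac band (0.6-4 Hz,
36-240 beats/min) with a zero-phase FIR filter before any beat analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import GRAY_WEIGHTS


@dataclass
class ActivityIndex:
    """Per-frame stability flag (1 = stable) and motion magnitude in px."""

    act: np.ndarray      # uint8, 0 during high motion
    motion: np.ndarray   # float px; NaN where a centroid was missing

    def __len__(self) -> int:
        return len(self.act)


def compute_motion(centroids: np.ndarray) -> np.ndarray:
    """Euclidean distance in pixels between consecutive face centroids.

    The first frame has no predecessor and is assigned 0. Frames with a
    missing centroid (NaN) yield NaN motion for themselves and their
    successor.
    """
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2 or len(c) < 2:
        raise ValueError("centroids must be an (n>=2, 2) array")
    motion = np.empty(len(c))
    motion[0] = 0.0
    motion[1:] = np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1]))
    return motion


def compute_activity(motion: np.ndarray, threshold_px: float = 100.0) -> ActivityIndex:
    """Binary activity index: 0 where motion strictly exceeds the threshold.

    Missing (NaN) motion is treated as active (0): a frame without a
    tracked face cannot be used for vital-sign estimation.
    """
    m = np.asarray(motion, dtype=float)
    act = np.ones(len(m), dtype=np.uint8)
    act[np.isnan(m) | (m > threshold_px)] = 0
    return ActivityIndex(act=act, motion=m)


def session_valid(activity: ActivityIndex, min_stable_fraction: float = 1.0 / 3.0) -> bool:
    """True when at least the required fraction of frames are stable."""
    if len(activity) == 0:
        raise ValueError("empty session")
    return float(np.mean(activity.act)) >= min_stable_fraction


def rgb_to_gray(r, g, b):
    """Luma grey level from RGB intensities (ITU-R 601 weights)."""
    wr, wg, wb = GRAY_WEIGHTS
    return wr * np.asarray(r) + wg * np.asarray(g) + wb * np.asarray(b)


def roi_grid(face_box: tuple[int, int, int, int], n: int = 9) -> list[tuple[int, int, int, int]]:
    """Tile a face bounding box into an ``n x n`` grid of subject ROIs.

    ``face_box`` is ``(x, y, width, height)`` in pixels. Tiles are returned
    row-major with integer edges; remainder pixels are absorbed by the last
    row and column so the tiles are disjoint and exactly cover the box.
    """
    x0, y0, w, h = face_box
    if w < n or h < n:
        raise ValueError(f"face box must be at least {n}x{n} pixels")
    xs = [x0 + (w // n) * i for i in range(n)] + [x0 + w]
    ys = [y0 + (h // n) * j for j in range(n)] + [y0 + h]
    tiles = []
    for j in range(n):          # rows
        for i in range(n):      # columns
            tiles.append((xs[i], ys[j], xs[i + 1] - xs[i], ys[j + 1] - ys[j]))
    return tiles


def roi_means(frame: np.ndarray, tiles) -> np.ndarray:
    """Mean intensity of one (grey or single-channel) frame over each tile."""
    out = np.empty(len(tiles))
    for k, (x, y, w, h) in enumerate(tiles):
        out[k] = float(frame[y : y + h, x : x + w].mean())
    return out


def design_bandpass(fps: float, band_hz=(0.6, 4.0)) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR band-pass taps for the cardiac band."""
    if fps < 2.0 * band_hz[1]:
        raise ValueError("fps too low: upper band edge above Nyquist")
    order = int(round(4 * fps / 2) * 2)  # even order -> odd tap count (type I)
    return signal.firwin(order + 1, list(band_hz), fs=fps, pass_zero=False, window="hamming")


def band_limit(series: np.ndarray, fps: float, band_hz=(0.6, 4.0)) -> np.ndarray:
    """Linear-detrend then zero-phase band-pass one raw intensity series.

    The filter is applied forward-backward (``filtfilt``), so onset timing
    is not biased by phase distortion; output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    taps = design_bandpass(fps, band_hz)
    if len(x) <= 3 * len(taps):
        raise ValueError("series too short for the band-pass filter warm-up")
    x = signal.detrend(x, type="linear")
    return signal.filtfilt(taps, [1.0], x)
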