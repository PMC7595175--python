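"""Beat-by-beat signal quality: pulse templates, multi-scale DTW, SQIs.

Each 30-s window (5-s step) gets a pulse template built in three stages
(physiological inter-beat interval; cross-correlation > 0.8 with the
stage-1 template; amplitude below three standard deviations of the
stage-2-valid beats), each stage requiring at least half the window's
beats to survive. Every beat is then compared with the template by a
dynamic time warping variant whose local cost is the absolute difference
of slopes, run coarse-to-fine on piecewise-linear approximations with the
refinement confined to a band around the projected path.

Six quality indices are combined multiplicatively into a per-beat score:
five binary gates (motion, step change, physiological rate, amplitude,
clipping) and the continuous DTW similarity ``1 - cost/100`` (clamped at
zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .beats import BeatRecord


# --------------------------------------------------------------------------
# domain types

@dataclass
class QualityFlags:
    """Per-beat quality components; ``sqi_beat`` is their product."""

    sqi_act: int = 1
    sqi_cp: int = 1
    sqi_freq: int = 1
    sqi_amp: int = 1
    sqi_clip: int = 1
    sqi_dtw: float = 0.0

    @property
    def sqi_beat(self) -> float:
        return (
            self.sqi_act
            * self.sqi_cp
            * self.sqi_freq
            * self.sqi_amp
            * self.sqi_clip
            * self.sqi_dtw
        )


@dataclass
class PulseTemplate:
    samples: np.ndarray | None
    length: int
    peak_pos: int
    stage_reached: int
    valid: bool
    retained: list[int] = field(default_factory=list)  # beat indices kept at the last stage


@dataclass
class DTWResult:
    cost: float
    path: list[tuple[int, int]]
    scales_used: int
    degenerate: bool = False


# --------------------------------------------------------------------------
# DTW

def rotate_normalise(x: np.ndarray) -> np.ndarray | None:
    """Remove the endpoint-to-endpoint linear trend and scale to [0, 1].

    Returns None for degenerate (constant after rotation) inputs.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return None
    trend = x[0] + (x[-1] - x[0]) * np.arange(n) / (n - 1)
    y = x - trend
    rng = np.ptp(y)
    if rng <= 0 or not np.isfinite(rng):
        return None
    return (y - y.min()) / rng


def _slope_cost_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = np.diff(x)
    dy = np.diff(y)
    return np.abs(dx[:, None] - dy[None, :])


def _dp(cost: np.ndarray, allowed: np.ndarray | None = None):
    """Classical DTW dynamic programme; optionally restricted to a mask."""
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    ok = allowed if allowed is not None else np.ones((n, m), dtype=bool)
    if not ok[0, 0] or not ok[n - 1, m - 1]:
        ok = ok.copy()
        ok[0, 0] = ok[n - 1, m - 1] = True
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if (i == 0 and j == 0) or not ok[i, j]:
                continue
            best = np.inf
            if i > 0 and acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if j > 0 and acc[i, j - 1] < best:
                best = acc[i, j - 1]
            if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                best = acc[i - 1, j - 1]
            if np.isfinite(best):
                acc[i, j] = cost[i, j] + best
    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        cands = []
        if i > 0 and j > 0:
            cands.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            cands.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            cands.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(cands, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    return float(acc[n - 1, m - 1]), path


def dtw_full(x: np.ndarray, y: np.ndarray) -> DTWResult:
    """Unconstrained DTW on slope sequences (the exact reference)."""
    cost, path = _dp(_slope_cost_matrix(x, y))
    return DTWResult(cost=cost, path=path, scales_used=1)


def _halve(x: np.ndarray) -> np.ndarray:
    """One piecewise-linear coarsening step: average adjacent samples."""
    n = 2 * (len(x) // 2)
    return x[:n].reshape(-1, 2).mean(axis=1)


def multiscale_dtw(
    beat: np.ndarray,
    template: np.ndarray,
    band: int | None = 2,
    min_scale_len: int = 16,
    max_cost: float = 100.0,
) -> DTWResult:
    """Coarse-to-fine DTW between a beat and the window template.

    Both inputs are rotated and amplitude-normalised before costing; the
    local cost is the absolute slope difference. Series are halved
    (piecewise-linear approximation) until shorter than ``min_scale_len``;
    the optimal path found at the coarsest scale is projected one scale up
    and refined within ``band`` cells of the projection. ``band=None``
    disables the constraint, reproducing classical DTW exactly.

    Degenerate (constant) beats return the max-cost sentinel.
    """
    xb = rotate_normalise(beat)
    yt = rotate_normalise(template)
    if xb is None or yt is None:
        return DTWResult(cost=max_cost, path=[], scales_used=0, degenerate=True)

    if band is None:
        return dtw_full(xb, yt)

    # build the scale pyramid (finest first)
    xs, ys = [xb], [yt]
    while len(xs[-1]) >= 2 * min_scale_len and len(ys[-1]) >= 2 * min_scale_len:
        xs.append(_halve(xs[-1]))
        ys.append(_halve(ys[-1]))

    # coarsest scale: unconstrained DP
    cost, path = _dp(_slope_cost_matrix(xs[-1], ys[-1]))
    for level in range(len(xs) - 2, -1, -1):
        cm = _slope_cost_matrix(xs[level], ys[level])
        n, m = cm.shape
        allowed = np.zeros((n, m), dtype=bool)
        for (i, j) in path:
            for di in range(-band, band + 2):
                for dj in range(-band, band + 2):
                    ii, jj = 2 * i + di, 2 * j + dj
                    if 0 <= ii < n and 0 <= jj < m:
                        allowed[ii, jj] = True
        cost, path = _dp(cm, allowed)
    return DTWResult(cost=cost, path=path, scales_used=len(xs))


# --------------------------------------------------------------------------
# template construction

def _beat_segments(beats: "list[BeatRecord]", x: np.ndarray):
    segs, peaks = [], []
    for b in beats:
        end = b.next_onset if b.next_onset is not None else None
        seg = np.asarray(x[b.onset : end], dtype=float)
        segs.append(seg)
        peaks.append((b.peak - b.onset) if b.peak is not None else int(np.argmax(seg)))
    return segs, peaks


def _average_aligned(segs, peak_offsets, length: int, peak_pos: int) -> np.ndarray:
    total = np.zeros(length)
    count = np.zeros(length)
    for seg, p in zip(segs, peak_offsets):
        off = peak_pos - p
        lo = max(0, off)
        hi = min(length, off + len(seg))
        if hi <= lo:
            continue
        total[lo:hi] += seg[lo - off : hi - off]
        count[lo:hi] += 1
    out = np.zeros(length)
    np.divide(total, count, out=out, where=count > 0)
    return out


def build_template(
    beats: "list[BeatRecord]",
    x: np.ndarray,
    hr_band: tuple[float, float] = (36.0, 240.0),
    xcorr_min: float = 0.8,
    min_valid_fraction: float = 0.5,
) -> PulseTemplate:
    """Three-stage pulse template for one 30-s window.

    Stages: (1) physiological inter-beat rate, (2) cross-correlation with
    the stage-1 template above ``xcorr_min``, (3) amplitude below three
    standard deviations of the stage-2-valid beats. Each stage must retain
    at least ``min_valid_fraction`` of the window's beats, beats are
    aligned at their peaks, and the template length is the median beat
    length.
    """
    n_total = len(beats)
    if n_total < 2:
        return PulseTemplate(None, 0, 0, stage_reached=0, valid=False)
    segs, peak_offsets = _beat_segments(beats, x)
    length = int(round(np.median([len(s) for s in segs])))
    peak_pos = int(round(np.median(peak_offsets)))

    def enough(idx):
        return len(idx) / n_total >= min_valid_fraction

    # stage 1: inter-beat interval within the physiological band
    s1 = [k for k, b in enumerate(beats)
          if b.hr_inst is not None and hr_band[0] <= b.hr_inst <= hr_band[1]]
    if not enough(s1):
        return PulseTemplate(None, length, peak_pos, stage_reached=1, valid=False)
    t1 = _average_aligned([segs[k] for k in s1], [peak_offsets[k] for k in s1],
                          length, peak_pos)

    # stage 2: zero-lag cross-correlation with the stage-1 template
    s2 = []
    for k in s1:
        seg, p = segs[k], peak_offsets[k]
        off = peak_pos - p
        lo, hi = max(0, off), min(length, off + len(seg))
        if hi - lo < 3:
            continue
        a = seg[lo - off : hi - off]
        b = t1[lo:hi]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        if np.corrcoef(a, b)[0, 1] > xcorr_min:
            s2.append(k)
    if not enough(s2):
        return PulseTemplate(None, length, peak_pos, stage_reached=2, valid=False)

    # stage 3: amplitude below 3 SD of the stage-2-valid beats
    pooled = np.concatenate([segs[k] - segs[k].mean() for k in s2])
    sigma = float(np.std(pooled))
    s3 = [k for k in s2 if np.max(np.abs(segs[k] - segs[k].mean())) < 3.0 * sigma]
    if not enough(s3):
        return PulseTemplate(None, length, peak_pos, stage_reached=3, valid=False)
    t3 = _average_aligned([segs[k] for k in s3], [peak_offsets[k] for k in s3],
                          length, peak_pos)
    return PulseTemplate(t3, length, peak_pos, stage_reached=3, valid=True, retained=s3)


# --------------------------------------------------------------------------
# per-beat scoring

def clipped_fraction(
    seg: np.ndarray,
    window: np.ndarray,
    deriv_rel_threshold: float = 0.1,
    extreme_fraction: float = 0.1,
) -> float:
    """Fraction of a beat's derivative samples that look saturated.

    The beat is normalised by the window's min-max range; a derivative
    sample counts as clipped when its magnitude is below
    ``deriv_rel_threshold`` times the window's maximum derivative while the
    signal sits within ``extreme_fraction`` of the window's extrema.
    """
    rng = np.ptp(window)
    if rng <= 0:
        return 1.0
    wn = (window - window.min()) / rng
    xn = (seg - window.min()) / rng
    dx = np.abs(np.diff(xn))
    if len(dx) == 0:
        return 1.0
    dmax = float(np.max(np.abs(np.diff(wn))))
    near_extreme = (xn[1:] > 1.0 - extreme_fraction) | (xn[1:] < extreme_fraction)
    clipped = (dx < deriv_rel_threshold * dmax) & near_extreme
    return float(np.mean(clipped))


def score_beat(
    beat: "BeatRecord",
    x: np.ndarray,
    template: PulseTemplate,
    act: np.ndarray,
    step_prob: np.ndarray,
    window_slice: slice,
    hr_band: tuple[float, float] = (36.0, 240.0),
    step_prob_threshold: float = 0.8,
    dtw_cost_scale: float = 100.0,
    dtw_band: int | None = 2,
    dtw_min_scale_len: int = 16,
    clip_deriv_rel_threshold: float = 0.1,
    clip_extreme_fraction: float = 0.1,
    clip_run_fraction: float = 1.0 / 3.0,
) -> QualityFlags:
    """Six-component quality score for one beat against its window context.

    ``x`` is the band-limited PPGi series; ``window_slice`` delimits the
    30-s window the beat was assigned to (amplitude statistics and the
    clipping reference are computed over it). A missing or invalid template
    rejects the beat outright.
    """
    flags = QualityFlags()
    end = beat.next_onset if beat.next_onset is not None else beat.onset + 1
    seg = np.asarray(x[beat.onset : end], dtype=float)
    win = np.asarray(x[window_slice], dtype=float)

    if np.any(act[beat.onset : end] == 0):
        flags.sqi_act = 0
    if np.any(step_prob[beat.onset : end] > step_prob_threshold):
        flags.sqi_cp = 0
    if beat.hr_inst is None or not (hr_band[0] <= beat.hr_inst <= hr_band[1]):
        flags.sqi_freq = 0
    mu, sd = float(np.mean(win)), float(np.std(win))
    if np.any(seg < mu - 3 * sd) or np.any(seg > mu + 3 * sd):
        flags.sqi_amp = 0
    frac = clipped_fraction(seg, win, clip_deriv_rel_threshold, clip_extreme_fraction)
    if frac > clip_run_fraction:
        flags.sqi_clip = 0

    if not template.valid or template.samples is None:
        flags.sqi_dtw = 0.0
    else:
        res = multiscale_dtw(seg, template.samples, band=dtw_band,
                             min_scale_len=dtw_min_scale_len, max_cost=dtw_cost_scale)
        flags.sqi_dtw = dtw_score(res.cost, dtw_cost_scale)
    return flags


def dtw_score(cost: float, scale: float = 100.0) -> float:
    """DTW similarity ``1 - cost/scale``, clamped to [0, 1]."""
    return float(max(0.0, 1.0 - cost / scale))


def window_sqi(beats: "list[BeatRecord]") -> float:
    """Window quality: arithmetic mean of the per-beat combined SQI."""
    if not beats:
        return 0.0
    return float(np.mean([b.sqi_beat for b in beats]))
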