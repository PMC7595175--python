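"""Pulse onset and peak detection via the slope sum function (SSF).

The band-limited PPGi waveform is transformed into a slope sum function
that accumulates only positive first differences over a trailing window
matched to the pulse upslope (170 ms at a resting heart rate). The SSF is
segmented into "boxes" between zero-level crossings (BSSF); only the rising
half of each box (uBSSF) is fed to an adaptive amplitude threshold that
declares beat onsets. Peaks are then the waveform maxima between
consecutive onsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .quality import QualityFlags


@dataclass
class BeatRecord:
    """One detected pulse."""

    onset: int                  # sample index
    peak: int | None = None     # sample index of the waveform maximum
    next_onset: int | None = None
    hr_inst: float | None = None  # beats/min from the inter-onset interval
    sqi: "QualityFlags | None" = None

    @property
    def sqi_beat(self) -> float:
        return 0.0 if self.sqi is None else self.sqi.sqi_beat


@dataclass
class Box:
    """One SSF excursion above zero: [start, end) with its internal peak."""

    start: int
    end: int
    argmax: int


def slope_sum(x: np.ndarray, fps: float, window_s: float = 0.170) -> np.ndarray:
    """SSF: trailing-window sum of positive first differences.

    The window length is ``round(window_s * fps)`` samples (the upslope
    duration of an adult pulse at 60 beats/min). The first samples use the
    available prefix.
    """
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(window_s * fps)))
    u = np.diff(x, prepend=x[:1])
    u[u < 0] = 0.0
    c = np.concatenate(([0.0], np.cumsum(u)))
    ssf = np.empty(len(x))
    ssf[:w] = c[1 : w + 1]           # prefix sums during warm-up
    ssf[w:] = c[w + 1 :] - c[1 : len(x) - w + 1]
    return ssf


def ssf_zero_level(ssf: np.ndarray, fps: float, span_s: float = 2.0,
                   fraction: float = 0.2) -> np.ndarray:
    """Adaptive per-sample "zero" level for SSF box segmentation.

    Two regimes break a literal zero-crossing rule: measurement noise keeps
    the SSF slightly positive between pulses (spurious boxes), and at high
    heart rates consecutive upslopes arrive inside the SSF window so the
    SSF floor never reaches zero (merged boxes). The level therefore sits a
    fixed fraction of the way between the rolling minimum and maximum of
    the SSF over a span longer than the longest physiological beat.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    size = max(3, int(round(span_s * fps)))
    lo = minimum_filter1d(ssf, size)
    hi = maximum_filter1d(ssf, size)
    return lo + fraction * (hi - lo)


def boxed_ssf(ssf: np.ndarray, zero_level: float | np.ndarray = 0.0) -> list[Box]:
    """Segment the SSF into boxes between zero-level crossings.

    ``zero_level`` sets the level treated as "zero" (scalar or per-sample,
    see :func:`ssf_zero_level`).
    """
    pos = np.asarray(ssf) > zero_level
    if not pos.any():
        return []
    edges = np.flatnonzero(np.diff(pos.astype(np.int8)))
    starts = list(edges[~pos[edges]] + 1)
    ends = list(edges[pos[edges]] + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        ends.append(len(pos))
    ssf = np.asarray(ssf)
    boxes = []
    prev_end = 0
    for s, e in zip(starts, ends):
        # the level crossing sits partway up the SSF rise; walk back to the
        # preceding local minimum, then start the box at the first rising
        # sample after the trough
        s0 = s
        while s > prev_end and ssf[s - 1] < ssf[s]:
            s -= 1
        if s < s0:
            s += 1
        boxes.append(Box(start=s, end=e, argmax=s + int(np.argmax(ssf[s:e]))))
        prev_end = e
    return boxes


def ubssf_points(ssf: np.ndarray, boxes: list[Box]):
    """Upslope (rising-half) points of each box: (sample index, value, box id)."""
    for b_id, b in enumerate(boxes):
        for i in range(b.start, b.argmax + 1):
            yield i, ssf[i], b_id


def detect_onsets(
    x: np.ndarray,
    fps: float,
    window_s: float = 0.170,
    init_s: float = 30.0,
    refractory_s: float = 0.25,
    decay: str = "multiplicative",
) -> list[int]:
    """Adaptive-threshold beat onset detection on the uBSSF signal.

    The threshold starts at the median of the first ``init_s`` seconds of
    uBSSF values. Each uBSSF point above the threshold declares an onset at
    the first sample of its box and raises the threshold by 10% of the
    excess; each point below decays the threshold by 10% (multiplicative by
    default, subtractive selectable). One onset per box; onsets closer than
    the refractory period (240 beats/min) to the previous one are
    suppressed.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < int(init_s * fps):
        raise ValueError(f"need at least {init_s:g} s of data to initialise the threshold")
    ssf = slope_sum(x, fps, window_s)
    boxes = boxed_ssf(ssf, ssf_zero_level(ssf, fps))
    if not boxes:
        return []
    init_end = int(init_s * fps)
    init_vals = [v for i, v, _ in ubssf_points(ssf, boxes) if i < init_end]
    if not init_vals:
        return []
    threshold = float(np.median(init_vals))
    refractory = int(round(refractory_s * fps))
    onsets: list[int] = []
    fired_box = -1
    for i, v, b_id in ubssf_points(ssf, boxes):
        if b_id == fired_box:
            continue
        if v > threshold:
            onset = boxes[b_id].start
            if not onsets or onset - onsets[-1] >= refractory:
                onsets.append(onset)
            threshold += 0.1 * (v - threshold)
            fired_box = b_id
        else:
            if decay == "multiplicative":
                threshold *= 0.9
            else:  # subtract 10% of the shortfall instead
                threshold -= 0.1 * (threshold - v)
    return onsets


def detect_peaks(x: np.ndarray, onsets: list[int]) -> list[int]:
    """Peak per onset pair: argmax of the waveform in (onset_k, onset_{k+1}).

    Ties take the earliest index; the last onset has no successor and emits
    no peak.
    """
    x = np.asarray(x, dtype=float)
    peaks = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        lo = a + 1
        peaks.append(lo + int(np.argmax(x[lo:b])) if b > lo else a)
    return peaks


def detect_beats(
    x: np.ndarray,
    fps: float,
    window_s: float = 0.170,
    init_s: float = 30.0,
    refractory_s: float = 0.25,
    decay: str = "multiplicative",
) -> list[BeatRecord]:
    """Full beat detection: onsets, peaks and instantaneous heart rate."""
    onsets = detect_onsets(x, fps, window_s, init_s, refractory_s, decay)
    peaks = detect_peaks(x, onsets)
    beats = []
    for k, onset in enumerate(onsets[:-1]):
        nxt = onsets[k + 1]
        beats.append(
            BeatRecord(
                onset=onset,
                peak=peaks[k],
                next_onset=nxt,
                hr_inst=60.0 * fps / (nxt - onset),
            )
        )
    return beats
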