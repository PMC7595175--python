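"""Data fusion of per-ROI heart-rate estimates.

Three strategies, in increasing sophistication:

* **median** -- the median of per-ROI estimates whose window SQI exceeds
  0.8, with the window SQI taken as the median of all per-ROI SQIs;
* **Kalman 1D** -- a scalar Kalman filter tracking the median-fused
  stream, with process noise switched between quiet (Q=0.1) and motion
  (Q=0.2) periods and the measurement noise inflated by
  ``exp(1/SQI^2 - 1)`` so poor-quality windows defer to the prediction;
* **Kalman ND** -- one filter per (ROI, channel) stream, combined by
  inverse-variance weights built from each filter's innovation scaled by
  its SQI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .heart_rate import VitalEstimate


@dataclass
class KalmanState:
    """Scalar Kalman filter state for one vital-sign stream."""

    q_quiet: float = 0.1
    q_motion: float = 0.2
    r_base: float = 4.0
    init_p: float = 100.0
    x_hat: float | None = None
    p: float = 100.0
    residual: float = 0.0
    last_time: float | None = None

    @property
    def initialized(self) -> bool:
        return self.x_hat is not None

    def reset(self) -> None:
        self.x_hat = None
        self.p = self.init_p
        self.residual = 0.0
        self.last_time = None


def measurement_noise(r_base: float, sqi: float) -> float:
    """SQI-inflated measurement noise ``R_base * exp(1/SQI^2 - 1)``.

    Equal to ``r_base`` exactly at SQI = 1 and divergent as SQI -> 0.
    """
    if not (0.0 < sqi <= 1.0):
        raise ValueError("sqi must be in (0, 1]")
    return r_base * float(np.exp(1.0 / (sqi * sqi) - 1.0))


def kalman_update(
    state: KalmanState,
    z: float | None,
    sqi: float,
    moving: bool = False,
) -> KalmanState:
    """One predict(+update) step; mutates and returns ``state``.

    ``sqi = 0`` (or a missing measurement) skips the update entirely and
    performs a prediction-only step: with an identity state transition the
    estimate is held and only the error variance grows.
    """
    q = state.q_motion if moving else state.q_quiet
    if state.x_hat is None:
        if z is not None and sqi > 0:
            state.x_hat = float(z)
            state.p = state.init_p
            state.residual = 0.0
        return state
    # predict (F = 1, no control input)
    state.p = state.p + q
    if z is None or sqi <= 0:
        return state
    r = measurement_noise(state.r_base, sqi)
    innovation = float(z) - state.x_hat
    gain = state.p / (state.p + r)
    state.x_hat = state.x_hat + gain * innovation
    state.p = (1.0 - gain) * state.p
    state.residual = innovation
    return state


def fuse_median(
    estimates: list[float],
    sqis: list[float],
    sqi_threshold: float = 0.8,
) -> tuple[float, float] | None:
    """Median fusion over ROI estimates with SQI strictly above threshold.

    Returns ``(value, window_sqi)`` where the window SQI is the median of
    *all* per-ROI SQIs, or None when no estimate passes.
    """
    passing = [v for v, s in zip(estimates, sqis) if v is not None and s > sqi_threshold]
    if not passing:
        return None
    return float(np.median(passing)), float(np.median(sqis)) if sqis else 0.0


def fuse_kalman_1d(
    times: np.ndarray,
    values: list[float | None],
    sqis: list[float],
    moving: list[bool] | None = None,
    state: KalmanState | None = None,
    reinit_horizon_s: float = 60.0,
) -> list[VitalEstimate]:
    """Track a (possibly gappy) fused stream with a scalar Kalman filter.

    Estimates are emitted for every instant with a usable measurement;
    after a measurement gap longer than ``reinit_horizon_s`` the filter is
    re-initialised from the next measurement instead of dragging a stale
    prediction.
    """
    state = state or KalmanState()
    moving = moving if moving is not None else [False] * len(times)
    out: list[VitalEstimate] = []
    for t, z, s, mv in zip(times, values, sqis, moving):
        usable = z is not None and s > 0
        if usable and state.last_time is not None and t - state.last_time > reinit_horizon_s:
            state.reset()
        kalman_update(state, z if usable else None, s if usable else 0.0, mv)
        if usable and state.x_hat is not None:
            state.last_time = float(t)
            out.append(VitalEstimate(time_s=float(t), value=state.x_hat,
                                     sqi=float(s), method="kalman1d", source="fused"))
    return out


def nd_weights(sigma_sq: np.ndarray) -> np.ndarray:
    """Normalised inverse-variance weights.

    Algebraically identical to the product form
    ``prod_{j != l} sigma_j^2 / sum_i prod_{j != i} sigma_j^2``.
    """
    s = np.maximum(np.asarray(sigma_sq, dtype=float), 1e-12)
    inv = 1.0 / s
    return inv / inv.sum()


def fuse_kalman_nd(
    times: np.ndarray,
    streams: dict[str, list[float | None]],
    stream_sqis: dict[str, list[float]],
    moving: list[bool] | None = None,
    kalman_kwargs: dict | None = None,
    reinit_horizon_s: float = 60.0,
) -> list[VitalEstimate]:
    """Per-stream Kalman tracking combined by residual/SQI weighting.

    Each (ROI, channel) stream is tracked by its own scalar filter; at each
    instant the tracked estimates of the streams that produced a usable
    measurement are combined with weights from ``sigma_i^2 =
    (r_i / SQI_i)^2``, where ``r_i`` is the filter innovation. Streams with
    zero SQI are excluded from the combination.
    """
    kalman_kwargs = kalman_kwargs or {}
    moving = moving if moving is not None else [False] * len(times)
    states = {k: KalmanState(**kalman_kwargs) for k in streams}
    out: list[VitalEstimate] = []
    for i, t in enumerate(times):
        xs, sig, sqs = [], [], []
        for name, vals in streams.items():
            z = vals[i]
            s = stream_sqis[name][i]
            st = states[name]
            usable = z is not None and s > 0
            if usable and st.last_time is not None and t - st.last_time > reinit_horizon_s:
                st.reset()
            kalman_update(st, z if usable else None, s if usable else 0.0, moving[i])
            if usable and st.x_hat is not None:
                st.last_time = float(t)
                xs.append(st.x_hat)
                sig.append((st.residual / s) ** 2)
                sqs.append(s)
        if not xs:
            continue
        w = nd_weights(np.asarray(sig))
        out.append(VitalEstimate(time_s=float(t), value=float(np.dot(w, xs)),
                                 sqi=float(np.median(sqs)), method="kalmanNd",
                                 source="fused"))
    return out


@dataclass
class GapStatistics:
    """Distribution of the time gaps between successive estimates."""

    gaps_s: np.ndarray
    session_length_s: float

    def fraction_under(self, threshold_s: float = 180.0) -> float:
        if len(self.gaps_s) == 0:
            return 1.0
        return float(np.mean(self.gaps_s < threshold_s))

    def histogram(self, bin_s: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
        hi = max(self.session_length_s, bin_s)
        edges = np.arange(0.0, hi + bin_s, bin_s)
        counts, edges = np.histogram(self.gaps_s, bins=edges)
        return counts, edges


def gap_statistics(
    estimate_times: np.ndarray,
    session_length_s: float,
    include_boundaries: bool = True,
) -> GapStatistics:
    """Inter-estimate gaps, including the leading/trailing uncovered spans.

    An empty stream yields a single gap equal to the session length.
    """
    t = np.sort(np.asarray(estimate_times, dtype=float))
    if len(t) == 0:
        return GapStatistics(np.asarray([session_length_s]), session_length_s)
    gaps = list(np.diff(t))
    if include_boundaries:
        gaps = [t[0] - 0.0] + gaps + [session_length_s - t[-1]]
    return GapStatistics(np.asarray(gaps), session_length_s)
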