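"""Pipeline configuration.

All defaults are the constants used throughout the estimation pipeline:
window geometries, physiological bands, quality thresholds and Kalman noise
parameters. Overriding any of them is supported everywhere via a single
:class:`PipelineConfig` instance, and the run manifest records the full
configuration so a run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any


@dataclass
class PipelineConfig:
    fps: float = 15.0

    # physiological bands
    hr_band_bpm: tuple[float, float] = (36.0, 240.0)
    rr_band_bpm: tuple[float, float] = (6.0, 42.0)
    # cardiac pass band of the FIR filter, Hz (36--240 beats/min)
    cardiac_band_hz: tuple[float, float] = (0.6, 4.0)
    resp_band_hz: tuple[float, float] = (0.1, 0.7)

    # stability / activity
    activity_threshold_px: float = 100.0
    min_stable_fraction: float = 1.0 / 3.0

    # change-point detection
    changepoint_window_s: float = 30.0
    changepoint_hop_s: float = 25.0       # "5-s overlap" read literally
    step_prob_threshold: float = 0.8

    # beat detection
    ssf_window_s: float = 0.170           # upslope duration at 60 beats/min
    refractory_s: float = 0.25            # 240 beats/min ceiling
    threshold_init_s: float = 30.0
    threshold_decay: str = "multiplicative"   # or "difference"

    # quality / template windows
    quality_window_s: float = 30.0
    quality_step_s: float = 5.0
    template_xcorr_min: float = 0.8
    template_min_valid_fraction: float = 0.5
    dtw_cost_scale: float = 100.0
    dtw_band: int | None = 2
    dtw_min_scale_len: int = 16
    clip_deriv_rel_threshold: float = 0.1
    clip_extreme_fraction: float = 0.1
    clip_run_fraction: float = 1.0 / 3.0

    # HR estimation
    hr_window_s: float = 15.0
    hr_step_s: float = 1.0
    ar_order: int = 8
    pole_tol_deg: float = 2.0
    ark_bg_min_radius: float = 0.8
    ark_radius_tol: float = 0.1
    spectrum_grid: int = 4096
    fft_zero_pad_factor: int = 8
    beat_count_intervals: bool = True     # (N-1)/dt; False -> N/dt
    # a usable window must be covered by credible beats: reject when any
    # internal onset gap exceeds max(this, 2.5x the window's median IBI)
    max_onset_gap_s: float = 2.0

    # fusion
    sqi_threshold: float = 0.8
    kalman_q_quiet: float = 0.1
    kalman_q_motion: float = 0.2
    kalman_r_base: float = 4.0
    kalman_init_p: float = 100.0
    kalman_reinit_horizon_s: float = 60.0

    # respiration
    rr_window_s: float = 30.0
    rr_step_s: float = 5.0
    resp_resample_hz: float = 4.0
    resp_pca_components: int = 5
    resp_var_explained_min: float = 0.3
    resp_snr_min: float = 1.0
    resp_snr_peak_halfwidth_hz: float = 0.05
    torso_lowpass_hz: float = 1.0

    seed: int | None = None

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("hr_band_bpm", "rr_band_bpm", "cardiac_band_hz", "resp_band_hz"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
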