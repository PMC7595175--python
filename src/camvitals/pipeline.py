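"""End-to-end session orchestration.

``run_pipeline`` takes a face session (and optionally a torso session),
runs stability selection, band-limiting, change-point detection, beat
detection, quality scoring, the four per-window heart-rate estimators and
the three fusion schemes, plus the respiratory branch, and returns all
estimate streams with a reproducibility manifest.

Estimates are timestamped at the end of their window (the moment the
estimate becomes available); a window whose report frame falls in a
high-activity (Act=0) span emits nothing, since the face is not reliably
tracked at that moment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as sig_detrend

from . import __version__
from .beats import BeatRecord, detect_beats
from .changepoint import scan_changepoints
from .config import PipelineConfig
from .fusion import (GapStatistics, fuse_kalman_1d, fuse_kalman_nd, fuse_median,
                     gap_statistics)
from .heart_rate import (AllPolesCancelledError, VitalEstimate, ark_cancel, fit_ar,
                         hr_ar_pole, hr_beat_count, hr_fft, windows)
from .preprocessing import band_limit, compute_activity, compute_motion, session_valid
from .quality import build_template, score_beat, window_sqi
from .respiration import (pca_components, riav_extract, rr_estimate, smooth_resp,
                          torso_candidates)
from .session import SessionSignals

log = logging.getLogger("camvitals.pipeline")

HR_METHODS = ("beat_count", "fft", "ar_pole", "ark")
FUSIONS = ("median", "kalman1d", "kalmanNd")


@dataclass
class StreamAnalysis:
    """Everything computed for one (ROI, channel) PPGi stream."""

    roi: int
    channel: str
    raw: np.ndarray
    filtered: np.ndarray
    step_prob: np.ndarray
    beats: list[BeatRecord]


@dataclass
class PipelineResult:
    status: str
    manifest: dict
    activity: object = None
    hr_streams: dict = field(default_factory=dict)   # (method, fusion) -> [VitalEstimate]
    rr_streams: dict = field(default_factory=dict)   # group -> [VitalEstimate]
    beat_table: pd.DataFrame | None = None
    gap_stats: GapStatistics | None = None

    def hr_table(self) -> pd.DataFrame:
        rows = []
        for (method, fusion), ests in self.hr_streams.items():
            for e in ests:
                rows.append({"time_s": e.time_s, "value": e.value, "sqi": e.sqi,
                             "method": method, "fusion": fusion})
        return pd.DataFrame(rows, columns=["time_s", "value", "sqi", "method", "fusion"])

    def rr_table(self) -> pd.DataFrame:
        rows = []
        for group, ests in self.rr_streams.items():
            for e in ests:
                rows.append({"time_s": e.time_s, "value": e.value, "sqi": e.sqi,
                             "group": group})
        return pd.DataFrame(rows, columns=["time_s", "value", "sqi", "group"])


def analyse_stream(
    raw: np.ndarray,
    act: np.ndarray,
    config: PipelineConfig,
    roi: int,
    channel: str,
) -> StreamAnalysis:
    """Filter, change-point scan, beat detection and quality scoring."""
    fps = config.fps
    filtered = band_limit(raw, fps, config.cardiac_band_hz)
    # change-point detection runs on the unfiltered series: the band-pass
    # would remove the step itself
    step_prob = scan_changepoints(raw, fps, config.changepoint_window_s,
                                  config.changepoint_hop_s)
    beats = detect_beats(filtered, fps, config.ssf_window_s,
                         config.threshold_init_s, config.refractory_s,
                         config.threshold_decay)

    # score each beat once, in the first 30-s window that fully contains it
    wlen = int(round(config.quality_window_s * fps))
    step = int(round(config.quality_step_s * fps))
    scored = [False] * len(beats)
    for start in range(0, max(1, len(raw) - wlen + 1), step):
        w = slice(start, start + wlen)
        in_win = [k for k, b in enumerate(beats)
                  if b.onset >= w.start and (b.next_onset or b.onset) <= w.stop]
        todo = [k for k in in_win if not scored[k]]
        if not todo:
            continue
        template = build_template([beats[k] for k in in_win], filtered,
                                  config.hr_band_bpm, config.template_xcorr_min,
                                  config.template_min_valid_fraction)
        for k in todo:
            beats[k].sqi = score_beat(
                beats[k], filtered, template, act, step_prob, w,
                hr_band=config.hr_band_bpm,
                step_prob_threshold=config.step_prob_threshold,
                dtw_cost_scale=config.dtw_cost_scale,
                dtw_band=config.dtw_band,
                dtw_min_scale_len=config.dtw_min_scale_len,
                clip_deriv_rel_threshold=config.clip_deriv_rel_threshold,
                clip_extreme_fraction=config.clip_extreme_fraction,
                clip_run_fraction=config.clip_run_fraction,
            )
            scored[k] = True
    return StreamAnalysis(roi=roi, channel=channel, raw=np.asarray(raw, dtype=float),
                          filtered=filtered, step_prob=step_prob, beats=beats)


def run_pipeline(
    session: SessionSignals,
    config: PipelineConfig | None = None,
    torso_session: SessionSignals | None = None,
    channels: tuple[str, ...] = ("red", "green", "blue"),
) -> PipelineResult:
    config = config or PipelineConfig()
    fps = config.fps
    if abs(session.fps - fps) > 1e-9:
        raise ValueError(f"session fps {session.fps} does not match config fps {fps}")
    manifest = {"config": config.to_dict(), "version": __version__,
                "n_frames": session.frame_count}

    activity = compute_activity(compute_motion(session.centroids),
                                config.activity_threshold_px)
    if not session_valid(activity, config.min_stable_fraction):
        log.info("session discarded: stable fraction below %.3f", config.min_stable_fraction)
        return PipelineResult(status="discarded", manifest=manifest, activity=activity)
    act = activity.act

    streams: dict[tuple[int, str], StreamAnalysis] = {}
    for (roi, ch), raw in sorted(session.subject_series.items()):
        if ch not in channels:
            continue
        streams[(roi, ch)] = analyse_stream(raw, act, config, roi, ch)
    if not streams:
        raise ValueError("no subject series in the requested channels")

    bg_filtered = {ch: band_limit(x, fps, config.cardiac_band_hz)
                   for ch, x in session.background_series.items() if ch in channels}
    bg_raw = {ch: np.asarray(x, dtype=float)
              for ch, x in session.background_series.items() if ch in channels}

    # ---- per-window, per-stream HR estimation -----------------------------
    n = session.frame_count
    wins = windows(n, fps, config.hr_window_s, config.hr_step_s)
    times = np.asarray([w.stop / fps for w in wins])
    report_frames = [min(w.stop, n - 1) for w in wins]
    emit_ok = [bool(act[f]) for f in report_frames]
    moving = [bool(np.any(act[w] == 0)) for w in wins]

    def beats_cover_window(onsets: list[int], w: slice) -> bool:
        """True when valid onsets leave no implausibly long pulse-free gap.

        A span without credible beats (clipping, saturation) corrupts the
        window's spectral estimators even when the rest of the window is
        clean, so coverage is required from window start to end.
        """
        if len(onsets) < 2:
            return False
        ibis = np.diff(onsets)
        max_gap = max(config.max_onset_gap_s * fps, 2.5 * float(np.median(ibis)))
        edges = np.diff([w.start] + list(onsets) + [w.stop])
        return bool(np.max(edges) <= max_gap)

    per_stream: dict[str, dict[str, list]] = {}
    stream_sqi: dict[str, list[float]] = {}
    bg_models: dict[tuple[str, int], object] = {}
    for (roi, ch), sa in streams.items():
        name = f"roi{roi}:{ch}"
        vals = {m: [] for m in HR_METHODS}
        sqis = []
        for wi, w in enumerate(wins):
            in_win = [b for b in sa.beats if w.start <= b.onset < w.stop]
            sw = window_sqi(in_win)
            sqis.append(sw)
            covered = beats_cover_window(
                [b.onset for b in in_win if b.sqi_beat > 0], w)
            if not emit_ok[wi] or not covered:
                log.debug("window %s %.0fs rejected: %s", name, times[wi],
                          "activity" if not emit_ok[wi] else "beat coverage")
                for m in HR_METHODS:
                    vals[m].append(None)
                continue
            vals["beat_count"].append(
                hr_beat_count(in_win, fps, w, config.hr_band_bpm,
                              config.beat_count_intervals))
            seg = sa.filtered[w]
            vals["fft"].append(hr_fft(seg, fps, config.cardiac_band_hz,
                                      config.fft_zero_pad_factor))
            try:
                model = fit_ar(seg, fps, config.ar_order)
            except (ValueError, np.linalg.LinAlgError):
                model = None
            vals["ar_pole"].append(
                hr_ar_pole(model, config.cardiac_band_hz) if model else None)
            # ARk models are fitted on detrended *raw* windows: band-passing
            # colours the background noise into spurious strong in-band
            # poles, and aliases outside the cardiac band must stay visible
            key = (ch, wi)
            if key not in bg_models:
                try:
                    bg_models[key] = fit_ar(sig_detrend(bg_raw[ch][w]), fps,
                                            config.ar_order)
                except (ValueError, np.linalg.LinAlgError, KeyError):
                    bg_models[key] = None
            bg = bg_models[key]
            ark_val = None
            if bg is not None:
                try:
                    subj_raw_model = fit_ar(sig_detrend(sa.raw[w]), fps,
                                            config.ar_order)
                    reduced = ark_cancel(subj_raw_model, bg, config.pole_tol_deg,
                                         config.ark_bg_min_radius,
                                         config.ark_radius_tol)
                    freqs, power = reduced.power_spectrum(config.spectrum_grid)
                    lo, hi = config.cardiac_band_hz
                    mask = (freqs >= lo) & (freqs <= hi)
                    if mask.any():
                        k = np.flatnonzero(mask)[np.argmax(power[mask])]
                        ark_val = float(freqs[k] * 60.0)
                except (AllPolesCancelledError, ValueError, np.linalg.LinAlgError):
                    ark_val = None
            vals["ark"].append(ark_val)
        per_stream[name] = vals
        stream_sqi[name] = sqis

    # ---- fusion -----------------------------------------------------------
    hr_streams: dict[tuple[str, str], list[VitalEstimate]] = {}
    for method in HR_METHODS:
        med_vals: list[float | None] = []
        med_sqis: list[float] = []
        for wi in range(len(wins)):
            ests = [per_stream[s][method][wi] for s in per_stream]
            sqis = [stream_sqi[s][wi] for s in per_stream]
            fused = fuse_median(ests, sqis, config.sqi_threshold) if emit_ok[wi] else None
            if fused is None:
                med_vals.append(None)
                med_sqis.append(float(np.median(sqis)) if sqis else 0.0)
            else:
                med_vals.append(fused[0])
                med_sqis.append(fused[1])
        hr_streams[(method, "median")] = [
            VitalEstimate(time_s=float(t), value=v, sqi=s, method=method, source="median")
            for t, v, s in zip(times, med_vals, med_sqis) if v is not None
        ]
        kk = dict(q_quiet=config.kalman_q_quiet, q_motion=config.kalman_q_motion,
                  r_base=config.kalman_r_base, init_p=config.kalman_init_p)
        k1 = fuse_kalman_1d(times, med_vals, med_sqis, moving,
                            state=None, reinit_horizon_s=config.kalman_reinit_horizon_s)
        for e in k1:
            e.method = method
        hr_streams[(method, "kalman1d")] = k1
        nd_streams = {s: [per_stream[s][method][wi] for wi in range(len(wins))]
                      for s in per_stream}
        nd_sqis = {s: stream_sqi[s] for s in per_stream}
        knd = fuse_kalman_nd(times, nd_streams, nd_sqis, moving, kalman_kwargs=kk,
                             reinit_horizon_s=config.kalman_reinit_horizon_s)
        for e in knd:
            e.method = method
        hr_streams[(method, "kalmanNd")] = knd

    # ---- respiration ------------------------------------------------------
    rr_streams: dict[str, list[VitalEstimate]] = {}
    duration_s = n / fps
    face_cands = []
    for (roi, ch), sa in streams.items():
        good = [b for b in sa.beats if b.sqi_beat > 0]
        resp = riav_extract(good, sa.filtered, fps, config.resp_resample_hz,
                            duration_s=duration_s)
        if resp is not None:
            # same preparation as the torso branch: only the respiratory
            # band of a beat-amplitude series is informative
            resp.samples = smooth_resp(resp.samples, resp.fs, config.torso_lowpass_hz)
            face_cands.append(resp)
    face_comps = (pca_components(face_cands, config.resp_pca_components,
                                 config.resp_band_hz)
                  if len(face_cands) >= 2 else [])
    kk = dict(q_quiet=config.kalman_q_quiet, q_motion=config.kalman_q_motion,
              r_base=config.kalman_r_base, init_p=config.kalman_init_p)
    rr_kwargs = dict(window_s=config.rr_window_s, step_s=config.rr_step_s,
                     order=config.ar_order, band_hz=config.resp_band_hz,
                     var_explained_min=config.resp_var_explained_min,
                     snr_min=config.resp_snr_min, kalman_kwargs=kk)
    rr_streams["face"] = rr_estimate(face_comps, "face", **rr_kwargs)

    torso_comps = []
    if torso_session is not None:
        grey = {key: x for key, x in torso_session.subject_series.items()
                if key[1] == "grey"}
        cands = torso_candidates(grey, torso_session.fps,
                                 config.torso_lowpass_hz, config.resp_resample_hz)
        if len(cands) >= 2:
            torso_comps = pca_components(cands, config.resp_pca_components,
                                         config.resp_band_hz)
    rr_streams["torso"] = rr_estimate(torso_comps, "torso", **rr_kwargs)
    rr_streams["combined"] = rr_estimate(face_comps + torso_comps, "combined",
                                         **rr_kwargs)

    # ---- beat table and gaps ---------------------------------------------
    rows = []
    for (roi, ch), sa in streams.items():
        for b in sa.beats:
            q = b.sqi
            rows.append({
                "roi": roi, "channel": ch, "onset_s": b.onset / fps,
                "hr_inst": b.hr_inst,
                "sqi_act": q.sqi_act if q else 0, "sqi_cp": q.sqi_cp if q else 0,
                "sqi_freq": q.sqi_freq if q else 0, "sqi_amp": q.sqi_amp if q else 0,
                "sqi_clip": q.sqi_clip if q else 0,
                "sqi_dtw": q.sqi_dtw if q else 0.0,
                "sqi_beat": b.sqi_beat,
            })
    beat_table = pd.DataFrame(rows)

    best = hr_streams.get(("ark", "kalmanNd"), [])
    gaps = gap_statistics(np.asarray([e.time_s for e in best]), duration_s)

    return PipelineResult(status="ok", manifest=manifest, activity=activity,
                          hr_streams=hr_streams, rr_streams=rr_streams,
                          beat_table=beat_table, gap_stats=gaps)
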