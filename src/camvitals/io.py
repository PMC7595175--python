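"""Session and results I/O: CSV, HDF5, JSON ground truth, YAML config.

The session schema is column-oriented: one column per (ROI, channel) named
``roi<id>_<channel>``, per-channel background columns named
``background_<channel>`` and the centroid trace as ``centroid_x`` /
``centroid_y``. CSV files carry the frame rate on a comment line; the HDF5
container stores it as a root attribute and round-trips losslessly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .heart_rate import VitalEstimate
from .session import SessionSignals
from .synthetic import SyntheticConfig, SyntheticGroundTruth, as_trace

_CSV_MAGIC = "# camvitals-session fps="
_COL_RE = re.compile(r"^roi(\d+)_(red|green|blue|grey)$")


def _session_frame(session: SessionSignals) -> pd.DataFrame:
    cols = {
        "centroid_x": session.centroids[:, 0],
        "centroid_y": session.centroids[:, 1],
    }
    for (roi, ch), x in sorted(session.subject_series.items()):
        cols[f"roi{roi}_{ch}"] = x
    for ch, x in sorted(session.background_series.items()):
        cols[f"background_{ch}"] = x
    return pd.DataFrame(cols)


def write_session_csv(session: SessionSignals, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_CSV_MAGIC}{session.fps:g}\n")
        _session_frame(session).to_csv(fh, index=False, float_format="%.10g")


def read_session_csv(path: str | Path, fps: float | None = None) -> SessionSignals:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_CSV_MAGIC):
            raise ValueError("not a session CSV: missing frame-rate header line")
        file_fps = float(first[len(_CSV_MAGIC):].strip())
        df = pd.read_csv(fh)
    if fps is not None and abs(fps - file_fps) > 1e-9:
        raise ValueError(f"fps mismatch: file says {file_fps}, config says {fps}")
    return _frame_to_session(df, file_fps)


def _frame_to_session(df: pd.DataFrame, fps: float) -> SessionSignals:
    missing = [c for c in ("centroid_x", "centroid_y") if c not in df.columns]
    subject: dict[tuple[int, str], np.ndarray] = {}
    background: dict[str, np.ndarray] = {}
    for col in df.columns:
        m = _COL_RE.match(col)
        if m:
            subject[(int(m.group(1)), m.group(2))] = df[col].to_numpy(dtype=float)
        elif col.startswith("background_"):
            background[col[len("background_"):]] = df[col].to_numpy(dtype=float)
    if not subject:
        missing.append("roi<N>_<channel>")
    if not background:
        missing.append("background")
    if missing:
        raise ValueError(f"session file missing columns: {', '.join(missing)}")
    centroids = np.column_stack(
        [df["centroid_x"].to_numpy(float), df["centroid_y"].to_numpy(float)]
    )
    return SessionSignals(fps=fps, subject_series=subject,
                          background_series=background, centroids=centroids)


def write_session_h5(session: SessionSignals, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fps"] = session.fps
        f.create_dataset("centroids", data=session.centroids)
        g = f.create_group("subject")
        for (roi, ch), x in session.subject_series.items():
            g.create_dataset(f"roi{roi}_{ch}", data=x)
        b = f.create_group("background")
        for ch, x in session.background_series.items():
            b.create_dataset(ch, data=x)


def read_session_h5(path: str | Path, fps: float | None = None) -> SessionSignals:
    with h5py.File(path, "r") as f:
        file_fps = float(f.attrs["fps"])
        if fps is not None and abs(fps - file_fps) > 1e-9:
            raise ValueError(f"fps mismatch: file says {file_fps}, config says {fps}")
        subject = {}
        for name, ds in f["subject"].items():
            m = _COL_RE.match(name)
            if m:
                subject[(int(m.group(1)), m.group(2))] = ds[()]
        background = {ch: ds[()] for ch, ds in f["background"].items()}
        centroids = f["centroids"][()]
    return SessionSignals(fps=file_fps, subject_series=subject,
                          background_series=background, centroids=centroids)


def read_session(path: str | Path, fps: float | None = None) -> SessionSignals:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return read_session_h5(path, fps)
    return read_session_csv(path, fps)


def write_session(session: SessionSignals, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        write_session_h5(session, path)
    else:
        write_session_csv(session, path)


def read_image_stack(directory: str | Path, face_box: tuple[int, int, int, int],
                     fps: float, channel_weights=None) -> SessionSignals:
    """Build a session from a directory of per-frame images (PNG/TIFF).

    Applies the 9x9 ROI grid to ``face_box`` and mean-pools each tile per
    colour channel; the face centroid is taken as the box centre (an
    external tracker should supply real centroids where available).
    """
    from imageio.v3 import imread

    from .preprocessing import roi_grid, roi_means

    paths = sorted(p for p in Path(directory).iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise ValueError(f"no PNG/TIFF frames found in {directory}")
    tiles = roi_grid(face_box)
    channels = ("red", "green", "blue")
    per_frame: list[dict] = []
    for p in paths:
        frame = np.asarray(imread(p), dtype=float)
        if frame.ndim == 2:
            frame = np.repeat(frame[:, :, None], 3, axis=2)
        per_frame.append({ch: roi_means(frame[:, :, c], tiles)
                          for c, ch in enumerate(channels)})
    x0, y0, w, h = face_box
    centroids = np.tile([x0 + w / 2.0, y0 + h / 2.0], (len(paths), 1))
    subject: dict[tuple[int, str], np.ndarray] = {}
    for k in range(len(tiles)):
        for ch in channels:
            subject[(k + 1, ch)] = np.array([f[ch][k] for f in per_frame])
    background = {ch: np.zeros(len(paths)) for ch in channels}
    return SessionSignals(fps=fps, subject_series=subject,
                          background_series=background, centroids=centroids)


# --------------------------------------------------------------------------
# ground truth sidecar

def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path,
                       duration_s: float | None = None) -> None:
    """JSON sidecar; the HR/RR traces are sampled on a 1-s grid."""
    if duration_s is None:
        duration_s = float(truth.beat_onset_times[-1]) if len(truth.beat_onset_times) else 0.0
    grid = np.arange(0.0, max(duration_s, 1.0) + 1.0, 1.0)
    payload = {
        "beat_onset_times": list(map(float, truth.beat_onset_times)),
        "beat_peak_times": list(map(float, truth.beat_peak_times)),
        "trace_times": grid.tolist(),
        "hr_trace": np.asarray(truth.hr_at(grid), dtype=float).tolist(),
        "rr_trace": np.asarray(truth.rr_at(grid), dtype=float).tolist(),
        "alias_freqs_hz": list(map(float, truth.alias_freqs_hz)),
        "step_change_samples": list(map(int, truth.step_change_samples)),
        "invalid_intervals": [list(map(float, iv)) for iv in truth.invalid_intervals],
        "clip_intervals": [list(map(float, iv)) for iv in truth.clip_intervals],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> SyntheticGroundTruth:
    d = json.loads(Path(path).read_text())
    tt = np.asarray(d["trace_times"])
    hr = np.asarray(d["hr_trace"])
    rr = np.asarray(d["rr_trace"])
    return SyntheticGroundTruth(
        beat_onset_times=np.asarray(d["beat_onset_times"]),
        beat_peak_times=np.asarray(d["beat_peak_times"]),
        hr_at=lambda t: np.interp(np.asarray(t, dtype=float), tt, hr),
        rr_at=lambda t: np.interp(np.asarray(t, dtype=float), tt, rr),
        alias_freqs_hz=list(d["alias_freqs_hz"]),
        step_change_samples=list(d["step_change_samples"]),
        invalid_intervals=[tuple(iv) for iv in d["invalid_intervals"]],
        clip_intervals=[tuple(iv) for iv in d["clip_intervals"]],
    )


# --------------------------------------------------------------------------
# estimates and config

def estimates_frame(estimates: list[VitalEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"time_s": e.time_s, "value": e.value, "sqi": e.sqi,
             "method": e.method, "source": e.source}
            for e in estimates
        ],
        columns=["time_s", "value", "sqi", "method", "source"],
    )


def write_estimates(estimates: list[VitalEstimate], path: str | Path) -> None:
    estimates_frame(estimates).to_csv(path, index=False, float_format="%.10g")


def read_estimates(path: str | Path) -> list[VitalEstimate]:
    df = pd.read_csv(path)
    return [
        VitalEstimate(time_s=float(r.time_s), value=float(r.value),
                      sqi=float(r.sqi), method=str(r.method), source=str(r.source))
        for r in df.itertuples()
    ]


def load_synthetic_config(path: str | Path) -> SyntheticConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("step_changes", "clip_intervals", "motion_intervals"):
        if key in d and d[key] is not None:
            d[key] = [tuple(item) for item in d[key]]
    cfg = SyntheticConfig(**d)
    cfg.validate()
    return cfg


def save_synthetic_config(cfg: SyntheticConfig, path: str | Path) -> None:
    d = dict(cfg.__dict__)
    if callable(d["hr_trace"]):
        d["hr_trace"] = [[float(t), float(as_trace(cfg.hr_trace)(np.asarray([t]))[0])]
                         for t in np.linspace(0, cfg.duration_s, 16)]
    if callable(d["rr_trace"]):
        d["rr_trace"] = [[float(t), float(as_trace(cfg.rr_trace)(np.asarray([t]))[0])]
                         for t in np.linspace(0, cfg.duration_s, 16)]
    for key in ("step_changes", "clip_intervals", "motion_intervals", "flicker_source_hz"):
        d[key] = [list(map(float, item)) if isinstance(item, (tuple, list)) else float(item)
                  for item in d[key]]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
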