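"""In-memory container for one recording session.

A session is the set of per-ROI, per-colour-channel mean pixel-intensity
time series extracted from a video, together with the face-centroid trace
and a background reference series per channel, all sampled at the camera
frame rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CHANNELS = ("red", "green", "blue", "grey")

#: luma weights used when collapsing RGB to grey
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass
class SessionSignals:
    """All intensity series for one recording.

    ``subject_series`` maps ``(roi_id, channel)`` to a 1-D intensity array;
    ``background_series`` maps ``channel`` to the background-ROI array.
    ``centroids`` is an ``(n_frames, 2)`` array of face-centroid pixel
    coordinates; NaN rows mark frames with no detection.
    """

    fps: float
    subject_series: dict[tuple[int, str], np.ndarray]
    background_series: dict[str, np.ndarray]
    centroids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        self.centroids = np.asarray(self.centroids, dtype=float)
        lengths = {len(v) for v in self.subject_series.values()}
        lengths |= {len(v) for v in self.background_series.values()}
        lengths.add(len(self.centroids))
        if len(lengths) > 1:
            raise ValueError(f"series lengths differ: {sorted(lengths)}")

    @property
    def frame_count(self) -> int:
        return len(self.centroids)

    @property
    def duration_s(self) -> float:
        return self.frame_count / self.fps

    @property
    def roi_ids(self) -> list[int]:
        return sorted({roi for roi, _ in self.subject_series})

    def channels(self, roi_id: int) -> list[str]:
        return [ch for (roi, ch) in self.subject_series if roi == roi_id]

    def times(self) -> np.ndarray:
        return np.arange(self.frame_count) / self.fps
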