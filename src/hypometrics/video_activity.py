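"""Locomotor activity from video by frame differencing.

The movement index maps the mean absolute intensity change between
consecutive frames onto [0, 1]: 0 for a static scene, 1 when every pixel
swings across the full dynamic range. Normalizing by the fixed dynamic range
(rather than a per-video maximum) keeps indices comparable across videos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import InvalidArgumentError, InvalidInputError, VideoStack


@dataclass
class ActivityTrace:
    """Per-frame-pair movement index (unitless, in [0, 1])."""

    times: np.ndarray  # seconds from start, one per frame pair
    index: np.ndarray
    frame_interval: float
    bin_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.index = np.asarray(self.index, dtype=float)
        if self.times.shape != self.index.shape:
            raise InvalidInputError("times and index must align")

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if self.times.size else 0.0


def movement_index(video: VideoStack, pre_blur_sigma: float = 0.0) -> ActivityTrace:
    """Movement index per consecutive frame pair.

    index_t = mean_pixels |I_t - I_{t-1}| / (range_max - range_min),
    guaranteed in [0, 1]; exactly 0 iff the two frames are identical.
    An optional Gaussian pre-blur (sigma in pixels) suppresses sensor noise.
    """
    frames = video.frames.astype(np.float64)
    if pre_blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        frames = np.stack([gaussian_filter(f, pre_blur_sigma) for f in frames])
    lo, hi = video.dynamic_range
    diffs = np.abs(np.diff(frames, axis=0))
    idx = diffs.mean(axis=(1, 2)) / (hi - lo)
    times = np.arange(1, video.n_frames) * video.frame_interval
    return ActivityTrace(times, idx, video.frame_interval)


def summarize_activity(
    trace: ActivityTrace,
    bin_width: float,
    group: str = "",
    replicate_id: str = "",
    provenance: str = "activity",
) -> pd.DataFrame:
    """Mean movement index per time bin, as GroupTable rows.

    Bins tile [0, duration) half-open; a trailing partial bin is kept and
    flagged ``partial_bin``.
    """
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")
    if bin_width < trace.frame_interval:
        raise InvalidArgumentError("bin_width must be >= the frame interval")
    duration = trace.duration
    edges = np.arange(0.0, duration + bin_width, bin_width)
    if edges[-1] < duration + 1e-12:
        edges = np.append(edges, edges[-1] + bin_width)
    which = np.digitize(trace.times, edges, right=True) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        partial = edges[b + 1] > duration + 1e-12
        rows.append(
            {
                "group": group,
                "replicate_id": replicate_id,
                "timepoint": float(edges[b]),
                "metric": "movement_index",
                "value": float(trace.index[sel].mean()),
                "unit": "",
                "qc_flag": "partial_bin" if partial else "",
                "provenance": provenance,
            }
        )
    from .types import GROUP_TABLE_COLUMNS

    return pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)


def relative_activity(treated: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-bin treated/reference activity ratio on a shared bin grid.

    Both inputs are GroupTable frames from :func:`summarize_activity`.
    Reference bins of zero yield NaN values flagged ``undefined`` rather
    than division errors.
    """
    t = treated.set_index("timepoint")["value"]
    r = reference.set_index("timepoint")["value"]
    if not t.index.equals(r.index):
        raise InvalidInputError("treated and reference bin grids differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t / r
    out = pd.DataFrame(
        {
            "timepoint": t.index,
            "relative_activity": np.where(r.values != 0, ratio.values, np.nan),
            "qc_flag": np.where(r.values != 0, "", "undefined"),
        }
    ).reset_index(drop=True)
    return out
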