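"""Core in-memory containers shared across analysis stages.

All containers are thin dataclasses over numpy arrays / pandas frames; they
validate their structural invariants at construction and are otherwise inert.
Long-format per-sample results travel as a pandas DataFrame with the
GROUP_TABLE_COLUMNS schema (see :func:`make_group_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class InvalidArgumentError(ValueError):
    """A caller-supplied parameter is outside its valid domain."""


class InvalidInputError(ValueError):
    """Input data violates a structural precondition (shape, grid, schema)."""


class InsufficientDataError(ValueError):
    """Not enough samples to perform the requested computation."""


class QcExcludedError(ValueError):
    """Operation refused because the trace was excluded by quality control."""


class MissingFieldError(ValueError):
    """A required optional field (e.g. measured SO2) is absent."""


@dataclass
class VideoStack:
    """Ordered grayscale frames with frame-interval metadata.

    frames: (T, H, W) intensity array; frame_interval in seconds;
    dynamic_range the (min, max) representable intensity.
    """

    frames: np.ndarray
    frame_interval: float
    dynamic_range: tuple[float, float] = (0.0, 65535.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidInputError(
                f"frames must be (T, H, W), got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InvalidInputError("a video needs at least 2 frames")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be positive")
        lo, hi = self.dynamic_range
        if not hi > lo:
            raise InvalidArgumentError("dynamic_range must satisfy max > min")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        return float((self.n_frames - 1) * self.frame_interval)


@dataclass
class TimeSeriesTrace:
    """(time, value) samples with units and QC flags.

    Used for O2 sensor logs (times in minutes), ROI intensity and ECG traces
    (times in seconds) and impedance series. ``qc_flags`` accumulates
    human-readable flag strings; ``excluded`` traces carry a reason and are
    refused by downstream fits.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = ""
    time_unit: str = "s"
    qc_flags: list[str] = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidInputError("times and values must be 1-D of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    def flag(self, flag: str) -> None:
        if flag not in self.qc_flags:
            self.qc_flags.append(flag)

    def exclude(self, reason: str) -> None:
        self.excluded = True
        self.exclusion_reason = reason
        self.flag("excluded")


@dataclass
class BloodGasSample:
    """One perfusate blood-gas measurement at the arterial or venous site."""

    site: str  # "arterial" | "venous"
    po2: float  # mmHg
    hb: float  # g/dL
    so2: Optional[float] = None  # measured saturation fraction, if available
    temp: float = 37.0  # degrees C

    def __post_init__(self) -> None:
        if self.site not in ("arterial", "venous"):
            raise InvalidArgumentError(f"unknown site {self.site!r}")
        if self.po2 < 0:
            raise InvalidArgumentError("po2 must be non-negative")
        if self.hb < 0:
            raise InvalidArgumentError("hb must be non-negative")
        if self.so2 is not None and not (0.0 <= self.so2 <= 1.0):
            raise InvalidArgumentError("measured so2 must lie in [0, 1]")


@dataclass
class PerfusionRecord:
    """Paired arterial/venous samples plus flow and organ weight at one time."""

    arterial: BloodGasSample
    venous: BloodGasSample
    flow_q: float  # mL/min
    organ_weight: float  # g
    time: float = 0.0  # minutes

    def __post_init__(self) -> None:
        if self.flow_q < 0:
            raise InvalidArgumentError("flow_q must be non-negative")
        if self.organ_weight <= 0:
            raise InvalidArgumentError("organ_weight must be positive")
        if self.arterial.site != "arterial" or self.venous.site != "venous":
            raise InvalidInputError("record sites must be arterial/venous")


@dataclass
class CellImageSet:
    """Co-registered RFP/YFP/CFP frames over a timepoint grid.

    ``channels[t]`` maps channel name -> 2-D float array for timepoint index t.
    Timepoints are minutes, by default a 20-min grid from 0 to 180.
    """

    timepoints: np.ndarray
    channels: list[dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(self.channels) != self.timepoints.size:
            raise InvalidInputError("one channel dict per timepoint required")
        if self.timepoints.size >= 2 and not np.all(np.diff(self.timepoints) > 0):
            raise InvalidInputError("timepoints must be strictly increasing")
        for chans in self.channels:
            shapes = {c: a.shape for c, a in chans.items()}
            if len(set(shapes.values())) > 1:
                raise InvalidInputError(f"channels not co-registered: {shapes}")
            for name in ("RFP", "YFP", "CFP"):
                if name not in chans:
                    raise InvalidInputError(f"missing channel {name}")


GROUP_TABLE_COLUMNS = [
    "group",
    "replicate_id",
    "timepoint",
    "metric",
    "value",
    "unit",
    "qc_flag",
    "provenance",
]


def make_group_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Build a long-format GroupTable DataFrame from row dicts.

    Every row must carry provenance; (group, replicate_id, timepoint, metric)
    must be unique. Excluded rows stay in the table (flagged) but are dropped
    by every summary.
    """
    df = pd.DataFrame(list(rows), columns=GROUP_TABLE_COLUMNS)
    if len(df):
        if df["provenance"].isna().any() or (df["provenance"] == "").any():
            raise InvalidInputError("every GroupTable row needs provenance")
        key = ["group", "replicate_id", "timepoint", "metric"]
        if df.duplicated(subset=key).any():
            dupes = df[df.duplicated(subset=key, keep=False)][key]
            raise InvalidInputError(f"duplicate GroupTable keys:\n{dupes}")
    return df


def active_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows that may enter summaries: anything not flagged excluded."""
    if not len(table):
        return table
    return table[table["qc_flag"] != "excluded"]
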