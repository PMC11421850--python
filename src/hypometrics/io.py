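"""Readers and writers for the on-disk interchange formats.

Videos and image sets travel as multi-page TIFF (tifffile); traces and
records as small headered CSVs (pandas); synthetic ground truth as a JSON
sidecar. Nothing here does analysis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .synthio import SyntheticTruth
from .types import BloodGasSample, PerfusionRecord, TimeSeriesTrace, VideoStack


def write_video(path, video: VideoStack) -> None:
    tifffile.imwrite(
        path,
        video.frames,
        metadata={"frame_interval_s": video.frame_interval, "axes": "TYX"},
    )


def read_video(path, frame_interval: float | None = None) -> VideoStack:
    """Read a multi-page TIFF or a directory of PNG/TIFF frames."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
    else:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            if frame_interval is None:
                meta = tf.shaped_metadata or tf.imagej_metadata or {}
                if isinstance(meta, (list, tuple)):
                    meta = meta[0] if meta else {}
                frame_interval = float(meta.get("frame_interval_s", 0.1))
    if frames.ndim == 4:  # RGB -> luminance
        frames = frames[..., :3].astype(float) @ np.array([0.2126, 0.7152, 0.0722])
    info = np.iinfo(frames.dtype) if np.issubdtype(frames.dtype, np.integer) else None
    rng = (float(info.min), float(info.max)) if info else (float(frames.min()), float(frames.max()))
    return VideoStack(frames, frame_interval or 0.1, rng)


def write_trace(path, trace: TimeSeriesTrace) -> None:
    df = pd.DataFrame(
        {
            f"time_{trace.time_unit}": trace.times,
            "value": trace.values,
            "unit": trace.unit,
            "flag": ";".join(trace.qc_flags),
        }
    )
    df.to_csv(path, index=False)


def read_trace(path, time_unit: str = "min") -> TimeSeriesTrace:
    df = pd.read_csv(path)
    tcol = next(c for c in df.columns if c.startswith("time"))
    vcol = "value" if "value" in df.columns else df.columns[1]
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns else ""
    if "_" in tcol:
        time_unit = tcol.split("_", 1)[1]
    return TimeSeriesTrace(df[tcol].to_numpy(), df[vcol].to_numpy(), unit=unit, time_unit=time_unit)


PERFUSION_COLUMNS = [
    "time_min",
    "site",
    "po2_mmhg",
    "hb_g_dl",
    "so2",
    "temp_c",
    "flow_ml_min",
    "weight_g",
]


def write_perfusion_csv(path, records: Sequence[PerfusionRecord]) -> None:
    rows = []
    for rec in records:
        for s in (rec.arterial, rec.venous):
            rows.append(
                {
                    "time_min": rec.time,
                    "site": s.site,
                    "po2_mmhg": s.po2,
                    "hb_g_dl": s.hb,
                    "so2": s.so2 if s.so2 is not None else "",
                    "temp_c": s.temp,
                    "flow_ml_min": rec.flow_q,
                    "weight_g": rec.organ_weight,
                }
            )
    pd.DataFrame(rows, columns=PERFUSION_COLUMNS).to_csv(path, index=False)


def read_perfusion_csv(path) -> list[PerfusionRecord]:
    df = pd.read_csv(path)
    records = []
    for time, grp in df.groupby("time_min", sort=True):
        samples = {}
        for _, row in grp.iterrows():
            so2 = row.get("so2")
            so2 = None if pd.isna(so2) or so2 == "" else float(so2)
            samples[row["site"]] = BloodGasSample(
                row["site"], float(row["po2_mmhg"]), float(row["hb_g_dl"]), so2, float(row["temp_c"])
            )
        records.append(
            PerfusionRecord(
                samples["arterial"],
                samples["venous"],
                float(grp["flow_ml_min"].iloc[0]),
                float(grp["weight_g"].iloc[0]),
                time=float(time),
            )
        )
    return records


def write_truth(path, truth: SyntheticTruth) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
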