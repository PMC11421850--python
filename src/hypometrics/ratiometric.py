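"""Per-cell ratiometric ATP/ADP (YFP/CFP) quantification.

A genetically encoded ratiometric reporter shifts its YFP/CFP excitation
ratio with the cellular ATP/ADP ratio, so metabolic suppression reads out as
a falling per-cell YFP/CFP value. The pipeline mirrors a standard
CellProfiler-style workflow: (1) nuclei from the RFP marker (Otsu threshold,
8-connected components, size filter); (2) each cell defined as the nucleus
plus a 4-pixel ring around its edge, with overlaps resolved by
nearest-nucleus so masks stay disjoint; (3) per-cell mean YFP and CFP and
their ratio (ratio of means — robust to dim pixels); (4-6) per-image cell
count and mean ratio; (5) nearest-centroid tracking across the timepoint
grid; plus a per-pixel ratio image with a floor on the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels

from .types import (
    GROUP_TABLE_COLUMNS,
    CellImageSet,
    InvalidInputError,
)

CELL_RING_PX = 4  # the cell is the nucleus dilated by this many pixels


@dataclass
class CellMeasurement:
    cell_id: int
    yfp_mean: float
    cfp_mean: float
    ratio: float  # NaN when flagged undefined
    timepoint: float = 0.0
    centroid: tuple[float, float] = (np.nan, np.nan)
    area: int = 0
    flags: list = field(default_factory=list)


def segment_nuclei(
    rfp: np.ndarray,
    min_area: int = 20,
    max_area: int = 100000,
) -> np.ndarray:
    """Label nuclei in the RFP channel.

    Otsu threshold -> 8-connected components -> [min_area, max_area] size
    filter -> sequential labels 1..n. A blank (constant) image yields zero
    labels, which is a valid result, not an error.
    """
    rfp = np.asarray(rfp)
    if rfp.ndim != 2:
        raise InvalidInputError("rfp must be a 2-D image")
    if rfp.max() == rfp.min():
        return np.zeros(rfp.shape, dtype=np.int32)
    thr = threshold_otsu(rfp)
    labels = cc_label(rfp > thr, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for prop in regionprops(labels):
        if min_area <= prop.area <= max_area:
            out[labels == prop.label] = nxt
            nxt += 1
    return out


def expand_cells(nuclei: np.ndarray, ring_px: int = CELL_RING_PX) -> np.ndarray:
    """Cell masks: each nucleus grown by ``ring_px`` pixels (Euclidean).

    Expansion assigns each background pixel within ``ring_px`` of a nucleus
    to its nearest nucleus, so cell masks are disjoint by construction and
    each nucleus is a subset of its cell.
    """
    nuclei = np.asarray(nuclei)
    return expand_labels(nuclei, distance=ring_px)


def measure_cells(
    cells: np.ndarray,
    yfp: np.ndarray,
    cfp: np.ndarray,
    timepoint: float = 0.0,
) -> list[CellMeasurement]:
    """Per-cell mean YFP, mean CFP and ratio = mean YFP / mean CFP.

    A zero CFP mean flags the measurement ``undefined`` (NaN ratio) rather
    than raising.
    """
    cells = np.asarray(cells)
    if yfp.shape != cells.shape or cfp.shape != cells.shape:
        raise InvalidInputError("channel shapes must match the cell masks")
    ids = [int(i) for i in np.unique(cells) if i != 0]
    if not ids:
        return []
    yfp_means = ndimage.mean(yfp, labels=cells, index=ids)
    cfp_means = ndimage.mean(cfp, labels=cells, index=ids)
    centroids = ndimage.center_of_mass(np.ones_like(cells), labels=cells, index=ids)
    areas = ndimage.sum_labels(np.ones_like(cells), labels=cells, index=ids)
    out = []
    for cid, ym, cm, cen, area in zip(ids, yfp_means, cfp_means, centroids, areas):
        if cm > 0:
            out.append(
                CellMeasurement(cid, float(ym), float(cm), float(ym / cm), timepoint, cen, int(area))
            )
        else:
            out.append(
                CellMeasurement(
                    cid, float(ym), float(cm), np.nan, timepoint, cen, int(area), ["undefined"]
                )
            )
    return out


def image_summary(measurements: Sequence[CellMeasurement]) -> tuple[float, int]:
    """(mean per-cell ratio over non-flagged cells, cell count).

    An empty input returns (NaN, 0) — an undefined summary, not an error.
    The count reports all detected cells, flagged or not.
    """
    n = len(measurements)
    ratios = [m.ratio for m in measurements if not m.flags]
    if not ratios:
        return (float("nan"), n)
    return (float(np.mean(ratios)), n)


@dataclass
class Track:
    track_id: int
    timepoints: list
    cell_ids: list
    ratios: list

    def __len__(self) -> int:
        return len(self.timepoints)


def _segment_and_measure(chans: dict, timepoint: float, min_area: int, max_area: int):
    nuclei = segment_nuclei(chans["RFP"], min_area, max_area)
    cells = expand_cells(nuclei)
    meas = measure_cells(cells, chans["YFP"], chans["CFP"], timepoint)
    return nuclei, cells, meas


def track_timecourse(
    imgset: CellImageSet,
    max_displacement: Optional[float] = None,
    min_area: int = 20,
    max_area: int = 100000,
    grid_step: float = 20.0,
    provenance: str = "track_timecourse",
) -> tuple[pd.DataFrame, list[Track]]:
    """Per-timepoint image summaries plus nearest-centroid cell tracks.

    Timepoints must sit on the declared acquisition grid (multiples of
    ``grid_step`` minutes). Cells are linked to the nearest centroid of the
    previous timepoint within ``max_displacement`` (default: 2x the median
    nucleus radius); unmatched cells start new tracks. Summary rows are
    emitted per timepoint regardless of linkage success.
    """
    tps = imgset.timepoints
    if np.any(np.abs(np.round(tps / grid_step) * grid_step - tps) > 1e-6):
        raise InvalidInputError(f"timepoints must lie on a {grid_step}-min grid")
    rows = []
    tracks: list[Track] = []
    open_tracks: dict[int, Track] = {}  # track_id -> Track, keyed by last centroid
    last_centroids: dict[int, tuple] = {}
    next_track = 0
    for tp, chans in zip(tps, imgset.channels):
        nuclei, cells, meas = _segment_and_measure(chans, float(tp), min_area, max_area)
        if max_displacement is None:
            radii = [np.sqrt(p.area / np.pi) for p in regionprops(nuclei)]
            max_disp = 2.0 * float(np.median(radii)) if radii else 10.0
        else:
            max_disp = max_displacement
        mean_ratio, n_cells = image_summary(meas)
        rows.append(
            {
                "group": "",
                "replicate_id": "",
                "timepoint": float(tp),
                "metric": "mean_yfp_cfp_ratio",
                "value": mean_ratio,
                "unit": "",
                "qc_flag": "" if np.isfinite(mean_ratio) else "undefined",
                "provenance": f"{provenance};n_cells={n_cells}",
            }
        )
        # nearest-centroid linkage against open tracks
        new_open: dict[int, Track] = {}
        new_centroids: dict[int, tuple] = {}
        used = set()
        for m in meas:
            best, best_d = None, np.inf
            for tid, cen in last_centroids.items():
                if tid in used:
                    continue
                d = np.hypot(m.centroid[0] - cen[0], m.centroid[1] - cen[1])
                if d < best_d:
                    best, best_d = tid, d
            if best is not None and best_d <= max_disp:
                tr = open_tracks[best]
                used.add(best)
            else:
                tr = Track(next_track, [], [], [])
                tracks.append(tr)
                next_track += 1
            tr.timepoints.append(float(tp))
            tr.cell_ids.append(m.cell_id)
            tr.ratios.append(m.ratio)
            new_open[tr.track_id] = tr
            new_centroids[tr.track_id] = m.centroid
        open_tracks, last_centroids = new_open, new_centroids
    table = pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)
    return table, tracks


def ratio_image(yfp: np.ndarray, cfp: np.ndarray, epsilon: float = 1.0) -> np.ndarray:
    """Per-pixel YFP / max(CFP, epsilon); finite everywhere."""
    yfp = np.asarray(yfp, dtype=np.float64)
    cfp = np.asarray(cfp, dtype=np.float64)
    if yfp.shape != cfp.shape:
        raise InvalidInputError("yfp and cfp shapes differ")
    if epsilon <= 0:
        raise InvalidInputError("epsilon must be positive")
    return yfp / np.maximum(cfp, epsilon)
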