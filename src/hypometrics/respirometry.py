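"""Closed-chamber oxygen consumption rates with leak/bubble QC.

In a sealed respirometry vial dissolved O2 falls linearly while organisms
consume it; the oxygen consumption rate (OCR) is minus the slope of an
ordinary-least-squares line through the O2 trace. Vials with leaks (a
sustained rising segment) or bubbles (a single abrupt jump) are flagged and
excluded — flagged data are never silently dropped, and excluded traces are
refused by the fit rather than averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    GROUP_TABLE_COLUMNS,
    InsufficientDataError,
    InvalidArgumentError,
    QcExcludedError,
    TimeSeriesTrace,
    active_rows,
)


@dataclass
class OcrResult:
    """A fitted oxygen consumption rate (positive = consumption)."""

    rate: float  # o2 units / min
    fit_window: tuple[float, float]
    r_squared: float
    stderr: float
    unit: str = ""
    n_points: int = 0


def _noise_sd(values: np.ndarray) -> float:
    """Robust noise SD from detrended first differences."""
    d = np.diff(values)
    d = d - np.median(d)
    mad = np.median(np.abs(d))
    return 1.4826 * float(mad) / np.sqrt(2.0)


def qc_trace(
    trace: TimeSeriesTrace,
    leak_slope_threshold: float = 0.5,
    leak_min_duration: float = 5.0,
    jump_threshold: float = 8.0,
) -> TimeSeriesTrace:
    """Flag leaks and bubbles; mark the trace excluded when either is found.

    Leak: any rolling window of at least ``leak_min_duration`` minutes whose
    fitted slope exceeds +``leak_slope_threshold`` (O2 units/min).
    Bubble: a single-step change larger than ``jump_threshold`` times the
    robust noise SD of the first differences.
    """
    if len(trace) < 5:
        raise InsufficientDataError("QC needs at least 5 samples")
    t, v = trace.times, trace.values
    # rolling-window slope scan
    n = len(t)
    found_leak = False
    win_len = leak_min_duration
    i = 0
    for i in range(n):
        j = np.searchsorted(t, t[i] + win_len, side="left")
        if j >= n:
            j = n - 1
        if t[j] - t[i] < win_len - 1e-9 or j - i + 1 < 3:
            continue
        slope = stats.linregress(t[i : j + 1], v[i : j + 1]).slope
        if slope > leak_slope_threshold:
            found_leak = True
            break
    if found_leak:
        trace.flag("leak")
        trace.exclude("leak detected: rising O2 segment")
    sd = _noise_sd(v)
    jumps = np.abs(np.diff(v) - np.median(np.diff(v)))
    if sd > 0 and np.any(jumps > jump_threshold * sd):
        trace.flag("bubble")
        trace.exclude("bubble detected: abrupt sensor jump")
    return trace


def fit_ocr(
    trace: TimeSeriesTrace,
    fit_window: Optional[tuple[float, float]] = None,
    equilibration_skip: float = 0.0,
) -> OcrResult:
    """OLS linear fit o2 = a + b*t over the window; OCR = -b.

    Refuses traces excluded by QC. The window used is recorded in the result
    for provenance; default is the full trace after ``equilibration_skip``
    minutes.
    """
    if trace.excluded:
        raise QcExcludedError(f"trace excluded: {trace.exclusion_reason}")
    t, v = trace.times, trace.values
    if fit_window is None:
        fit_window = (float(t[0]) + equilibration_skip, float(t[-1]))
    t0, t1 = fit_window
    sel = (t >= t0 - 1e-12) & (t <= t1 + 1e-12)
    if sel.sum() < 3:
        raise InsufficientDataError("need >= 3 samples in the fit window")
    res = stats.linregress(t[sel], v[sel])
    rate = -float(res.slope)
    r2 = float(res.rvalue**2) if np.std(v[sel]) > 0 else 1.0
    return OcrResult(
        rate=rate,
        fit_window=(float(t0), float(t1)),
        r_squared=r2,
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        unit=f"{trace.unit}/min",
        n_points=int(sel.sum()),
    )


def ocr_table(
    results: dict[str, list[OcrResult]],
    provenance: str = "fit_ocr",
) -> pd.DataFrame:
    """Assemble {group: [OcrResult...]} into GroupTable rows."""
    rows = []
    for group, fits in results.items():
        for k, fit in enumerate(fits):
            rows.append(
                {
                    "group": group,
                    "replicate_id": f"{group}-{k}",
                    "timepoint": fit.fit_window[0],
                    "metric": "ocr",
                    "value": fit.rate,
                    "unit": fit.unit,
                    "qc_flag": "",
                    "provenance": f"{provenance};window={fit.fit_window}",
                }
            )
    return pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)


@dataclass
class FoldChange:
    value: float
    ci_low: float
    ci_high: float
    n_treated: int
    n_reference: int
    flags: list


def group_fold_change(
    table: pd.DataFrame,
    treated_label: str,
    reference_label: str,
    metric: str = "ocr",
    n_boot: int = 1000,
    seed: int = 0,
) -> FoldChange:
    """mean(treated)/mean(reference) with a bootstrap percentile interval.

    Excluded rows never contribute. A non-positive reference mean yields a
    NaN value flagged ``undefined`` instead of an error.
    """
    df = active_rows(table)
    df = df[df["metric"] == metric]
    tr = df[df["group"] == treated_label]["value"].to_numpy(float)
    rf = df[df["group"] == reference_label]["value"].to_numpy(float)
    if tr.size == 0 or rf.size == 0:
        raise InvalidArgumentError("both groups need at least one usable result")
    ref_mean = rf.mean()
    if ref_mean <= 0:
        return FoldChange(np.nan, np.nan, np.nan, tr.size, rf.size, ["undefined"])
    fold = tr.mean() / ref_mean
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = rng.choice(tr, size=tr.size, replace=True).mean()
        rb = rng.choice(rf, size=rf.size, replace=True).mean()
        boots[b] = tb / rb if rb > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return FoldChange(float(fold), float(lo), float(hi), tr.size, rf.size, [])


def relative_metabolic_rate(
    table: pd.DataFrame,
    baseline_window: tuple[float, float],
    metric: str = "ocr",
) -> pd.DataFrame:
    """Each OCR divided by the mean OCR over the baseline window.

    Returns the input rows with a ``relative_rate`` column; a non-positive
    baseline mean flags every row ``undefined`` with NaN rates.
    """
    df = active_rows(table)
    df = df[df["metric"] == metric].copy()
    t0, t1 = baseline_window
    base = df[(df["timepoint"] >= t0) & (df["timepoint"] <= t1)]["value"]
    if base.size == 0:
        raise InsufficientDataError("baseline window contains no results")
    base_mean = base.mean()
    if base_mean <= 0:
        df["relative_rate"] = np.nan
        df["qc_flag"] = "undefined"
        return df
    df["relative_rate"] = df["value"] / base_mean
    return df
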