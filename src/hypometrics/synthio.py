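"""Synthetic inputs with known ground truth for every analysis stage.

Each generator returns ``(data, SyntheticTruth)`` where the truth records the
generating parameters, so downstream estimators can be tested against exact
values without any downloaded data. Generators are deterministic: one RNG
stream per call, seeded explicitly; identical (params, seed) gives
byte-identical output.

What is emulated (and what is not): swimming tadpoles become dark Gaussian-
random-walk blobs on a bright dish — no kinematic realism; a beating heart
becomes a raised-sine pulsing disk; O2 sensor logs are piecewise-linear
depletion plus Gaussian sensor noise; perfusion records are constructed by
inverting the Fick/content formulas so the true MVO2 is exact; cell images
are disk nuclei with uniform channel intensities whose YFP/CFP quotient is
the stated truth; ECGs are schematic P-QRS-T trains. None of these model
optics, hemodynamics or biology beyond what the detectors need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import perfusion as perf
from .types import (
    BloodGasSample,
    CellImageSet,
    InvalidArgumentError,
    PerfusionRecord,
    TimeSeriesTrace,
    VideoStack,
)

UINT16_RANGE = (0.0, 65535.0)


@dataclass
class SyntheticTruth:
    """Ground truth attached to every generator output."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# swimming activity


def gen_swim_video(
    n_organisms: int = 5,
    activity_level: float = 0.5,
    n_frames: int = 50,
    frame_interval: float = 0.2,
    seed: int = 0,
    image_size: tuple[int, int] = (120, 120),
    blob_radius: int = 3,
    max_step: float = 6.0,
) -> tuple[VideoStack, SyntheticTruth]:
    """Dark blobs random-walking on a bright dish background.

    Per-frame displacement is a Gaussian random walk with step SD equal to
    ``activity_level * max_step`` pixels, so inter-frame difference grows
    monotonically with activity_level; activity_level 0 freezes every blob.
    Positions reflect at the dish walls.
    """
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    if n_organisms <= 0 or min(image_size) <= 0:
        raise InvalidArgumentError("n_organisms and image_size must be positive")
    if not (0.0 <= activity_level <= 1.0):
        raise InvalidArgumentError("activity_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_size
    lo, hi = UINT16_RANGE
    background = 0.9 * hi
    blob_value = 0.1 * hi
    margin = blob_radius + 1
    pos = rng.uniform([margin, margin], [h - margin, w - margin], size=(n_organisms, 2))
    # raw unit steps scale linearly with activity_level -> same seed, larger
    # level means strictly larger displacements
    steps = rng.standard_normal((n_frames - 1, n_organisms, 2))
    yy, xx = np.mgrid[0:h, 0:w]
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    step_sd = activity_level * max_step
    for t in range(n_frames):
        img = np.full((h, w), background)
        for i in range(n_organisms):
            cy, cx = pos[i]
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_radius**2
            img[mask] = blob_value
        frames[t] = np.round(img).astype(np.uint16)
        if t < n_frames - 1:
            pos = pos + step_sd * steps[t]
            # reflect at the dish walls
            upper = np.array([h - margin, w - margin], dtype=float)
            pos = margin + np.abs(pos - margin)
            pos = upper - np.abs(upper - pos)
            pos = np.clip(pos, margin, upper)
    video = VideoStack(frames, frame_interval, UINT16_RANGE)
    truth = SyntheticTruth(
        "swim_video",
        {
            "n_organisms": n_organisms,
            "activity_level": activity_level,
            "n_frames": n_frames,
            "frame_interval": frame_interval,
            "blob_radius": blob_radius,
            "max_step": max_step,
        },
        seed,
    )
    return video, truth


# ---------------------------------------------------------------------------
# heart video


def gen_heart_video(
    bpm: float = 60.0,
    duration: float = 10.0,
    frame_interval: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    image_size: tuple[int, int] = (64, 64),
    roi_radius: int = 12,
    amplitude: float = 20000.0,
    baseline: float = 20000.0,
) -> tuple[VideoStack, SyntheticTruth]:
    """A circular region pulsing in intensity at a known rate.

    The region-mean signal is amplitude * sin^2(pi * t * bpm / 60), which
    peaks once per beat at the beat midpoints and touches its minimum at the
    recorded beat onset times k * 60/bpm.
    """
    if bpm <= 0 or duration <= 0 or frame_interval <= 0:
        raise InvalidArgumentError("bpm, duration and frame_interval must be positive")
    if bpm / 60.0 >= 1.0 / (2.0 * frame_interval):
        raise InvalidArgumentError(
            f"bpm {bpm} violates Nyquist at frame_interval {frame_interval}"
        )
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration / frame_interval))
    if n_frames < 2:
        raise InvalidArgumentError("duration too short for the frame interval")
    t = np.arange(n_frames) * frame_interval
    period = 60.0 / bpm
    pulse = np.sin(np.pi * t / period) ** 2  # in [0, 1], one max per beat
    h, w = image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius**2
    lo, hi = UINT16_RANGE
    frames = np.empty((n_frames, h, w), dtype=np.uint16)
    for k in range(n_frames):
        img = np.full((h, w), baseline)
        img[roi] = baseline + amplitude * pulse[k]
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[k] = np.round(np.clip(img, lo, hi)).astype(np.uint16)
    onsets = np.arange(0.0, duration - 1e-12, period)
    truth = SyntheticTruth(
        "heart_video",
        {
            "bpm": bpm,
            "duration": duration,
            "frame_interval": frame_interval,
            "noise_sd": noise_sd,
            "beat_onsets": onsets.tolist(),
            "roi": (cy, cx, float(roi_radius)),
            "amplitude": amplitude,
        },
        seed,
    )
    return VideoStack(frames, frame_interval, UINT16_RANGE), truth


# ---------------------------------------------------------------------------
# closed-chamber O2 traces


def gen_o2_trace(
    baseline_rate: float = 2.0,
    fold_change: float = 1.0,
    onset_time: float = 30.0,
    duration: float = 60.0,
    sample_interval: float = 1.0,
    noise_sd: float = 0.0,
    inject_leak: bool = False,
    seed: int = 0,
    o2_start: float = 100.0,
    unit: str = "%air",
    n_organisms: int = 5,
) -> tuple[TimeSeriesTrace, SyntheticTruth]:
    """Closed-vial O2 depletion: linear decline with optional drug-onset
    slope change, Gaussian sensor noise and an optional leak artifact.

    O2 falls at ``baseline_rate`` (units/min) before ``onset_time`` and at
    ``baseline_rate * fold_change`` after. ``inject_leak`` overwrites a
    10-minute mid-trace window with a rising segment (slope = +baseline_rate),
    emulating the vial leaks the QC stage must catch.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be positive")
    if baseline_rate < 0 or fold_change < 0:
        raise InvalidArgumentError("rates must be non-negative")
    if sample_interval <= 0:
        raise InvalidArgumentError("sample_interval must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * sample_interval, sample_interval)
    pre = np.minimum(t, onset_time)
    post = np.maximum(t - onset_time, 0.0)
    o2 = o2_start - baseline_rate * pre - baseline_rate * fold_change * post
    leak_window = None
    if inject_leak:
        leak_len = min(10.0, duration / 3.0)
        t0 = duration / 2.0 - leak_len / 2.0
        t1 = t0 + leak_len
        leak_window = (t0, t1)
        in_leak = (t >= t0) & (t <= t1)
        o2 = o2.copy()
        o2[in_leak] = o2[in_leak][0] + baseline_rate * (t[in_leak] - t0)
        after = t > t1
        if after.any():
            # resume the decline from the (raised) leak end value
            shift = o2[in_leak][-1] - o2[after][0] - baseline_rate * sample_interval
            o2[after] += shift
    if noise_sd > 0:
        o2 = o2 + rng.normal(0.0, noise_sd, size=o2.shape)
    trace = TimeSeriesTrace(
        t,
        o2,
        unit=unit,
        time_unit="min",
        meta={"n_organisms": n_organisms},
    )
    truth = SyntheticTruth(
        "o2_trace",
        {
            "baseline_rate": baseline_rate,
            "post_rate": baseline_rate * fold_change,
            "fold_change": fold_change,
            "onset_time": onset_time,
            "noise_sd": noise_sd,
            "leak_window": leak_window,
            "o2_start": o2_start,
        },
        seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# perfusion records


def gen_perfusion_records(
    true_mvo2: float = 2.4,
    hb: float = 3.0,
    q: float = 300.0,
    weight: float = 300.0,
    temp: float = 21.0,
    n_timepoints: int = 5,
    seed: int = 0,
    arterial_po2: float = 400.0,
    noise_sd: float = 0.0,
    constants: perf.PerfusionConstants | None = None,
) -> tuple[list[PerfusionRecord], SyntheticTruth]:
    """Perfusion records whose exact MVO2 is known by construction.

    Fixes the arterial sample, computes the venous oxygen content the Fick
    formula requires for ``true_mvo2``, and inverts the content function to a
    Severinghaus-consistent venous pO2 (so both measured and computed SO2
    modes round-trip). ``noise_sd`` jitters the venous pO2 in mmHg.
    """
    if min(hb, q, weight) <= 0 or true_mvo2 < 0 or arterial_po2 <= 0:
        raise InvalidArgumentError("physical quantities must be positive")
    constants = constants or perf.PerfusionConstants()
    rng = np.random.default_rng(seed)
    art = BloodGasSample("arterial", arterial_po2, hb, None, temp)
    art.so2 = constants.so2(arterial_po2)
    content_a = perf.o2_content(art, constants, "computed")
    # MVO2 = (Ca - Cv)/100 * Q / W * 100  =>  Cv = Ca - MVO2 * W / Q
    content_v = content_a - true_mvo2 * weight / q
    if content_v < 0:
        raise InvalidArgumentError(
            f"infeasible: required venous content {content_v:.3f} < 0 "
            "(raise Q or arterial pO2, or lower true_mvo2)"
        )
    if content_v == 0:
        venous_po2 = 0.0
    else:
        venous_po2 = perf.invert_content_to_po2(content_v, hb, temp, constants)
    records = []
    for i in range(n_timepoints):
        vpo2 = venous_po2
        if noise_sd > 0:
            vpo2 = max(0.0, vpo2 + rng.normal(0.0, noise_sd))
        ven = BloodGasSample("venous", vpo2, hb, constants.so2(vpo2), temp)
        arts = BloodGasSample("arterial", arterial_po2, hb, art.so2, temp)
        records.append(PerfusionRecord(arts, ven, q, weight, time=float(i)))
    truth = SyntheticTruth(
        "perfusion_records",
        {
            "true_mvo2": true_mvo2,
            "hb": hb,
            "q": q,
            "weight": weight,
            "temp": temp,
            "arterial_po2": arterial_po2,
            "venous_po2": venous_po2,
            "content_a": content_a,
            "content_v": content_v,
            "noise_sd": noise_sd,
        },
        seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# ratiometric cell images


def gen_cell_images(
    n_cells: int = 10,
    true_ratios: Sequence[float] | None = None,
    image_size: int = 256,
    nucleus_radius: int = 6,
    noise_sd: float = 0.0,
    n_timepoints: int = 1,
    seed: int = 0,
    cfp_level: float = 1000.0,
    rfp_level: float = 30000.0,
    background: float = 50.0,
    drift_px: float = 0.0,
) -> tuple[CellImageSet, SyntheticTruth]:
    """RFP/YFP/CFP image stacks with known per-cell YFP/CFP ratios.

    Nuclei are disks of ``nucleus_radius`` placed so that centers are at
    least 2*(r+4)+2 px apart — the 4-px measurement rings can never touch.
    Over each nucleus-plus-ring region CFP is uniform at ``cfp_level`` and
    YFP at ``ratio * cfp_level``, so the noise-free ratio is exact; Gaussian
    noise is added afterwards. Arrays are float32 to keep ratios exact.
    ``drift_px`` shifts all cells per timepoint (for tracking tests).
    """
    if true_ratios is None:
        rng0 = np.random.default_rng(seed)
        true_ratios = rng0.uniform(0.8, 2.4, size=n_cells).tolist()
    true_ratios = list(true_ratios)
    if len(true_ratios) != n_cells:
        raise InvalidArgumentError("need one true ratio per cell")
    # uniform-intensity region radius r+5.5 strictly contains the analysis
    # mask (nucleus + 4-px ring), so measured means are exact noise-free;
    # separation keeps painted regions disjoint (stricter than the 2(r+4)+2
    # floor the ring analysis itself needs)
    paint_radius = nucleus_radius + 5.5
    min_sep = int(np.ceil(2 * paint_radius + 2))
    margin = nucleus_radius + 8
    rng = np.random.default_rng(seed)
    # rejection-sample centers with the spacing guarantee
    centers: list[tuple[float, float]] = []
    total_drift = drift_px * max(n_timepoints - 1, 0)
    attempts = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 20000:
            raise InvalidArgumentError(
                f"cannot place {n_cells} cells with spacing {min_sep} in "
                f"{image_size}x{image_size} image"
            )
        c = rng.uniform(margin, image_size - margin - total_drift, size=2)
        if all((c[0] - y) ** 2 + (c[1] - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((float(c[0]), float(c[1])))
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    channel_stacks = []
    for tp in range(n_timepoints):
        rfp = np.full((image_size, image_size), background, dtype=np.float32)
        yfp = np.full_like(rfp, background)
        cfp = np.full_like(rfp, background)
        for (cy, cx), ratio in zip(centers, true_ratios):
            cy, cx = cy + tp * drift_px, cx + tp * drift_px
            nuc = (yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius**2
            region = (yy - cy) ** 2 + (xx - cx) ** 2 <= paint_radius**2
            rfp[nuc] = rfp_level
            cfp[region] = cfp_level
            yfp[region] = np.float32(ratio) * np.float32(cfp_level)
        if noise_sd > 0:
            yfp = yfp + rng.normal(0.0, noise_sd, yfp.shape).astype(np.float32)
            cfp = cfp + rng.normal(0.0, noise_sd, cfp.shape).astype(np.float32)
            rfp = rfp + rng.normal(0.0, noise_sd, rfp.shape).astype(np.float32)
        channel_stacks.append(
            {"RFP": np.clip(rfp, 0, None), "YFP": np.clip(yfp, 0, None), "CFP": np.clip(cfp, 0, None)}
        )
    timepoints = np.arange(n_timepoints) * 20.0
    imgset = CellImageSet(timepoints, channel_stacks)
    truth = SyntheticTruth(
        "cell_images",
        {
            "n_cells": n_cells,
            "true_ratios": true_ratios,
            "centers": centers,
            "nucleus_radius": nucleus_radius,
            "noise_sd": noise_sd,
            "cfp_level": cfp_level,
            "drift_px": drift_px,
        },
        seed,
    )
    return imgset, truth


# ---------------------------------------------------------------------------
# ECG


def gen_ecg(
    bpm: float = 80.0,
    qrs_width: float = 0.08,
    st_offset: float = 0.0,
    duration: float = 30.0,
    fs: float = 1000.0,
    seed: int = 0,
    r_amplitude: float = 1.0,
    noise_sd: float = 0.0,
) -> tuple[TimeSeriesTrace, SyntheticTruth]:
    """Schematic P-QRS-T waveform train on a zero isoelectric baseline.

    The R complex is a raised-cosine bump scaled so its width at 10% of the
    R amplitude equals ``qrs_width`` (matching the detector's 10%-threshold
    definition); the ST plateau at ``st_offset`` mV runs from the QRS end to
    the T wave 160 ms later.
    """
    if fs < 250:
        raise InvalidArgumentError("fs must be >= 250 Hz")
    if bpm <= 0 or duration <= 0:
        raise InvalidArgumentError("bpm and duration must be positive")
    period = 60.0 / bpm
    if qrs_width >= period:
        raise InvalidArgumentError("qrs_width must be shorter than the beat period")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    # raised cosine full width W has 10%-amplitude width W*arccos(-0.8)/pi
    w_full = qrs_width * np.pi / np.arccos(2 * 0.1 - 1.0)
    r_times = np.arange(0.5 * period, duration - 1e-12, period)
    st_len = 0.16  # s, QRS end -> T onset
    for r0 in r_times:
        # QRS
        in_qrs = np.abs(t - r0) < w_full / 2
        sig[in_qrs] += r_amplitude * 0.5 * (1 + np.cos(2 * np.pi * (t[in_qrs] - r0) / w_full))
        # ST plateau with smooth (cosine-ramped) end into the T wave
        qrs_end = r0 + w_full / 2
        in_st = (t >= qrs_end) & (t < qrs_end + st_len)
        sig[in_st] += st_offset
        # T wave: gaussian bump after the ST segment
        t_center = qrs_end + st_len + 0.04
        sig += 0.25 * r_amplitude * np.exp(-0.5 * ((t - t_center) / 0.025) ** 2)
        # P wave before the QRS
        p_center = r0 - w_full / 2 - 0.10
        sig += 0.12 * r_amplitude * np.exp(-0.5 * ((t - p_center) / 0.02) ** 2)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, n)
    trace = TimeSeriesTrace(t, sig, unit="mV", time_unit="s", meta={"fs": fs})
    truth = SyntheticTruth(
        "ecg",
        {
            "bpm": bpm,
            "qrs_width": qrs_width,
            "st_offset": st_offset,
            "r_amplitude": r_amplitude,
            "r_times": r_times.tolist(),
            "fs": fs,
            "noise_sd": noise_sd,
        },
        seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# binding dose-response (helper for the assays module)


def gen_binding_series(
    ic50: float = 3470.0,
    hill: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    top: float = 100.0,
    bottom: float = 0.0,
    n_conc: int = 8,
    c_max: float = 10000.0,
    dilution: float = 3.0,
):
    """Percent-specific-binding series from a four-parameter logistic truth.

    Default concentration ladder: 8 points, threefold dilutions from 10 uM.
    Returns (concentrations nM, binding %, SyntheticTruth).
    """
    if ic50 <= 0 or hill <= 0:
        raise InvalidArgumentError("ic50 and hill must be positive")
    rng = np.random.default_rng(seed)
    conc = c_max / dilution ** np.arange(n_conc)
    binding = bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)
    if noise_sd > 0:
        binding = binding + rng.normal(0.0, noise_sd, n_conc)
    truth = SyntheticTruth(
        "binding_series",
        {"ic50": ic50, "hill": hill, "top": top, "bottom": bottom, "noise_sd": noise_sd},
        seed,
    )
    return conc, binding, truth
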