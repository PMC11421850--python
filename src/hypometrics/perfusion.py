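"""Perfusate oxygen content and whole-organ oxygen consumption (MVO2).

For an ex vivo perfused organ the Fick principle gives the oxygen consumption
per 100 g of tissue from the arterio-venous content difference and flow:

    MVO2 = (([O2]a - [O2]v) / 100 * Q / weight) * 100   [mL O2/min/100 g]

with oxygen content per dL of perfusate

    [O2] = 1.34 * Hb * SO2 + K(T) * pO2                 [mL O2/dL]

where 1.34 mL O2 binds per gram of saturated hemoglobin, SO2 is the
hemoglobin saturation fraction and K(T) the temperature-adjusted oxygen
solubility coefficient (mL O2/dL/mmHg). When no co-oximeter saturation is
available SO2 is computed from pO2 with the Severinghaus closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import (
    BloodGasSample,
    InvalidArgumentError,
    MissingFieldError,
    PerfusionRecord,
)

HB_O2_CAPACITY = 1.34  # mL O2 per g saturated hemoglobin

# Oxygen solubility in aqueous perfusate, mL O2/dL/mmHg, versus temperature.
# Physiological plasma-solubility scale: 0.00415 near 4 C declining to
# ~0.003 at body temperature; interpolated piecewise-linearly and swappable.
DEFAULT_K_TABLE: tuple[tuple[float, float], ...] = (
    (4.0, 0.00415),
    (10.0, 0.00385),
    (15.0, 0.00361),
    (20.0, 0.00340),
    (25.0, 0.00321),
    (30.0, 0.00309),
    (35.0, 0.00302),
    (37.0, 0.00300),
    (40.0, 0.00295),
)


def severinghaus_so2(po2):
    """Hemoglobin O2 saturation fraction from pO2 (mmHg), Severinghaus form.

    SO2 = 1 / (23400 / (pO2^3 + 150 pO2) + 1)

    Strictly increasing, 0 at pO2 = 0 and approaching 1 at high tension; the
    half-saturation point sits near 26.9 mmHg (human blood P50).
    """
    po2_arr = np.asarray(po2, dtype=float)
    if np.any(po2_arr < 0):
        raise InvalidArgumentError("po2 must be non-negative")
    with np.errstate(divide="ignore"):
        denom = 23400.0 / (po2_arr**3 + 150.0 * po2_arr) + 1.0
    so2 = np.where(po2_arr > 0, 1.0 / denom, 0.0)
    return float(so2) if np.isscalar(po2) or so2.ndim == 0 else so2


def severinghaus_po2(so2: float, lo: float = 1e-9, hi: float = 5000.0) -> float:
    """Numerical inverse of :func:`severinghaus_so2` by bisection/Brent."""
    if not (0.0 < so2 < 1.0):
        raise InvalidArgumentError("so2 must lie strictly in (0, 1) to invert")
    return float(brentq(lambda p: severinghaus_so2(p) - so2, lo, hi, xtol=1e-12))


@dataclass
class PerfusionConstants:
    """Physical constants of the content calculation.

    hb_capacity is fixed at 1.34 mL O2/g Hb; k_table maps temperature (C) to
    the solubility coefficient and is interpolated piecewise-linearly; p50
    is an optional saturation-curve override (scales pO2 by 26.86/p50 before
    the Severinghaus form, for non-human oxygen carriers).
    """

    hb_capacity: float = HB_O2_CAPACITY
    k_table: tuple[tuple[float, float], ...] = DEFAULT_K_TABLE
    p50: Optional[float] = None
    temp_tolerance: float = 0.5  # max arterial/venous temperature mismatch, C

    _P50_HUMAN = 26.86

    def k_solubility(self, temp: float) -> float:
        temps = np.array([t for t, _ in self.k_table])
        ks = np.array([k for _, k in self.k_table])
        return float(np.interp(temp, temps, ks))

    def so2(self, po2: float) -> float:
        if self.p50 is not None:
            po2 = po2 * self._P50_HUMAN / self.p50
        return severinghaus_so2(po2)


@dataclass
class MvO2Result:
    value: float  # mL O2/min/100 g
    content_a: float  # mL O2/dL
    content_v: float  # mL O2/dL
    k_used: float
    so2_source: str
    time: float = 0.0
    warnings: list[str] = field(default_factory=list)


def o2_content(
    sample: BloodGasSample,
    constants: PerfusionConstants | None = None,
    so2_source: str = "auto",
) -> float:
    """Oxygen content of a perfusate sample in mL O2/dL.

    so2_source: "measured" uses the blood-gas analyzer SO2 (error if absent),
    "computed" uses the Severinghaus curve on pO2, "auto" prefers measured.
    """
    constants = constants or PerfusionConstants()
    if so2_source == "measured":
        if sample.so2 is None:
            raise MissingFieldError("sample has no measured so2")
        so2 = sample.so2
    elif so2_source == "computed":
        so2 = constants.so2(sample.po2)
    elif so2_source == "auto":
        so2 = sample.so2 if sample.so2 is not None else constants.so2(sample.po2)
    else:
        raise InvalidArgumentError(f"unknown so2_source {so2_source!r}")
    k = constants.k_solubility(sample.temp)
    return constants.hb_capacity * sample.hb * so2 + k * sample.po2


def compute_mvo2(
    record: PerfusionRecord,
    constants: PerfusionConstants | None = None,
    so2_source: str = "auto",
) -> MvO2Result:
    """Myocardial (or limb) oxygen consumption from one perfusion record.

    Negative values (venous content above arterial) are returned with a
    warning flag rather than clipped: they signal a measurement anomaly the
    analyst should see.
    """
    constants = constants or PerfusionConstants()
    dt = abs(record.arterial.temp - record.venous.temp)
    warnings = []
    if dt > constants.temp_tolerance:
        warnings.append(f"site temperature mismatch {dt:.2f} C")
    content_a = o2_content(record.arterial, constants, so2_source)
    content_v = o2_content(record.venous, constants, so2_source)
    mvo2 = ((content_a - content_v) / 100.0 * record.flow_q / record.organ_weight) * 100.0
    if content_a < content_v:
        warnings.append("negative MVO2: venous content exceeds arterial")
    return MvO2Result(
        value=mvo2,
        content_a=content_a,
        content_v=content_v,
        k_used=constants.k_solubility(record.arterial.temp),
        so2_source=so2_source,
        time=record.time,
        warnings=warnings,
    )


def mvo2_timecourse(
    records: Iterable[PerfusionRecord],
    constants: PerfusionConstants | None = None,
    so2_source: str = "auto",
    group: str = "",
    replicate_id: str = "",
) -> pd.DataFrame:
    """One MVO2 GroupTable row per record, with provenance of K and SO2 source."""
    constants = constants or PerfusionConstants()
    rows = []
    for rec in records:
        res = compute_mvo2(rec, constants, so2_source)
        rows.append(
            {
                "group": group,
                "replicate_id": replicate_id,
                "timepoint": rec.time,
                "metric": "mvo2",
                "value": res.value,
                "unit": "mL O2/min/100 g",
                "qc_flag": ";".join(res.warnings),
                "provenance": f"so2_source={res.so2_source};K={res.k_used:.6g}",
            }
        )
    from .types import GROUP_TABLE_COLUMNS

    return pd.DataFrame(rows, columns=GROUP_TABLE_COLUMNS)


def invert_content_to_po2(
    content: float, hb: float, temp: float, constants: PerfusionConstants | None = None
) -> float:
    """Solve for the pO2 whose Severinghaus-consistent content equals ``content``.

    The content function 1.34*Hb*SO2(p) + K*p is strictly increasing in p, so
    the root is unique; solved by Brent to 1e-14 (used by the synthetic
    perfusion generator to construct records with a known true MVO2).
    """
    constants = constants or PerfusionConstants()
    if content < 0:
        raise InvalidArgumentError("content must be non-negative")
    if content == 0:
        return 0.0
    sample = lambda p: BloodGasSample("arterial", p, hb, None, temp)  # noqa: E731
    f = lambda p: o2_content(sample(p), constants, "computed") - content  # noqa: E731
    hi = 10.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e7:
            raise InvalidArgumentError("content not attainable at any pO2")
    return float(brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-15))
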