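"""Exactly specified assay computations: TEER, comparative CT, binding IC50.

TEER (barrier integrity on-chip): the impedance magnitude at 100 Hz minus
the magnitude at 100 kHz isolates the tissue contribution from the
electrode/medium background; reported in ohms, negative values flagged.

Comparative CT: relative gene expression 2^-ddCT, with dCT = CT(target) -
CT(housekeeping, GAPDH role) per sample and ddCT the treated-minus-control
difference of group mean dCTs.

Binding: four-parameter logistic competitive-binding fit
B(c) = bottom + (top - bottom) / (1 + (c / IC50)^h) on percent specific
binding, parameterized on log-concentration for conditioning; with
asymptotes constrained to 0/100 by default. High-affinity ligands whose
IC50 falls below the tested range are reported as a bounded estimate
("IC50 < c_min") rather than a number, and series with no inflection are
flagged non-converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .types import InsufficientDataError, InvalidArgumentError, InvalidInputError


@dataclass
class ImpedancePair:
    chip_id: str
    time: float  # hours
    z_100hz: float  # ohm
    z_100khz: float  # ohm

    def __post_init__(self) -> None:
        if self.z_100hz < 0 or self.z_100khz < 0:
            raise InvalidArgumentError("impedances must be non-negative")


@dataclass
class TeerResult:
    tissue_impedance: float  # ohm
    chip_id: str
    time: float
    anomalous: bool = False


def teer(pair: ImpedancePair) -> TeerResult:
    """Tissue impedance = Z(100 Hz) - Z(100 kHz), in ohms.

    Negative results are physically anomalous (the low-frequency magnitude
    should dominate) and are returned flagged, never dropped.
    """
    value = pair.z_100hz - pair.z_100khz
    return TeerResult(float(value), pair.chip_id, pair.time, anomalous=value < 0)


@dataclass
class QpcrRecord:
    sample_id: str
    group: str
    ct_target: float
    ct_housekeeping: float
    target: str = ""

    def __post_init__(self) -> None:
        for ct in (self.ct_target, self.ct_housekeeping):
            if not np.isfinite(ct) or not (0 < ct <= 40):
                raise InvalidArgumentError(f"CT {ct} outside (0, 40]")


@dataclass
class DdctResult:
    fold_change: float
    ddct: float
    mean_dct_treated: float
    mean_dct_control: float
    n_treated: int
    n_control: int


def ddct_fold_change(
    records: Sequence[QpcrRecord],
    treated_label: str,
    control_label: str,
) -> DdctResult:
    """Relative expression by the comparative CT (2^-ddCT) method.

    dCT = CT(target) - CT(housekeeping) per sample; group dCTs are averaged
    before exponentiation; fold = 2^-(mean dCT treated - mean dCT control).
    """
    dct = {treated_label: [], control_label: []}
    for r in records:
        if r.group in dct:
            dct[r.group].append(r.ct_target - r.ct_housekeeping)
    if not dct[treated_label] or not dct[control_label]:
        raise InvalidInputError("need at least one record in each group")
    m_t = float(np.mean(dct[treated_label]))
    m_c = float(np.mean(dct[control_label]))
    ddct = m_t - m_c
    return DdctResult(
        fold_change=float(2.0 ** (-ddct)),
        ddct=ddct,
        mean_dct_treated=m_t,
        mean_dct_control=m_c,
        n_treated=len(dct[treated_label]),
        n_control=len(dct[control_label]),
    )


@dataclass
class BindingSeries:
    concentrations: np.ndarray  # nM
    percent_specific_binding: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.percent_specific_binding = np.asarray(
            self.percent_specific_binding, dtype=float
        )
        if self.concentrations.shape != self.percent_specific_binding.shape:
            raise InvalidInputError("concentration and binding lengths differ")
        if np.any(self.concentrations <= 0):
            raise InvalidArgumentError("concentrations must be positive")


@dataclass
class BindingFit:
    ic50: Optional[float]  # nM; None when not estimable
    hill_slope: Optional[float]
    top: float = 100.0
    bottom: float = 0.0
    converged: bool = False
    bounded_estimate: Optional[str] = None  # e.g. "IC50 < 4.6 nM"
    residual_sd: float = np.nan
    flags: list = field(default_factory=list)


def _logistic(logc, log_ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_binding(series: BindingSeries, constrain_asymptotes: bool = True) -> BindingFit:
    """Fit IC50 and Hill slope of a percent-specific-binding series.

    Degenerate series (no inflection: the observed span is under 20% of the
    asymptote span) return a non-convergence flag. A fitted IC50 below the
    lowest tested concentration returns a bounded estimate "IC50 < c_min",
    mirroring how very-high-affinity ligands are reported.
    """
    c = series.concentrations
    b = series.percent_specific_binding
    n_params = 2 if constrain_asymptotes else 4
    if c.size < max(5, n_params + 1):
        raise InsufficientDataError("need at least 5 concentration points")
    logc = np.log10(c)
    span = b.max() - b.min()
    top0, bot0 = (100.0, 0.0) if constrain_asymptotes else (b.max(), b.min())
    if span < 0.2 * max(top0 - bot0, 1e-9):
        return BindingFit(None, None, top0, bot0, False, None, np.nan, ["no_inflection"])
    # initial IC50: concentration nearest the half-maximal response
    half = 0.5 * (top0 + bot0)
    log_ic50_0 = logc[np.argmin(np.abs(b - half))]
    try:
        if constrain_asymptotes:
            popt, _ = curve_fit(
                lambda lc, li, h: _logistic(lc, li, h, 100.0, 0.0),
                logc,
                b,
                p0=[log_ic50_0, 1.0],
                maxfev=20000,
            )
            log_ic50, hill = popt
            top, bottom = 100.0, 0.0
        else:
            popt, _ = curve_fit(
                _logistic,
                logc,
                b,
                p0=[log_ic50_0, 1.0, top0, bot0],
                maxfev=20000,
            )
            log_ic50, hill, top, bottom = popt
    except RuntimeError:
        return BindingFit(None, None, top0, bot0, False, None, np.nan, ["no_convergence"])
    ic50 = float(10.0**log_ic50)
    resid = b - _logistic(logc, *popt) if not constrain_asymptotes else b - _logistic(
        logc, log_ic50, hill, 100.0, 0.0
    )
    rsd = float(np.std(resid, ddof=min(n_params, resid.size - 1)))
    c_min = float(c.min())
    if ic50 < c_min:
        return BindingFit(
            None,
            float(hill),
            float(top),
            float(bottom),
            False,
            f"IC50 < {c_min:g} nM",
            rsd,
            ["below_tested_range"],
        )
    return BindingFit(ic50, float(hill), float(top), float(bottom), True, None, rsd)


def teer_table(pairs: Sequence[ImpedancePair]) -> pd.DataFrame:
    """TEER results for a set of impedance pairs, one row per measurement."""
    rows = [
        {
            "chip_id": p.chip_id,
            "time_h": p.time,
            "tissue_impedance_ohm": (r := teer(p)).tissue_impedance,
            "anomalous": r.anomalous,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows)
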