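"""Kinase-assay dose–response analysis.

Percent inhibition normalizes TR-FRET plate signal ratios (665 nm/615 nm)
between two controls:

    inhibition = 100 · (R_noCompound − R_sample) / (R_noCompound − R_noKinase)

so the no-compound control reads 0 % and the no-kinase control reads 100 %.
IC50 is fitted with a four-parameter logistic (4PL) on log10 concentration,
with top/bottom box-constrained to [−10, 110] %. Both the relative IC50
(the fitted midpoint between top and bottom) and the absolute 50 % crossing
are reported; curves that never reach 50 % inhibition within the tested
range are censored as "> max tested concentration".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

PLATE_ROLES = ("sample", "no_compound_control", "no_kinase_control")


@dataclass
class PlateReading:
    well: str
    concentration_um: float  # 0 for controls
    signal_ratio: float      # 665 nm / 615 nm
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.role not in PLATE_ROLES:
            raise ValueError(f"unknown plate role {self.role!r}")
        if self.signal_ratio <= 0:
            raise ValueError("signal_ratio must be positive")


@dataclass
class DoseResponseCurve:
    concentrations_um: np.ndarray
    inhibition_percent: np.ndarray
    ic50_um: float | None          # relative IC50 (fitted midpoint)
    absolute_ic50_um: float | None  # concentration crossing 50 % inhibition
    hill_slope: float | None
    top: float | None
    bottom: float | None
    converged: bool
    censored: bool
    censor_bound_um: float | None  # "> bound" when censored
    rss: float | None

    def summary(self) -> str:
        if self.censored:
            return f"IC50 > {self.censor_bound_um:g} µM"
        return f"IC50 = {self.ic50_um:.3g} µM (hill {self.hill_slope:.2f})"


def dilution_series(initial_um: float = 50.0, points: int = 10,
                    factor: float = 2.0) -> np.ndarray:
    """Descending serial dilution: c_k = initial / factor**k, k = 0..points−1."""
    if initial_um <= 0:
        raise ValueError("initial concentration must be positive")
    if points < 2:
        raise ValueError("need at least 2 points")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    return initial_um / factor ** np.arange(points)


def percent_inhibition(readings: Sequence[PlateReading]) -> pd.DataFrame:
    """Per-concentration inhibition from one plate group.

    Control wells are averaged when replicated; sample wells at the same
    concentration are likewise averaged.
    """
    by_role: dict[str, list[PlateReading]] = {r: [] for r in PLATE_ROLES}
    for reading in readings:
        by_role[reading.role].append(reading)
    if not by_role["no_compound_control"] or not by_role["no_kinase_control"]:
        raise ValueError("plate group needs both control roles")
    if not by_role["sample"]:
        raise ValueError("plate group has no sample wells")
    r_nc = float(np.mean([r.signal_ratio for r in by_role["no_compound_control"]]))
    r_nk = float(np.mean([r.signal_ratio for r in by_role["no_kinase_control"]]))
    window = r_nc - r_nk
    if window == 0:
        raise ValueError("assay window collapsed: control ratios are equal")
    samples = pd.DataFrame({
        "concentration_um": [r.concentration_um for r in by_role["sample"]],
        "signal_ratio": [r.signal_ratio for r in by_role["sample"]],
    })
    grouped = samples.groupby("concentration_um", sort=False)["signal_ratio"].mean()
    inhibition = 100.0 * (r_nc - grouped) / window
    out = pd.DataFrame({"concentration_um": grouped.index.to_numpy(),
                        "inhibition_percent": inhibition.to_numpy()})
    return out.sort_values("concentration_um", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# 4PL fitting
# ---------------------------------------------------------------------------

def _logistic4(logc: np.ndarray, bottom: float, top: float, log_ic50: float,
               hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - logc)))


_BOUND_LO = -10.0
_BOUND_HI = 110.0


def _initial_guess(logc: np.ndarray, y: np.ndarray) -> list[float]:
    bottom = float(np.clip(y.min(), _BOUND_LO, _BOUND_HI))
    top = float(np.clip(y.max(), _BOUND_LO, _BOUND_HI))
    mid = (top + bottom) / 2.0
    # linear interpolation of the midpoint crossing for the IC50 start
    order = np.argsort(logc)
    yc, xc = y[order], logc[order]
    log_ic50 = float(xc[np.argmin(np.abs(yc - mid))])
    above = np.where(yc >= mid)[0]
    below = np.where(yc < mid)[0]
    if len(above) and len(below):
        i = above[0]
        if i > 0:
            x0, x1 = xc[i - 1], xc[i]
            y0, y1 = yc[i - 1], yc[i]
            if y1 != y0:
                log_ic50 = float(x0 + (mid - y0) * (x1 - x0) / (y1 - y0))
    return [bottom, top, log_ic50, 1.0]


def fit_ic50(concentrations_um: Sequence[float],
             inhibition_percent: Sequence[float],
             censor_threshold: float = 50.0) -> DoseResponseCurve:
    """Four-parameter logistic dose–response fit on log10 concentration.

    Censors ("> max tested") when the observed maximum inhibition stays
    below the 50 % threshold; non-convergence also yields a censored result
    with diagnostics rather than an exception.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    y = np.asarray(inhibition_percent, dtype=float)
    if len(conc) < 4:
        raise ValueError("need at least 4 concentration points")
    if len(conc) != len(y) or not np.all(np.isfinite(y)):
        raise ValueError("inhibition values must be finite and aligned")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    order = np.argsort(conc)  # ascending; fit is order-invariant
    conc, y = conc[order], y[order]
    logc = np.log10(conc)
    cmax = float(conc.max())

    censored_low = y.max() < censor_threshold

    lo = [_BOUND_LO, _BOUND_LO, logc.min() - 3.0, 0.1]
    hi = [_BOUND_HI, _BOUND_HI, logc.max() + 3.0, 10.0]
    p0 = _initial_guess(logc, y)
    p0 = [min(max(v, l), h) for v, l, h in zip(p0, lo, hi)]
    try:
        popt, _ = curve_fit(_logistic4, logc, y, p0=p0, bounds=(lo, hi),
                            maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = None, False

    if not converged:
        return DoseResponseCurve(conc, y, None, None, None, None, None,
                                 converged=False, censored=True,
                                 censor_bound_um=cmax, rss=None)

    bottom, top, log_ic50, hill = (float(v) for v in popt)
    rss = float(np.sum((y - _logistic4(logc, *popt)) ** 2))
    relative_ic50 = 10.0 ** log_ic50

    absolute = None
    if bottom < censor_threshold < top:
        # solve 4PL(x) = threshold for log10 concentration
        ratio = (top - bottom) / (censor_threshold - bottom) - 1.0
        if ratio > 0:
            absolute = 10.0 ** (log_ic50 - np.log10(ratio) / hill)

    if censored_low:
        return DoseResponseCurve(conc, y, None, None, hill, top, bottom,
                                 converged=True, censored=True,
                                 censor_bound_um=cmax, rss=rss)
    return DoseResponseCurve(conc, y, relative_ic50, absolute, hill, top, bottom,
                             converged=True, censored=False,
                             censor_bound_um=None, rss=rss)


def fit_plate(readings: Sequence[PlateReading]) -> DoseResponseCurve:
    """Convenience: percent inhibition then 4PL fit for one plate group."""
    table = percent_inhibition(readings)
    return fit_ic50(table["concentration_um"], table["inhibition_percent"])
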