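"""Pharmacokinetic metrics computed from concentration-time curves.

Metric definitions:

* ``C_max`` / ``t_max`` — maximum concentration on the dense simulation grid
  and the earliest time attaining it.
* ``AUC_0-inf`` — area under the curve obtained by integrating
  dAUC/dt = C(t) alongside the model (preferred, exact to solver tolerance)
  or by trapezoid quadrature on a stored series; "infinity" is a finite
  horizon (default 48 h) with an optional convergence check.
* ``AUC_x-y`` — difference of the two clipped integrals AUC_0-y - AUC_0-x.
* ``t_1/2`` — terminal half-life from an ordinary least-squares line through
  (t, ln C) at the fixed anchor times 6, 8 and 10 h, t_1/2 = ln 2 / (-slope).
* ``CL/F`` — apparent oral clearance, dose_mg x 1e6 / (AUC_0-inf,losartan x
  461.01), with a zero branch while plasma losartan is identically zero.
* curve distance ``D`` — Euclidean distance between two sampled curves over
  their common time points.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import AnalysisError
from .model import ConcentrationSeries, _norm_analyte
from .params import DoseRegimen

__all__ = [
    "PKSummary",
    "cmax_tmax",
    "auc_0_inf",
    "auc_x_y",
    "half_life_semilog",
    "cl_over_f",
    "curve_distance",
    "pk_summary",
]

#: Fixed anchor times (h) for the terminal-phase semilog regression.
HALF_LIFE_ANCHORS = (6.0, 8.0, 10.0)

#: Default finite horizon standing in for "infinity" in AUC_0-inf (h).
DEFAULT_AUC_HORIZON = 48.0


def cmax_tmax(series: ConcentrationSeries, analyte: str = "losartan") -> tuple[float, float]:
    """Maximum concentration and the earliest grid time attaining it."""
    conc = series.concentration(analyte)
    idx = int(np.argmax(conc))  # argmax returns the first maximum
    return float(conc[idx]), float(series.times[idx])


def _cumulative_trapezoid(times: np.ndarray, conc: np.ndarray) -> np.ndarray:
    out = np.zeros_like(conc)
    np.cumsum(np.diff(times) * (conc[1:] + conc[:-1]) / 2.0, out=out[1:])
    return out


def auc_0_inf(
    series: ConcentrationSeries,
    analyte: str = "losartan",
    horizon: float = DEFAULT_AUC_HORIZON,
    method: str = "auto",
) -> float:
    """AUC from dosing to the finite horizon standing in for infinity.

    ``method="ode"`` uses the running integral carried by the simulation
    (dAUC/dt = C); ``"trapezoid"`` integrates the stored curve; ``"auto"``
    prefers the ODE route when available. The series must extend to the
    horizon (clip ``horizon`` to ask for less).
    """
    if series.times[-1] + 1e-9 < horizon:
        raise AnalysisError(
            f"series ends at {series.times[-1]} h, before the AUC horizon {horizon} h"
        )
    key = _norm_analyte(analyte)
    cum = series.auc_p if key == "losartan" else series.auc_m
    if method == "auto":
        method = "ode" if cum is not None else "trapezoid"
    if method == "ode":
        if cum is None:
            raise AnalysisError("series carries no running AUC integral; use trapezoid")
        return float(np.interp(horizon, series.times, cum))
    if method == "trapezoid":
        conc = series.concentration(analyte)
        cum_t = _cumulative_trapezoid(series.times, conc)
        return float(np.interp(horizon, series.times, cum_t))
    raise AnalysisError(f"unknown AUC method {method!r}")


def auc_x_y(
    series: ConcentrationSeries,
    x: float,
    y: float,
    analyte: str = "losartan",
    method: str = "auto",
) -> float:
    """Partial area AUC_x-y = AUC_0-y - AUC_0-x (piecewise construction)."""
    if x > y:
        raise AnalysisError(f"AUC bounds must satisfy x <= y, got x={x}, y={y}")
    if x < 0:
        raise AnalysisError(f"AUC lower bound must be >= 0, got {x}")
    return auc_0_inf(series, analyte, horizon=y, method=method) - auc_0_inf(
        series, analyte, horizon=x, method=method
    )


def half_life_semilog(
    series: ConcentrationSeries,
    analyte: str = "losartan",
    anchors: tuple[float, ...] = HALF_LIFE_ANCHORS,
) -> float:
    """Terminal half-life from the semilog OLS line through the anchor times.

    Concentrations are interpolated (cubic) to the anchor times when the grid
    does not contain them; the half-life is ln 2 / (-slope), equivalently the
    two-point form t2 - t1 times ln 2 / ln(C1/C2) evaluated on the fitted
    line.
    """
    if series.times[-1] + 1e-9 < max(anchors) or series.times[0] - 1e-9 > min(anchors):
        raise AnalysisError(
            f"series [{series.times[0]}, {series.times[-1]}] h does not cover the "
            f"half-life anchors {anchors}"
        )
    conc = series.concentration(analyte)
    spline = CubicSpline(series.times, conc)
    c_anchor = np.asarray([float(spline(t)) for t in anchors])
    if np.any(c_anchor <= 0):
        raise AnalysisError(
            f"nonpositive concentration at half-life anchors {anchors}: {c_anchor}"
        )
    slope, _ = np.polyfit(np.asarray(anchors), np.log(c_anchor), 1)
    if slope >= 0:
        raise AnalysisError("no terminal decline: semilog slope is nonnegative")
    return float(math.log(2.0) / (-slope))


def cl_over_f(dose: DoseRegimen, auc_losartan: float) -> float:
    """Apparent oral clearance CL/F (L/h).

    ``dose_mg x 1e6 / (AUC x MW)`` with the piecewise zero branch: while
    plasma losartan is identically zero (AUC == 0) the clearance is reported
    as 0 rather than dividing by zero.
    """
    if auc_losartan < 0:
        raise AnalysisError(f"AUC must be nonnegative, got {auc_losartan}")
    if auc_losartan == 0:
        return 0.0
    return dose.dose_mg * 1.0e6 / (auc_losartan * dose.molecular_weight)


def curve_distance(
    curve_a: ConcentrationSeries,
    curve_b: ConcentrationSeries,
    analyte: str = "losartan",
    time_tol: float = 1e-9,
) -> float:
    """Euclidean distance between two curves over their common time points.

    D = sqrt(sum_i (c_i^A - c_i^B)^2) over the j time points shared by both
    series (matched to within ``time_tol`` hours).
    """
    ta, tb = curve_a.times, curve_b.times
    ia = []
    ib = []
    j = 0
    for i, t in enumerate(ta):
        while j < len(tb) and tb[j] < t - time_tol:
            j += 1
        if j < len(tb) and abs(tb[j] - t) <= time_tol:
            ia.append(i)
            ib.append(j)
            j += 1
    if not ia:
        raise AnalysisError("curves share no common time points")
    ca = curve_a.concentration(analyte)[ia]
    cb = curve_b.concentration(analyte)[ib]
    return float(np.sqrt(np.sum((ca - cb) ** 2)))


@dataclass
class PKSummary:
    """Per-analyte PK metrics plus losartan CL/F for one simulated curve."""

    dose_mg: float
    genotype_label: str | None
    cmax_losartan: float
    tmax_losartan: float
    auc0inf_losartan: float
    cmax_E3174: float
    tmax_E3174: float
    auc0inf_E3174: float
    cl_over_f: float
    t_half_losartan: float | None = None
    t_half_E3174: float | None = None
    auc_windows: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "dose_mg": self.dose_mg,
            "genotype": self.genotype_label,
            "Cmax_losartan_nM": self.cmax_losartan,
            "tmax_losartan_h": self.tmax_losartan,
            "thalf_losartan_h": self.t_half_losartan,
            "AUC0inf_losartan_nmolh_L": self.auc0inf_losartan,
            "CL_F_L_h": self.cl_over_f,
            "Cmax_E3174_nM": self.cmax_E3174,
            "tmax_E3174_h": self.tmax_E3174,
            "thalf_E3174_h": self.t_half_E3174,
            "AUC0inf_E3174_nmolh_L": self.auc0inf_E3174,
        }
        for (x, y), (v_p, v_m) in self.auc_windows.items():
            d[f"AUC{x:g}_{y:g}_losartan_nmolh_L"] = v_p
            d[f"AUC{x:g}_{y:g}_E3174_nmolh_L"] = v_m
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def pk_summary(
    series: ConcentrationSeries,
    dose: DoseRegimen,
    horizon: float = DEFAULT_AUC_HORIZON,
    half_life: bool = True,
    auc_windows: tuple[tuple[float, float], ...] = (),
) -> PKSummary:
    """Compute the full PK metric panel for a simulated curve."""
    cmax_p, tmax_p = cmax_tmax(series, "losartan")
    cmax_m, tmax_m = cmax_tmax(series, "E3174")
    auc_p = auc_0_inf(series, "losartan", horizon=horizon)
    auc_m = auc_0_inf(series, "E3174", horizon=horizon)
    windows = {
        (x, y): (auc_x_y(series, x, y, "losartan"), auc_x_y(series, x, y, "E3174"))
        for x, y in auc_windows
    }
    th_p = th_m = None
    if half_life:
        th_p = half_life_semilog(series, "losartan")
        th_m = half_life_semilog(series, "E3174")
    return PKSummary(
        dose_mg=dose.dose_mg,
        genotype_label=series.genotype_label,
        cmax_losartan=cmax_p,
        tmax_losartan=tmax_p,
        auc0inf_losartan=auc_p,
        cmax_E3174=cmax_m,
        tmax_E3174=tmax_m,
        auc0inf_E3174=auc_m,
        cl_over_f=cl_over_f(dose, auc_p),
        t_half_losartan=th_p,
        t_half_E3174=th_m,
        auc_windows=windows,
    )
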