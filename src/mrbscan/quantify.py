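"""Velocity estimation, calibration and figures of merit.

The quantitative chain: boundary positions from successive scans are
regressed on the electrophoresis clock to give the boundary velocity V_MRB
(mm/min); V_MRB is linear in log10 of the analyte concentration, so an
ordinary least-squares calibration v = a*log10(C) + b inverts to
C = 10^((v - b)/a).  LOD follows the k*SD(blank) inverse-prediction
convention; RSD and spike recovery are the usual analytical definitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateModelError, DomainError, InsufficientDataError
from .processing import BoundaryFix


@dataclass(frozen=True)
class VelocityEstimate:
    """OLS fit of boundary position (mm) against electrophoresis clock (min)."""

    v_mrb: float  # slope, mm/min
    intercept_mm: float
    r2: float
    n_points: int
    residual_sd_mm: float


@dataclass(frozen=True)
class CalibrationModel:
    """OLS fit of V_MRB (mm/min) against log10(concentration / mM)."""

    slope_a: float  # mm/min per decade
    intercept_b: float  # mm/min
    r2: float
    conc_range_mM: tuple[float, float]
    lod_mM: float | None = None


@dataclass(frozen=True)
class Prediction:
    """Inverse-predicted concentration, flagged if outside the fitted range."""

    conc_mM: float
    extrapolated: bool


@dataclass(frozen=True)
class RecoveryResult:
    spiked_mM: float
    found_mM: float
    recovery_pct: float
    rsd_pct: float | None = None


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, r2 and residual SD (n-2 dof) of y on x."""
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    dof = max(x.size - 2, 1)
    resid_sd = float(np.sqrt(np.sum((y - yhat) ** 2) / dof))
    # r2 via explained variance; exact-line fits give 1 to round-off
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return float(res.slope), float(res.intercept), r2, resid_sd


def fit_velocity(fixes: Sequence[BoundaryFix]) -> VelocityEstimate:
    """Boundary velocity V_MRB from >= 3 valid fixes (position vs clock OLS)."""
    valid = [f for f in fixes if f.valid]
    if len(valid) < 3:
        raise InsufficientDataError(f"need >= 3 valid fixes, got {len(valid)}")
    t = np.array([f.clock_min for f in valid], dtype=float)
    x = np.array([f.x_boundary_mm for f in valid], dtype=float)
    if np.ptp(t) == 0:
        raise InsufficientDataError("all fixes share the same clock: cannot fit")
    slope, intercept, r2, resid = _ols(t, x)
    return VelocityEstimate(
        v_mrb=slope,
        intercept_mm=intercept,
        r2=r2,
        n_points=len(valid),
        residual_sd_mm=resid,
    )


def fit_calibration(
    points: Sequence[tuple[float, float]],
    blank_sd: float | None = None,
    lod_k: float = 3.0,
) -> CalibrationModel:
    """Calibration line V_MRB = a*log10(C) + b from (conc_mM, v_mrb) pairs.

    If ``blank_sd`` is given, the LOD is computed and stored on the model.
    """
    if len(points) < 3:
        raise InsufficientDataError(f"need >= 3 calibration points, got {len(points)}")
    conc = np.array([p[0] for p in points], dtype=float)
    v = np.array([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise DomainError("concentrations must be positive for a log calibration")
    slope, intercept, r2, _ = _ols(np.log10(conc), v)
    model = CalibrationModel(
        slope_a=slope,
        intercept_b=intercept,
        r2=r2,
        conc_range_mM=(float(conc.min()), float(conc.max())),
    )
    if blank_sd is not None:
        from dataclasses import replace

        model = replace(model, lod_mM=compute_lod(model, blank_sd, k=lod_k))
    return model


def predict_concentration(model: CalibrationModel, v_mrb: float) -> Prediction:
    """Invert the calibration: C = 10^((v - b)/a), flagging extrapolation."""
    if model.slope_a == 0:
        raise DegenerateModelError("zero calibration slope: cannot invert")
    conc = 10.0 ** ((v_mrb - model.intercept_b) / model.slope_a)
    lo, hi = model.conc_range_mM
    return Prediction(conc_mM=float(conc), extrapolated=not (lo <= conc <= hi))


def compute_lod(
    model: CalibrationModel,
    blank_sd: float,
    k: float = 3.0,
    v_blank: float = 0.0,
) -> float:
    """Limit of detection as inverse prediction of the blank + k*SD signal.

    LOD = 10^(((v_blank + k*blank_sd) - b)/a), with ``v_blank`` the mean
    blank velocity signal (default 0) and blank_sd its standard deviation,
    both in mm/min.  The convention (k = 3 by default) is parameterized.
    """
    if blank_sd < 0:
        raise DomainError("blank_sd must be non-negative")
    if model.slope_a <= 0:
        raise DegenerateModelError("LOD needs a positive calibration slope")
    return float(10.0 ** (((v_blank + k * blank_sd) - model.intercept_b) / model.slope_a))


def compute_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation (%) with the n-1 sample SD, on |mean|."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("RSD needs at least 2 replicates")
    mean = v.mean()
    if mean == 0:
        raise DomainError("RSD undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / abs(mean))


def compute_recovery(spiked_mM: float, found_mM: float) -> float:
    """Spike recovery, 100 * found/spiked, reported to one decimal place."""
    if spiked_mM <= 0:
        raise DomainError("spiked concentration must be positive")
    return round(100.0 * found_mM / spiked_mM, 1)
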