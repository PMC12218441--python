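"""Isolate physiology: growth-curve AUC, growth boost, sugar degradation,
and coculture fold change."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError

__all__ = [
    "GrowthCurve",
    "CalibrationCurve",
    "DegradationResult",
    "GrowthBoost",
    "auc",
    "growth_boost",
    "fit_calibration",
    "concentration_from_signal",
    "degradation_percent",
    "coculture_l2fc",
]


@dataclass
class GrowthCurve:
    """OD600 time series for one strain/medium/replicate."""

    times: np.ndarray
    od600: np.ndarray
    strain: str = ""
    medium: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if t.size != od.size:
            raise ValidationError("times and od600 must have equal length")
        if t.size and (t < 0).any():
            raise ValidationError("times must be non-negative")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValidationError("times must be strictly increasing")
        if not np.isfinite(od).all() or not np.isfinite(t).all():
            raise ValidationError("growth curve contains non-finite values")
        self.times = t
        self.od600 = od


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS standard line: signal = slope * concentration + intercept."""

    slope: float
    intercept: float
    r2: float
    analyte: str = ""
    n_standards: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValidationError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.n_standards < 2:
            raise ValidationError("calibration needs >= 2 standards")


@dataclass(frozen=True)
class DegradationResult:
    c0: float
    ct: float
    percent_degraded: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_degraded <= 100.0:
            raise ValidationError("percent_degraded must lie in [0, 100]")


@dataclass(frozen=True)
class GrowthBoost:
    auc_treatment: float
    auc_control: float
    boost: float


def _resolve_blank(curve: GrowthCurve, blank) -> float:
    if blank == "first":
        return float(curve.od600[0])
    return float(blank)


def auc(curve: GrowthCurve, blank: float | str = 0.0) -> float:
    """Trapezoidal area of max(od600 - blank, 0) over the full time span.

    ``blank="first"`` subtracts the curve's first reading.
    """
    if curve.times.size < 2:
        raise InsufficientDataError("AUC needs >= 2 time points")
    b = _resolve_blank(curve, blank)
    y = np.maximum(curve.od600 - b, 0.0)
    return float(np.trapezoid(y, curve.times))


def growth_boost(
    treatment: GrowthCurve, control: GrowthCurve, blank: float | str = 0.0
) -> GrowthBoost:
    """AUC of the treatment curve relative to the control curve."""
    a_t = auc(treatment, blank)
    a_c = auc(control, blank)
    if a_c <= 0:
        raise DomainError(f"control AUC is {a_c}; boost undefined")
    return GrowthBoost(auc_treatment=a_t, auc_control=a_c, boost=a_t / a_c)


def fit_calibration(
    standards: Sequence[tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """Ordinary least-squares standard line through (concentration, signal)."""
    pts = np.asarray(list(standards), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("need >= 2 (concentration, signal) standards")
    conc, signal = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise DomainError("all standard concentrations are equal; cannot fit")
    res = stats.linregress(conc, signal)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(min(max(res.rvalue**2, 0.0), 1.0)),
        analyte=analyte,
        n_standards=pts.shape[0],
    )


def concentration_from_signal(cal: CalibrationCurve, signal: float) -> float:
    """Invert the standard line; negative predictions clamp to 0."""
    if cal.slope == 0:
        raise DomainError("calibration slope is 0; cannot invert")
    return max((signal - cal.intercept) / cal.slope, 0.0)


def degradation_percent(c0: float, ct: float) -> DegradationResult:
    """Percent of substrate consumed: 100 * (c0 - ct) / c0, clamped to [0, 100]."""
    if c0 <= 0:
        raise DomainError(f"initial concentration must be positive, got {c0}")
    if ct < 0:
        raise DomainError(f"final concentration must be non-negative, got {ct}")
    if ct > c0:
        warnings.warn(
            f"final concentration {ct} exceeds initial {c0}; clamping to 0%",
            stacklevel=2,
        )
    pct = 100.0 * (c0 - ct) / c0
    return DegradationResult(c0=c0, ct=ct, percent_degraded=float(np.clip(pct, 0.0, 100.0)))


def coculture_l2fc(
    mono: Sequence[float], co: Sequence[float]
) -> dict[str, float]:
    """log2(mean(co)/mean(mono)) with a Student's t-test on log2 quantities.

    Returns ``{"l2fc": ..., "t": ..., "p": ...}``.
    """
    mono_arr = np.asarray(list(mono), dtype=float)
    co_arr = np.asarray(list(co), dtype=float)
    if mono_arr.size < 2 or co_arr.size < 2:
        raise InsufficientDataError("need >= 2 replicates per condition")
    if (mono_arr <= 0).any() or (co_arr <= 0).any():
        raise DomainError("quantities must be positive for log2 fold change")
    l2fc = float(np.log2(co_arr.mean() / mono_arr.mean()))
    log_mono, log_co = np.log2(mono_arr), np.log2(co_arr)
    if np.ptp(log_mono) == 0 and np.ptp(log_co) == 0:
        # zero variance in both groups: identical -> p=1, else p->0
        if log_mono[0] == log_co[0]:
            return {"l2fc": l2fc, "t": 0.0, "p": 1.0}
        return {"l2fc": l2fc, "t": float("inf"), "p": 0.0}
    t_stat, p = stats.ttest_ind(log_co, log_mono, equal_var=True)
    return {"l2fc": l2fc, "t": float(t_stat), "p": float(p)}
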