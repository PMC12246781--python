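"""Cross-method agreement statistics for paired ANI values.

When validating one ANI implementation against another, the conventional
summary is the best-fitting linear model y = a + b*x between the paired
values (both on the 0-100 percent scale) with its adjusted R² and the
largest absolute disagreement. Two implementations that are effectively
interchangeable show slope ~1, intercept ~0 and adjusted R² ~1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AgreementReport", "DegenerateFitError", "fit_agreement"]


class DegenerateFitError(ValueError):
    """The predictor has zero variance; the slope is undefined."""


@dataclass(frozen=True)
class AgreementReport:
    """OLS agreement summary between two vectors of paired ANI values."""

    n: int
    slope: float
    intercept: float
    r2_adjusted: float
    max_abs_diff: float


def fit_agreement(x: Sequence[float], y: Sequence[float]) -> AgreementReport:
    """Closed-form two-parameter OLS of y on x with adjusted R².

    Both inputs must be on the 0-100 percent scale (rescale fraction-valued
    ANIs by 100 before calling). r2_adjusted = 1 - (1 - R²)(n-1)/(n-2) for
    the single-predictor model; max_abs_diff = max|y_i - x_i| measures the
    worst pointwise disagreement, independent of the fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired values for an agreement fit")
    xm = x - x.mean()
    sxx = float(xm @ xm)
    if sxx == 0.0:
        raise DegenerateFitError("zero variance in x: agreement slope is undefined")
    slope = float(xm @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ym = y - y.mean()
    ss_tot = float(ym @ ym)
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AgreementReport(
        n=n,
        slope=slope,
        intercept=intercept,
        r2_adjusted=r2_adj,
        max_abs_diff=float(np.max(np.abs(y - x))),
    )
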