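"""Stable-isotope-dilution calibration: curve fitting, LOD/LOQ and
single-point quantification.

The response variable is the light/heavy (L/H) peak-area ratio at a fixed
heavy spike, regressed on the spiked light amount by ordinary least
squares.  Detection and quantification limits follow the ICH
calibration-curve method: LOD = 3.3 * s_yx / slope and
LOQ = 10 * s_yx / slope, where s_yx is the residual standard error of the
fit — so LOQ/LOD = 10/3.3 ~ 3.03 by construction.

When sample material is too scarce to run a full curve per sample, one
calibration point is reused: ``single_point_quantify`` supports a
through-origin proportional rule (default) or inversion of a previously
fitted line.  Miscleaved species, which respond on their own curves, are
quantified per form against external light-peptide curves and summed
(``external_curve_correct``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "FormContribution",
    "fit_calibration",
    "lod_loq",
    "single_point_quantify",
    "external_curve_correct",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: known light amount vs observed L/H ratio."""

    amount: float
    lh: float
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.lh < 0:
            raise ValueError("L/H ratio must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of L/H on amount, with residual scatter and detection limits.

    ``r2`` is adjusted r-squared for n >= 3 (plain r-squared at n = 2, where
    the adjustment is undefined).  ``s_yx`` and the limits are None when
    n < 3 (no residual degrees of freedom).
    """

    peptide: str
    slope: float
    intercept: float
    r2: float
    s_yx: float | None
    lod: float | None
    loq: float | None
    n_points: int
    external: bool = False

    def predict(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def invert(self, lh: float) -> float:
        """Amount at a given L/H ratio (line inversion)."""
        return (lh - self.intercept) / self.slope


def fit_calibration(
    points: Sequence[CalibrationPoint],
    peptide: str = "",
    external: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares of L/H ratio on amount.

    Requires at least two distinct amounts.  LOD/LOQ are attached when a
    residual standard error exists (n >= 3) and the slope is positive.
    """
    if len(points) < 2:
        raise ValueError("calibration needs at least 2 points")
    x = np.array([p.amount for p in points], dtype=float)
    y = np.array([p.lh for p in points], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("all amounts identical: slope is undefined")
    n = len(points)

    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm

    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2_plain = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    if n >= 3:
        r2 = 1.0 - (1.0 - r2_plain) * (n - 1) / (n - 2)
        s_yx = math.sqrt(ss_res / (n - 2))
    else:
        r2 = r2_plain
        s_yx = None

    lod = loq = None
    if s_yx is not None and slope > 0:
        lod = LOD_FACTOR * s_yx / slope
        loq = LOQ_FACTOR * s_yx / slope
    return CalibrationCurve(
        peptide=peptide,
        slope=slope,
        intercept=intercept,
        r2=r2,
        s_yx=s_yx,
        lod=lod,
        loq=loq,
        n_points=n,
        external=external,
    )


def lod_loq(curve: CalibrationCurve) -> tuple[float, float]:
    """(LOD, LOQ) in amount units from residual scatter and slope."""
    if curve.s_yx is None:
        raise ValueError("residual standard error unavailable (n < 3)")
    if curve.slope <= 0:
        raise ValueError(f"slope must be positive, got {curve.slope}")
    return (
        LOD_FACTOR * curve.s_yx / curve.slope,
        LOQ_FACTOR * curve.s_yx / curve.slope,
    )


def single_point_quantify(
    lh_sample: float,
    reference: CalibrationPoint | None = None,
    mode: Literal["proportional", "curve"] = "proportional",
    curve: CalibrationCurve | None = None,
) -> float:
    """Quantify a sample from its L/H ratio using one calibration point.

    proportional: amount = lh_sample * ref.amount / ref.lh (through origin);
    curve: amount = (lh_sample - intercept) / slope.  A negative curve-mode
    result is reported as 0 with a warning.
    """
    if lh_sample < 0:
        raise ValueError("L/H ratio must be >= 0")
    if mode == "proportional":
        if reference is None:
            raise ValueError("proportional mode requires a reference point")
        if reference.lh <= 0:
            raise ValueError("reference L/H must be positive in proportional mode")
        return lh_sample * reference.amount / reference.lh
    if mode == "curve":
        if curve is None:
            raise ValueError("curve mode requires a fitted CalibrationCurve")
        amount = curve.invert(lh_sample)
        if amount < 0:
            warnings.warn(
                f"computed amount {amount:.4g} below zero; reporting 0",
                stacklevel=2,
            )
            return 0.0
        return amount
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class FormContribution:
    """Per-form quantification result within a miscleavage correction."""

    form: str
    amount: float
    below_lod: bool


def external_curve_correct(
    forms: Iterable[tuple[str, float, CalibrationCurve]],
) -> tuple[float, list[FormContribution]]:
    """Total amount from independently calibrated peptide forms.

    Each detected form (fully cleaved, miscleaved, ...) is quantified by
    inverting its own curve; forms falling below their curve's LOD are
    censored to 0 and flagged.  Returns (total, per-form contributions).
    """
    contributions: list[FormContribution] = []
    forms = list(forms)
    if not forms:
        raise ValueError("at least one form is required")
    for form_id, lh, curve in forms:
        if curve is None:
            raise ValueError(f"form {form_id!r} lacks a calibration curve")
        amount = single_point_quantify(lh, mode="curve", curve=curve)
        below = curve.lod is not None and amount < curve.lod
        contributions.append(
            FormContribution(form=form_id, amount=0.0 if below else amount, below_lod=below)
        )
    total = sum(c.amount for c in contributions)
    return total, contributions
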