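"""Densitometric body composition: replicate selection, density, Siri percent
fat, body-volume calibration, and the fat-mass prediction equation.

The chain mirrors standard air-displacement-plethysmography practice: body
volume (BV) replicates are reduced to a single value by the closest-pair
rule, density is mass over (thoracic-gas-corrected) volume, percent body fat
follows the two-compartment Siri equation, and the camera system's raw BV is
mapped onto the reference scale by ordinary least squares ("fitted" BV).
Fat mass in kilograms is then predicted from sex, physical activity, height
and fitted BV by a fixed linear equation estimated on the validation cohort:

    FM = 42.5 - 5.73*sex - 0.02254*PA - 26.3*height + 0.4879*BV

with sex coded 1 for women and 2 for men, PA in minutes/week, height in
metres and BV in litres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InputError, ReplicateError, SingularFitError

__all__ = [
    "SubjectRecord",
    "ReplicateSet",
    "CalibrationModel",
    "FMEstimate",
    "select_replicates",
    "body_density",
    "siri_percent_fat",
    "fit_bv_calibration",
    "apply_calibration",
    "predict_fat_mass",
    "report_bv_error",
    "FM_COEFFS",
]

# FM-equation coefficients: intercept, sex, PA (min/week), height (m), BV (L)
FM_COEFFS = {
    "intercept": 42.5,
    "sex": -5.73,
    "pa_min_week": -0.02254,
    "height_m": -26.3,
    "bv_l": 0.4879,
}

#: Replicate agreement tolerance: 150 mL or 0.3 % of the pair mean.
REPLICATE_TOL_L = 0.150
REPLICATE_TOL_FRAC = 0.003


@dataclass
class SubjectRecord:
    """Covariates of one subject.

    ``sex_code`` is 1 for female, 2 for male.  Height and weight outside the
    study's inclusion bounds (height <= 1.94 m, weight <= 136 kg, and sane
    lower bounds) produce a warning, not an error — the prediction equation
    simply extrapolates there.
    """

    subject_id: str
    sex_code: int
    age_years: float
    height_m: float
    weight_kg: float
    pa_min_week: float
    bmi_kg_m2: float = field(init=False)

    def __post_init__(self):
        if self.sex_code not in (1, 2):
            raise DomainError(f"sex_code must be 1 (female) or 2 (male), got {self.sex_code}")
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise DomainError("height and weight must be positive")
        if self.pa_min_week < 0:
            raise DomainError("physical activity minutes/week must be >= 0")
        if not (0.5 < self.height_m <= 1.94):
            warnings.warn(
                f"height {self.height_m} m outside inclusion bounds (0.5, 1.94]",
                stacklevel=2,
            )
        if not (20 < self.weight_kg <= 136):
            warnings.warn(
                f"weight {self.weight_kg} kg outside inclusion bounds (20, 136]",
                stacklevel=2,
            )
        self.bmi_kg_m2 = self.weight_kg / self.height_m**2


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate BV measurements with the selected closest pair."""

    bv_liters: tuple
    selected_pair: tuple
    selected_value: float


@dataclass(frozen=True)
class CalibrationModel:
    """OLS map from raw camera BV to the reference scale."""

    slope: float
    intercept: float
    n_fit: int
    residual_sd: float

    def __post_init__(self):
        if self.n_fit < 3:
            raise InputError("calibration needs at least 3 subjects")
        if not np.isfinite(self.slope):
            raise SingularFitError("calibration slope is not finite")


@dataclass(frozen=True)
class FMEstimate:
    """Predicted fat mass plus an echo of the inputs that produced it."""

    fm_kg: float
    sex_code: int
    pa_min_week: float
    height_m: float
    fitted_bv_liters: float


def _pair_tolerance_l(v1: float, v2: float) -> float:
    return max(REPLICATE_TOL_L, REPLICATE_TOL_FRAC * (v1 + v2) / 2.0)


def select_replicates(values) -> ReplicateSet:
    """Reduce replicate BV measurements to one value by the closest-pair rule.

    Two replicates agreeing within 150 mL or 0.3 % of their mean are simply
    averaged.  If they disagree, a third measurement is required
    (:class:`ReplicateError` if absent).  With three or more values the pair
    with the smallest absolute difference is averaged; ties go to the pair
    whose mean is closest to the overall median, then to the earliest pair in
    index order.
    """
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise InputError("need at least two replicate measurements")
    if len(vals) == 2:
        v1, v2 = vals
        if abs(v1 - v2) <= _pair_tolerance_l(v1, v2):
            return ReplicateSet(tuple(vals), (0, 1), (v1 + v2) / 2.0)
        raise ReplicateError(
            f"replicates differ by {abs(v1 - v2) * 1000:.0f} mL "
            f"(> {_pair_tolerance_l(v1, v2) * 1000:.0f} mL); a third measurement is required"
        )
    med = float(np.median(vals))
    best = None
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            diff = abs(vals[i] - vals[j])
            mean = (vals[i] + vals[j]) / 2.0
            key = (diff, abs(mean - med), (i, j))
            if best is None or key < best[0]:
                best = (key, (i, j), mean)
    _, pair, mean = best
    return ReplicateSet(tuple(vals), pair, mean)


def body_density(weight_kg: float, corrected_bv_liters: float) -> float:
    """Whole-body density in kg/L: mass over thoracic-gas-corrected volume."""
    if weight_kg <= 0 or corrected_bv_liters <= 0:
        raise DomainError("weight and volume must be positive")
    return weight_kg / corrected_bv_liters


def siri_percent_fat(density_kg_l: float, a: float = 495.0, b: float = 450.0) -> float:
    """Two-compartment Siri percent body fat: ``a / density - b``.

    The standard constants 495/450 are the defaults and are config-exposed.
    Densities outside the physiological band (0.9, 1.15) kg/L warn.
    """
    if density_kg_l <= 0:
        raise DomainError("density must be positive")
    if not (0.9 < density_kg_l < 1.15):
        warnings.warn(
            f"density {density_kg_l:.3f} kg/L outside the physiological band (0.9, 1.15)",
            stacklevel=2,
        )
    return a / density_kg_l - b


def fit_bv_calibration(raw_bv, reference_bv) -> CalibrationModel:
    """OLS of reference BV on raw camera BV (reference = a*raw + b).

    Residual SD uses the n-2 denominator.  By construction the fitted values
    have the same mean as the reference on the fitting set.
    """
    raw = np.asarray(raw_bv, dtype=float)
    ref = np.asarray(reference_bv, dtype=float)
    if raw.shape != ref.shape or raw.ndim != 1:
        raise InputError("raw and reference BV must be equal-length 1-D")
    n = len(raw)
    if n < 3:
        raise InputError("calibration needs at least 3 subjects")
    if np.ptp(raw) == 0:
        raise SingularFitError("raw BV is constant; calibration is singular")
    slope, intercept = np.polyfit(raw, ref, 1)
    resid = ref - (slope * raw + intercept)
    residual_sd = float(np.sqrt((resid**2).sum() / (n - 2))) if n > 2 else 0.0
    return CalibrationModel(float(slope), float(intercept), n, residual_sd)


def apply_calibration(model: CalibrationModel, raw_liters):
    """Map raw BV (scalar or array) onto the reference scale."""
    raw = np.asarray(raw_liters, dtype=float)
    out = model.slope * raw + model.intercept
    return float(out) if out.ndim == 0 else out


def predict_fat_mass(
    subject: SubjectRecord | None,
    fitted_bv_liters: float,
    sex_code: int | None = None,
    pa_min_week: float | None = None,
    height_m: float | None = None,
) -> FMEstimate:
    """Predict fat mass (kg) from sex, physical activity, height and fitted BV.

    Covariates come from *subject* or can be passed directly.  A negative
    prediction is returned as-is with an out-of-domain warning (the linear
    model extrapolates).
    """
    if subject is not None:
        sex_code = subject.sex_code
        pa_min_week = subject.pa_min_week
        height_m = subject.height_m
    if sex_code not in (1, 2):
        raise DomainError(f"sex_code must be 1 or 2, got {sex_code}")
    if pa_min_week is None or pa_min_week < 0:
        raise DomainError("physical activity minutes/week must be >= 0")
    if height_m is None or height_m <= 0:
        raise DomainError("height must be positive (metres)")
    c = FM_COEFFS
    fm = (
        c["intercept"]
        + c["sex"] * sex_code
        + c["pa_min_week"] * pa_min_week
        + c["height_m"] * height_m
        + c["bv_l"] * fitted_bv_liters
    )
    if fm < 0:
        warnings.warn(f"predicted fat mass is negative ({fm:.2f} kg)", stacklevel=2)
    return FMEstimate(float(fm), int(sex_code), float(pa_min_week), float(height_m),
                      float(fitted_bv_liters))


def report_bv_error(estimates, references) -> dict:
    """Mean-level BV error of an estimator against a reference method.

    Returns absolute error ``mean(estimates) - mean(references)`` in litres
    and the percent error relative to the reference mean, both at full
    precision (rounding is a display concern).
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape or est.ndim != 1 or len(est) < 1:
        raise InputError("estimates and references must be equal-length 1-D, n >= 1")
    abs_err = float(est.mean() - ref.mean())
    pct_err = abs_err / float(ref.mean()) * 100.0
    return {
        "mean_estimate_l": float(est.mean()),
        "mean_reference_l": float(ref.mean()),
        "absolute_error_l": abs_err,
        "percent_error": pct_err,
        "n": len(est),
    }
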