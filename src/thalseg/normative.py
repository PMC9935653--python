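"""Normative thalamus volumetry and single-subject atrophy detection.

The normative model regresses bilateral thalamus volume (THALV, mL) on
total intracranial volume (TIV, mL) and age (years) with the full quadratic

    THALV = a*TIV^2 + b*age^2 + c*TIV*age + d*TIV + e*age + f

fitted by least squares in a reference (normal) database. Fitting is
two-step: after a first fit, records whose residuals fall outside the Tukey
fences (quartile +/- 1.5 IQR of the residual distribution) are excluded and
the model is refitted once. The residual spread sigma_norm of the retained
records defines the normal 95% band [-1.96*sigma_norm, +1.96*sigma_norm].

A patient's volume is called reduced under a two-sample rule: the upper
edge of the patient's own 95% CI (+/-1.96*sigma_scanner, the inter-scanner
variability of the measurement) must lie strictly below the lower edge of
the normal band. This is deliberately more conservative than comparing the
point estimate alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

COEF_NAMES = ("a", "b", "c", "d", "e", "f")


def design_matrix(tiv, age) -> np.ndarray:
    """Columns (TIV^2, age^2, TIV*age, TIV, age, 1) for the quadratic model."""
    tiv = np.asarray(tiv, dtype=float)
    age = np.asarray(age, dtype=float)
    return np.column_stack(
        [tiv**2, age**2, tiv * age, tiv, age, np.ones_like(tiv)]
    )


@dataclass
class DetectionResult:
    """Outcome of the two-sample reduced-volume rule for one subject."""

    res_thalv: float  # mL
    ci_half_width: float  # mL, 1.96 * sigma_scanner
    normal_lower_bound: float  # mL, -1.96 * sigma_norm
    reduced: bool
    margin: float  # mL, normal lower bound minus patient CI upper edge (>0 => reduced)


def _split_xy(X, y=None):
    """Accept a cohort DataFrame or explicit (tiv, age) columns + THALV."""
    if isinstance(X, pd.DataFrame):
        tiv = X["tiv_ml"].to_numpy(dtype=float)
        age = X["age_years"].to_numpy(dtype=float)
        if y is None:
            y = X["thalv_ml"].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of [TIV, age] or a cohort DataFrame")
        tiv, age = X[:, 0], X[:, 1]
    if y is None:
        raise ValueError("y (THALV, mL) is required when X is an array")
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(tiv)) and np.all(np.isfinite(age)) and np.all(np.isfinite(y))):
        raise ValueError("TIV, age and THALV must be finite")
    return tiv, age, y


def _lstsq(A, y):
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        col_sd = A.std(axis=0)
        deficient = [COEF_NAMES[i] for i in range(5) if col_sd[i] == 0]
        raise np.linalg.LinAlgError(
            "rank-deficient normative design matrix"
            + (f"; constant term(s): {deficient}" if deficient else "")
        )
    return coef


def tukey_fences(values, k: float = 1.5):
    """(lower, upper) = quartiles -/+ k*IQR, linear-interpolation quartiles."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


class NormativeThalamusModel(BaseEstimator, RegressorMixin):
    """Quadratic THALV-TIV-age normative model with one outlier-trim refit.

    Parameters
    ----------
    iqr_factor
        Tukey fence multiplier for the outlier exclusion after the first
        fit (1.5 by default).
    z_crit
        Normal-band quantile; 1.96 gives the conventional 95% band.
    ddof
        Degrees-of-freedom correction for sigma_norm (std of retained
        residuals).

    Attributes
    ----------
    coef_ : ndarray (6,)
        (a, b, c, d, e, f) in the parameterization above (mL, mL-years).
    sigma_ : float
        Residual std (mL) over the retained records after the second fit.
    n_used_, n_outliers_ : int
    fence_bounds_ : (float, float)
        Tukey fences (mL) applied to first-fit residuals.
    outlier_mask_ : ndarray of bool, True where excluded.
    """

    def __init__(self, iqr_factor: float = 1.5, z_crit: float = 1.96, ddof: int = 1):
        self.iqr_factor = iqr_factor
        self.z_crit = z_crit
        self.ddof = ddof

    def fit(self, X, y=None):
        tiv, age, thalv = _split_xy(X, y)
        if thalv.size < 12:
            raise ValueError(
                f"need >= 12 records (2x parameters) to fit, got {thalv.size}"
            )
        A = design_matrix(tiv, age)
        coef1 = _lstsq(A, thalv)
        res1 = thalv - A @ coef1
        lo, hi = tukey_fences(res1, self.iqr_factor)
        keep = (res1 >= lo) & (res1 <= hi)
        coef2 = _lstsq(A[keep], thalv[keep])
        res2 = thalv[keep] - A[keep] @ coef2

        self.coef_ = coef2
        self.sigma_ = float(res2.std(ddof=self.ddof))
        self.n_used_ = int(keep.sum())
        self.n_outliers_ = int((~keep).sum())
        self.fence_bounds_ = (lo, hi)
        self.outlier_mask_ = ~keep
        return self

    # ------------------------------------------------------------------
    def predict(self, X):
        """Model THALV (mL) for [TIV, age] rows or a cohort DataFrame."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            A = design_matrix(X["tiv_ml"].to_numpy(), X["age_years"].to_numpy())
        else:
            X = np.asarray(X, dtype=float)
            A = design_matrix(X[:, 0], X[:, 1])
        return A @ self.coef_

    def residuals(self, X, y=None):
        """resTHALV = THALV - model(TIV, age), in mL (vectorized)."""
        self._check_fitted()
        tiv, age, thalv = _split_xy(X, y)
        return thalv - design_matrix(tiv, age) @ self.coef_

    def res_thalv(self, tiv: float, age: float, thalv: float) -> float:
        """Signed residual of a single record (pure function of model + record)."""
        self._check_fitted()
        return float(thalv - design_matrix([tiv], [age])[0] @ self.coef_)

    def normal_interval(self):
        """The normal band (-z*sigma_norm, +z*sigma_norm), mL."""
        self._check_fitted()
        return (-self.z_crit * self.sigma_, +self.z_crit * self.sigma_)

    def detect_reduced(self, res_thalv: float, sigma_scanner: float) -> DetectionResult:
        """Two-sample reduced-volume rule.

        reduced <=> res_thalv + z*sigma_scanner < -z*sigma_norm (strict).
        ``sigma_scanner`` is the measurement's inter-scanner std (mL),
        typically estimated from a traveling-phantom study.
        """
        self._check_fitted()
        if sigma_scanner < 0:
            raise ValueError("sigma_scanner must be >= 0")
        half = self.z_crit * sigma_scanner
        lower = -self.z_crit * self.sigma_
        upper_edge = res_thalv + half
        return DetectionResult(
            res_thalv=float(res_thalv),
            ci_half_width=float(half),
            normal_lower_bound=float(lower),
            reduced=bool(upper_edge < lower),
            margin=float(lower - upper_edge),
        )

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "coefficients": dict(zip(COEF_NAMES, map(float, self.coef_))),
            "sigma_norm_ml": self.sigma_,
            "n_used": self.n_used_,
            "n_outliers": self.n_outliers_,
            "fence_bounds_ml": list(self.fence_bounds_),
            "z_crit": self.z_crit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeThalamusModel":
        m = cls(z_crit=d.get("z_crit", 1.96))
        m.coef_ = np.array([d["coefficients"][k] for k in COEF_NAMES], dtype=float)
        m.sigma_ = float(d["sigma_norm_ml"])
        m.n_used_ = int(d["n_used"])
        m.n_outliers_ = int(d["n_outliers"])
        m.fence_bounds_ = tuple(d["fence_bounds_ml"])
        m.outlier_mask_ = None
        return m


def fit_normative(cohort, iqr_factor: float = 1.5) -> NormativeThalamusModel:
    """Thin functional wrapper: fit the normative model on a cohort."""
    return NormativeThalamusModel(iqr_factor=iqr_factor).fit(cohort)


def cohort_detection_rate(
    patients, model: NormativeThalamusModel, sigma_scanner: float
) -> float:
    """Fraction of patient records flagged as reduced by the two-sample rule."""
    res = model.residuals(patients)
    if res.size == 0:
        raise ValueError("patient cohort is empty")
    return float(
        np.mean([model.detect_reduced(r, sigma_scanner).reduced for r in res])
    )
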