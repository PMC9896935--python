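"""Regression-based biological-age estimators: MLR, PCA and Klemera-Doubal.

All three treat BA as a function of the biomarker panel calibrated
against chronological age:

* **MLR** — OLS of CA on all markers; the fitted values are BA.  A known
  consequence is that the regression of BA back on CA has slope equal to
  the model R² (< 1 with noisy markers).
* **PCA** — first principal component of the z-scored markers,
  sign-aligned with CA and mapped to age units by matching the mean and
  SD of CA.
* **KD** — Klemera-Doubal two-step estimator: per-marker bivariate
  regressions of marker on CA, combined by inverse-variance weighting;
  the "corrected" variant shrinks toward CA with weight 1/s_BA².
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .cohort import Cohort

__all__ = [
    "BAEstimates",
    "KDCalibration",
    "MLRAge",
    "PCAAge",
    "KlemeraDoubal",
    "DegenerateMarkerError",
    "estimate_mlr",
    "estimate_pca",
    "kd_calibrate",
    "estimate_kd",
]


class DegenerateMarkerError(ValueError):
    """A marker is an exact deterministic function of CA (residual SD ~ 0)."""


@dataclass
class BAEstimates:
    """Method-tagged biological-age vector with ``delta = BA - CA``."""

    method: str
    ba: np.ndarray
    ca: np.ndarray
    subject_id: pd.Series | None = None
    delta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ba = np.asarray(self.ba, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ba.shape != self.ca.shape:
            raise ValueError("BA and CA must have the same length")
        if not np.all(np.isfinite(self.ba)):
            raise ValueError("BA estimates must be finite")
        self.delta = self.ba - self.ca

    def to_frame(self) -> pd.DataFrame:
        sid = (
            self.subject_id.reset_index(drop=True)
            if self.subject_id is not None
            else pd.Series(np.arange(len(self.ba)).astype(str))
        )
        return pd.DataFrame(
            {"subject_id": sid, "method": self.method, "ba": self.ba, "delta": self.delta}
        )


@dataclass
class KDCalibration:
    """Per-marker calibration of the Klemera-Doubal estimator."""

    markers: list[str]
    slopes: np.ndarray       # k_j from x_j = q_j + k_j * CA
    intercepts: np.ndarray   # q_j
    resid_sds: np.ndarray    # s_j
    correlations: np.ndarray  # r_j
    s_ba: float              # SD of BA around CA
    age_range: tuple[float, float]
    included: np.ndarray = None  # markers retained in the weighted sum

    def __post_init__(self) -> None:
        if self.included is None:
            self.included = np.ones(len(self.markers), dtype=bool)
        if np.any(self.resid_sds[self.included] <= 0) or self.s_ba <= 0:
            raise ValueError("residual SDs and s_BA must be > 0")
        if np.any(np.abs(self.correlations) > 1 + 1e-12):
            raise ValueError("|r_j| must be <= 1")


def _as_marker_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


class MLRAge(BaseEstimator):
    """BA as the fitted values of an OLS regression of CA on the markers."""

    method = "MLR"

    def fit(self, X, y):
        Xv, self.markers_ = _as_marker_matrix(X)
        y = np.asarray(y, dtype=float)
        n, J = Xv.shape
        if n <= J + 1:
            raise ValueError("need n > J + 1 subjects")
        design = np.column_stack([np.ones(n), Xv])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("marker matrix is rank deficient (collinear markers)")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_, self.coef_ = float(coef[0]), coef[1:]
        fitted = design @ coef
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot
        return self

    def predict(self, X, y=None):
        Xv, _ = _as_marker_matrix(X)
        return self.intercept_ + Xv @ self.coef_


class PCAAge(BaseEstimator):
    """BA from the first principal component of z-scored markers.

    The component is sign-aligned to correlate positively with CA and
    rescaled so that BA has exactly the mean and SD of CA in the training
    cohort.  This fixed-moment scaling (rather than regressing CA on the
    component) deliberately preserves the full CA-scale spread.
    """

    method = "PCA"

    def fit(self, X, y):
        Xv, self.markers_ = _as_marker_matrix(X)
        y = np.asarray(y, dtype=float)
        if Xv.shape[1] < 2:
            raise ValueError("PCA needs at least 2 markers")
        sd = Xv.std(axis=0, ddof=1)
        flat = [self.markers_[j] for j in np.flatnonzero(sd <= 0)]
        if flat:
            raise ValueError(f"markers with zero variance: {flat}")
        self.mean_x_, self.sd_x_ = Xv.mean(axis=0), sd
        Z = (Xv - self.mean_x_) / self.sd_x_
        pca = PCA(n_components=1)
        pc1 = pca.fit_transform(Z)[:, 0]
        self.explained_variance_ratio_ = float(pca.explained_variance_ratio_[0])
        sign = 1.0 if np.corrcoef(pc1, y)[0, 1] >= 0 else -1.0
        self.component_ = sign * pca.components_[0]
        pc1 = sign * pc1
        self.pc_mean_, self.pc_sd_ = float(pc1.mean()), float(pc1.std(ddof=1))
        self.ca_mean_, self.ca_sd_ = float(y.mean()), float(y.std(ddof=1))
        return self

    def predict(self, X, y=None):
        Xv, _ = _as_marker_matrix(X)
        pc1 = ((Xv - self.mean_x_) / self.sd_x_) @ self.component_
        return self.ca_mean_ + (pc1 - self.pc_mean_) / self.pc_sd_ * self.ca_sd_


class KlemeraDoubal(BaseEstimator):
    """Klemera-Doubal two-step BA estimator.

    Step 1 regresses each marker on CA: ``x_j = q_j + k_j CA + e_j`` with
    residual SD ``s_j`` and correlation ``r_j``.  Step 2 combines markers
    by inverse-variance weights,

        BA_E = sum_j (x_j - q_j) k_j / s_j^2  /  sum_j (k_j / s_j)^2 ,

    and the corrected default shrinks toward CA,

        BA = [sum_j (x_j - q_j) k_j / s_j^2 + CA / s_BA^2]
             / [sum_j (k_j / s_j)^2 + 1 / s_BA^2] .

    ``s_BA^2`` defaults to
    ``max(eps, mean[(BA_E - CA)^2] - ((1 - rbar^2)/rbar^2) * (CA_max - CA_min)^2 / (12 J))``
    with ``rbar`` the mean |r_j|; pass ``s_ba2`` to override.
    """

    method = "KD"

    def __init__(self, corrected: bool = True, s_ba2: float | None = None):
        self.corrected = corrected
        self.s_ba2 = s_ba2

    def fit(self, X, y):
        Xv, self.markers_ = _as_marker_matrix(X)
        y = np.asarray(y, dtype=float)
        n, J = Xv.shape
        if n < 3:
            raise ValueError("need at least 3 subjects")
        yc = y - y.mean()
        syy = float(yc @ yc)
        if syy <= 0:
            raise ValueError("CA has zero variance")
        slopes = (Xv - Xv.mean(axis=0)).T @ yc / syy
        intercepts = Xv.mean(axis=0) - slopes * y.mean()
        resid = Xv - (intercepts + np.outer(y, slopes))
        resid_sds = np.sqrt((resid**2).sum(axis=0) / max(n - 2, 1))
        sx = Xv.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = slopes * y.std(ddof=1) / sx
        corr = np.nan_to_num(corr)

        degenerate = [self.markers_[j] for j in np.flatnonzero(resid_sds < 1e-10)]
        if degenerate:
            raise DegenerateMarkerError(
                f"markers are exact functions of CA (residual SD ~ 0): {degenerate}"
            )
        included = np.abs(corr) > 1e-10
        dropped = [self.markers_[j] for j in np.flatnonzero(~included)]
        if dropped:
            warnings.warn(
                f"markers uncorrelated with CA excluded from KD sum: {dropped}",
                stacklevel=2,
            )
        if not included.any():
            raise ValueError("all markers excluded: none correlate with CA")

        w = np.zeros(J)
        w[included] = slopes[included] / resid_sds[included] ** 2
        denom = float(np.sum((slopes[included] / resid_sds[included]) ** 2))
        ba_e = ((Xv - intercepts) @ w) / denom

        if self.s_ba2 is not None:
            s_ba2 = float(self.s_ba2)
            if s_ba2 <= 0:
                raise ValueError("s_ba2 must be > 0")
        else:
            rbar = float(np.mean(np.abs(corr[included])))
            age_span = float(y.max() - y.min())
            j_used = int(included.sum())
            penalty = ((1.0 - rbar**2) / rbar**2) * age_span**2 / (12.0 * j_used)
            s_ba2 = max(1e-6, float(np.mean((ba_e - y) ** 2)) - penalty)

        self.calibration_ = KDCalibration(
            markers=self.markers_,
            slopes=slopes,
            intercepts=intercepts,
            resid_sds=resid_sds,
            correlations=corr,
            s_ba=float(np.sqrt(s_ba2)),
            age_range=(float(y.min()), float(y.max())),
            included=included,
        )
        self._w, self._denom = w, denom
        return self

    def predict(self, X, y=None):
        """Corrected BA needs CA (``y``); the uncorrected BA_E does not."""
        Xv, _ = _as_marker_matrix(X)
        cal = self.calibration_
        num = (Xv - cal.intercepts) @ self._w
        if not self.corrected:
            return num / self._denom
        if y is None:
            raise ValueError("corrected KD prediction requires CA (y)")
        y = np.asarray(y, dtype=float)
        s2 = cal.s_ba**2
        return (num + y / s2) / (self._denom + 1.0 / s2)

    def predict_uncorrected(self, X):
        Xv, _ = _as_marker_matrix(X)
        return ((Xv - self.calibration_.intercepts) @ self._w) / self._denom


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def estimate_mlr(cohort: Cohort) -> BAEstimates:
    """BA via multiple linear regression of CA on the marker panel."""
    est = MLRAge().fit(cohort.marker_frame, cohort.age)
    return BAEstimates("MLR", est.predict(cohort.marker_frame), cohort.age, cohort.subject_id)


def estimate_pca(cohort: Cohort) -> BAEstimates:
    """BA via the first principal component mapped to age units."""
    est = PCAAge().fit(cohort.marker_frame, cohort.age)
    return BAEstimates("PCA", est.predict(cohort.marker_frame), cohort.age, cohort.subject_id)


def kd_calibrate(cohort: Cohort, s_ba2: float | None = None) -> KDCalibration:
    """Step-1 KD calibration: per-marker regressions on CA plus s_BA."""
    est = KlemeraDoubal(s_ba2=s_ba2).fit(cohort.marker_frame, cohort.age)
    return est.calibration_


def estimate_kd(
    cohort: Cohort, cal: KDCalibration | None = None, corrected: bool = True
) -> BAEstimates:
    """Step-2 KD combination; ``corrected=True`` (default) shrinks to CA.

    When a calibration is supplied it is applied as-is (no refitting), so
    a calibration from one age window can score another cohort.
    """
    if cal is None:
        cal = kd_calibrate(cohort)
    if not cal.included.any():
        raise ValueError("all markers excluded from the KD calibration")
    missing = [m for m in cal.markers if m not in cohort.markers]
    if missing:
        raise ValueError(f"calibration markers absent from cohort: {missing}")
    X = cohort.data[cal.markers].to_numpy(dtype=float)
    w = np.where(cal.included, cal.slopes / cal.resid_sds**2, 0.0)
    denom = float(np.sum((cal.slopes[cal.included] / cal.resid_sds[cal.included]) ** 2))
    num = (X - cal.intercepts) @ w
    if corrected:
        s2 = cal.s_ba**2
        ba = (num + cohort.age / s2) / (denom + 1.0 / s2)
    else:
        ba = num / denom
    return BAEstimates("KD", ba, cohort.age, cohort.subject_id)
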