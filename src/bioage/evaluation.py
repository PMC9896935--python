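"""Downstream analyses: life expectancy under delta-BA scenarios, ROC/AUC
by specificity band, BA-on-CA hypothesis tests, and delta-BA disparity
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, special, stats
from sklearn.metrics import roc_curve

from .cohort import Cohort
from .estimators import BAEstimates
from .gompertz import GompertzFit, _expm1_over

__all__ = [
    "life_expectancy",
    "life_expectancy_closed_form",
    "e65_delta_curve",
    "roc_auc",
    "roc_inputs_at_horizon",
    "ba_ca_regression",
    "BACARegression",
    "disparity_regression",
]

_OMEGA_AGE = 120.0  # oldest age the survival integral runs to


def _phi_from_fit(fit: GompertzFit, phi_name: str | None) -> float:
    if phi_name is None:
        if len(fit.coef) == 1:
            return next(iter(fit.coef.values()))
        if not fit.coef:
            return 0.0
        raise ValueError("ambiguous covariates; pass phi_name")
    return fit.coef[phi_name]


def life_expectancy(
    fit: GompertzFit, age: float = 65.0, delta: float = 0.0, phi_name: str | None = None
) -> float:
    """Remaining life expectancy at ``age`` for a subject with BA - CA =
    ``delta``, by adaptive quadrature of the Gompertz survivor function.

    ``E = int_0^omega exp(-(k/beta) * exp(beta*age + phi*delta) *
    (exp(beta*t) - 1)) dt`` with omega = 120 - age.
    """
    if fit.beta <= 0 or fit.k <= 0:
        raise ValueError("fit must have k > 0 and beta > 0")
    phi = _phi_from_fit(fit, phi_name)
    a = (fit.k / fit.beta) * np.exp(fit.alpha * age + phi * delta)
    omega = _OMEGA_AGE - age
    if omega <= 0:
        raise ValueError("age must be below 120")

    def surv(t):
        return np.exp(-a * np.expm1(fit.beta * t))

    val, _ = integrate.quad(surv, 0.0, omega, epsabs=1e-8, epsrel=1e-8, limit=200)
    return float(val)


def life_expectancy_closed_form(
    fit: GompertzFit, age: float = 65.0, delta: float = 0.0, phi_name: str | None = None
) -> float:
    """Same integral via the exponential-integral change of variable:
    ``E = e^a / beta * (E1(a) - E1(a * e^(beta*omega)))``.
    """
    phi = _phi_from_fit(fit, phi_name)
    a = (fit.k / fit.beta) * np.exp(fit.alpha * age + phi * delta)
    omega = _OMEGA_AGE - age
    upper = a * np.exp(fit.beta * omega)
    return float(np.exp(a) / fit.beta * (special.exp1(a) - special.exp1(upper)))


def e65_delta_curve(
    fit: GompertzFit,
    delta_grid=None,
    age: float = 65.0,
    phi_name: str | None = None,
) -> pd.DataFrame:
    """E(age) across delta-BA scenarios, differenced against delta = 0."""
    if delta_grid is None:
        delta_grid = np.linspace(-5.0, 5.0, 21)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if not np.all(np.isfinite(delta_grid)):
        raise ValueError("delta grid must be finite")
    e_ref = life_expectancy(fit, age=age, delta=0.0, phi_name=phi_name)
    rows = []
    for d in delta_grid:
        e = life_expectancy(fit, age=age, delta=float(d), phi_name=phi_name)
        rows.append({"age": age, "delta": float(d), "e_years": e, "diff_vs_zero": e - e_ref})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels, specificity_band: tuple[float, float] = (0.0, 1.0)) -> float:
    """AUC over a specificity band, normalized by band width.

    ``specificity_band=(lo, hi)`` restricts the ROC to false-positive
    rates in ``[1 - hi, 1 - lo]``; the default covers the full curve and
    equals the usual rank-statistic AUC (ties by midrank).  A perfect
    classifier scores 1 on any band under the width normalization.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    lo, hi = specificity_band
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("need 0 <= lo < hi <= 1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    f0, f1 = 1.0 - hi, 1.0 - lo
    # keep the curve's own points (including vertical segments) inside the
    # band and linearly interpolate the two band edges
    inside = (fpr >= f0) & (fpr <= f1)
    xs = np.concatenate([[f0], fpr[inside], [f1]])
    ys = np.concatenate([[np.interp(f0, fpr, tpr)], tpr[inside], [np.interp(f1, fpr, tpr)]])
    area = float(np.trapezoid(ys, xs))
    return area / (f1 - f0)


def roc_inputs_at_horizon(
    cohort: Cohort, fit: GompertzFit, horizon: float, covariates: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Risk scores and death labels at a fixed follow-up horizon.

    The score is the model-predicted cumulative hazard at the horizon;
    the label is death within the horizon.  Subjects censored before the
    horizon carry no label and are dropped.
    """
    dead_by_h = (cohort.dead == 1) & (cohort.duration <= horizon)
    known = dead_by_h | (cohort.duration >= horizon)
    lin = np.zeros(cohort.n)
    if covariates:
        for name, vec in covariates.items():
            lin = lin + fit.coef[name] * np.asarray(vec, dtype=float)
    scores = fit.k * np.exp(fit.alpha * cohort.age + lin) * _expm1_over(fit.beta, np.full(cohort.n, horizon))
    return scores[known], dead_by_h[known].astype(int)


# ---------------------------------------------------------------------------
# BA-on-CA and disparity regressions
# ---------------------------------------------------------------------------

@dataclass
class BACARegression:
    """OLS of BA on CA with the (intercept, slope) = (0, 1) Wald battery."""

    method: str
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    p_intercept_zero: float
    p_slope_one: float
    delta_slope: float          # slope of (BA - CA) on CA
    delta_intercept: float
    r2: float


def ba_ca_regression(ba: BAEstimates, cohort: Cohort) -> BACARegression:
    """Linear association between BA and CA with tests of 0/1 nulls."""
    ca = cohort.age
    if len(ba.ba) != len(ca) or len(ca) <= 2:
        raise ValueError("need matching BA/CA vectors with n > 2")
    X = sm.add_constant(ca)
    fit = sm.OLS(ba.ba, X).fit()
    c0, c1 = fit.params
    t0 = c0 / fit.bse[0]
    t1 = (c1 - 1.0) / fit.bse[1]
    dof = fit.df_resid
    dfit = sm.OLS(ba.delta, X).fit()
    return BACARegression(
        method=ba.method,
        slope=float(c1),
        intercept=float(c0),
        se_slope=float(fit.bse[1]),
        se_intercept=float(fit.bse[0]),
        p_intercept_zero=float(2 * stats.t.sf(abs(t0), dof)),
        p_slope_one=float(2 * stats.t.sf(abs(t1), dof)),
        delta_slope=float(dfit.params[1]),
        delta_intercept=float(dfit.params[0]),
        r2=float(fit.rsquared),
    )


_DISPARITY_TERMS = [
    ("ca", None),
    ("female", None),
    ("nh_black", ("race", "nh_black")),
    ("mex_american", ("race", "mex_american")),
    ("hs", ("education", "hs")),
    ("college_plus", ("education", "college_plus")),
]


def _disparity_design(cohort: Cohort) -> pd.DataFrame:
    for cov in ("sex", "race", "education"):
        if cov not in cohort.covariates:
            raise ValueError(f"cohort lacks covariate {cov!r}")
    refs = {"race": "nh_white", "education": "less_than_hs"}
    for cov, ref in refs.items():
        present = set(cohort.data[cov].unique())
        if ref not in present:
            raise ValueError(f"reference level {ref!r} missing from {cov!r}; levels: {sorted(present)}")
    d = pd.DataFrame({"ca": cohort.age})
    d["female"] = (cohort.data["sex"] == "female").astype(float)
    for name, spec in _DISPARITY_TERMS:
        if spec is None:
            continue
        cov, level = spec
        d[name] = (cohort.data[cov] == level).astype(float)
    return d


def disparity_regression(ba_list, cohort: Cohort) -> pd.DataFrame:
    """Table of delta-BA regressions on CA, sex, race/ethnicity, education.

    ``ba_list`` is one :class:`BAEstimates` or a sequence; columns follow
    the conventional method ordering (KD, MLR, PCA, OF/OD linear, OF/OD
    nonlinear) for those present.
    """
    if isinstance(ba_list, BAEstimates):
        ba_list = [ba_list]
    order = ["KD", "MLR", "PCA", "OF-linear", "OD-linear", "OF-nonlinear", "OD-nonlinear"]
    ba_list = sorted(
        ba_list, key=lambda b: order.index(b.method) if b.method in order else len(order)
    )
    design = _disparity_design(cohort)
    X = sm.add_constant(design)
    rows: dict[str, dict] = {}
    for ba in ba_list:
        fit = sm.OLS(ba.delta, X).fit()
        col: dict[str, float] = {}
        for name in ["const"] + [t for t, _ in _DISPARITY_TERMS]:
            col[name] = float(fit.params[name])
            col[f"p_{name}"] = float(fit.pvalues[name])
        col["n"] = int(fit.nobs)
        col["adj_r2"] = float(fit.rsquared_adj)
        col["aic"] = float(fit.aic)
        col["bic"] = float(fit.bic)
        rows[ba.method] = col
    return pd.DataFrame(rows)
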