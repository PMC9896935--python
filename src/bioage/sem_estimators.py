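"""Outcome-free (OF) and outcome-dependent (OD) biological-age estimators.

Both build on factor scores FS(BA) from the one-factor SEM.

**OF**: regress CA (linear form) or ln CA (log-linear form) on FS and take
the fitted values (exponentiated for the log form, no retransformation
correction) as BA.  Because OLS fitted values are invariant to affine
maps of the regressor, OF BA inherits the SEM's invariance to marker
rescaling.

**OD**: anchor BA on mortality.  Given a null Gompertz hazard in age only
and an augmented hazard that adds FS, BA is the age at which the null
hazard equals the augmented hazard evaluated at the subject's actual
(CA, FS):

    k_n * exp(beta_n * BA) = k_a * exp(beta_a * CA + gamma * FS)
    BA = [ln(k_a / k_n) + beta_a * CA + gamma * FS] / beta_n .

When gamma = 0 and the two fits coincide, BA == CA for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .cohort import Cohort
from .estimators import BAEstimates
from .gompertz import GompertzFit
from .sem import FactorScores

__all__ = [
    "OFCalibration",
    "estimate_of",
    "estimate_od",
    "od_closed_form",
    "delta_ba",
]


@dataclass
class OFCalibration:
    """OLS calibration of CA (or ln CA) on factor scores with Wald tests.

    The null hypotheses follow the reduction argument: if (intercept,
    slope) = (0, 1) in the linear form — or (1, 1) in the log form — the
    SEM collapses to the restricted mapping the classic methods assume.
    """

    form: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r2: float
    null_intercept: float
    null_slope: float
    wald_p_intercept: float
    wald_p_slope: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")


def estimate_of(
    fs: FactorScores, cohort: Cohort, form: str = "linear"
) -> tuple[BAEstimates, OFCalibration]:
    """Outcome-free BA: fitted values of CA (or ln CA) regressed on FS."""
    if form not in {"linear", "loglinear"}:
        raise ValueError("form must be 'linear' or 'loglinear'")
    scores = np.asarray(fs.scores, dtype=float)
    ca = cohort.age
    if len(scores) != len(ca):
        raise ValueError("factor scores and cohort have different lengths")
    if np.ptp(scores) == 0:
        raise ValueError("factor scores are constant; no calibration possible")
    target = np.log(ca) if form == "loglinear" else ca
    if form == "loglinear" and np.any(ca <= 0):
        raise ValueError("CA must be > 0 for the log-linear form")
    X = sm.add_constant(scores)
    ols = sm.OLS(target, X).fit()
    c0, c1 = ols.params
    fitted = ols.fittedvalues
    ba = np.exp(fitted) if form == "loglinear" else np.asarray(fitted)
    null0, null1 = (1.0, 1.0) if form == "loglinear" else (0.0, 1.0)
    t0 = (c0 - null0) / ols.bse[0]
    t1 = (c1 - null1) / ols.bse[1]
    from scipy import stats

    dof = ols.df_resid
    cal = OFCalibration(
        form=form,
        intercept=float(c0),
        slope=float(c1),
        se_intercept=float(ols.bse[0]),
        se_slope=float(ols.bse[1]),
        r2=float(ols.rsquared),
        null_intercept=null0,
        null_slope=null1,
        wald_p_intercept=float(2 * stats.t.sf(abs(t0), dof)),
        wald_p_slope=float(2 * stats.t.sf(abs(t1), dof)),
    )
    tag = "OF-linear" if form == "linear" else "OF-nonlinear"
    return BAEstimates(tag, ba, ca, cohort.subject_id), cal


def od_closed_form(
    ca: np.ndarray,
    fs: np.ndarray,
    k_null: float,
    beta_null: float,
    k_aug: float,
    beta_aug: float,
    gamma: float,
) -> np.ndarray:
    """Solve the hazard-matching identity for BA in closed form."""
    if beta_null <= 0:
        raise ValueError("the null Gompertz slope must be > 0")
    if k_null <= 0 or k_aug <= 0:
        raise ValueError("hazard levels must be > 0")
    ca = np.asarray(ca, dtype=float)
    fs = np.asarray(fs, dtype=float)
    if not np.all(np.isfinite(fs)):
        raise ValueError("factor scores must be finite")
    return (np.log(k_aug / k_null) + beta_aug * ca + gamma * fs) / beta_null


def estimate_od(
    fs: FactorScores,
    cohort: Cohort,
    null_fit: GompertzFit,
    aug_fit: GompertzFit,
    fs_name: str = "fs",
) -> BAEstimates:
    """Outcome-dependent BA via risk matching against the null hazard.

    ``aug_fit`` must carry the factor-score coefficient under ``fs_name``.
    """
    if fs_name not in aug_fit.coef:
        raise ValueError(f"augmented fit lacks a {fs_name!r} coefficient")
    gamma = aug_fit.coef[fs_name]
    ba = od_closed_form(
        cohort.age,
        fs.scores,
        null_fit.k,
        null_fit.beta,
        aug_fit.k,
        aug_fit.alpha,
        gamma,
    )
    tag = "OD-linear" if fs.form == "linear" else "OD-nonlinear"
    return BAEstimates(tag, ba, cohort.age, cohort.subject_id)


def delta_ba(ba: BAEstimates, cohort: Cohort) -> BAEstimates:
    """Recompute delta = BA - CA against the cohort's baseline ages."""
    if len(ba.ba) != cohort.n:
        raise ValueError("BA vector and cohort have different lengths")
    return BAEstimates(ba.method, ba.ba, cohort.age, cohort.subject_id)
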