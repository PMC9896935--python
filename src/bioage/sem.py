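"""One-factor structural equation model for latent biological age.

Model: a latent deterioration factor BA is measured by J biomarkers and
structurally regressed on g(CA), where g is the identity (linear form) or
the natural log (log-linear form):

    x_j = nu_j + lambda_j * BA + eps_j,   eps_j ~ N(0, theta_j)
    BA  = b * g(CA) + zeta,               zeta  ~ N(0, psi)

Identification fixes the first marker's loading to 1 (reference-indicator
convention); the latent intercept is fixed to 0 because it is not
separately identified when every marker intercept is free.  Estimation is
maximum likelihood on the conditional distribution of the markers given
g(CA) — equivalent to joint normal ML with the exogenous moments
saturated — so log-likelihoods of the linear and log-linear forms are
comparable (same dependent data, different regressor).

Factor scores are regression (expected a posteriori) scores,
``FS_i = E[BA | x_i, g_i]`` under the fitted Gaussian model; Bartlett
scores are available behind a flag.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

from .cohort import Cohort

__all__ = [
    "SemSpec",
    "SemFit",
    "FactorScores",
    "OneFactorSEM",
    "IdentificationError",
    "SemConvergenceError",
    "fit_sem",
    "factor_scores",
    "sem_fit_stats",
]


class IdentificationError(ValueError):
    """Model not identified (fewer than three markers, or degenerate data)."""


class SemConvergenceError(RuntimeError):
    """Optimizer failed after the allotted restarts."""


@dataclass
class SemSpec:
    """Which markers enter the measurement model and the structural form."""

    markers: list[str]
    form: str = "linear"  # CA enters as-is; "loglinear" uses ln CA

    def __post_init__(self) -> None:
        if self.form not in {"linear", "loglinear"}:
            raise ValueError("form must be 'linear' or 'loglinear'")
        if len(self.markers) < 3:
            raise IdentificationError("a one-factor model needs at least 3 markers")


@dataclass
class SemFit:
    """Fitted measurement/structural parameters plus fit statistics."""

    markers: list[str]
    form: str
    loadings: np.ndarray            # lambda_j, loadings[0] == 1
    intercepts: np.ndarray          # nu_j
    resid_vars: np.ndarray          # theta_j (variances)
    structural_slope: float         # b on g(CA)
    structural_intercept: float     # fixed 0.0
    psi: float                      # disturbance variance
    loglik: float
    n_params: int
    aic: float
    bic: float
    srmr: float
    n: int
    converged: bool
    n_iter: int
    estimator: "OneFactorSEM"

    def __post_init__(self) -> None:
        if np.any(self.resid_vars <= 0) or self.psi < 0:
            raise ValueError("resid_vars must be > 0 and psi >= 0")


@dataclass
class FactorScores:
    """Per-subject unitless score of the latent factor."""

    scores: np.ndarray
    method: str
    markers: list[str]
    form: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("factor scores must be finite")


def _g(ca: np.ndarray, form: str) -> np.ndarray:
    if form == "loglinear":
        if np.any(ca <= 0):
            raise ValueError("CA must be > 0 for the log-linear form")
        return np.log(ca)
    return np.asarray(ca, dtype=float)


class OneFactorSEM(BaseEstimator):
    """Maximum-likelihood one-factor measurement model with an exogenous
    age regressor, in the scikit-learn estimator idiom.

    Parameters
    ----------
    form : {"linear", "loglinear"}
        Whether the latent is regressed on CA or ln CA.
    score_method : {"regression", "bartlett"}
        Factor-score flavour returned by :meth:`transform`.
    max_restarts : int
        Jittered restarts on non-convergence.
    random_state : int
        Seed for restart jitter only (the fit itself is deterministic).
    """

    def __init__(
        self,
        form: str = "linear",
        score_method: str = "regression",
        max_restarts: int = 5,
        random_state: int = 0,
    ):
        self.form = form
        self.score_method = score_method
        self.max_restarts = max_restarts
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _unpack(params: np.ndarray, J: int):
        lam = np.concatenate([[1.0], params[: J - 1]])
        b = params[J - 1]
        psi = np.exp(params[J])
        theta = np.exp(params[J + 1 : 2 * J + 1])
        return lam, b, psi, theta

    @staticmethod
    def _neg_loglik_per_n(params, J, S_xx, s_xg, s_gg):
        val, _ = OneFactorSEM._neg_loglik_grad(params, J, S_xx, s_xg, s_gg)
        return val

    @staticmethod
    def _neg_loglik_grad(params, J, S_xx, s_xg, s_gg):
        """Objective (per subject) and its analytic gradient."""
        lam, b, psi, theta = OneFactorSEM._unpack(params, J)
        sigma = psi * np.outer(lam, lam)
        sigma[np.diag_indices(J)] += theta
        bad = 1e12, np.zeros_like(params)
        try:
            chol = linalg.cholesky(sigma, lower=True)
        except linalg.LinAlgError:
            return bad
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        c = b * lam
        M = S_xx - np.outer(c, s_xg) - np.outer(s_xg, c) + s_gg * np.outer(c, c)
        P = linalg.cho_solve((chol, True), np.eye(J))
        PM = P @ M
        val = 0.5 * (J * np.log(2.0 * np.pi) + logdet + np.trace(PM))
        if not np.isfinite(val):
            return bad
        # dF/dSigma = (P - P M P)/2; M depends on (lambda, b), Sigma on
        # (lambda, psi, theta)
        G = 0.5 * (P - PM @ P)
        Pl = P @ lam
        Ps = P @ s_xg
        g_lam = 2.0 * psi * (G @ lam) + b**2 * s_gg * Pl - b * Ps
        g_b = float(b * s_gg * (lam @ Pl) - lam @ Ps)
        g_logpsi = float(lam @ (G @ lam)) * psi
        g_logtheta = np.diag(G) * theta
        grad = np.concatenate([g_lam[1:], [g_b, g_logpsi], g_logtheta])
        return val, grad

    def _newton_polish(self, x, J, S_xx, s_xg, s_gg, iters: int = 4):
        """Newton steps on the analytic gradient (finite-difference
        Hessian) to reach the optimum to near machine precision — the
        affine-invariance identities of downstream BA hold only there."""
        f, g = self._neg_loglik_grad(x, J, S_xx, s_xg, s_gg)
        p = len(x)
        for _ in range(iters):
            if np.linalg.norm(g) < 1e-13:
                break
            H = np.zeros((p, p))
            eps = 1e-6
            for j in range(p):
                up = x.copy()
                up[j] += eps
                _, gu = self._neg_loglik_grad(up, J, S_xx, s_xg, s_gg)
                H[:, j] = (gu - g) / eps
            H = 0.5 * (H + H.T)
            try:
                step = linalg.solve(H, g, assume_a="sym")
            except linalg.LinAlgError:
                break
            x_new = x - step
            f_new, g_new = self._neg_loglik_grad(x_new, J, S_xx, s_xg, s_gg)
            if not np.isfinite(f_new) or f_new > f + 1e-12:
                break
            x, f, g = x_new, f_new, g_new
        return x, f

    def _initial_params(self, J, S_xx, s_xg, s_gg):
        # principal-axis start: partial g out of the markers, take the
        # leading eigenvector of the residual covariance
        R = S_xx - np.outer(s_xg, s_xg) / s_gg
        evals, evecs = linalg.eigh(R)
        u, e = evecs[:, -1], max(evals[-1], 1e-8)
        if abs(u[0]) < 1e-8:
            lam0 = np.ones(J)
            psi0 = max(e, 1e-4)
        else:
            lam0 = u / u[0]
            psi0 = max(e * u[0] ** 2, 1e-8)
        theta0 = np.maximum(np.diag(R) - psi0 * lam0**2, 0.05 * np.diag(R))
        b0 = s_xg[0] / s_gg
        return np.concatenate([lam0[1:], [b0, np.log(psi0)], np.log(theta0)])

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y):
        """Fit the model.

        Parameters
        ----------
        X : DataFrame or array, shape (n, J)
            Biomarker panel (J >= 3 markers with positive variance).
        y : array, shape (n,)
            Chronological age at baseline (years; > 0 for log-linear).
        """
        if self.form not in {"linear", "loglinear"}:
            raise ValueError("form must be 'linear' or 'loglinear'")
        if isinstance(X, pd.DataFrame):
            self.markers_ = list(X.columns)
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            self.markers_ = [f"x{j}" for j in range(Xv.shape[1])]
        y = np.asarray(y, dtype=float)
        n, J = Xv.shape
        if J < 3:
            raise IdentificationError("a one-factor model needs at least 3 markers")
        if n <= J + 1:
            raise ValueError("need more subjects than markers")
        if np.isnan(Xv).any() or np.isnan(y).any():
            raise ValueError("markers and age must be complete (no NaN)")
        var = Xv.var(axis=0)
        flat = [self.markers_[j] for j in np.flatnonzero(var <= 0)]
        if flat:
            raise ValueError(f"markers with zero variance: {flat}")

        g = _g(y, self.form)
        xm, gm = Xv.mean(axis=0), g.mean()
        Xc, gc = Xv - xm, g - gm
        S_xx = (Xc.T @ Xc) / n
        s_xg = (Xc.T @ gc) / n
        s_gg = float(gc @ gc) / n
        if s_gg <= 0:
            raise ValueError("age has zero variance")

        x0 = self._initial_params(J, S_xx, s_xg, s_gg)
        rng = np.random.default_rng(self.random_state)
        best = None
        for attempt in range(self.max_restarts + 1):
            start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.1, size=x0.size)
            res = optimize.minimize(
                self._neg_loglik_grad,
                start,
                args=(J, S_xx, s_xg, s_gg),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        if best is None or not np.isfinite(best.fun):
            raise SemConvergenceError("SEM optimizer failed to produce a finite optimum")
        best_x, best_f = self._newton_polish(best.x, J, S_xx, s_xg, s_gg)
        _, best_grad = self._neg_loglik_grad(best_x, J, S_xx, s_xg, s_gg)
        best.x, best.fun = best_x, best_f
        converged = bool(best.success) or float(np.linalg.norm(best_grad)) < 1e-8

        lam, b, psi, theta = self._unpack(best.x, J)
        if lam[0] < 0:  # cannot happen with the reference convention, kept defensive
            lam = -lam
        self.loadings_ = lam
        self.structural_slope_ = float(b)
        self.structural_intercept_ = 0.0
        self.psi_ = float(psi)
        self.resid_vars_ = theta
        self.intercepts_ = xm - lam * b * gm
        self.n_, self.n_features_in_ = n, J
        self.converged_ = converged
        self.n_iter_ = int(best.nit)
        self.loglik_ = -float(best.fun) * n
        # free parameters: nu (J) + lambda (J-1) + b + psi + theta (J)
        self.n_params_ = 3 * J + 1
        self.aic_ = -2.0 * self.loglik_ + 2.0 * self.n_params_
        self.bic_ = -2.0 * self.loglik_ + self.n_params_ * np.log(n)
        self.srmr_ = self._srmr(S_xx, s_xg, s_gg)
        self._moments_ = (S_xx, s_xg, s_gg)
        return self

    def _implied_joint(self, s_gg: float):
        """Model-implied covariance of (markers, g) with saturated g."""
        lam, b = self.loadings_, self.structural_slope_
        var_ba = b**2 * s_gg + self.psi_
        sig_xx = var_ba * np.outer(lam, lam)
        sig_xx[np.diag_indices(len(lam))] += self.resid_vars_
        sig_xg = lam * b * s_gg
        top = np.hstack([sig_xx, sig_xg[:, None]])
        bot = np.hstack([sig_xg, [s_gg]])
        return np.vstack([top, bot])

    def _srmr(self, S_xx, s_xg, s_gg) -> float:
        S = np.vstack(
            [np.hstack([S_xx, s_xg[:, None]]), np.hstack([s_xg, [s_gg]])]
        )
        Sigma = self._implied_joint(s_gg)
        ds = np.sqrt(np.diag(S))
        dm = np.sqrt(np.diag(Sigma))
        Rs = S / np.outer(ds, ds)
        Rm = Sigma / np.outer(dm, dm)
        # include the diagonal: variance residuals enter as 1 - sigma/s
        diag_resid = (np.diag(S) - np.diag(Sigma)) / np.diag(S)
        p = S.shape[0]
        iu = np.triu_indices(p, k=1)
        resid2 = np.concatenate([(Rs - Rm)[iu] ** 2, diag_resid**2])
        return float(np.sqrt(resid2.mean()))

    def transform(self, X, y) -> np.ndarray:
        """Factor scores for (markers, age); requires a fitted model."""
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.markers_:
                raise ValueError(
                    f"marker mismatch: fitted on {self.markers_}, got {list(X.columns)}"
                )
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.shape[1] != self.n_features_in_:
                raise ValueError("marker count mismatch")
        g = _g(np.asarray(y, dtype=float), self.form)
        lam, b = self.loadings_, self.structural_slope_
        resid = Xv - self.intercepts_ - np.outer(b * g, lam)
        if self.score_method == "regression":
            sigma = self.psi_ * np.outer(lam, lam)
            sigma[np.diag_indices(len(lam))] += self.resid_vars_
            w = self.psi_ * linalg.solve(sigma, lam, assume_a="pos")
            scores = b * g + resid @ w
        elif self.score_method == "bartlett":
            wt = lam / self.resid_vars_
            scores = b * g + (resid @ wt) / (lam @ wt)
        else:
            raise ValueError("score_method must be 'regression' or 'bartlett'")
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite factor scores")
        return scores

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X, y)

    def _check_fitted(self) -> None:
        if not hasattr(self, "loadings_"):
            raise RuntimeError("OneFactorSEM is not fitted")

    def to_fit(self) -> SemFit:
        self._check_fitted()
        return SemFit(
            markers=self.markers_,
            form=self.form,
            loadings=self.loadings_,
            intercepts=self.intercepts_,
            resid_vars=self.resid_vars_,
            structural_slope=self.structural_slope_,
            structural_intercept=self.structural_intercept_,
            psi=self.psi_,
            loglik=self.loglik_,
            n_params=self.n_params_,
            aic=self.aic_,
            bic=self.bic_,
            srmr=self.srmr_,
            n=self.n_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            estimator=self,
        )


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def fit_sem(cohort: Cohort, spec: SemSpec, **kwargs) -> SemFit:
    """Fit the one-factor SEM on a filtered cohort."""
    missing = [m for m in spec.markers if m not in cohort.markers]
    if missing:
        raise ValueError(f"spec markers absent from cohort: {missing}")
    est = OneFactorSEM(form=spec.form, **kwargs)
    est.fit(cohort.data[spec.markers], cohort.age)
    if not est.converged_:
        raise SemConvergenceError("SEM did not converge after restarts")
    return est.to_fit()


def factor_scores(fit: SemFit, cohort: Cohort, method: str | None = None) -> FactorScores:
    """Regression-method factor scores FS(BA) for every subject."""
    est = fit.estimator
    if method is not None:
        est = OneFactorSEM(**{**est.get_params(), "score_method": method})
        for attr in (
            "markers_", "loadings_", "intercepts_", "resid_vars_", "structural_slope_",
            "structural_intercept_", "psi_", "n_", "n_features_in_", "converged_",
        ):
            setattr(est, attr, getattr(fit.estimator, attr))
    scores = est.transform(cohort.data[fit.markers], cohort.age)
    return FactorScores(
        scores=scores, method=est.score_method, markers=fit.markers, form=fit.form
    )


def sem_fit_stats(fit: SemFit) -> dict:
    """Log-likelihood, AIC, BIC and SRMR of the fitted model."""
    return {
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "bic": fit.bic,
        "srmr": fit.srmr,
        "n": fit.n,
    }


def sem_fit_to_dict(fit: SemFit) -> dict:
    """JSON-serializable report of a fitted SEM."""
    d = dataclasses.asdict(fit)
    d.pop("estimator")
    for key in ("loadings", "intercepts", "resid_vars"):
        d[key] = [float(v) for v in d[key]]
    return d
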