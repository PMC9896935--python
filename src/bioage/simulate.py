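"""Synthetic cohorts with a single latent deterioration factor.

The generator mirrors the measurement model the SEM-based estimators
assume and the mortality process the Gompertz models assume:

* chronological age ``CA ~ Uniform(age_range)``;
* latent deterioration ``L = a + b*CA + zeta`` with ``zeta ~ N(0, psi^2)``;
* markers ``x_j = nu_j + lambda_j * L + eps_j``, ``eps_j ~ N(0, theta_j^2)``
  (two loadings negative by default, mirroring lung function and albumin,
  which improve as physiology worsens);
* event times drawn by inverse-CDF from the Gompertz hazard
  ``mu(t) = k * exp(beta*(CA + t) + gamma*z)`` with ``z`` the latent
  standardized by its population moments, right-censored at
  ``censor_time``.

The generating parameters are kept in :class:`SyntheticTruth` so recovery
tests can compare estimates against known values.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import AGE, DEAD, DURATION, EXCLUDED, SUBJECT, Cohort

__all__ = ["SyntheticTruth", "default_truth", "simulate_cohort", "sample_gompertz_time"]

_DEFAULT_LOADINGS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, -0.6, -0.8)
# vaguely biomarker-like locations; the estimators are location-invariant
_DEFAULT_INTERCEPTS = (50.0, 13.0, 5.5, 120.0, 80.0, 1.0, 7.4, 95.0, 4.3)

_SEX_LEVELS = ("female", "male")
_RACE_LEVELS = ("nh_white", "nh_black", "mex_american")
_RACE_P = (0.60, 0.25, 0.15)
_EDU_LEVELS = ("less_than_hs", "hs", "college_plus")
_EDU_P = (0.30, 0.40, 0.30)


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated cohort.

    ``psi=None`` applies the calibration rule that chronological age
    explains half the latent variance: ``psi = slope * range / sqrt(12)``
    (the SD of a uniform age distribution times the structural slope).
    ``latent_effect`` (gamma) is per SD of the latent, matching the
    unitless character of factor scores.
    """

    n: int = 5000
    age_range: tuple[float, float] = (30.0, 75.0)
    structural_intercept: float = -4.0425
    structural_slope: float = 0.077
    psi: float | None = None
    loadings: tuple[float, ...] = _DEFAULT_LOADINGS
    marker_intercepts: tuple[float, ...] = _DEFAULT_INTERCEPTS
    residual_sds: tuple[float, ...] = tuple([1.0] * 9)
    hazard_level: float = 1e-4
    hazard_slope: float = 0.09
    latent_effect: float = 1.5
    censor_time: float = 25.0
    seed: int = 20220726
    marker_names: tuple[str, ...] = ()
    covariate_effects: dict = field(default_factory=dict)
    excluded_cause_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        lo, hi = self.age_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("age_range must be finite with lo < hi")
        if self.hazard_level <= 0 or self.hazard_slope <= 0:
            raise ValueError("hazard level k and slope beta must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if len(self.loadings) != len(self.residual_sds) or len(self.loadings) != len(
            self.marker_intercepts
        ):
            raise ValueError("loadings, marker_intercepts and residual_sds must have equal length")
        if any(s <= 0 for s in self.residual_sds):
            raise ValueError("residual SDs must be > 0")
        if self.psi is not None and self.psi < 0:
            raise ValueError("psi must be >= 0")
        if not (0.0 <= self.excluded_cause_frac <= 1.0):
            raise ValueError("excluded_cause_frac must lie in [0, 1]")
        if not self.marker_names:
            self.marker_names = tuple(f"bm{j + 1}" for j in range(len(self.loadings)))
        if len(self.marker_names) != len(self.loadings):
            raise ValueError("marker_names length must match loadings")

    @property
    def psi_effective(self) -> float:
        if self.psi is not None:
            return self.psi
        lo, hi = self.age_range
        return abs(self.structural_slope) * (hi - lo) / math.sqrt(12.0)

    @property
    def latent_mean(self) -> float:
        lo, hi = self.age_range
        return self.structural_intercept + self.structural_slope * (lo + hi) / 2.0

    @property
    def latent_sd(self) -> float:
        lo, hi = self.age_range
        age_var = (hi - lo) ** 2 / 12.0
        return math.sqrt(self.structural_slope**2 * age_var + self.psi_effective**2)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def default_truth(seed: int = 20220726, **overrides) -> SyntheticTruth:
    """The package's reference simulation conditions (a test fixture)."""
    return SyntheticTruth(seed=seed, **overrides)


def sample_gompertz_time(k_eff, beta: float, u):
    """Invert the Gompertz survival function.

    ``S(t) = exp(-(k_eff/beta) * (exp(beta*t) - 1))``; given a uniform draw
    ``u`` the returned ``T`` satisfies ``S(T) = u`` exactly:
    ``T = (1/beta) * ln(1 - (beta/k_eff) * ln u)``.
    """
    k_eff = np.asarray(k_eff, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any(k_eff <= 0) or beta <= 0:
        raise ValueError("k_eff and beta must be > 0")
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly in (0, 1)")
    return np.log1p(-(beta / k_eff) * np.log(u)) / beta


def simulate_cohort(truth: SyntheticTruth) -> tuple[Cohort, np.ndarray]:
    """Draw a cohort from the generating model; returns (cohort, latent).

    All randomness flows from ``truth.seed`` through deterministic
    sub-streams, so the same truth yields a bit-identical cohort.
    """
    if not isinstance(truth, SyntheticTruth):
        raise TypeError("truth must be a SyntheticTruth")
    n, J = truth.n, len(truth.loadings)
    streams = np.random.SeedSequence(truth.seed).spawn(5)
    rng_age, rng_latent, rng_marker, rng_surv, rng_cov = (np.random.default_rng(s) for s in streams)

    lo, hi = truth.age_range
    ca = rng_age.uniform(lo, hi, size=n)
    zeta = rng_latent.normal(0.0, truth.psi_effective, size=n)
    latent = truth.structural_intercept + truth.structural_slope * ca + zeta

    # categorical covariates, with optional group shifts of the latent
    # expressed in years of chronological age
    sex = rng_cov.choice(_SEX_LEVELS, size=n)
    race = rng_cov.choice(_RACE_LEVELS, size=n, p=_RACE_P)
    edu = rng_cov.choice(_EDU_LEVELS, size=n, p=_EDU_P)
    levels = {"sex": sex, "race": race, "education": edu}
    for cov_name, shifts in truth.covariate_effects.items():
        if cov_name not in levels:
            raise ValueError(f"unknown covariate in covariate_effects: {cov_name!r}")
        for level, years in shifts.items():
            latent = latent + np.where(levels[cov_name] == level, truth.structural_slope * years, 0.0)

    lam = np.asarray(truth.loadings)
    eps = rng_marker.normal(0.0, 1.0, size=(n, J)) * np.asarray(truth.residual_sds)
    markers = np.asarray(truth.marker_intercepts) + latent[:, None] * lam[None, :] + eps

    z = (latent - truth.latent_mean) / truth.latent_sd
    k_eff = truth.hazard_level * np.exp(truth.hazard_slope * ca + truth.latent_effect * z)
    u = rng_surv.random(n)
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    t_event = sample_gompertz_time(k_eff, truth.hazard_slope, u)
    dead = (t_event <= truth.censor_time).astype(int)
    duration = np.minimum(t_event, truth.censor_time)

    excluded = np.zeros(n, dtype=int)
    if truth.excluded_cause_frac > 0:
        flag = rng_cov.random(n) < truth.excluded_cause_frac
        excluded = (flag & (dead == 1)).astype(int)

    df = pd.DataFrame(
        {
            SUBJECT: [f"s{i:06d}" for i in range(n)],
            AGE: ca,
            DURATION: duration,
            DEAD: dead,
            EXCLUDED: excluded,
        }
    )
    for j, name in enumerate(truth.marker_names):
        df[name] = markers[:, j]
    df["sex"] = sex
    df["race"] = race
    df["education"] = edu
    cohort = Cohort(df, list(truth.marker_names), ["sex", "race", "education"])
    return cohort, latent
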