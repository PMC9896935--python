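import numpy as np
import pandas as pd
import pytest

import bioage as ba


@pytest.fixture(scope="session")
def truth():
    return ba.default_truth(seed=101)


@pytest.fixture(scope="session")
def cohort_latent(truth):
    return ba.simulate_cohort(truth)


@pytest.fixture(scope="session")
def cohort(cohort_latent):
    return cohort_latent[0]


@pytest.fixture(scope="session")
def latent(cohort_latent):
    return cohort_latent[1]


@pytest.fixture(scope="session")
def sem_fit_linear(cohort):
    return ba.fit_sem(cohort, ba.SemSpec(list(cohort.markers), "linear"))


@pytest.fixture(scope="session")
def fs_linear(sem_fit_linear, cohort):
    return ba.factor_scores(sem_fit_linear, cohort)


@pytest.fixture(scope="session")
def null_fit(cohort):
    return ba.fit_gompertz(cohort)


@pytest.fixture(scope="session")
def aug_fit(cohort, fs_linear):
    return ba.fit_gompertz(cohort, {"fs": fs_linear.scores})


def make_cohort(
    age,
    markers: dict,
    duration=None,
    dead=None,
    excluded=None,
    covariates: dict | None = None,
) -> ba.Cohort:
    """Hand-build a small cohort for toy tests."""
    n = len(age)
    df = pd.DataFrame(
        {
            "subject_id": [f"t{i}" for i in range(n)],
            "age": np.asarray(age, dtype=float),
            "duration": np.ones(n) if duration is None else np.asarray(duration, dtype=float),
            "dead": np.zeros(n, dtype=int) if dead is None else np.asarray(dead, dtype=int),
            "excluded_cause": np.zeros(n, dtype=int)
            if excluded is None
            else np.asarray(excluded, dtype=int),
        }
    )
    for name, vals in markers.items():
        df[name] = np.asarray(vals, dtype=float)
    covs = []
    if covariates:
        for name, vals in covariates.items():
            df[name] = vals
            covs.append(name)
    return ba.Cohort(df, list(markers), covs)


def bare_gompertz_fit(k, beta, coef=None, alpha=None) -> ba.GompertzFit:
    """A GompertzFit carrying only parameters, for evaluation helpers."""
    return ba.GompertzFit(
        k=k,
        beta=beta,
        alpha=beta if alpha is None else alpha,
        coef=coef or {},
        se={},
        conf_int={},
        loglik=0.0,
        n_params=2 + len(coef or {}),
        aic=0.0,
        bic=0.0,
        n=1,
        events=1,
        constrained=alpha is None,
        converged=True,
    )
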