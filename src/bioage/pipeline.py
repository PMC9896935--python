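"""End-to-end orchestration: filter -> SEM -> BA estimation -> hazard
models -> evaluation, with a reproducible artifact bundle."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, ColumnConfig, apply_eligibility_filters, read_cohort, write_cohort
from .estimators import estimate_kd, estimate_mlr, estimate_pca, kd_calibrate
from .evaluation import disparity_regression, e65_delta_curve, roc_auc, roc_inputs_at_horizon
from .gompertz import fit_gompertz
from .sem import SemSpec, factor_scores, fit_sem, sem_fit_to_dict
from .sem_estimators import estimate_od, estimate_of
from .simulate import SyntheticTruth, simulate_cohort

log = logging.getLogger("bioage")

ALL_METHODS = ("mlr", "pca", "kd", "of", "od")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    outdir: str
    input_path: str | None = None
    column_config: ColumnConfig | None = None
    truth: SyntheticTruth | None = None
    seed: int | None = None
    methods: tuple[str, ...] = ALL_METHODS
    sem_forms: tuple[str, ...] = ("linear", "loglinear")
    age_min: float = 30.0
    age_max: float = 75.0
    excluded_cause_action: str = "censor"
    roc_horizon: float = 20.0
    delta_grid: tuple[float, ...] = tuple(np.linspace(-5.0, 5.0, 21))

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method is required")
        bad = set(self.methods) - set(ALL_METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if self.input_path is None and self.truth is None:
            raise ValueError("provide an input file or simulation truth")
        if self.truth is not None and self.seed is not None:
            self.truth = dataclasses.replace(self.truth, seed=self.seed)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the artifact bundle.

    Returns a dict of in-memory artifacts; the same config and seed
    produce an identical bundle.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.truth is not None:
        cohort, _latent = _stage("simulate")(simulate_cohort)(config.truth)
        write_cohort(cohort, outdir / "cohort.csv")
        config.truth.to_json(outdir / "truth.json")
    else:
        cohort = _stage("read")(read_cohort)(config.input_path, config.column_config)

    cohort, report = _stage("filter")(apply_eligibility_filters)(
        cohort, config.age_min, config.age_max, config.excluded_cause_action
    )
    cohort.assert_analysis_ready()
    report.to_frame().to_csv(outdir / "filter_report.csv", index=False)

    estimates = []
    sem_fits = {}
    scores = {}
    hazard_fits = {}

    if "mlr" in config.methods:
        estimates.append(_stage("mlr")(estimate_mlr)(cohort))
    if "pca" in config.methods:
        estimates.append(_stage("pca")(estimate_pca)(cohort))
    if "kd" in config.methods:
        cal = kd_calibrate(cohort)
        estimates.append(_stage("kd")(estimate_kd)(cohort, cal))

    need_sem = {"of", "od"} & set(config.methods)
    if need_sem:
        for form in config.sem_forms:
            fit = _stage(f"sem-{form}")(fit_sem)(cohort, SemSpec(list(cohort.markers), form))
            sem_fits[form] = fit
            scores[form] = factor_scores(fit, cohort)
            with open(outdir / f"sem_{form}.json", "w") as fh:
                json.dump(sem_fit_to_dict(fit), fh, indent=2)

    if "of" in config.methods:
        for form in config.sem_forms:
            ba, _cal = _stage(f"of-{form}")(estimate_of)(scores[form], cohort, form)
            estimates.append(ba)

    if "od" in config.methods:
        null_fit = _stage("hazard-null")(fit_gompertz)(cohort)
        hazard_fits["null"] = null_fit
        for form in config.sem_forms:
            aug = _stage(f"hazard-aug-{form}")(fit_gompertz)(
                cohort, {"fs": scores[form].scores}
            )
            hazard_fits[f"augmented-{form}"] = aug
            estimates.append(estimate_od(scores[form], cohort, null_fit, aug))

    ba_frame = pd.concat([e.to_frame() for e in estimates], ignore_index=True)
    ba_frame.to_csv(outdir / "ba_estimates.csv", index=False)

    # delta-BA hazard models + evaluation per method
    e65_rows, auc_rows = [], []
    for est in estimates:
        fit = _stage(f"hazard-delta-{est.method}")(fit_gompertz)(
            cohort, {"delta_ba": est.delta}
        )
        hazard_fits[f"delta-{est.method}"] = fit
        curve = e65_delta_curve(fit, config.delta_grid, phi_name="delta_ba")
        curve.insert(0, "method", est.method)
        e65_rows.append(curve)
        sc, labels = roc_inputs_at_horizon(
            cohort, fit, config.roc_horizon, {"delta_ba": est.delta}
        )
        for band in ((0.8, 0.9), (0.9, 1.0), (0.0, 1.0)):
            auc_rows.append(
                {
                    "method": est.method,
                    "spec_lo": band[0],
                    "spec_hi": band[1],
                    "auc": roc_auc(sc, labels, band),
                }
            )
    pd.concat(e65_rows, ignore_index=True).to_csv(outdir / "e65_curves.csv", index=False)
    pd.DataFrame(auc_rows).to_csv(outdir / "auc_by_band.csv", index=False)

    disparity = None
    if set(cohort.covariates) >= {"sex", "race", "education"}:
        disparity = _stage("disparity")(disparity_regression)(estimates, cohort)
        disparity.to_csv(outdir / "disparity_table.csv")

    for name, fit in hazard_fits.items():
        fit.to_json(outdir / f"hazard_{name}.json")

    manifest = {
        "bioage_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed if config.seed is not None else (
            config.truth.seed if config.truth else None
        ),
        "methods": list(config.methods),
        "sem_forms": list(config.sem_forms),
        "age_window": [config.age_min, config.age_max],
        "excluded_cause_action": config.excluded_cause_action,
        "n_analysis": cohort.n,
        "filter_report": {
            k: int(v) for k, v in dataclasses.asdict(report).items()
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "cohort": cohort,
        "filter_report": report,
        "estimates": estimates,
        "sem_fits": sem_fits,
        "hazard_fits": hazard_fits,
        "ba_frame": ba_frame,
        "disparity": disparity,
        "manifest": manifest,
    }
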