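"""Cohort container, file readers/writers and eligibility filtering.

A :class:`Cohort` holds one row per subject: chronological age at baseline
(years), a panel of J biomarkers, follow-up duration (years), a death
indicator, an optional flag for deaths from causes unrelated to aging
(HIV, violence, accidents), and categorical covariates (sex,
race/ethnicity, education).  Internally everything lives in a single
pandas DataFrame with canonical column names; :class:`ColumnConfig` maps
arbitrary file columns onto those roles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Cohort",
    "ColumnConfig",
    "FilterReport",
    "CohortError",
    "ColumnConfigError",
    "CohortParseError",
    "EmptyCohortError",
    "read_cohort",
    "write_cohort",
    "apply_eligibility_filters",
]

#: canonical column names used inside the package
AGE, DURATION, DEAD, EXCLUDED, SUBJECT = (
    "age",
    "duration",
    "dead",
    "excluded_cause",
    "subject_id",
)


class CohortError(ValueError):
    """Base class for cohort construction/validation problems."""


class ColumnConfigError(CohortError):
    """A logical role maps to a column that is absent or duplicated."""


class CohortParseError(CohortError):
    """Numeric cells could not be parsed; carries the offending row indices."""

    def __init__(self, column: str, rows: list[int]):
        self.column = column
        self.rows = rows
        super().__init__(
            f"column {column!r}: unparseable numeric value in rows {rows[:20]}"
            + (" ..." if len(rows) > 20 else "")
        )


class EmptyCohortError(CohortError):
    """No subjects remain after filtering; downstream fits are impossible."""


@dataclass
class ColumnConfig:
    """Mapping from logical roles to file column names.

    Parameters
    ----------
    age, duration, event
        Column names for baseline chronological age (years), follow-up
        duration (years) and the binary death indicator.
    markers
        Non-empty list of biomarker column names (kept as canonical marker
        names inside the package).
    cause_flag
        Optional column flagging deaths from HIV/violence/accidents.
    subject_id
        Optional subject label column; a running index is used if absent.
    covariates
        Mapping canonical covariate name (e.g. ``"sex"``) -> file column.
    log_markers
        Markers to log-transform on read (natural log).
    """

    age: str
    duration: str
    event: str
    markers: list[str]
    cause_flag: str | None = None
    subject_id: str | None = None
    covariates: dict[str, str] = field(default_factory=dict)
    log_markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ColumnConfigError("marker list must be non-empty")
        roles = [self.age, self.duration, self.event, *self.markers]
        roles += [c for c in (self.cause_flag, self.subject_id) if c]
        roles += list(self.covariates.values())
        dupes = {c for c in roles if roles.count(c) > 1}
        if dupes:
            raise ColumnConfigError(f"columns mapped to more than one role: {sorted(dupes)}")
        unknown = set(self.log_markers) - set(self.markers)
        if unknown:
            raise ColumnConfigError(f"log_markers not in marker list: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class Cohort:
    """One row per subject with canonical columns.

    ``data`` always carries ``subject_id, age, duration, dead,
    excluded_cause``, one column per marker and one per covariate.
    """

    data: pd.DataFrame
    markers: list[str]
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = [SUBJECT, AGE, DURATION, DEAD, EXCLUDED]
        missing = [c for c in required + self.markers + self.covariates if c not in self.data.columns]
        if missing:
            raise CohortError(f"cohort frame is missing columns: {missing}")
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def age(self) -> np.ndarray:
        return self.data[AGE].to_numpy(dtype=float)

    @property
    def duration(self) -> np.ndarray:
        return self.data[DURATION].to_numpy(dtype=float)

    @property
    def dead(self) -> np.ndarray:
        return self.data[DEAD].to_numpy(dtype=int)

    @property
    def excluded_cause(self) -> np.ndarray:
        return self.data[EXCLUDED].to_numpy(dtype=int)

    @property
    def subject_id(self) -> pd.Series:
        return self.data[SUBJECT]

    @property
    def marker_frame(self) -> pd.DataFrame:
        return self.data[self.markers]

    @property
    def marker_matrix(self) -> np.ndarray:
        return self.marker_frame.to_numpy(dtype=float)

    # -- checks ------------------------------------------------------------
    def validate(self) -> None:
        dur = self.data[DURATION]
        if (dur.dropna() < 0).any():
            raise CohortError("duration must be >= 0 for every subject")
        ev = self.data[DEAD].dropna()
        if not ev.isin([0, 1]).all():
            raise CohortError("dead indicator must be 0/1")
        exc = self.data[EXCLUDED].dropna()
        if not exc.isin([0, 1]).all():
            raise CohortError("excluded_cause flag must be 0/1")

    def assert_analysis_ready(self) -> None:
        """Invariants expected after eligibility filtering."""
        if self.data[[AGE, *self.markers]].isna().any().any():
            raise CohortError("analysis view contains missing age/marker values")
        var = self.marker_frame.var(ddof=0)
        flat = var[var <= 0].index.tolist()
        if flat:
            raise CohortError(f"markers with zero variance in analysis view: {flat}")

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.data.loc[mask].reset_index(drop=True), list(self.markers), list(self.covariates))


@dataclass
class FilterReport:
    """Per-rule accounting of the eligibility filter."""

    n_in: int
    n_out: int
    dropped_age: int = 0
    dropped_incomplete: int = 0
    dropped_excluded_cause: int = 0
    recoded_censored: int = 0

    def __post_init__(self) -> None:
        drops = self.dropped_age + self.dropped_incomplete + self.dropped_excluded_cause
        if drops != self.n_in - self.n_out:
            raise CohortError(
                f"filter accounting broken: drops {drops} != n_in-n_out {self.n_in - self.n_out}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "input",
                    "age window",
                    "incomplete age/markers",
                    "excluded-cause death (dropped)",
                    "excluded-cause death (recoded censored)",
                    "output",
                ],
                "count": [
                    self.n_in,
                    self.dropped_age,
                    self.dropped_incomplete,
                    self.dropped_excluded_cause,
                    self.recoded_censored,
                    self.n_out,
                ],
            }
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_frame().to_string(index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix == ".dta":
        return pd.read_stata(path)
    if suffix in {".tsv", ".tab"}:
        return pd.read_csv(path, sep="\t")
    if suffix == ".csv":
        return pd.read_csv(path)
    return pd.read_csv(path, sep=None, engine="python")


def _coerce_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    raw = df[column]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        raise CohortParseError(column, list(np.flatnonzero(bad.to_numpy())))
    return out


def read_cohort(path: str | Path, config: ColumnConfig) -> Cohort:
    """Read a delimited text or Stata DTA file into a :class:`Cohort`.

    Rows are preserved in file order and no filtering is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_table(path)

    mapped = {"age": config.age, "duration": config.duration, "event": config.event}
    for m in config.markers:
        mapped[f"marker {m!r}"] = m
    if config.cause_flag:
        mapped["cause_flag"] = config.cause_flag
    if config.subject_id:
        mapped["subject_id"] = config.subject_id
    for role, col in config.covariates.items():
        mapped[f"covariate {role!r}"] = col
    missing = {role: col for role, col in mapped.items() if col not in raw.columns}
    if missing:
        raise ColumnConfigError(
            "mapped columns absent from file: "
            + ", ".join(f"{role} -> {col!r}" for role, col in missing.items())
        )

    out = pd.DataFrame()
    out[SUBJECT] = (
        raw[config.subject_id].astype(str)
        if config.subject_id
        else pd.Series(np.arange(len(raw)).astype(str))
    )
    out[AGE] = _coerce_numeric(raw, config.age)
    out[DURATION] = _coerce_numeric(raw, config.duration)
    out[DEAD] = _coerce_numeric(raw, config.event)
    out[EXCLUDED] = _coerce_numeric(raw, config.cause_flag) if config.cause_flag else 0
    for m in config.markers:
        col = _coerce_numeric(raw, m)
        out[m] = np.log(col) if m in config.log_markers else col
    covs = []
    for role, col in config.covariates.items():
        out[role] = raw[col].astype(str)
        covs.append(role)
    return Cohort(out, list(config.markers), covs)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the canonical frame as delimited text (full float precision)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    cohort.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Eligibility filters
# ---------------------------------------------------------------------------

def apply_eligibility_filters(
    cohort: Cohort,
    age_min: float = 30.0,
    age_max: float = 75.0,
    excluded_cause_action: str = "censor",
) -> tuple[Cohort, FilterReport]:
    """Apply the analytic-sample rules: age window, complete cases, and
    handling of deaths from causes unrelated to aging.

    Subjects outside ``[age_min, age_max]`` are dropped; subjects with any
    missing age or marker value are dropped; deaths flagged as
    HIV/violence/accident are, by default, recoded as censored at their
    observed duration (``excluded_cause_action="censor"``) or dropped
    (``"drop"``).
    """
    if not np.isfinite(age_min) or not np.isfinite(age_max) or age_min >= age_max:
        raise ValueError("age bounds must be finite with age_min < age_max")
    if excluded_cause_action not in {"censor", "drop"}:
        raise ValueError("excluded_cause_action must be 'censor' or 'drop'")

    df = cohort.data
    incomplete = df[[AGE, *cohort.markers]].isna().any(axis=1).to_numpy()
    age = df[AGE].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out_of_window = (~incomplete) & ((age < age_min) | (age > age_max))
    keep = ~(incomplete | out_of_window)

    dropped_excluded = 0
    recoded = 0
    kept = df.loc[keep].copy()
    is_excluded_death = (kept[DEAD] == 1) & (kept[EXCLUDED] == 1)
    if excluded_cause_action == "drop":
        dropped_excluded = int(is_excluded_death.sum())
        kept = kept.loc[~is_excluded_death]
    else:
        recoded = int(is_excluded_death.sum())
        kept.loc[is_excluded_death, DEAD] = 0

    report = FilterReport(
        n_in=len(df),
        n_out=len(kept),
        dropped_age=int(out_of_window.sum()),
        dropped_incomplete=int(incomplete.sum()),
        dropped_excluded_cause=dropped_excluded,
        recoded_censored=recoded,
    )
    if len(kept) == 0:
        raise EmptyCohortError("no subjects remain after eligibility filtering")
    out = Cohort(kept.reset_index(drop=True), list(cohort.markers), list(cohort.covariates))
    return out, report
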