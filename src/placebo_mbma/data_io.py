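"""Trial-level dataset model and CSV input/output.

The analysis operates on aggregate (arm-level) longitudinal data: one record
per placebo arm per follow-up visit, carrying the mean change from baseline in
ESSDAI score, the number of subjects contributing at that visit, and a set of
trial-level covariates.  The on-disk format is a long CSV with one row per
(trial, time) pair; covariate columns repeat their trial-level value on every
row of that trial.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CSV_COLUMNS",
    "COVARIATE_NAMES",
    "OPTIONAL_COVARIATES",
    "FRACTION_COVARIATES",
    "DataFormatError",
    "DataValidationError",
    "ObservationRecord",
    "TrialCovariates",
    "Trial",
    "MetaDataset",
    "CovariatePreparation",
    "read_dataset",
    "write_dataset",
    "prepare_covariates",
]

#: Canonical column order of the long CSV format.
CSV_COLUMNS = [
    "trial_id",
    "time_weeks",
    "change_essdai",
    "n_subjects",
    "baseline_essdai",
    "age_years",
    "male_pct",
    "duration_weeks",
    "diagnosis_years",
    "base_therapy_pct",
]

#: Trial-level covariate fields, in canonical order.
COVARIATE_NAMES = [
    "baseline_essdai",
    "age_years",
    "male_pct",
    "duration_weeks",
    "diagnosis_years",
    "base_therapy_pct",
]

#: Covariates that may be missing.  Baseline ESSDAI is mandatory (it is both
#: the retained covariate of the final model and the simulation input), and
#: treatment duration is a design quantity every report states.
OPTIONAL_COVARIATES = ["age_years", "male_pct", "diagnosis_years", "base_therapy_pct"]

#: Percentage-type covariates; these are centred at 0 in covariate models
#: rather than at their corpus median.
FRACTION_COVARIATES = {"male_pct", "base_therapy_pct"}


class DataFormatError(ValueError):
    """Raised when a file does not conform to the long CSV contract."""


class DataValidationError(ValueError):
    """Raised when parsed data violate a dataset invariant."""


@dataclass(frozen=True)
class ObservationRecord:
    """One arm-level observation: mean ESSDAI change at a follow-up visit.

    ``change_essdai`` is the change from baseline (negative = improvement);
    ``n_subjects`` is the sample size contributing at this visit, which scales
    the residual error as 1/sqrt(N).
    """

    time_weeks: float
    change_essdai: float
    n_subjects: int

    def __post_init__(self) -> None:
        if not (self.time_weeks >= 0):
            raise DataValidationError(f"time_weeks must be >= 0, got {self.time_weeks}")
        if not (self.n_subjects >= 1):
            raise DataValidationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not math.isfinite(self.change_essdai):
            raise DataValidationError("change_essdai must be finite")


@dataclass(frozen=True)
class TrialCovariates:
    """Trial-level covariates.  ``None`` marks a missing value."""

    baseline_essdai: float
    duration_weeks: float
    age_years: Optional[float] = None
    male_pct: Optional[float] = None
    diagnosis_years: Optional[float] = None
    base_therapy_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.baseline_essdai > 0):
            raise DataValidationError(
                f"baseline_essdai must be > 0, got {self.baseline_essdai}"
            )
        if not (self.duration_weeks > 0):
            raise DataValidationError(
                f"duration_weeks must be > 0, got {self.duration_weeks}"
            )
        for name in FRACTION_COVARIATES:
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 100.0):
                raise DataValidationError(f"{name} must lie in [0, 100], got {value}")

    def get(self, name: str) -> Optional[float]:
        if name not in COVARIATE_NAMES:
            raise KeyError(f"unknown covariate {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class Trial:
    """One placebo arm: an identifier, covariates, and ordered observations."""

    trial_id: str
    covariates: TrialCovariates
    observations: tuple[ObservationRecord, ...]

    def __post_init__(self) -> None:
        if len(self.observations) == 0:
            raise DataValidationError(f"trial {self.trial_id!r} has no observations")
        times = [o.time_weeks for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DataValidationError(
                f"trial {self.trial_id!r}: observation times must be strictly increasing"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_weeks for o in self.observations], dtype=float)

    @property
    def changes(self) -> np.ndarray:
        return np.array([o.change_essdai for o in self.observations], dtype=float)

    @property
    def n_subjects(self) -> np.ndarray:
        return np.array([o.n_subjects for o in self.observations], dtype=float)


@dataclass(frozen=True)
class MetaDataset:
    """The trial-level longitudinal corpus the model is fitted to."""

    trials: tuple[Trial, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate trial_ids: {dup}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_obs(self) -> int:
        return sum(len(t.observations) for t in self.trials)

    def trial(self, trial_id: str) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    def drop_trial(self, trial_id: str) -> "MetaDataset":
        """Return the dataset without the named trial (used by the jackknife)."""
        kept = tuple(t for t in self.trials if t.trial_id != trial_id)
        if len(kept) == len(self.trials):
            raise KeyError(trial_id)
        return MetaDataset(kept, provenance=self.provenance)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view, one row per (trial, time), canonical columns."""
        rows = []
        for t in self.trials:
            for o in t.observations:
                row = {
                    "trial_id": t.trial_id,
                    "time_weeks": o.time_weeks,
                    "change_essdai": o.change_essdai,
                    "n_subjects": o.n_subjects,
                }
                for name in COVARIATE_NAMES:
                    row[name] = t.covariates.get(name)
                rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    raw = df[column]
    parsed = pd.to_numeric(raw, errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise DataFormatError(
            f"non-numeric value {raw[bad.idxmax()]!r} in column {column!r} (line {row})"
        )
    return parsed


def _trial_covariates(group: pd.DataFrame, trial_id: str) -> TrialCovariates:
    values: dict[str, Optional[float]] = {}
    for name in COVARIATE_NAMES:
        col = group[name].dropna()
        values[name] = float(col.iloc[0]) if len(col) else None
    for name in ("baseline_essdai", "duration_weeks"):
        if values[name] is None:
            raise DataValidationError(f"trial {trial_id!r}: {name} is mandatory")
    return TrialCovariates(**values)  # type: ignore[arg-type]


def read_dataset(path: str | Path) -> MetaDataset:
    """Read and validate a long-format CSV into a :class:`MetaDataset`.

    Rows are grouped by ``trial_id`` (order of first appearance preserved) and
    sorted by time within each trial.  A missing per-visit ``n_subjects`` is
    carried forward from the previous visit of the same trial (attrition is
    rarely reported per visit in the source publications).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"trial_id": str}, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing mandatory column(s): {', '.join(missing)}")
    for column in CSV_COLUMNS[1:]:
        df[column] = _parse_numeric(df, column)

    dup = df.duplicated(subset=["trial_id", "time_weeks"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["trial_id", "time_weeks"]].iloc[0]
        raise DataValidationError(
            f"duplicate (trial_id, time) row: ({pair['trial_id']!r}, {pair['time_weeks']})"
        )

    trials = []
    for trial_id in df["trial_id"].drop_duplicates():
        group = df[df["trial_id"] == trial_id].sort_values("time_weeks")
        cov = _trial_covariates(group, trial_id)
        n_prev: Optional[float] = None
        observations = []
        for _, row in group.iterrows():
            n = row["n_subjects"]
            if pd.isna(n):
                if n_prev is None:
                    raise DataValidationError(
                        f"trial {trial_id!r}: n_subjects missing at the first visit"
                    )
                n = n_prev  # last observation carried forward
            n_prev = n
            if pd.isna(row["change_essdai"]) or pd.isna(row["time_weeks"]):
                raise DataValidationError(
                    f"trial {trial_id!r}: time_weeks and change_essdai are mandatory"
                )
            observations.append(
                ObservationRecord(
                    time_weeks=float(row["time_weeks"]),
                    change_essdai=float(row["change_essdai"]),
                    n_subjects=int(round(n)),
                )
            )
        trials.append(Trial(trial_id, cov, tuple(observations)))
    return MetaDataset(tuple(trials), provenance=f"read from {path.name}")


def write_dataset(ds: MetaDataset, path: str | Path) -> Path:
    """Write ``ds`` as a long CSV that :func:`read_dataset` inverts exactly.

    Missing covariates become empty cells; floats are written with full
    precision so the round-trip is the identity.
    """
    path = Path(path)
    df = ds.to_frame().copy()
    for column in df.columns:
        if column in ("trial_id", "n_subjects"):
            continue
        # shortest round-trip decimal representation, lossless on re-read
        df[column] = df[column].map(
            lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v))
            else repr(float(v))
        )
    df.to_csv(path, index=False)
    return path


@dataclass
class CovariatePreparation:
    """Report of the covariate missingness screen and median imputation."""

    dropped: dict[str, float] = field(default_factory=dict)  # name -> missing fraction
    imputed: dict[str, tuple[float, tuple[str, ...]]] = field(default_factory=dict)
    usable: tuple[str, ...] = ()

    @property
    def actions(self) -> list[str]:
        out = [
            f"dropped {name} (missing in {frac:.0%} of trials)"
            for name, frac in self.dropped.items()
        ]
        out += [
            f"imputed {name} = {median:g} (median) in trials {', '.join(ids)}"
            for name, (median, ids) in self.imputed.items()
        ]
        return out


def prepare_covariates(
    ds: MetaDataset, max_missing_fraction: float = 0.4
) -> tuple[MetaDataset, CovariatePreparation]:
    """Apply the covariate missingness rules ahead of covariate modelling.

    A covariate missing in at least ``max_missing_fraction`` of trials
    (default 40%, inclusive) is flagged unusable and left untouched; remaining
    missing values are imputed with the across-trial median of that covariate.
    Observation records are never altered.  The operation is idempotent.
    """
    report = CovariatePreparation()
    n = ds.n_trials
    usable: list[str] = ["baseline_essdai", "duration_weeks"]
    medians: dict[str, float] = {}
    for name in OPTIONAL_COVARIATES:
        values = [t.covariates.get(name) for t in ds.trials]
        missing = [v is None for v in values]
        frac = sum(missing) / n
        if frac >= max_missing_fraction:
            if any(missing):
                report.dropped[name] = frac
            else:
                usable.append(name)
            continue
        usable.append(name)
        if any(missing):
            medians[name] = float(np.median([v for v in values if v is not None]))
            report.imputed[name] = (
                medians[name],
                tuple(t.trial_id for t, m in zip(ds.trials, missing) if m),
            )
    report.usable = tuple(usable)

    if not medians:
        return ds, report
    trials = []
    for t in ds.trials:
        fills = {
            name: median
            for name, median in medians.items()
            if t.covariates.get(name) is None
        }
        cov = replace(t.covariates, **fills) if fills else t.covariates
        trials.append(Trial(t.trial_id, cov, t.observations))
    return MetaDataset(tuple(trials), provenance=ds.provenance), report
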