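"""Domain types, validation and delimited-text I/O for joint datasets.

A joint dataset ties together three tables keyed by subject id:

* long-format longitudinal biomarker measurements ``(subject_id, t, y)``,
  with ``t`` in days since randomization;
* one survival record per subject ``(subject_id, time, delta)`` where
  ``delta`` is 0 for non-informative censoring, 1 for failure cause 1
  (e.g. death in the ICU) and 2 for cause 2 (e.g. live discharge);
* one row of baseline covariates per subject, the first column being the
  treatment indicator.

Files are comma-delimited with a header row; times are floats in days.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "JointDataError",
    "LinkageError",
    "ValidationError",
    "SpecificationError",
    "LongitudinalObservation",
    "SurvivalRecord",
    "CovariateRow",
    "JointDataset",
    "ModelSpec",
    "DesignMatrices",
    "load_joint_dataset",
    "write_joint_dataset",
    "build_design",
]

LONG_COLUMNS = ("subject_id", "t", "y")
SURV_COLUMNS = ("subject_id", "time", "delta")


class JointDataError(ValueError):
    """Base class for joint-dataset errors."""


class LinkageError(JointDataError):
    """A subject appears in one table but is missing from another."""


class ValidationError(JointDataError):
    """A table violates a dataset invariant."""


class SpecificationError(JointDataError):
    """A model specification references unknown covariates or options."""


@dataclass(frozen=True)
class LongitudinalObservation:
    """One biomarker measurement: subject, visit time (days), value."""

    subject_id: int | str
    t: float
    y: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t < 0:
            raise ValidationError(f"observation time must be >= 0, got {self.t}")
        if not np.isfinite(self.y):
            raise ValidationError(f"biomarker value must be finite, got {self.y}")


@dataclass(frozen=True)
class SurvivalRecord:
    """Observed time min(T, C) in days and event cause (0 = censored)."""

    subject_id: int | str
    time: float
    delta: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValidationError(f"survival time must be > 0, got {self.time}")
        if self.delta not in (0, 1, 2):
            raise ValidationError(f"delta must be in {{0,1,2}}, got {self.delta}")


@dataclass(frozen=True)
class CovariateRow:
    """Baseline covariate vector; the first entry is the treatment arm."""

    subject_id: int | str
    z: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not np.isfinite(v) for v in self.z):
            raise ValidationError("covariates must have no missing entries")


@dataclass
class JointDataset:
    """Aligned longitudinal + survival + covariate tables.

    ``observations`` has columns ``(subject_id, t, y)``; ``survival`` has
    ``(subject_id, time, delta)`` with one row per subject; ``covariates``
    has ``subject_id`` plus one column per baseline covariate.  Subjects are
    ordered deterministically by id, and every longitudinal record must fall
    at or before its subject's observed survival time (measurement stops at
    dropout; a tied day-of-event measurement is allowed).
    """

    observations: pd.DataFrame
    survival: pd.DataFrame
    covariates: pd.DataFrame
    horizon: float = 28.0

    def __post_init__(self) -> None:
        self.observations = (
            pd.DataFrame(self.observations)
            .loc[:, list(LONG_COLUMNS)]
            .sort_values(["subject_id", "t"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.survival = (
            pd.DataFrame(self.survival)
            .loc[:, list(SURV_COLUMNS)]
            .sort_values("subject_id", kind="mergesort")
            .reset_index(drop=True)
        )
        cov = pd.DataFrame(self.covariates)
        if cov.columns[0] != "subject_id":
            raise ValidationError("covariate table must start with subject_id")
        self.covariates = cov.sort_values("subject_id", kind="mergesort").reset_index(
            drop=True
        )
        self.observations["t"] = self.observations["t"].astype(float)
        self.observations["y"] = self.observations["y"].astype(float)
        self.survival["time"] = self.survival["time"].astype(float)
        self.survival["delta"] = self.survival["delta"].astype(int)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        surv_ids = self.survival["subject_id"]
        if surv_ids.duplicated().any():
            dup = surv_ids[surv_ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate survival record for subject {dup!r}")
        cov_ids = self.covariates["subject_id"]
        if cov_ids.duplicated().any():
            dup = cov_ids[cov_ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate covariate row for subject {dup!r}")
        surv_set, cov_set = set(surv_ids), set(cov_ids)
        for sid in self.observations["subject_id"].unique():
            if sid not in surv_set:
                raise LinkageError(f"subject {sid!r} has observations but no survival record")
        for sid in surv_set ^ cov_set:
            raise LinkageError(f"subject {sid!r} missing from survival or covariate table")

        bad = (self.survival["time"] <= 0) | ~np.isfinite(self.survival["time"])
        if bad.any():
            sid = self.survival.loc[bad, "subject_id"].iloc[0]
            raise ValidationError(f"non-positive survival time for subject {sid!r}")
        if not self.survival["delta"].isin([0, 1, 2]).all():
            bad = ~self.survival["delta"].isin([0, 1, 2])
            raise ValidationError(
                f"delta outside {{0,1,2}} for subject "
                f"{self.survival.loc[bad, 'subject_id'].iloc[0]!r}"
            )
        if (self.observations["t"] < 0).any() or not np.isfinite(
            self.observations[["t", "y"]].to_numpy()
        ).all():
            raise ValidationError("longitudinal records must have t >= 0 and finite y")

        tmax = self.observations.merge(self.survival, on="subject_id")
        late = tmax["t"] > tmax["time"] + 1e-9
        if late.any():
            row = tmax.loc[late].iloc[0]
            raise ValidationError(
                f"subject {row['subject_id']!r} has an observation at t={row['t']} "
                f"after its survival time {row['time']}"
            )
        if self.covariates.iloc[:, 1:].isna().any().any():
            raise ValidationError("covariates must have no missing entries")
        if self.horizon < self.survival["time"].max():
            raise ValidationError("horizon must cover the largest observed time")

    # -- convenience -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.survival)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.survival["subject_id"].to_numpy()

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates.columns[1:])

    def __eq__(self, other: object) -> bool:  # round-trip equality
        if not isinstance(other, JointDataset):
            return NotImplemented
        return (
            self.horizon == other.horizon
            and self.observations.equals(other.observations)
            and self.survival.equals(other.survival)
            and self.covariates.equals(other.covariates)
        )


def load_joint_dataset(
    long_path: str | Path,
    surv_path: str | Path,
    cov_path: str | Path,
    horizon: float = 28.0,
) -> JointDataset:
    """Read the three delimited files and return a validated dataset."""
    # round_trip parsing: the default fast parser loses the last ulp
    obs = pd.read_csv(long_path, float_precision="round_trip")
    surv = pd.read_csv(surv_path, float_precision="round_trip")
    cov = pd.read_csv(cov_path, float_precision="round_trip")
    for frame, cols, path in ((obs, LONG_COLUMNS, long_path), (surv, SURV_COLUMNS, surv_path)):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return JointDataset(obs, surv, cov, horizon=horizon)


def write_joint_dataset(
    dataset: JointDataset,
    long_path: str | Path,
    surv_path: str | Path,
    cov_path: str | Path,
) -> None:
    """Write the three delimited files (full float precision, round-trip safe)."""
    dataset.observations.to_csv(long_path, index=False)
    dataset.survival.to_csv(surv_path, index=False)
    dataset.covariates.to_csv(cov_path, index=False)


# ---------------------------------------------------------------------------
# Model specification and design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter each submodel, and structural switches.

    Longitudinal fixed effects are always ``[intercept, t, treatment,
    treatment x t]`` followed by ``longitudinal_covariates`` (baseline, time
    constant).  ``survival_covariates`` (default: all covariate columns)
    enter each cause's linear predictor.

    ``re_structure`` selects the latent process W1(t) of the mixed model:
    ``"intercept_slope"`` for W1 = U0 + U1 t or ``"slope_only"`` for
    W1 = U1 t.  ``survival_link`` selects which part of W1 is scaled by
    gamma^(k) in the hazards: ``"intercept_slope"``, ``"slope_only"`` or
    ``"intercept"`` (U0 only).  ``submodel_kind`` chooses subdistribution
    (Fine-Gray-type) or cause-specific hazards; ``"none"`` drops the
    survival component entirely (separate longitudinal fit).
    """

    longitudinal_covariates: tuple[str, ...] = ()
    survival_covariates: tuple[str, ...] | None = None
    re_structure: str = "intercept_slope"
    survival_link: str = "intercept_slope"
    submodel_kind: str = "subdistribution"
    n_baseline_intervals: int = 10

    def __post_init__(self) -> None:
        if self.re_structure not in ("intercept_slope", "slope_only"):
            raise SpecificationError(f"unknown re_structure {self.re_structure!r}")
        if self.survival_link not in ("intercept_slope", "slope_only", "intercept"):
            raise SpecificationError(f"unknown survival_link {self.survival_link!r}")
        if self.submodel_kind not in ("subdistribution", "cause_specific", "none"):
            raise SpecificationError(f"unknown submodel_kind {self.submodel_kind!r}")


@dataclass
class DesignMatrices:
    """Per-observation longitudinal design and per-subject survival design.

    ``long_X`` has one row per longitudinal record with columns
    ``long_columns``; ``surv_Z`` has one row per subject (order matching
    ``JointDataset.subject_ids``) with columns ``surv_columns``.
    ``subject_index`` maps each longitudinal row to its subject's position.
    """

    long_X: np.ndarray
    long_columns: tuple[str, ...]
    long_t: np.ndarray
    long_y: np.ndarray
    subject_index: np.ndarray
    surv_Z: np.ndarray
    surv_columns: tuple[str, ...]


def build_design(dataset: JointDataset, spec: ModelSpec) -> DesignMatrices:
    """Assemble design matrices in the documented, stable column order.

    Longitudinal row for a record at time ``t`` of a subject with treatment
    ``X`` and extra covariates ``z2..``: ``[1, t, X, X*t, z2, ...]``.
    Survival row: ``[treatment, z2...]`` restricted to
    ``spec.survival_covariates``.
    """
    cov_names = dataset.covariate_names
    if not cov_names:
        raise SpecificationError("covariate table has no covariate columns")
    treat = cov_names[0]
    for name in spec.longitudinal_covariates:
        if name not in cov_names:
            raise SpecificationError(f"unknown longitudinal covariate {name!r}")
    surv_names = spec.survival_covariates if spec.survival_covariates is not None else cov_names
    for name in surv_names:
        if name not in cov_names:
            raise SpecificationError(f"unknown survival covariate {name!r}")

    ids = dataset.subject_ids
    pos = {sid: i for i, sid in enumerate(ids)}
    cov = dataset.covariates.set_index("subject_id")

    obs = dataset.observations
    subject_index = obs["subject_id"].map(pos).to_numpy(dtype=np.intp)
    t = obs["t"].to_numpy(dtype=float)
    x_treat = cov[treat].to_numpy(dtype=float)[subject_index]
    cols = [np.ones_like(t), t, x_treat, x_treat * t]
    names = ["intercept", "t", treat, f"{treat}:t"]
    for name in spec.longitudinal_covariates:
        if name == treat:
            continue
        cols.append(cov[name].to_numpy(dtype=float)[subject_index])
        names.append(name)
    long_X = np.column_stack(cols) if len(t) else np.empty((0, len(names)))

    surv_Z = cov.loc[ids, list(surv_names)].to_numpy(dtype=float)
    return DesignMatrices(
        long_X=long_X,
        long_columns=tuple(names),
        long_t=t,
        long_y=obs["y"].to_numpy(dtype=float),
        subject_index=subject_index,
        surv_Z=surv_Z,
        surv_columns=tuple(surv_names),
    )
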