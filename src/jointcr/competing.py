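"""Competing-risks survival submodel with a shared-random-effect link.

Two mutually exclusive failure causes (K = 2 hard-wired).  For cause k the
hazard is

    lambda_k(t | Z, U) = lambda_0k(t) * exp(Z' beta_k + gamma_k * W1(t))

with a piecewise-constant baseline ``lambda_0k`` and the latent process
``W1(t)`` of the longitudinal submodel scaled by the association parameter
``gamma_k``.  Under the subdistribution (Fine-Gray-type) kind this is the
hazard attached to the crude cumulative incidence function: subjects who
fail from the OTHER cause remain in the cause-k risk set from their failure
time up to the administrative horizon.  Under the cause-specific kind a
subject leaves every risk set at its observed time.

Because the baseline is piecewise constant and W1 is linear in t, every
cumulative-hazard integral has the closed form

    lambda_0k * exp(Z' beta_k + gamma_k U0) * (e^{c b} - e^{c a}) / c,

with c = gamma_k U1 and the limit lambda_0k * exp(.) * (b - a) as c -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DesignMatrices, JointDataset, ModelSpec, build_design
from .simulate import RandomEffects

__all__ = [
    "BaselineHazard",
    "SurvivalParams",
    "at_risk",
    "risk_span",
    "cumulative_linked_hazard",
    "survival_loglik",
    "cumulative_incidence",
    "hazard_ratio_summaries",
    "default_baseline_cuts",
    "SurvivalEngine",
]

CAUSES = (1, 2)


def _phi(x: np.ndarray) -> np.ndarray:
    """expm1(x)/x with the x -> 0 limit 1, elementwise and stable."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 + 0.5 * x, np.expm1(safe) / safe)


@dataclass
class BaselineHazard:
    """Piecewise-constant baseline hazards, one set of cuts per cause.

    ``cuts[k]`` are the increasing interval boundaries over [0, horizon]
    for cause k in {1, 2}; intervals are half-open [a, b).  ``heights[k]``
    holds the per-interval positive hazard levels.
    """

    cuts: dict[int, np.ndarray]
    heights: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for k in CAUSES:
            self.cuts[k] = np.asarray(self.cuts[k], dtype=float)
            self.heights[k] = np.asarray(self.heights[k], dtype=float)
            if np.any(np.diff(self.cuts[k]) <= 0):
                raise ValueError(f"cause-{k} cuts must be strictly increasing")
            if len(self.heights[k]) != len(self.cuts[k]) - 1:
                raise ValueError(f"cause-{k} heights/cuts length mismatch")
            if np.any(self.heights[k] <= 0):
                raise ValueError(f"cause-{k} heights must be > 0")

    def interval_index(self, cause: int, t: float | np.ndarray) -> np.ndarray:
        """Index of the half-open interval [a, b) containing t.

        An event exactly on a boundary belongs to the interval starting
        there; t at or beyond the last cut raises a coverage error.
        """
        cuts = self.cuts[cause]
        t = np.asarray(t, dtype=float)
        if np.any(t < cuts[0]) or np.any(t >= cuts[-1]):
            raise ValueError(
                f"time outside cause-{cause} baseline support "
                f"[{cuts[0]}, {cuts[-1]})"
            )
        return np.searchsorted(cuts, t, side="right") - 1

    def value_at(self, cause: int, t: float) -> float:
        return float(self.heights[cause][self.interval_index(cause, t)])


def default_baseline_cuts(
    dataset: JointDataset, n_intervals: int = 10
) -> dict[int, np.ndarray]:
    """Per-cause cuts at event-time quantiles, covering [0, horizon].

    Interior cuts sit at quantiles of that cause's event times so each
    interval carries a comparable number of events; degenerate (duplicate)
    quantiles are dropped.  With no events for a cause a single interval
    [0, horizon] is used.
    """
    surv = dataset.survival
    end = float(dataset.horizon) * (1 + 1e-9) + 1e-9  # horizon itself stays covered
    cuts: dict[int, np.ndarray] = {}
    for k in CAUSES:
        times = surv.loc[surv["delta"] == k, "time"].to_numpy()
        if len(times) == 0:
            cuts[k] = np.array([0.0, end])
            continue
        qs = np.quantile(times, np.linspace(0, 1, n_intervals + 1)[1:-1])
        interior = np.unique(qs[(qs > 0) & (qs < end)])
        cuts[k] = np.concatenate([[0.0], interior, [end]])
    return cuts


@dataclass
class SurvivalParams:
    """Per-cause covariate effects, association scalars and baseline."""

    beta: dict[int, np.ndarray]
    gamma: dict[int, float]
    baseline: BaselineHazard
    submodel_kind: str = "subdistribution"
    survival_link: str = "intercept_slope"

    def __post_init__(self) -> None:
        for k in CAUSES:
            self.beta[k] = np.asarray(self.beta[k], dtype=float)
            if not np.isfinite(self.gamma[k]):
                raise ValueError("gamma must be finite")
        if self.submodel_kind not in ("subdistribution", "cause_specific"):
            raise ValueError(f"unknown submodel_kind {self.submodel_kind!r}")

    def link_coeffs(self, cause: int) -> tuple[float, float]:
        """(coefficient on U0, coefficient on U1) implied by the link."""
        g = self.gamma[cause]
        if self.survival_link == "intercept":
            return g, 0.0
        if self.survival_link == "slope_only":
            return 0.0, g
        return g, g


def at_risk(
    record,
    t: float,
    cause: int,
    kind: str = "subdistribution",
    horizon: float = 28.0,
) -> bool:
    """Is this subject in the cause-``cause`` risk set at time ``t``?

    Cause-specific: at risk iff ``t < record.time`` (any observed failure
    or censoring removes the subject).  Subdistribution: additionally,
    subjects who failed from the OTHER cause remain at risk from their
    failure time up to the administrative horizon — the Fine-Gray risk-set
    extension that ties the hazard to the crude cumulative incidence.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t < record.time:
        return True
    if kind == "subdistribution":
        other = 3 - cause
        return record.delta == other and t < horizon
    return False


def risk_span(record, cause: int, kind: str, horizon: float) -> float:
    """End of the at-risk interval [0, stop) for this subject and cause."""
    if kind == "subdistribution" and record.delta == 3 - cause:
        return float(horizon)
    return float(record.time)


def cumulative_linked_hazard(
    params: SurvivalParams,
    re: RandomEffects,
    z: np.ndarray,
    a: float,
    b: float,
    cause: int,
) -> float:
    """Closed-form integral of the linked hazard over [a, b].

    The span may cross baseline intervals; within each piece with constant
    height ``lam`` the integral is ``lam * exp(z beta + g0 U0) *
    (e^{c b'} - e^{c a'}) / c`` with ``c = g1 U1`` and the (b' - a')
    limit as c -> 0, evaluated via expm1 to avoid cancellation.
    """
    if a > b:
        raise ValueError(f"need a <= b, got a={a}, b={b}")
    if a == b:
        return 0.0
    g0, g1 = params.link_coeffs(cause)
    cuts = params.baseline.cuts[cause]
    heights = params.baseline.heights[cause]
    lo = np.maximum(cuts[:-1], a)
    hi = np.minimum(cuts[1:], b)
    length = np.clip(hi - lo, 0.0, None)
    c = g1 * re.U1
    pieces = heights * np.exp(c * lo) * length * _phi(c * length)
    base = math.exp(float(z @ params.beta[cause]) + g0 * re.U0)
    return float(base * np.sum(pieces * (length > 0)))


def cumulative_incidence(
    params: SurvivalParams,
    re: RandomEffects,
    z: np.ndarray,
    t: float,
    cause: int,
) -> float:
    """Crude cumulative incidence F_k(t) = 1 - exp(-Lambda_k(t)).

    Only meaningful for the subdistribution kind, where Lambda_k is the
    cumulative linked subdistribution hazard; under cause-specific hazards
    the CIF requires all causes jointly and is not implemented.
    """
    if params.submodel_kind != "subdistribution":
        raise NotImplementedError(
            "cumulative incidence from cause-specific hazards is not implemented"
        )
    if t < 0:
        raise ValueError("t must be >= 0")
    lam = cumulative_linked_hazard(params, re, z, 0.0, t, cause)
    return float(-np.expm1(-lam))


class SurvivalEngine:
    """Vectorized survival log-likelihood over a prepared dataset.

    Precomputes, per cause: at-risk span ends, the overlap of each span
    with every baseline interval, the event interval index and event time.
    The counting-process / piecewise-exponential log-likelihood is then

        sum_i d_ik [log lam_0k(T_i) + Z_i' beta_k + g0 U0_i + g1 U1_i T_i]
              - Lambda_k(span_i)

    evaluated with the closed-form interval integrals of
    :func:`cumulative_linked_hazard`.
    """

    def __init__(
        self,
        dataset: JointDataset,
        spec: ModelSpec,
        cuts: dict[int, np.ndarray] | None = None,
        design: DesignMatrices | None = None,
    ) -> None:
        self.kind = spec.submodel_kind
        self.link = spec.survival_link
        design = design if design is not None else build_design(dataset, spec)
        self.Z = design.surv_Z
        self.columns = design.surv_columns
        surv = dataset.survival
        self.time = surv["time"].to_numpy(dtype=float)
        self.delta = surv["delta"].to_numpy(dtype=int)
        self.horizon = float(dataset.horizon)
        self.n = len(self.time)
        if cuts is None:
            cuts = default_baseline_cuts(dataset)
        self.cuts = {k: np.asarray(cuts[k], dtype=float) for k in CAUSES}
        self.d: dict[int, np.ndarray] = {}
        self.ev_idx: dict[int, np.ndarray] = {}
        self.lo: dict[int, np.ndarray] = {}
        self.length: dict[int, np.ndarray] = {}
        for k in CAUSES:
            ck = self.cuts[k]
            self.d[k] = (self.delta == k).astype(float)
            if self.kind == "subdistribution":
                stop = np.where(self.delta == 3 - k, self.horizon, self.time)
            else:
                stop = self.time
            ev_t = np.where(self.delta == k, self.time, ck[0])
            if np.any(ev_t[self.delta == k] >= ck[-1]):
                raise ValueError(f"cause-{k} event time outside baseline support")
            self.ev_idx[k] = np.searchsorted(ck, ev_t, side="right") - 1
            lo = np.maximum(ck[None, :-1], 0.0)
            hi = np.minimum(ck[None, 1:], stop[:, None])
            self.lo[k] = lo * np.ones((self.n, 1))
            self.length[k] = np.clip(hi - self.lo[k], 0.0, None)

    def _coeffs(self, gamma_k: float) -> tuple[float, float]:
        if self.link == "intercept":
            return gamma_k, 0.0
        if self.link == "slope_only":
            return 0.0, gamma_k
        return gamma_k, gamma_k

    def cumhaz(
        self,
        cause: int,
        beta_k: np.ndarray,
        gamma_k: float,
        heights: np.ndarray,
        U0: np.ndarray,
        U1: np.ndarray,
    ) -> np.ndarray:
        """Per-subject cumulative linked hazard over the at-risk span."""
        g0, g1 = self._coeffs(gamma_k)
        c = g1 * U1  # (n,)
        lo, length = self.lo[cause], self.length[cause]
        pieces = (
            heights[None, :]
            * np.exp(c[:, None] * lo)
            * length
            * _phi(c[:, None] * length)
        )
        eta = self.Z @ beta_k + g0 * U0
        return np.exp(eta) * np.sum(pieces, axis=1)

    def exposures(
        self,
        cause: int,
        beta_k: np.ndarray,
        gamma_k: float,
        U0: np.ndarray,
        U1: np.ndarray,
    ) -> np.ndarray:
        """Per-interval total exposure sum_i exp(eta_i) int e^{c s} ds.

        The cause-``k`` likelihood is proportional to
        ``prod_j h_j^{d_j} exp(-h_j E_j)`` in the heights, so these E_j are
        the Gamma-update rates.
        """
        g0, g1 = self._coeffs(gamma_k)
        c = g1 * U1
        lo, length = self.lo[cause], self.length[cause]
        pieces = np.exp(c[:, None] * lo) * length * _phi(c[:, None] * length)
        eta = self.Z @ beta_k + g0 * U0
        return np.sum(np.exp(eta)[:, None] * pieces, axis=0)

    def event_counts(self, cause: int) -> np.ndarray:
        """Observed cause-k events per baseline interval."""
        J = len(self.cuts[cause]) - 1
        return np.bincount(
            self.ev_idx[cause], weights=self.d[cause], minlength=J
        )

    def loglik_terms(
        self,
        cause: int,
        beta_k: np.ndarray,
        gamma_k: float,
        heights: np.ndarray,
        U0: np.ndarray,
        U1: np.ndarray,
    ) -> np.ndarray:
        """Per-subject cause-k log-likelihood contributions."""
        g0, g1 = self._coeffs(gamma_k)
        ev = self.d[cause] * (
            np.log(heights[self.ev_idx[cause]])
            + self.Z @ beta_k
            + g0 * U0
            + g1 * U1 * self.time
        )
        return ev - self.cumhaz(cause, beta_k, gamma_k, heights, U0, U1)

    def loglik(
        self,
        beta: dict[int, np.ndarray],
        gamma: dict[int, float],
        heights: dict[int, np.ndarray],
        U0: np.ndarray,
        U1: np.ndarray,
        per_subject: bool = False,
    ) -> float | np.ndarray:
        total = sum(
            self.loglik_terms(k, beta[k], gamma[k], heights[k], U0, U1)
            for k in CAUSES
        )
        return total if per_subject else float(np.sum(total))


def survival_loglik(
    params: SurvivalParams,
    re: tuple[np.ndarray, np.ndarray],
    dataset: JointDataset,
    spec: ModelSpec | None = None,
) -> float:
    """Joint survival log-likelihood over both causes and all subjects.

    ``re`` is the pair ``(U0, U1)`` of per-subject arrays aligned with
    ``dataset.subject_ids``.
    """
    spec = spec or ModelSpec(
        submodel_kind=params.submodel_kind, survival_link=params.survival_link
    )
    if spec.submodel_kind != params.submodel_kind or spec.survival_link != params.survival_link:
        spec = ModelSpec(
            longitudinal_covariates=spec.longitudinal_covariates,
            survival_covariates=spec.survival_covariates,
            re_structure=spec.re_structure,
            survival_link=params.survival_link,
            submodel_kind=params.submodel_kind,
            n_baseline_intervals=spec.n_baseline_intervals,
        )
    engine = SurvivalEngine(dataset, spec, cuts=params.baseline.cuts)
    U0, U1 = (np.asarray(u, dtype=float) for u in re)
    return float(
        engine.loglik(
            params.beta,
            params.gamma,
            params.baseline.heights,
            U0,
            U1,
        )
    )


def coherence_check(
    params: SurvivalParams,
    re: RandomEffects,
    z: np.ndarray,
    grid: np.ndarray,
) -> float:
    """Monitor F1(t) + F2(t) <= 1 on a time grid; warn on violation.

    Twin subdistribution models do not constrain the two cumulative
    incidences to sum below one; violations are a known limitation and are
    logged, not raised.  Returns the largest F1 + F2 over the grid.
    """
    import logging

    worst = 0.0
    for t in np.asarray(grid, dtype=float):
        tot = sum(cumulative_incidence(params, re, z, float(t), k) for k in CAUSES)
        worst = max(worst, tot)
    if worst > 1.0:
        logging.getLogger("jointcr").warning(
            "cumulative incidences sum to %.3f > 1 on the grid", worst
        )
    return worst


def hazard_ratio_summaries(
    draws: np.ndarray | pd.DataFrame,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Posterior HR/SHR table: exp-scale mean and 2.5/97.5 percentiles.

    ``draws`` holds posterior draws of log-hazard-ratio coefficients, one
    column per covariate.
    """
    if isinstance(draws, pd.DataFrame):
        names = list(draws.columns)
        arr = draws.to_numpy(dtype=float)
    else:
        arr = np.asarray(draws, dtype=float)
        if arr.ndim == 1:  # a single covariate's draws
            arr = arr.reshape(-1, 1)
        if names is None:
            names = [f"z{i}" for i in range(arr.shape[1])]
    hr = np.exp(arr)
    return pd.DataFrame(
        {
            "hr": hr.mean(axis=0),
            "lo2.5": np.percentile(hr, 2.5, axis=0),
            "hi97.5": np.percentile(hr, 97.5, axis=0),
        },
        index=names,
    )
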