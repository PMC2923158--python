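"""Synthetic joint longitudinal + competing-risks data generator.

The generator emulates a randomized two-arm trial with a Gaussian biomarker
measured on a fixed visit schedule and informative dropout from two
competing causes.  Per subject:

* treatment ``X ~ Bernoulli(0.5)``; random intercept ``U0 ~ N(0, sigma_U0^2)``
  and slope ``U1 ~ N(0, sigma_U1^2)``, independent;
* biomarker at each scheduled visit time t (days):
  ``Y = beta10 + beta11 t + beta12 X + beta13 X t + U0 + U1 t + eps``,
  ``eps ~ N(0, sigma2_eps)``;
* cause-1 failure via a proportional subdistribution-hazards (Fine-Gray)
  construction whose baseline is a unit-exponential mixture with mass ``p``:
  ``F1(t; x) = 1 - [1 - p (1 - e^{-t})]^{exp(eta1)}`` — cause 1 occurs with
  probability ``F1(inf)`` and its time comes from inverting ``F1`` —
  with a frailty term in ``eta1`` inducing association with the biomarker;
* cause-2 failure times exponential with rate ``lam20 * exp(eta2)``;
* non-informative censoring ``C ~ Exp(cens_rate)``.

Association: ``eta1 = x beta2 + gamma * W``, ``eta2 = x beta2 - gamma * W``
with ``W = U0`` under the default ``frailty_mode="intercept"``;
``frailty_mode="intercept_slope"`` instead uses the full time-varying
``W1(s) = U0 + U1 s`` inside the cause-1 subdistribution hazard and requires
numerical inversion of the cumulative subdistribution hazard.

Failure and censoring times are generated on the unit-exponential scale and
multiplied by ``time_scale`` to map them to days; the visit schedule is then
truncated at the observed time (no measurements after dropout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .data import JointDataset

__all__ = [
    "RandomEffects",
    "SimulationDesign",
    "eval_cause1_subdist",
    "invert_cause1_subdist",
    "draw_failure",
    "simulate_dataset",
    "replicate_seeds",
]

_EXP_CAP = 700.0  # exp() overflow guard on the log scale


@dataclass(frozen=True)
class RandomEffects:
    """Per-subject random intercept and slope of the latent process."""

    U0: float
    U1: float

    def w1(self, t: float, structure: str = "intercept_slope") -> float:
        """W1(t) = U0 + U1 t, or U1 t under the slope-only structure."""
        if structure == "slope_only":
            return self.U1 * t
        return self.U0 + self.U1 * t


@dataclass(frozen=True)
class SimulationDesign:
    """True generative parameters of the simulation study.

    Defaults follow the study design used throughout: biomarker fixed
    effects (6.15, -0.25, 0.25, 0), measurement-error variance 0.1,
    unit-SD random intercept and slope, cause-1 mixture mass p = 0.25,
    zero survival covariate effect, association gamma = +/-1 and
    exponential censoring with rate 0.25.  ``lam20`` is the baseline rate
    multiplier of the cause-2 exponential and ``time_scale`` maps the
    generative (unit-exponential) time scale to days; both are calibrated
    so that simulated data reproduce the design's event mix
    (~25% cause 1 / ~65% cause 2 / ~10% censored) and ~7.0 longitudinal
    observations per subject under the {0..7, 14, 28}-day visit schedule.
    """

    n: int = 500
    beta10: float = 6.15
    beta11: float = -0.25
    beta12: float = 0.25
    beta13: float = 0.0
    sigma2_eps: float = 0.1
    sigma_U0: float = 1.0
    sigma_U1: float = 1.0
    p: float = 0.25
    beta2: float = 0.0
    gamma: float = 1.0
    lam20: float = 4.0
    cens_rate: float = 0.25
    visit_times: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 14, 28)
    time_scale: float = 67.0
    frailty_mode: str = "intercept"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0,1), got {self.p}")
        if self.sigma2_eps <= 0:
            raise ValueError("sigma2_eps must be > 0")
        if self.time_scale <= 0 or self.lam20 <= 0 or self.cens_rate <= 0:
            raise ValueError("time_scale, lam20 and cens_rate must be > 0")
        vt = np.asarray(self.visit_times, dtype=float)
        if len(vt) == 0 or np.any(np.diff(vt) <= 0):
            raise ValueError("visit_times must be strictly increasing")
        if self.frailty_mode not in ("intercept", "intercept_slope"):
            raise ValueError(f"unknown frailty_mode {self.frailty_mode!r}")

    @property
    def truths(self) -> dict[str, float]:
        """True values keyed by the fitted model's parameter names."""
        return {
            "beta_long[intercept]": self.beta10,
            "beta_long[t]": self.beta11,
            "beta_long[treatment]": self.beta12,
            "beta_long[treatment:t]": self.beta13,
            "sigma2_eps": self.sigma2_eps,
            "sigma_U0": self.sigma_U0,
            "sigma_U1": self.sigma_U1,
            "beta_surv1[treatment]": self.beta2,
            "beta_surv2[treatment]": self.beta2,
            "gamma1": self.gamma,
            "gamma2": -self.gamma,
        }


def eval_cause1_subdist(
    t: float | np.ndarray,
    x: float,
    p: float,
    beta: float,
    eta_re: float = 0.0,
) -> float | np.ndarray:
    """Cause-1 subdistribution F1(t; x) of the unit-exponential mixture.

    ``F1(t) = 1 - [1 - p (1 - e^{-t})]^{exp(x beta + eta_re)}``: a unit
    exponential mixture with mass ``1 - p`` at infinity when the linear
    predictor is zero, pushed through the proportional subdistribution
    hazards model otherwise.  ``eta_re`` is an optional frailty offset.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    e = math.exp(min(x * beta + eta_re, _EXP_CAP))
    out = -np.expm1(e * np.log1p(-p * (-np.expm1(-t))))
    return float(out) if out.ndim == 0 else out


def invert_cause1_subdist(
    q: float, x: float, p: float, beta: float, eta_re: float = 0.0
) -> float:
    """Closed-form inverse of :func:`eval_cause1_subdist` in ``t``.

    Valid for ``0 <= q < F1(inf; x)``; raises outside that range.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    e = math.exp(min(x * beta + eta_re, _EXP_CAP))
    q_inf = -math.expm1(e * math.log1p(-p))
    if not 0 <= q < q_inf:
        raise ValueError(f"q must be in [0, F1(inf)={q_inf:.6g}), got {q}")
    inner = math.expm1(math.log1p(-q) / e)  # (1-q)^(1/e) - 1, in (-p, 0]
    return -math.log1p(inner / p)


def _cause1_cumhaz_w1(t: float, a0: float, c: float, p: float) -> float:
    """Cumulative cause-1 subdistribution hazard with time-varying frailty.

    Integrand: ``lam01(s) exp(a0 + c s)`` with the mixture baseline
    ``lam01(s) = p e^{-s} / (1 - p (1 - e^{-s}))``.
    """

    def integrand(s: float) -> float:
        return (
            p
            * math.exp(-s)
            / (1.0 - p * (-math.expm1(-s)))
            * math.exp(min(a0 + c * s, _EXP_CAP))
        )

    val, _ = quad(integrand, 0.0, t, limit=200)
    return val


def draw_failure(
    x: float,
    re: RandomEffects,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Draw one (latent failure time, cause) pair on the generative scale.

    Cause 1 occurs with probability ``F1(inf)`` under the frailty-adjusted
    predictor; its time is obtained by inverting the cause-1
    subdistribution given cause 1 (closed form under the intercept frailty
    mode, numerical inversion of the cumulative subdistribution hazard
    under the time-varying mode).  Otherwise the cause-2 time is
    exponential with rate ``lam20 * exp(x beta2 - gamma U0)``.
    """
    eta2 = x * design.beta2 - design.gamma * re.U0
    rate2 = design.lam20 * math.exp(min(eta2, _EXP_CAP))
    if design.frailty_mode == "intercept":
        eta1 = x * design.beta2 + design.gamma * re.U0
        p_inf = eval_cause1_subdist(np.inf, x, design.p, design.beta2, design.gamma * re.U0)
        if rng.random() < p_inf:
            q = rng.random() * p_inf
            return invert_cause1_subdist(q, x, design.p, design.beta2, design.gamma * re.U0), 1
        return rng.exponential(1.0 / rate2), 2

    # time-varying frailty: eta1(s) = x beta2 + gamma (U0 + U1 s)
    a0 = x * design.beta2 + design.gamma * re.U0
    c = design.gamma * re.U1
    if c >= 1.0 - 1e-9:
        p_inf = 1.0  # hazard integral diverges: cause 1 almost surely
    else:
        lam_inf = _cause1_cumhaz_w1(np.inf, a0, c, design.p)
        p_inf = -math.expm1(-lam_inf)
    if rng.random() < p_inf:
        target = -math.log1p(-rng.random() * p_inf)
        f = lambda t: _cause1_cumhaz_w1(t, a0, c, design.p) - target
        hi = 1.0
        for _ in range(60):
            if f(hi) > 0:
                break
            hi *= 2.0
        else:
            raise RuntimeError(
                f"failed to bracket cause-1 inversion: a0={a0:.3g} c={c:.3g} "
                f"target={target:.3g}"
            )
        return brentq(f, 0.0, hi, xtol=1e-10), 1
    return rng.exponential(1.0 / rate2), 2


def simulate_dataset(design: SimulationDesign, seed: int | None = None) -> JointDataset:
    """Generate a full :class:`~jointcr.data.JointDataset` from ``design``.

    The longitudinal vector is truncated at the observed event or censoring
    time (measurements stop at dropout; a visit exactly at the observed
    time is retained).  The dataset horizon is the last scheduled visit or
    the largest observed time, whichever is larger.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n
    x = rng.integers(0, 2, size=n).astype(float)
    U0 = rng.normal(0.0, design.sigma_U0, size=n)
    U1 = rng.normal(0.0, design.sigma_U1, size=n)

    if design.frailty_mode == "intercept":
        # vectorized Fine-Gray draw with shared-intercept frailty
        eta1 = x * design.beta2 + design.gamma * U0
        e1 = np.exp(np.minimum(eta1, _EXP_CAP))
        p_inf = -np.expm1(e1 * np.log1p(-design.p))
        is_c1 = rng.random(n) < p_inf
        q = rng.random(n) * p_inf
        inner = np.expm1(np.log1p(-q) / e1)
        t1 = -np.log1p(inner / design.p)
        rate2 = design.lam20 * np.exp(np.minimum(x * design.beta2 - design.gamma * U0, _EXP_CAP))
        t2 = rng.exponential(1.0, size=n) / rate2
        T = np.where(is_c1, t1, t2)
        cause = np.where(is_c1, 1, 2)
    else:
        T = np.empty(n)
        cause = np.empty(n, dtype=int)
        for i in range(n):
            T[i], cause[i] = draw_failure(x[i], RandomEffects(U0[i], U1[i]), design, rng)

    C = rng.exponential(1.0 / design.cens_rate, size=n)
    obs_time = np.minimum(T, C) * design.time_scale
    delta = np.where(T <= C, cause, 0)

    visits = np.asarray(design.visit_times, dtype=float)
    keep = visits[None, :] <= obs_time[:, None]  # tied day-of-event visit retained
    subj = np.repeat(np.arange(1, n + 1), keep.sum(axis=1))
    tt = np.concatenate([visits[k] for k in keep])
    xx = x[subj - 1]
    mean = (
        design.beta10
        + design.beta11 * tt
        + design.beta12 * xx
        + design.beta13 * xx * tt
        + U0[subj - 1]
        + U1[subj - 1] * tt
    )
    y = mean + rng.normal(0.0, math.sqrt(design.sigma2_eps), size=len(tt))

    obs = pd.DataFrame({"subject_id": subj, "t": tt, "y": y})
    surv = pd.DataFrame(
        {"subject_id": np.arange(1, n + 1), "time": obs_time, "delta": delta}
    )
    cov = pd.DataFrame({"subject_id": np.arange(1, n + 1), "treatment": x})
    horizon = float(max(visits[-1], obs_time.max()))
    return JointDataset(obs, surv, cov, horizon=horizon)


def replicate_seeds(base_seed: int, n_reps: int) -> list[int]:
    """Deterministic, collision-free per-replicate seeds below 2**31."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    state = np.random.SeedSequence(base_seed).generate_state(2 * n_reps) % (2**31)
    seeds: list[int] = []
    seen: set[int] = set()
    for s in state:
        s = int(s)
        if s not in seen:
            seen.add(s)
            seeds.append(s)
        if len(seeds) == n_reps:
            return seeds
    # astronomically unlikely: extend deterministically
    k = 0
    while len(seeds) < n_reps:
        cand = (seeds[-1] + 1 + k) % (2**31)
        if cand not in seen:
            seen.add(cand)
            seeds.append(cand)
        k += 1
    return seeds
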