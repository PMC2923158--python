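"""Linear mixed submodel: likelihood and conjugate Gibbs updates.

The biomarker follows ``Y_ij = x_ij' beta + W1_i(t_ij) + eps_ij`` with
``eps_ij ~ N(0, sigma2)`` independent across measurements and
``W1_i(t) = U0_i + U1_i t`` (or ``U1_i t`` under the slope-only structure),
``U0_i ~ N(0, sigma2_U0)`` and ``U1_i ~ N(0, sigma2_U1)`` independent.

All full conditionals here are conjugate: Gaussian for the fixed effects
given the random effects, Gamma for the error precision and for the
random-effect precisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import DesignMatrices, JointDataset, ModelSpec, build_design
from .simulate import RandomEffects

__all__ = [
    "LongitudinalParams",
    "conditional_mean",
    "longitudinal_loglik",
    "gibbs_update_fixed_effects",
    "gibbs_update_error_variance",
    "gibbs_update_re_variance",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class LongitudinalParams:
    """Fixed effects and variance components of the mixed submodel."""

    beta: np.ndarray
    sigma2: float
    sigma2_U0: float
    sigma2_U1: float
    re_structure: str = "intercept_slope"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma2 <= 0 or self.sigma2_U0 <= 0 or self.sigma2_U1 <= 0:
            raise ValueError("variances must be strictly positive")
        if self.re_structure not in ("intercept_slope", "slope_only"):
            raise ValueError(f"unknown re_structure {self.re_structure!r}")


def conditional_mean(
    params: LongitudinalParams,
    re: RandomEffects,
    row: np.ndarray,
    t: float,
) -> float:
    """E[Y | U] for one design row: ``row . beta + W1(t)``."""
    row = np.asarray(row, dtype=float)
    if row.shape != params.beta.shape:
        raise ValueError(f"design row has shape {row.shape}, beta {params.beta.shape}")
    return float(row @ params.beta + re.w1(t, params.re_structure))


def w1_values(
    U0: np.ndarray, U1: np.ndarray, t: np.ndarray, structure: str
) -> np.ndarray:
    """Vectorized W1(t) per observation (U0, U1 already expanded)."""
    if structure == "slope_only":
        return U1 * t
    return U0 + U1 * t


def longitudinal_loglik(
    params: LongitudinalParams,
    re: tuple[np.ndarray, np.ndarray],
    dataset: JointDataset,
    spec: ModelSpec | None = None,
    design: DesignMatrices | None = None,
) -> float:
    """Gaussian log-likelihood of all observations given the random effects.

    ``re`` is the pair ``(U0, U1)`` of per-subject arrays aligned with
    ``dataset.subject_ids``.
    """
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    if design is None:
        design = build_design(dataset, spec or ModelSpec())
    U0, U1 = (np.asarray(u, dtype=float) for u in re)
    idx = design.subject_index
    mu = design.long_X @ params.beta + w1_values(
        U0[idx], U1[idx], design.long_t, params.re_structure
    )
    resid = design.long_y - mu
    n = len(resid)
    return float(
        -0.5 * n * (_LOG_2PI + math.log(params.sigma2))
        - 0.5 * np.sum(resid**2) / params.sigma2
    )


def gibbs_update_fixed_effects(
    y: np.ndarray,
    X: np.ndarray,
    w1: np.ndarray,
    sigma2: float,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact draw from the conjugate Gaussian full conditional of beta.

    Conditionally on the random effects the residual target ``y - w1`` is
    Gaussian around ``X beta``, so with an independent Gaussian prior the
    full conditional is ``N(m, V)`` with
    ``V^-1 = X'X / sigma2 + diag(1/prior_var)`` and
    ``V^-1 m = X'(y - w1)/sigma2 + prior_mean/prior_var``.
    With no data the draw comes from the prior.
    """
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    q = X.shape[1] if X.ndim == 2 else len(prior_mean)
    prec = np.diag(1.0 / prior_var)
    b = prior_mean / prior_var
    if len(y):
        prec = prec + X.T @ X / sigma2
        b = b + X.T @ (y - w1) / sigma2
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular precision in beta update (cond={np.linalg.cond(prec):.3g})"
        ) from exc
    mean = np.linalg.solve(prec, b)
    z = rng.standard_normal(q)
    return mean + np.linalg.solve(L.T, z)


def gibbs_update_error_variance(
    resid: np.ndarray,
    shape0: float,
    rate0: float,
    rng: np.random.Generator,
) -> float:
    """Draw sigma2 by sampling its precision from the conjugate Gamma.

    Full conditional of ``1/sigma2``: ``Gamma(shape0 + n/2,
    rate0 + sum(resid^2)/2)``.  With no residuals this is a prior draw.
    """
    shape = shape0 + 0.5 * len(resid)
    rate = rate0 + 0.5 * float(np.sum(np.square(resid)))
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def gibbs_update_re_variance(
    u: np.ndarray,
    shape0: float,
    rate0: float,
    rng: np.random.Generator,
) -> float:
    """Conjugate Gamma draw for a random-effect variance (same algebra)."""
    return gibbs_update_error_variance(np.asarray(u, dtype=float), shape0, rate0, rng)
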