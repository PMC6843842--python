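"""The Bernoulli multilevel logistic model: linear predictors, priors, posterior.

Four nested variants of the logit-scale linear predictor for individual j in
area i:

    M1: lambda_ij = alpha + v_i
    M2: lambda_ij = alpha + X_ij' beta + v_i
    M3: lambda_ij = alpha + X_ij' beta + W_i' gamma + v_i
    M4: lambda_ij = alpha + X_ij' beta + W_i' gamma + u_i + v_i

with v_i iid Normal(0, sigma_v^2) (unstructured heterogeneity) and u_i an
intrinsic CAR field (spatially structured heterogeneity).  Fixed effects get
vague Normal(0, 10000) priors; the log-precisions of both variance
components get logGamma(1, 0.0005) priors — equivalently Gamma(1, 0.0005)
on the precisions — with a logGamma(1, 1) alternative for prior-sensitivity
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .data_model import DesignMatrices
from .spatial_graph import AreaGraph, car_precision

VARIANTS = ("M1", "M2", "M3", "M4")

__all__ = [
    "ModelSpec",
    "ParameterState",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "VARIANTS",
]

_LAMBDA_CLIP = 35.0  # |logit| beyond this is numerically saturated


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit, with covariate lists and hyperparameters.

    ``prior_logprec_shape``/``prior_logprec_rate`` parameterise the
    Gamma(shape, rate) prior on each precision (rate convention); setting
    ``prior_logprec_rate=1`` reproduces the logGamma(1, 1) sensitivity prior.
    ``gamma_scale`` flips to the shape/scale convention if ever needed.
    """

    variant: str = "M4"
    individual_covariates: tuple[str, ...] = ()
    area_covariates: tuple[str, ...] = ()
    prior_fixed_variance: float = 10_000.0
    prior_logprec_shape: float = 1.0
    prior_logprec_rate: float = 0.0005
    gamma_scale: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.variant == "M1" and (self.individual_covariates or self.area_covariates):
            raise ValueError("M1 uses no covariates")
        if self.variant == "M2" and self.area_covariates:
            raise ValueError("M2 uses individual covariates only")

    @property
    def uses_x(self) -> bool:
        return self.variant in ("M2", "M3", "M4")

    @property
    def uses_w(self) -> bool:
        return self.variant in ("M3", "M4")

    @property
    def uses_u(self) -> bool:
        return self.variant == "M4"

    def with_variant(self, variant: str) -> "ModelSpec":
        ind = self.individual_covariates if variant != "M1" else ()
        area = self.area_covariates if variant in ("M3", "M4") else ()
        return replace(
            self, variant=variant, individual_covariates=ind, area_covariates=area
        )

    def precision_rate(self) -> float:
        """Rate of the Gamma prior on precisions, honouring the scale flag."""
        return (
            1.0 / self.prior_logprec_rate if self.gamma_scale else self.prior_logprec_rate
        )


@dataclass
class ParameterState:
    """One point in parameter space: intercept, fixed effects, random effects,
    and the two variance components."""

    alpha: float
    beta: np.ndarray = field(default_factory=lambda: np.zeros(0))
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    u: np.ndarray = field(default_factory=lambda: np.zeros(0))
    v: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sigma_u2: float = 1.0
    sigma_v2: float = 1.0

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha=self.alpha,
            beta=self.beta.copy(),
            gamma=self.gamma.copy(),
            u=self.u.copy(),
            v=self.v.copy(),
            sigma_u2=self.sigma_u2,
            sigma_v2=self.sigma_v2,
        )

    def validate(self, spec: ModelSpec) -> None:
        if self.v.size and self.sigma_v2 <= 0:
            raise ValueError("sigma_v2 must be positive")
        if spec.uses_u and self.sigma_u2 <= 0:
            raise ValueError("sigma_u2 must be positive for M4")
        if not spec.uses_u and self.u.size and np.any(self.u != 0):
            raise ValueError(f"u must be zero under {spec.variant}")
        if not spec.uses_w and self.gamma.size and np.any(self.gamma != 0):
            raise ValueError(f"gamma must be zero under {spec.variant}")
        if not spec.uses_x and self.beta.size and np.any(self.beta != 0):
            raise ValueError(f"beta must be zero under {spec.variant}")


def linear_predictor(
    state: ParameterState, design: DesignMatrices, spec: ModelSpec
) -> np.ndarray:
    """lambda_ij = alpha + X beta + W gamma + u_i + v_i, absent terms zero."""
    lam = np.full(design.n_rows, state.alpha)
    if spec.uses_x and state.beta.size:
        if state.beta.size != design.X.shape[1]:
            raise ValueError(
                f"beta has {state.beta.size} entries, X has {design.X.shape[1]} columns"
            )
        lam += design.X @ state.beta
    if spec.uses_w and state.gamma.size:
        if state.gamma.size != design.W.shape[1]:
            raise ValueError(
                f"gamma has {state.gamma.size} entries, W has {design.W.shape[1]} columns"
            )
        lam += design.W @ state.gamma
    if spec.uses_u and state.u.size:
        lam += state.u[design.area_index]
    if state.v.size:
        lam += state.v[design.area_index]
    return lam


def log_likelihood(y: np.ndarray, lam: np.ndarray) -> float:
    """Bernoulli log-likelihood sum[y*lambda - log(1 + e^lambda)].

    log(1+e^lambda) via logaddexp stays finite for |lambda| up to ~700.
    """
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if y.shape != lam.shape:
        raise ValueError("y and lambda must have equal length")
    return float(np.sum(y * lam - np.logaddexp(0.0, lam)))


def probabilities(lam: np.ndarray) -> np.ndarray:
    """Inverse-logit with clipping for numeric safety."""
    return 1.0 / (1.0 + np.exp(-np.clip(lam, -_LAMBDA_CLIP, _LAMBDA_CLIP)))


def _normal_logpdf(x: np.ndarray | float, var: float) -> float:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    return float(-0.5 * x.size * np.log(2 * np.pi * var) - np.sum(x**2) / (2 * var))


def log_prior(
    state: ParameterState,
    spec: ModelSpec,
    graph: AreaGraph | None = None,
    Q: sp.spmatrix | None = None,
) -> float:
    """Joint log prior density (improper CAR part included up to its rank).

    Terms: Normal(0, prior_fixed_variance) on alpha and each fixed effect;
    Gamma(shape, rate) on each precision 1/sigma^2 (the logGamma prior on
    the log-precision); Normal(0, sigma_v^2) on v; and the generalized
    intrinsic-CAR density -(rank(Q)/2) log sigma_u^2 - u'Qu/(2 sigma_u^2)
    for u, with rank(Q) = N - (number of connected components).
    """
    from scipy.stats import gamma as gamma_dist

    lp = _normal_logpdf(state.alpha, spec.prior_fixed_variance)
    if state.beta.size:
        lp += _normal_logpdf(state.beta, spec.prior_fixed_variance)
    if state.gamma.size:
        lp += _normal_logpdf(state.gamma, spec.prior_fixed_variance)

    shape, rate = spec.prior_logprec_shape, spec.precision_rate()
    if state.v.size:
        if state.sigma_v2 <= 0:
            raise ValueError("sigma_v2 must be positive")
        lp += float(gamma_dist.logpdf(1.0 / state.sigma_v2, a=shape, scale=1.0 / rate))
        lp += _normal_logpdf(state.v, state.sigma_v2)
    if spec.uses_u and state.u.size:
        if state.sigma_u2 <= 0:
            raise ValueError("sigma_u2 must be positive")
        if Q is None:
            if graph is None:
                raise ValueError("need graph or Q for the CAR prior")
            Q = car_precision(graph)
        n_comp = graph.n_components if graph is not None else 1
        rank = state.u.size - n_comp
        quad = float(state.u @ (Q @ state.u))
        lp += float(gamma_dist.logpdf(1.0 / state.sigma_u2, a=shape, scale=1.0 / rate))
        lp += -0.5 * rank * np.log(2 * np.pi * state.sigma_u2) - quad / (
            2 * state.sigma_u2
        )
    return lp


def log_posterior(
    state: ParameterState,
    y: np.ndarray,
    design: DesignMatrices,
    spec: ModelSpec,
    graph: AreaGraph | None = None,
) -> float:
    lam = linear_predictor(state, design, spec)
    return log_likelihood(y, lam) + log_prior(state, spec, graph=graph)
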