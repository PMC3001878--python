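"""Bayesian-decision-theoretic response layer.

Given a belief (Gaussian posterior over hidden states) and a loss function
``l(a, x; phi)``, a rational subject picks the action minimizing *posterior
risk* — the expected loss under the belief.  This module computes posterior
risk (closed form for quadratic losses, Gauss-Hermite quadrature otherwise),
optimal actions over continuous / finite / integer action spaces, softmax
(logit) choice policies whose noise scales with posterior risk, and response
log-likelihoods for both Gaussian-residual and softmax response channels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import log_softmax, softmax

from .errors import (
    CovarianceError,
    InvalidInputError,
    InvalidLossError,
    UnsupportedDimensionError,
)
from .recognition import Belief

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# action spaces
# ---------------------------------------------------------------------------

@dataclass
class ContinuousBox:
    """A box of admissible real-valued actions; None bounds mean unbounded."""
    lower: Union[float, np.ndarray, None] = None
    upper: Union[float, np.ndarray, None] = None
    dim: int = 1


@dataclass
class FiniteSet:
    """A finite, ordered set of admissible actions (ties break to lowest index)."""
    actions: Sequence


@dataclass
class NonnegativeIntegers:
    """Actions are counts n = 0, 1, 2, ...; optionally capped at ``upper``."""
    upper: Optional[int] = None


ActionSpace = Union[ContinuousBox, FiniteSet, NonnegativeIntegers]


@dataclass
class LossSpec:
    """A loss function over (action, hidden state) with parameters phi.

    ``risk_closed_form(belief, action, phi)`` and
    ``argmin_closed_form(belief, phi)`` are optional analytic shortcuts; when
    absent, risk falls back to quadrature and the argmin to numerical search.
    """

    evaluate: Callable[[object, np.ndarray, np.ndarray], float]
    action_space: ActionSpace
    phi_names: Sequence[str] = ()
    risk_closed_form: Optional[Callable] = None
    argmin_closed_form: Optional[Callable] = None


def squared_error_loss() -> LossSpec:
    """l(a, x) = |a - x|^2 over unbounded continuous actions.

    Posterior risk is (a - mu)'(a - mu) + tr(Sigma); the optimal action is the
    posterior mean — both supplied in closed form.
    """

    def evaluate(a, x, phi):
        a = np.atleast_1d(np.asarray(a, dtype=float))
        return float(np.sum((a - x) ** 2))

    def risk(belief: Belief, a, phi):
        a = np.atleast_1d(np.asarray(a, dtype=float))
        return float(np.sum((a - belief.mode) ** 2) + np.trace(belief.covariance))

    def argmin(belief: Belief, phi):
        return belief.mode.copy()

    return LossSpec(
        evaluate=evaluate,
        action_space=ContinuousBox(),
        risk_closed_form=risk,
        argmin_closed_form=argmin,
    )


# ---------------------------------------------------------------------------
# posterior risk
# ---------------------------------------------------------------------------

def _gauss_hermite_risk(loss: LossSpec, belief: Belief, action, phi,
                        order: int) -> float:
    d = belief.mode.size
    nodes, weights = np.polynomial.hermite.hermgauss(order)
    L = np.linalg.cholesky(belief.covariance)
    total = 0.0
    norm = np.pi ** (-0.5 * d)
    for idx in itertools.product(range(order), repeat=d):
        z = np.array([nodes[i] for i in idx])
        w = np.prod([weights[i] for i in idx])
        x = belief.mode + np.sqrt(2.0) * (L @ z)
        total += w * loss.evaluate(action, x, phi)
    return float(total * norm)


def posterior_risk(loss: LossSpec, belief: Belief, action, phi,
                   order: int = 21, refine_tol: float = 1e-8,
                   max_order: int = 85) -> float:
    """Expected loss of ``action`` under the Gaussian belief.

    Uses the loss's closed form when available; otherwise tensor-product
    Gauss-Hermite quadrature (default order 21 per dimension, doubled while
    refinement changes the value by more than ``refine_tol``).  Quadrature is
    limited to state dimension <= 4.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if loss.risk_closed_form is not None:
        return float(loss.risk_closed_form(belief, action, phi))
    if belief.mode.size > 4:
        raise UnsupportedDimensionError(
            f"quadrature supports state dimension <= 4, got {belief.mode.size}"
        )
    value = _gauss_hermite_risk(loss, belief, action, phi, order)
    while order < max_order:
        order = min(2 * order, max_order)
        refined = _gauss_hermite_risk(loss, belief, action, phi, order)
        if abs(refined - value) <= refine_tol:
            return refined
        value = refined
    return value


# ---------------------------------------------------------------------------
# optimal action
# ---------------------------------------------------------------------------

_TIE_TOL = 1e-12
_COERCIVITY_PROBE = 1e4


def optimal_action(loss: LossSpec, belief: Belief, phi,
                   n_starts: int = 3, return_info: bool = False):
    """Action minimizing posterior risk; deterministic tie-break to lowest index.

    Finite sets are enumerated; continuous boxes use bounded minimization with
    ``n_starts`` multistarts; integer spaces are relaxed to the continuous
    line, then the floor/ceiling neighbours (and 0) are compared exactly.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    info: dict = {"tie": False}

    if loss.argmin_closed_form is not None:
        a = loss.argmin_closed_form(belief, phi)
        return (a, info) if return_info else a

    risk = lambda a: posterior_risk(loss, belief, a, phi)
    space = loss.action_space

    if isinstance(space, FiniteSet):
        risks = np.array([risk(a) for a in space.actions])
        best = int(np.argmin(risks))
        ties = np.flatnonzero(risks <= risks[best] + _TIE_TOL)
        if ties.size > 1:
            info["tie"] = True
            logger.warning("optimal_action: tie among actions %s; lowest index kept",
                           ties.tolist())
        best = int(ties[0])
        a = space.actions[best]
        return (a, info) if return_info else a

    if isinstance(space, NonnegativeIntegers):
        upper = space.upper if space.upper is not None else 10**6
        res = minimize_scalar(risk, bounds=(0.0, float(upper)), method="bounded")
        n_star = float(res.x)
        candidates = sorted({0, int(np.floor(n_star)), int(np.ceil(n_star)), upper})
        candidates = [c for c in candidates if 0 <= c <= upper]
        risks = [risk(c) for c in candidates]
        best = candidates[int(np.argmin(risks))]
        return (best, info) if return_info else best

    if isinstance(space, ContinuousBox):
        lo = -np.inf if space.lower is None else np.asarray(space.lower, dtype=float)
        hi = np.inf if space.upper is None else np.asarray(space.upper, dtype=float)
        if np.any(~np.isfinite(np.atleast_1d(lo))) or np.any(~np.isfinite(np.atleast_1d(hi))):
            # unbounded: verify coercivity by probing far out along each axis
            center = belief.mode[: space.dim] if belief.mode.size >= space.dim else np.zeros(space.dim)
            r0 = risk(np.asarray(center, dtype=float))
            for sign in (-1.0, 1.0):
                probe = np.asarray(center, dtype=float) + sign * _COERCIVITY_PROBE
                if risk(probe) < r0:
                    raise InvalidLossError("posterior risk appears unbounded below")
        if space.dim == 1:
            lo1 = float(np.atleast_1d(lo)[0]) if np.all(np.isfinite(np.atleast_1d(lo))) else None
            hi1 = float(np.atleast_1d(hi)[0]) if np.all(np.isfinite(np.atleast_1d(hi))) else None
            scalar_risk = lambda a: risk(np.array([a]))
            best_a, best_r = None, np.inf
            if lo1 is not None and hi1 is not None:
                # bounded: multistart over sub-intervals
                edges = np.linspace(lo1, hi1, n_starts + 1)
                for i in range(n_starts):
                    res = minimize_scalar(scalar_risk, bounds=(edges[i], edges[i + 1]),
                                          method="bounded")
                    if res.fun < best_r:
                        best_a, best_r = float(res.x), float(res.fun)
            else:
                center = float(belief.mode[0])
                for start in (center, center - 1.0, center + 1.0)[:n_starts]:
                    res = minimize_scalar(scalar_risk, bracket=(start - 1.0, start, start + 1.0))
                    if res.fun < best_r:
                        best_a, best_r = float(res.x), float(res.fun)
            a = np.array([best_a])
            return (a, info) if return_info else a
        # multi-dimensional box
        rng = np.random.default_rng(0)
        x0s = [np.asarray(belief.mode[: space.dim], dtype=float)]
        for _ in range(n_starts - 1):
            x0s.append(x0s[0] + rng.standard_normal(space.dim))
        bounds = None
        if np.all(np.isfinite(np.atleast_1d(lo))) and np.all(np.isfinite(np.atleast_1d(hi))):
            bounds = list(zip(np.broadcast_to(lo, (space.dim,)),
                              np.broadcast_to(hi, (space.dim,))))
        best_a, best_r = None, np.inf
        for x0 in x0s:
            res = minimize(lambda a: risk(a), x0, method="L-BFGS-B", bounds=bounds)
            if res.fun < best_r:
                best_a, best_r = res.x, float(res.fun)
        return (best_a, info) if return_info else best_a

    raise InvalidInputError(f"unknown action space {space!r}")


# ---------------------------------------------------------------------------
# stochastic policies and response likelihoods
# ---------------------------------------------------------------------------

def softmax_policy(risks: np.ndarray, temperature: float) -> np.ndarray:
    """Choice probabilities p_i proportional to exp(-risk_i / temperature)."""
    risks = np.asarray(risks, dtype=float)
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    if np.all(np.isinf(risks)):
        raise InvalidInputError("all risks are infinite")
    if np.any(np.isnan(risks)):
        raise InvalidInputError("risks contain NaN")
    return softmax(-risks / temperature)


@dataclass
class ResponseModelSpec:
    """The experimenter's model of measured responses.

    ``observation_map(belief, phi)`` predicts the response vector from the
    subject's current representation.  ``residual_covariance`` is a fixed SPD
    matrix, or the string 'estimated' when the residual variance is a noise
    hyperparameter optimized during inversion.  ``likelihood`` selects the
    channel type: 'gaussian' (additive residual, continuous responses) or
    'softmax' (discrete choice with risk-scaled logit noise, in which case
    ``loss`` and ``temperature(phi)`` define the per-action risks).
    ``phi_transform`` maps unconstrained estimates to the natural scale.
    ``predict_fast`` is an optional vectorized map
    ``(theta, phi, TrialData) -> (T, response_dim)`` used by the inversion as
    a fast equivalent of recognition + observation mapping.
    """

    loss: Optional[LossSpec]
    observation_map: Callable[[Belief, np.ndarray], np.ndarray]
    residual_covariance: Union[np.ndarray, str]
    response_dim: int
    likelihood: str = "gaussian"
    phi_names: Sequence[str] = ()
    phi_transform: Sequence[str] = ()
    temperature: Optional[Callable[[np.ndarray], float]] = None
    recognition_scope: str = "sequential"  # or 'per_trial'
    predict_fast: Optional[Callable] = None

    def __post_init__(self):
        if not self.phi_transform:
            self.phi_transform = tuple("identity" for _ in self.phi_names)
        if isinstance(self.residual_covariance, np.ndarray):
            cov = self.residual_covariance
            if cov.shape != (self.response_dim, self.response_dim):
                raise InvalidInputError("residual covariance shape mismatch")
            if np.any(np.linalg.eigvalsh(0.5 * (cov + cov.T)) <= 0):
                raise CovarianceError("residual covariance must be positive definite")


def gaussian_loglik(residual: np.ndarray, covariance: np.ndarray) -> float:
    """Log density of a zero-mean Gaussian residual; raises on singular covariance."""
    residual = np.atleast_1d(np.asarray(residual, dtype=float))
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    sign, logdet = np.linalg.slogdet(covariance)
    if sign <= 0:
        raise CovarianceError("residual covariance is singular")
    sol = np.linalg.solve(covariance, residual)
    return float(-0.5 * residual @ sol - 0.5 * logdet - 0.5 * residual.size * _LOG_2PI)


def response_loglik(resp: ResponseModelSpec, belief: Belief, phi,
                    observed, noise_variance: float | None = None) -> float:
    """Log likelihood of one observed response given the current belief.

    Gaussian channels score the residual ``observed - g(belief, phi)``;
    softmax channels score the log choice probability of the observed action
    under risk-scaled logit noise.  Responses are conditionally independent
    given the representation, so trajectory log-likelihoods are per-trial sums.
    """
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    if resp.likelihood == "gaussian":
        observed = np.atleast_1d(np.asarray(observed, dtype=float))
        if observed.size != resp.response_dim:
            raise InvalidInputError(
                f"observed has dimension {observed.size}, expected {resp.response_dim}"
            )
        predicted = np.atleast_1d(np.asarray(resp.observation_map(belief, phi), dtype=float))
        if predicted.size != resp.response_dim:
            raise InvalidInputError("observation map returned wrong dimension")
        if isinstance(resp.residual_covariance, str):
            if noise_variance is None:
                raise InvalidInputError(
                    "residual covariance is 'estimated'; pass noise_variance"
                )
            cov = noise_variance * np.eye(resp.response_dim)
        else:
            cov = resp.residual_covariance
        mask = ~np.isnan(observed)
        if not mask.any():
            return 0.0
        return gaussian_loglik((observed - predicted)[mask], cov[np.ix_(mask, mask)])
    if resp.likelihood == "softmax":
        if resp.loss is None or not isinstance(resp.loss.action_space, FiniteSet):
            raise InvalidInputError("softmax likelihood needs a finite-action loss")
        actions = list(resp.loss.action_space.actions)
        risks = np.array([posterior_risk(resp.loss, belief, a, phi) for a in actions])
        temp = resp.temperature(phi) if resp.temperature is not None else 1.0
        logp = log_softmax(-risks / temp)
        try:
            idx = actions.index(observed)
        except ValueError as exc:
            raise InvalidInputError(f"observed action {observed!r} not in action set") from exc
        return float(logp[idx])
    raise InvalidInputError(f"unknown likelihood kind {resp.likelihood!r}")


def trajectory_loglik(resp: ResponseModelSpec, beliefs: Sequence[Belief], phi,
                      responses: Sequence, noise_variance: float | None = None) -> float:
    """Sum of per-trial response log-likelihoods (conditional independence)."""
    if len(beliefs) != len(responses):
        raise InvalidInputError("beliefs and responses must align")
    return float(sum(
        response_loglik(resp, b, phi, y, noise_variance=noise_variance)
        for b, y in zip(beliefs, responses)
    ))
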