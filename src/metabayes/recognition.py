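"""Subject-level recognition: sequential Laplace inversion of a perceptual model.

The subject is assumed to hold a generative (perceptual) model of its sensory
inputs — a prior over hidden states ``x`` and an input likelihood, both
parameterized by perceptual parameters ``theta`` — and to update a Gaussian
approximate posterior (the *representation* ``lambda_t``) after each input by
maximizing a free-energy bound.  Because the previous posterior is propagated
as the next prior (assumed-density filtering, exact within the Laplace
family), recognition is a Markovian state-space recursion
``lambda_t = f(lambda_{t-1}, u_t; theta)``: the current belief depends only on
the previous belief and the current input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import InvalidInputError, MetaBayesError, NumericalPrecisionError
from .vlaplace import LogJointSpec, laplace_fit

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PerceptualModelSpec:
    """The subject's generative model of sensory input.

    ``log_prior(x, theta)`` and ``log_likelihood(u, x, theta)`` are log
    densities over the hidden state ``x`` (length ``state_dim``).  Gradients /
    Hessians with respect to ``x`` are optional; when supplied, recognition
    steps use exact Newton updates.  ``theta_transform`` records, per
    parameter, how an unconstrained estimate maps to the natural scale
    ('identity' or 'exp'); recognition itself always runs on the natural scale.
    """

    log_prior: Callable[[np.ndarray, np.ndarray], float]
    log_likelihood: Callable[[np.ndarray, np.ndarray, np.ndarray], float]
    state_dim: int
    theta_names: Sequence[str]
    theta_transform: Sequence[str] = ()
    log_prior_grad: Optional[Callable] = None
    log_prior_hess: Optional[Callable] = None
    log_likelihood_grad: Optional[Callable] = None
    log_likelihood_hess: Optional[Callable] = None

    def __post_init__(self):
        if not self.theta_transform:
            self.theta_transform = tuple("identity" for _ in self.theta_names)
        if len(self.theta_transform) != len(self.theta_names):
            raise InvalidInputError("theta_transform length must match theta_names")

    def validate_theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        if theta.size != len(self.theta_names):
            raise InvalidInputError(
                f"theta has length {theta.size}, expected {len(self.theta_names)}"
            )
        if not np.all(np.isfinite(theta)):
            raise InvalidInputError("theta contains non-finite values")
        return theta


@dataclass
class Belief:
    """The representation lambda_t: moments of the subject's approximate posterior.

    ``perceptual_free_energy`` accumulates the per-step Laplace evidence
    increments, so along a trajectory it approximates the log marginal
    likelihood of all inputs seen so far (exactly, for conjugate-Gaussian
    models).  Trial 0 is the prior, with free energy 0 by convention.
    """

    trial: int
    mode: np.ndarray
    covariance: np.ndarray
    perceptual_free_energy: float
    converged: bool = True

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


def prior_belief(model: PerceptualModelSpec, theta: np.ndarray,
                 init: np.ndarray | None = None) -> Belief:
    """Laplace fit of the prior alone: the subject's belief before any input."""
    theta = model.validate_theta(theta)
    target = LogJointSpec(
        evaluate=lambda x: model.log_prior(x, theta),
        dimension=model.state_dim,
        gradient=(lambda x: model.log_prior_grad(x, theta)) if model.log_prior_grad else None,
        hessian=(lambda x: model.log_prior_hess(x, theta)) if model.log_prior_hess else None,
    )
    x0 = np.zeros(model.state_dim) if init is None else np.asarray(init, dtype=float)
    fit = laplace_fit(target, x0)
    return Belief(trial=0, mode=fit.mode, covariance=fit.covariance,
                  perceptual_free_energy=0.0, converged=fit.converged)


def _gaussian_logpdf(x: np.ndarray, mean: np.ndarray, precision: np.ndarray,
                     logdet_cov: float) -> float:
    r = x - mean
    return float(-0.5 * r @ precision @ r - 0.5 * logdet_cov - 0.5 * r.size * _LOG_2PI)


def recognise_step(model: PerceptualModelSpec, prev: Belief, input: np.ndarray,
                   theta: np.ndarray) -> Belief:
    """One belief update: the previous posterior becomes the prior (Markov step).

    Fits ``log_likelihood(u, x, theta) + log N(x; prev.mode, prev.covariance)``
    by Laplace, warm-started at ``prev.mode``.  The free-energy increment
    approximates ``log p(u_t | u_{1:t-1})`` and is accumulated.
    """
    theta = model.validate_theta(theta)
    u = np.atleast_1d(np.asarray(input, dtype=float))
    prec_prev = np.linalg.inv(prev.covariance)
    sign, logdet_prev = np.linalg.slogdet(prev.covariance)

    def evaluate(x: np.ndarray) -> float:
        return float(model.log_likelihood(u, x, theta)) + _gaussian_logpdf(
            x, prev.mode, prec_prev, logdet_prev
        )

    gradient = None
    hessian = None
    if model.log_likelihood_grad is not None:
        gradient = lambda x: (
            np.atleast_1d(model.log_likelihood_grad(u, x, theta))
            - prec_prev @ (x - prev.mode)
        )
    if model.log_likelihood_hess is not None:
        hessian = lambda x: (
            np.atleast_2d(model.log_likelihood_hess(u, x, theta)) - prec_prev
        )

    target = LogJointSpec(evaluate=evaluate, dimension=model.state_dim,
                          gradient=gradient, hessian=hessian)
    fit = laplace_fit(target, prev.mode)
    if not fit.converged:
        logger.warning("recognition step at trial %d did not converge", prev.trial + 1)
    return Belief(
        trial=prev.trial + 1,
        mode=fit.mode,
        covariance=fit.covariance,
        perceptual_free_energy=prev.perceptual_free_energy + fit.free_energy,
        converged=fit.converged,
    )


def recognise_sequence(model: PerceptualModelSpec, inputs: Sequence[np.ndarray],
                       theta: np.ndarray,
                       init_belief: Belief | None = None) -> list[Belief]:
    """Run recognition over a sequence of inputs; returns [prior, b_1, ..., b_T]."""
    if len(inputs) == 0:
        raise InvalidInputError("inputs must be non-empty")
    belief = prior_belief(model, theta) if init_belief is None else init_belief
    trajectory = [belief]
    for t, u in enumerate(inputs):
        try:
            belief = recognise_step(model, belief, u, theta)
        except MetaBayesError as exc:
            raise type(exc)(f"trial {t}: {exc}") from exc
        trajectory.append(belief)
    return trajectory


def evolution_jacobian(model: PerceptualModelSpec, prev: Belief, input: np.ndarray,
                       theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Sensitivity of the updated belief mode to the previous belief mode.

    Central finite differences of ``recognise_step``'s mode with respect to
    ``prev.mode``.  For conjugate-Gaussian models this equals
    prior-precision x posterior-covariance, i.e. learning carries over in
    proportion to the remaining posterior uncertainty.
    """
    d = prev.mode.size
    J = np.empty((d, d))
    for j in range(d):
        h = rel_step * (1.0 + abs(prev.mode[j]))
        if h == 0.0 or prev.mode[j] + h == prev.mode[j]:
            raise NumericalPrecisionError("finite-difference step underflowed")
        bp = Belief(prev.trial, prev.mode.copy(), prev.covariance,
                    prev.perceptual_free_energy)
        bm = Belief(prev.trial, prev.mode.copy(), prev.covariance,
                    prev.perceptual_free_energy)
        bp.mode[j] += h
        bm.mode[j] -= h
        mode_p = recognise_step(model, bp, input, theta).mode
        mode_m = recognise_step(model, bm, input, theta).mode
        J[:, j] = (mode_p - mode_m) / (2.0 * h)
    return J
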