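"""Closed-form toy observer: estimating a signal mean under a sampling cost.

The task: a subject must report the mean ``x`` of a unit-variance Gaussian
signal using as few samples as possible.  Their perceptual model is

    x ~ N(prior_mean, 1/beta),      u_i | x ~ N(x, 1),   i = 1..n,

with prior precision ``beta`` the (single) perceptual parameter.  The loss
trades estimation accuracy against a linear sampling cost with weight ``k``:

    l(a_hat, n, x) = (a_hat - x)^2 + k * n,

so the posterior risk after ``n`` samples, at estimator offset
``a_hat - mu_n``, is  offset^2 + 1/(beta + n) + k*n.  The optimal estimator is
always the posterior mean; the optimal sample size balances the marginal gain
in posterior precision against the sampling cost (brute-force minimization is
the binding definition here; the stationary point max(0, k^{-1/2} - beta) is
only an accelerator).  Everything is conjugate, so this module doubles as the
exact oracle for the generic recognition/decision machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decision import LossSpec, NonnegativeIntegers, ResponseModelSpec
from .errors import InvalidInputError
from .recognition import PerceptualModelSpec

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ToyObserverConfig:
    """Ground-truth observer for the sampling task.

    beta : prior precision of the signal mean (perceptual parameter theta).
    k : per-sample cost weight (response parameter phi).
    sigma2 : response residual variance shared by both response channels
        (reported estimate, chosen sample size); per-channel overrides via
        ``sigma2_estimate`` / ``sigma2_n``.
    signal_variance : known to the subject; unity in the task definition.
    """

    beta: float
    k: float
    sigma2: float
    prior_mean: float = 0.0
    signal_variance: float = 1.0
    sigma2_estimate: float | None = None
    sigma2_n: float | None = None

    def __post_init__(self):
        if self.beta <= 0 or self.k <= 0:
            raise InvalidInputError("beta and k must be positive")
        if self.sigma2 < 0:
            raise InvalidInputError("sigma2 must be nonnegative")
        if self.signal_variance <= 0:
            raise InvalidInputError("signal_variance must be positive")

    @property
    def channel_variances(self) -> tuple[float, float]:
        est = self.sigma2 if self.sigma2_estimate is None else self.sigma2_estimate
        n = self.sigma2 if self.sigma2_n is None else self.sigma2_n
        return float(est), float(n)


def toy_posterior(beta: float, prior_mean: float,
                  samples: Sequence[float]) -> tuple[float, float, float]:
    """Conjugate posterior over the signal mean after ``samples``.

    Returns (posterior mean, posterior precision, exact log marginal
    likelihood of the samples).  Precision grows linearly with the number of
    samples: beta + n.
    """
    if beta <= 0:
        raise InvalidInputError("beta must be positive")
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    precision = beta + n
    # no-data identity kept exact (avoids beta*m0/beta rounding)
    mean = prior_mean if n == 0 else (beta * prior_mean + samples.sum()) / precision
    # exact evidence via the chain of one-step-ahead predictives
    log_evidence = 0.0
    m, p = prior_mean, beta
    for u in samples:
        pred_var = 1.0 + 1.0 / p
        log_evidence += -0.5 * (u - m) ** 2 / pred_var - 0.5 * np.log(pred_var) - 0.5 * _LOG_2PI
        m = (p * m + u) / (p + 1.0)
        p += 1.0
    return float(mean), float(precision), float(log_evidence)


def toy_risk(config: ToyObserverConfig, n: int, estimator_offset: float = 0.0) -> float:
    """Posterior risk after n samples at estimator offset a_hat - mu_n."""
    if n < 0:
        raise InvalidInputError("n must be nonnegative")
    return float(estimator_offset**2 + 1.0 / (config.beta + n) + config.k * n)


def toy_optimal_n(beta: float, k: float) -> int:
    """Integer sample size minimizing 1/(beta+n) + k*n.

    Evaluates the continuous stationary point max(0, k^{-1/2} - beta) and
    compares its floor/ceiling neighbours and 0; agrees with brute force
    (ties break to the smaller n).
    """
    if beta <= 0 or k <= 0:
        raise InvalidInputError("beta and k must be positive")
    n_c = max(0.0, k**-0.5 - beta)
    candidates = sorted({0, int(np.floor(n_c)), int(np.ceil(n_c))})
    risk = lambda n: 1.0 / (beta + n) + k * n
    best = candidates[0]
    for c in candidates[1:]:
        if risk(c) < risk(best) - 0.0:
            best = c
    return int(best)


def toy_optimal_n_bruteforce(beta: float, k: float, n_max: int = 1000) -> int:
    """Exhaustive minimizer over n in 0..n_max (independent check of toy_optimal_n)."""
    ns = np.arange(n_max + 1)
    risks = 1.0 / (beta + ns) + k * ns
    return int(np.argmin(risks))


def toy_response_map(config: ToyObserverConfig, signal_mean: float,
                     samples: Sequence[float]) -> tuple[float, int]:
    """Deterministic subject response: (reported estimate, chosen sample size).

    The subject samples n* = toy_optimal_n(beta, k) draws and reports the
    posterior mean, which minimizes the risk at any n (offset 0).  Response
    noise is added by the simulator, not here.
    """
    n_star = toy_optimal_n(config.beta, config.k)
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < n_star:
        raise InvalidInputError(
            f"need at least n*={n_star} samples, got {samples.size}"
        )
    mean, _, _ = toy_posterior(config.beta, config.prior_mean, samples[:n_star])
    return float(mean), int(n_star)


# ---------------------------------------------------------------------------
# specs plugging the toy observer into the generic machinery
# ---------------------------------------------------------------------------

def toy_perceptual_model(prior_mean: float = 0.0,
                         signal_variance: float = 1.0) -> PerceptualModelSpec:
    """PerceptualModelSpec for the toy task; theta = [beta] on the natural scale."""
    inv_sv = 1.0 / signal_variance

    def log_prior(x, theta):
        beta = theta[0]
        return float(-0.5 * beta * (x[0] - prior_mean) ** 2
                     + 0.5 * np.log(beta) - 0.5 * _LOG_2PI)

    def log_prior_grad(x, theta):
        return np.array([-theta[0] * (x[0] - prior_mean)])

    def log_prior_hess(x, theta):
        return np.array([[-theta[0]]])

    def log_likelihood(u, x, theta):
        u = np.atleast_1d(u)
        return float(-0.5 * inv_sv * np.sum((u - x[0]) ** 2)
                     - 0.5 * u.size * (np.log(signal_variance) + _LOG_2PI))

    def log_likelihood_grad(u, x, theta):
        u = np.atleast_1d(u)
        return np.array([inv_sv * np.sum(u - x[0])])

    def log_likelihood_hess(u, x, theta):
        return np.array([[-inv_sv * np.atleast_1d(u).size]])

    return PerceptualModelSpec(
        log_prior=log_prior,
        log_likelihood=log_likelihood,
        state_dim=1,
        theta_names=("beta",),
        theta_transform=("exp",),
        log_prior_grad=log_prior_grad,
        log_prior_hess=log_prior_hess,
        log_likelihood_grad=log_likelihood_grad,
        log_likelihood_hess=log_likelihood_hess,
    )


def smoothed_sample_size(beta: float, k: float) -> float:
    """Softplus relaxation of the optimal sample size, softplus(k^{-1/2} - beta).

    Coincides with max(0, k^{-1/2} - beta) to within log(2)*exp(-|z|) and is
    differentiable everywhere, which the gradient-based inversion requires
    (the integer argmin is piecewise constant in (beta, k)).  Whenever
    k^{-1/2} - beta is a nonnegative integer n — as at all study conditions —
    the relaxation matches the integer optimum to exp(-n), i.e. < 1e-3 for
    n >= 7.
    """
    z = k**-0.5 - beta
    return float(np.logaddexp(0.0, z))


def toy_sampling_loss(beta: float) -> LossSpec:
    """The sample-size decision as a LossSpec: risk(n) = 1/(beta+n) + k*n.

    The ex-ante risk of committing to n samples under the prior belief; used
    to drive decision.optimal_action over the nonnegative integers (phi = [k]).
    """

    def evaluate(n, x, phi):  # pragma: no cover - risk supplied in closed form
        raise NotImplementedError("use the closed-form risk")

    def risk(belief, n, phi):
        return 1.0 / (beta + float(n)) + phi[0] * float(n)

    return LossSpec(
        evaluate=evaluate,
        action_space=NonnegativeIntegers(upper=10**6),
        phi_names=("k",),
        risk_closed_form=risk,
    )


def toy_estimation_loss(config: ToyObserverConfig) -> LossSpec:
    """Joint loss l((a_hat, n), x; k) = (a_hat - x)^2 + k*n with closed-form risk."""

    def evaluate(action, x, phi):
        a_hat, n = action
        return float((a_hat - x[0]) ** 2 + phi[0] * n)

    def risk(belief, action, phi):
        a_hat, n = action
        offset = a_hat - belief.mode[0]
        return float(offset**2 + belief.covariance[0, 0] + phi[0] * n)

    from .decision import ContinuousBox

    return LossSpec(
        evaluate=evaluate,
        action_space=ContinuousBox(),
        phi_names=("k",),
        risk_closed_form=risk,
    )


def toy_response_model(config: ToyObserverConfig) -> ResponseModelSpec:
    """ResponseModelSpec for the toy task; phi = [k], both channels Gaussian.

    Channel 0 is the reported estimate: the terminal belief mode.  Channel 1
    is the chosen sample size, predicted by the smoothed optimal sample size;
    the prior precision beta is recovered from the terminal belief as
    (posterior precision) - (number of unit-precision samples seen), which is
    exact in this conjugate model.
    """
    v_est, v_n = config.channel_variances

    def observation_map(belief, phi):
        k = phi[0]
        beta = belief.precision[0, 0] - belief.trial
        return np.array([belief.mode[0], smoothed_sample_size(beta, k)])

    def predict_fast(theta, phi, data):
        beta, k = theta[0], phi[0]
        n_pred = smoothed_sample_size(beta, k)
        out = np.empty((len(data.inputs), 2))
        for t, u in enumerate(data.inputs):
            u = np.asarray(u, dtype=float).ravel()
            out[t, 0] = (beta * config.prior_mean + u.sum()) / (beta + u.size)
            out[t, 1] = n_pred
        return out

    return ResponseModelSpec(
        loss=toy_estimation_loss(config),
        observation_map=observation_map,
        residual_covariance=(np.diag([v_est, v_n]) if config.sigma2 > 0 else "estimated"),
        response_dim=2,
        likelihood="gaussian",
        phi_names=("k",),
        phi_transform=("exp",),
        recognition_scope="per_trial",
        predict_fast=predict_fast,
    )
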