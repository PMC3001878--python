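"""Experimenter-level inversion: observing the observer.

The experimenter embeds the subject's recognition process in a generative
model of trial-wise responses: unconstrained parameters eta = (theta, phi)
(perceptual and response parameters, positive ones on the log scale) map —
through recognition and an observation function — to predicted responses,
which differ from observed responses by Gaussian residuals.  Fitting this
response model by variational Laplace yields

* a Gaussian posterior q(theta, phi) over the subject's prior beliefs and
  loss-function parameters (mode by penalized least squares, covariance from
  the curvature including the prior precision),
* a response free energy F — a lower bound on the log model evidence with a
  built-in complexity penalty — used to compare competing observer models,
* diagnostics: identifiability (posterior correlations) and the subject's
  belief reconstructed with the experimenter's own uncertainty folded in,
  which inflates the subject's credible intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .decision import ResponseModelSpec, gaussian_loglik
from .errors import (
    ConvergenceError,
    IllPosedError,
    InvalidInputError,
    MetaBayesError,
)
from .recognition import Belief, PerceptualModelSpec, prior_belief, recognise_step
from .vlaplace import LogJointSpec, fit_with_hyperparameters, laplace_fit

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class TrialData:
    """Aligned trial-wise inputs and responses.

    ``inputs[t]`` is the sensory input vector of trial ``t`` (possibly ragged
    across trials); ``responses[t]`` is the observed response vector, with NaN
    marking missing channels.  ``meta`` records provenance (seed, generator
    settings, ground truth for simulations).
    """

    inputs: list
    responses: list
    labels: Optional[Sequence[str]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inputs = [np.atleast_1d(np.asarray(u, dtype=float)) for u in self.inputs]
        self.responses = [np.atleast_1d(np.asarray(y, dtype=float)) for y in self.responses]
        if len(self.inputs) != len(self.responses):
            raise InvalidInputError("inputs and responses must have equal length")
        if len(self.inputs) < 1:
            raise InvalidInputError("need at least one trial")

    @property
    def n_trials(self) -> int:
        return len(self.inputs)

    def response_matrix(self) -> np.ndarray:
        return np.vstack([y for y in self.responses])


@dataclass
class ParameterPrior:
    """Gaussian prior over the unconstrained (theta, phi) vector.

    Positive parameters are estimated on the log scale, so 'non-informative'
    priors are realized as proper wide Gaussians (the free-energy complexity
    term requires proper prior expectations).  ``noise_hyperprior`` is either
    'fixed' (known residual covariance) or an inverse-gamma-like
    (shape, scale) pair for the residual variance.
    """

    mean: np.ndarray
    covariance: np.ndarray
    names: Sequence[str] = ()
    noise_hyperprior: object = "fixed"

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise InvalidInputError("prior covariance shape mismatch")
        if np.any(np.linalg.eigvalsh(0.5 * (self.covariance + self.covariance.T)) <= 0):
            raise InvalidInputError("prior covariance must be positive definite")

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


@dataclass
class InversionOptions:
    tol: float = 1e-8
    grad_tol: float = 1e-6
    max_iter: int = 100
    n_starts: int = 5
    seed: int = 0
    store_beliefs: bool = True
    sigma2_init: float = 1.0
    noise_bounds: tuple = (1e-8, 1e6)
    hyper_tol: float = 1e-6


@dataclass
class ExperimenterPosterior:
    """Approximate posterior q(theta, phi) plus everything needed downstream."""

    mode: np.ndarray
    covariance: np.ndarray
    free_energy: float
    residuals: list
    noise_variance: float
    belief_trajectory_at_mode: Optional[list]
    param_names: Sequence[str]
    loglik: float
    hyper_log_prior: float
    prior_mean: np.ndarray
    prior_covariance: np.ndarray
    settings: dict = field(default_factory=dict)
    converged: bool = True

    def posterior_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    # -- JSON round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        beliefs = None
        if self.belief_trajectory_at_mode is not None:
            beliefs = [
                {
                    "trial": b.trial,
                    "mode": b.mode.tolist(),
                    "covariance": b.covariance.tolist(),
                    "perceptual_free_energy": b.perceptual_free_energy,
                    "converged": bool(b.converged),
                }
                for b in self.belief_trajectory_at_mode
            ]
        return {
            "mode": self.mode.tolist(),
            "covariance": self.covariance.tolist(),
            "free_energy": self.free_energy,
            "residuals": [r.tolist() for r in self.residuals],
            "noise_variance": self.noise_variance,
            "beliefs": beliefs,
            "param_names": list(self.param_names),
            "loglik": self.loglik,
            "hyper_log_prior": self.hyper_log_prior,
            "prior_mean": self.prior_mean.tolist(),
            "prior_covariance": self.prior_covariance.tolist(),
            "settings": self.settings,
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimenterPosterior":
        beliefs = None
        if d.get("beliefs") is not None:
            beliefs = [
                Belief(
                    trial=b["trial"],
                    mode=np.asarray(b["mode"], dtype=float),
                    covariance=np.asarray(b["covariance"], dtype=float),
                    perceptual_free_energy=b["perceptual_free_energy"],
                    converged=b.get("converged", True),
                )
                for b in d["beliefs"]
            ]
        return cls(
            mode=np.asarray(d["mode"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            free_energy=d["free_energy"],
            residuals=[np.asarray(r, dtype=float) for r in d["residuals"]],
            noise_variance=d["noise_variance"],
            belief_trajectory_at_mode=beliefs,
            param_names=d["param_names"],
            loglik=d["loglik"],
            hyper_log_prior=d["hyper_log_prior"],
            prior_mean=np.asarray(d["prior_mean"], dtype=float),
            prior_covariance=np.asarray(d["prior_covariance"], dtype=float),
            settings=d.get("settings", {}),
            converged=d.get("converged", True),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ExperimenterPosterior":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ComparisonResult:
    model_ids: Sequence[str]
    free_energies: np.ndarray
    posterior_model_probabilities: np.ndarray
    posteriors: Optional[list] = None


# ---------------------------------------------------------------------------
# parameter transforms and prediction
# ---------------------------------------------------------------------------

def _to_natural(values: np.ndarray, transforms: Sequence[str]) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    for i, tr in enumerate(transforms):
        if tr == "exp":
            out[i] = np.exp(out[i])
        elif tr != "identity":
            raise InvalidInputError(f"unknown transform {tr!r}")
    return out


def _split_eta(eta, perc, resp):
    nt = len(perc.theta_names)
    theta = _to_natural(eta[:nt], perc.theta_transform)
    phi = _to_natural(eta[nt:], resp.phi_transform)
    return theta, phi


def _belief_for_trial(perc: PerceptualModelSpec, data: TrialData, theta: np.ndarray,
                      scope: str, trial: int) -> Belief:
    """Subject belief relevant to a given trial at perceptual parameters theta."""
    if scope == "per_trial":
        belief = prior_belief(perc, theta)
        for u in np.atleast_1d(data.inputs[trial]):
            belief = recognise_step(perc, belief, np.atleast_1d(u), theta)
        return belief
    belief = prior_belief(perc, theta)
    for t in range(trial + 1):
        belief = recognise_step(perc, belief, data.inputs[t], theta)
    return belief


def predict_responses(perc: PerceptualModelSpec, resp: ResponseModelSpec,
                      data: TrialData, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Predicted response matrix (T, response_dim) at natural-scale parameters.

    Uses the response model's vectorized fast path when present; otherwise
    runs generic recognition (per-trial or sequential scope) and applies the
    observation map to each trial's belief.
    """
    if resp.predict_fast is not None:
        return np.asarray(resp.predict_fast(theta, phi, data), dtype=float)
    T = data.n_trials
    out = np.empty((T, resp.response_dim))
    if resp.recognition_scope == "per_trial":
        for t in range(T):
            belief = _belief_for_trial(perc, data, theta, "per_trial", t)
            out[t] = resp.observation_map(belief, phi)
    else:
        belief = prior_belief(perc, theta)
        for t in range(T):
            belief = recognise_step(perc, belief, data.inputs[t], theta)
            out[t] = resp.observation_map(belief, phi)
    return out


# ---------------------------------------------------------------------------
# the inversion itself
# ---------------------------------------------------------------------------

def _channel_variances(resp: ResponseModelSpec, sigma2: float) -> np.ndarray:
    if isinstance(resp.residual_covariance, str):
        return np.full(resp.response_dim, float(sigma2))
    cov = resp.residual_covariance
    if not np.allclose(cov, np.diag(np.diag(cov))):
        return None  # full covariance: caller uses gaussian_loglik per trial
    return np.diag(cov).astype(float)


def _data_loglik(resp: ResponseModelSpec, observed: np.ndarray, predicted: np.ndarray,
                 sigma2: float) -> float:
    """Gaussian response log-likelihood over all observed (non-NaN) entries."""
    mask = ~np.isnan(observed)
    if not mask.any():
        return 0.0
    resid = observed - predicted
    variances = _channel_variances(resp, sigma2)
    if variances is not None:
        var = np.broadcast_to(variances, observed.shape)
        r = resid[mask]
        v = var[mask]
        return float(-0.5 * np.sum(r * r / v) - 0.5 * np.sum(np.log(2.0 * np.pi * v)))
    total = 0.0
    cov = resp.residual_covariance
    for t in range(observed.shape[0]):
        m = mask[t]
        if m.any():
            total += gaussian_loglik(resid[t][m], cov[np.ix_(m, m)])
    return float(total)


def invert(perc: PerceptualModelSpec, resp: ResponseModelSpec, data: TrialData,
           prior: ParameterPrior, options: InversionOptions | None = None
           ) -> ExperimenterPosterior:
    """Fit the response model to observed behaviour by variational Laplace.

    Maximizes ``log p(y | eta) + log p(eta)`` — a regularized sum of squared
    residuals for Gaussian channels — over the unconstrained parameters, with
    multistart from the prior; the posterior covariance is the inverse
    curvature including the prior precision.  When the prior declares a noise
    hyperprior, the residual variance is point-optimized by alternating with
    the parameter fit (and excluded from the parameter covariance).
    """
    options = options or InversionOptions()
    dim = prior.mean.size
    n_expected = len(perc.theta_names) + len(resp.phi_names)
    if dim != n_expected:
        raise InvalidInputError(
            f"prior dimension {dim} != n_theta + n_phi = {n_expected}"
        )

    observed = data.response_matrix()
    n_obs = int(np.sum(~np.isnan(observed)))
    if n_obs < dim and np.any(np.diag(prior.covariance) > 1e10):
        raise IllPosedError(
            "fewer observed responses than parameters with effectively improper "
            "priors; supply proper (finite-variance) priors to regularize the "
            "inverse decision-theoretic problem"
        )

    prior_prec = prior.precision
    sign, prior_logdet = np.linalg.slogdet(prior.covariance)

    def log_prior_pdf(eta: np.ndarray) -> float:
        d = eta - prior.mean
        return float(-0.5 * d @ prior_prec @ d - 0.5 * prior_logdet - 0.5 * dim * _LOG_2PI)

    estimate_noise = prior.noise_hyperprior != "fixed"
    if estimate_noise:
        shape, scale = prior.noise_hyperprior
    hyper_kernel = (
        (lambda s2: float(-(shape + 1.0) * np.log(s2) - scale / s2))
        if estimate_noise else (lambda s2: 0.0)
    )

    def build_target(sigma2: float) -> LogJointSpec:
        def evaluate(eta: np.ndarray) -> float:
            # extreme multistart draws may overflow; they score -inf, not raise
            with np.errstate(all="ignore"):
                try:
                    theta, phi = _split_eta(eta, perc, resp)
                    pred = predict_responses(perc, resp, data, theta, phi)
                except MetaBayesError as exc:
                    logger.debug("candidate penalized (-inf): %s", exc)
                    return -np.inf
                if not np.all(np.isfinite(pred)):
                    return -np.inf
                ll = _data_loglik(resp, observed, pred, sigma2)
            if not np.isfinite(ll):
                return -np.inf
            return ll + log_prior_pdf(eta) + hyper_kernel(sigma2)

        return LogJointSpec(evaluate=evaluate, dimension=dim)

    rng = np.random.default_rng(options.seed)
    chol = np.linalg.cholesky(prior.covariance)
    starts = [prior.mean.copy()]
    for _ in range(max(0, options.n_starts - 1)):
        starts.append(prior.mean + chol @ rng.standard_normal(dim))

    best = None
    best_sigma2 = options.sigma2_init
    for j, start in enumerate(starts):
        try:
            if estimate_noise:
                fit, s2 = fit_with_hyperparameters(
                    build_target, start, hyper_init=options.sigma2_init,
                    tol=options.hyper_tol, hyper_bounds=options.noise_bounds,
                    max_iter=options.max_iter,
                )
            else:
                fit = laplace_fit(build_target(1.0), start, tol=options.tol,
                                  max_iter=options.max_iter, grad_tol=options.grad_tol)
                s2 = float("nan")
        except MetaBayesError as exc:
            logger.info("start %d failed: %s", j, exc)
            continue
        logger.debug("start %d: F=%.6f", j, fit.free_energy)
        if best is None or fit.free_energy > best.free_energy:
            best, best_sigma2 = fit, s2
    if best is None:
        raise ConvergenceError("all optimizer starts failed")

    theta, phi = _split_eta(best.mode, perc, resp)
    pred = predict_responses(perc, resp, data, theta, phi)
    residuals = [observed[t] - pred[t] for t in range(data.n_trials)]
    sigma2_eff = best_sigma2 if estimate_noise else 1.0
    loglik = _data_loglik(resp, observed, pred, sigma2_eff)
    if not estimate_noise:
        if isinstance(resp.residual_covariance, str):
            raise InvalidInputError(
                "residual covariance 'estimated' requires a noise hyperprior"
            )
        noise_variance = float(np.mean(np.diag(resp.residual_covariance)))
    else:
        noise_variance = float(best_sigma2)

    beliefs = None
    if options.store_beliefs:
        try:
            beliefs = [
                _belief_for_trial(perc, data, theta, resp.recognition_scope, t)
                for t in range(data.n_trials)
            ]
        except MetaBayesError as exc:  # pragma: no cover - diagnostic only
            logger.warning("could not store belief trajectory: %s", exc)

    return ExperimenterPosterior(
        mode=best.mode,
        covariance=best.covariance,
        free_energy=best.free_energy,
        residuals=residuals,
        noise_variance=noise_variance,
        belief_trajectory_at_mode=beliefs,
        param_names=list(prior.names) or (
            [f"theta:{n}" for n in perc.theta_names] + [f"phi:{n}" for n in resp.phi_names]
        ),
        loglik=loglik,
        hyper_log_prior=hyper_kernel(sigma2_eff) if estimate_noise else 0.0,
        prior_mean=prior.mean.copy(),
        prior_covariance=prior.covariance.copy(),
        settings={
            "recognition_scope": resp.recognition_scope,
            "n_starts": options.n_starts,
            "seed": options.seed,
            "noise": "estimated (point-optimized, excluded from covariance)"
            if estimate_noise else "fixed",
        },
        converged=best.converged,
    )


def response_free_energy(post: ExperimenterPosterior, prior: ParameterPrior) -> float:
    """Recompute the Laplace evidence bound from the fitted posterior.

    F = loglik(mode) - 1/2 (mode - prior mean)' P_prior (mode - prior mean)
        + 1/2 log det(Sigma_post P_prior), i.e. accuracy minus the complexity
    penalty for moving away from (and tightening relative to) the prior.
    """
    if post.mode.size != prior.mean.size:
        raise InvalidInputError("posterior/prior dimension mismatch")
    d = post.mode - prior.mean
    quad = float(d @ prior.precision @ d)
    _, logdet_post = np.linalg.slogdet(post.covariance)
    _, logdet_prior = np.linalg.slogdet(prior.covariance)
    return float(post.loglik + post.hyper_log_prior - 0.5 * quad
                 + 0.5 * (logdet_post - logdet_prior))


def compare_models(candidates: Sequence, data: TrialData,
                   options: InversionOptions | None = None,
                   model_ids: Sequence[str] | None = None,
                   keep_posteriors: bool = False) -> ComparisonResult:
    """Fit every (perceptual, response, prior) candidate and compare evidences.

    Posterior model probabilities are softmax(F) under uniform model priors
    (max-subtracted for stability); a candidate whose fit fails gets
    probability zero with the reason logged.
    """
    if len(candidates) < 2:
        raise InvalidInputError("need at least 2 candidate models")
    ids = list(model_ids) if model_ids else [f"model_{i}" for i in range(len(candidates))]
    free_energies = np.full(len(candidates), -np.inf)
    posteriors: list = []
    for i, (perc, resp, prior) in enumerate(candidates):
        try:
            post = invert(perc, resp, data, prior, options)
            free_energies[i] = post.free_energy
            posteriors.append(post)
        except MetaBayesError as exc:
            logger.warning("candidate %s failed: %s; assigned probability 0", ids[i], exc)
            posteriors.append(None)
    finite = np.isfinite(free_energies)
    probs = np.zeros(len(candidates))
    if finite.any():
        f = free_energies[finite]
        w = np.exp(f - f.max())
        probs[finite] = w / w.sum()
    return ComparisonResult(
        model_ids=ids,
        free_energies=free_energies,
        posterior_model_probabilities=probs,
        posteriors=posteriors if keep_posteriors else None,
    )


def reconstruct_subject_belief(post: ExperimenterPosterior, perc: PerceptualModelSpec,
                               data: TrialData, trial: int, level: float = 0.90,
                               rel_step: float = 1e-4
                               ) -> tuple[np.ndarray, np.ndarray, tuple]:
    """The subject's belief as seen through the experimenter's uncertainty.

    First-order propagation: the belief mean is evaluated at the parameter
    mode; its variance is the subject's own posterior variance there plus
    J Sigma_eta J', where J is the finite-difference sensitivity of the belief
    mode to the unconstrained parameters.  The returned credible interval
    (default two-sided 90%) is therefore never narrower than the subject's
    own — response noise inflates the experimenter's estimate of the
    subject's uncertainty.
    """
    if not 0 <= trial < data.n_trials:
        raise IndexError(f"trial {trial} out of range [0, {data.n_trials})")
    scope = post.settings.get("recognition_scope", "per_trial")
    nt = len(perc.theta_names)

    def belief_mode(eta: np.ndarray) -> np.ndarray:
        theta = _to_natural(eta[:nt], perc.theta_transform)
        return _belief_for_trial(perc, data, theta, scope, trial).mode

    theta_mode = _to_natural(post.mode[:nt], perc.theta_transform)
    belief = _belief_for_trial(perc, data, theta_mode, scope, trial)
    d_state = belief.mode.size
    n_par = post.mode.size
    J = np.zeros((d_state, n_par))
    for i in range(n_par):
        h = rel_step * (1.0 + abs(post.mode[i]))
        ep, em = post.mode.copy(), post.mode.copy()
        ep[i] += h
        em[i] -= h
        J[:, i] = (belief_mode(ep) - belief_mode(em)) / (2.0 * h)
    variance = belief.covariance + J @ post.covariance @ J.T
    z = float(norm.ppf(0.5 + level / 2.0))
    sd = np.sqrt(np.diag(variance))
    ci = (belief.mode - z * sd, belief.mode + z * sd)
    return belief.mode.copy(), variance, ci


@dataclass
class IdentifiabilityReport:
    correlation: np.ndarray
    flagged_pairs: list
    degenerate: list


def identifiability_report(post: ExperimenterPosterior,
                           threshold: float = 0.95) -> IdentifiabilityReport:
    """Posterior correlations between parameters; flags near-redundant pairs.

    Strong off-diagonal posterior correlation means the data cannot tell two
    parameters apart (they move predictions the same way) — the classic
    symptom of a weakly identified observer model.
    """
    sd = np.sqrt(np.diag(post.covariance))
    degenerate = [post.param_names[i] for i in range(sd.size) if not sd[i] > 0]
    corr = np.eye(sd.size)
    flagged = []
    for i in range(sd.size):
        for j in range(i + 1, sd.size):
            if sd[i] > 0 and sd[j] > 0:
                c = post.covariance[i, j] / (sd[i] * sd[j])
                corr[i, j] = corr[j, i] = c
                if abs(c) > threshold:
                    flagged.append((post.param_names[i], post.param_names[j], float(c)))
    return IdentifiabilityReport(correlation=corr, flagged_pairs=flagged,
                                 degenerate=degenerate)
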