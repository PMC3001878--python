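"""Variational Bayes under the Laplace approximation.

A small, generic engine for fitting a Gaussian approximation
``q(x) = N(mode, covariance)`` to an unnormalized log-density and for scoring
it with the Laplace free energy

    F = log h(mode) + 1/2 log det(covariance) + d/2 log 2*pi,

which approximates (and, for log-quadratic ``h``, equals) the log normalizer
``log Z = log \\int h(x) dx``.  The same engine serves two roles in this
package: recognition (the subject's trial-wise posterior over hidden states)
and response-model inversion (the experimenter's posterior over model
parameters).  The optimizer is a damped Newton ascent: exact derivatives when
the caller supplies them, central finite differences otherwise, with
step-halving so the objective sequence is non-decreasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateCurvatureError, InvalidInputError

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))

# Finite-difference steps, relative to 1+|x|.  The Hessian step is larger than
# the gradient step: second differences lose ~eps/h^2 to cancellation, and
# 3e-4 keeps that below 1e-9 for O(1) objectives while second differences of
# quadratics stay exact.
GRAD_REL_STEP = 1e-5
HESS_REL_STEP = 3e-4


@dataclass
class GaussianApprox:
    """Gaussian approximation to a density: sufficient statistics + evidence bound.

    Attributes
    ----------
    mode : (d,) array — first-order moment (posterior mode).
    covariance : (d, d) array — symmetric positive-definite second-order moment.
    free_energy : float — Laplace bound on the log normalizer, in nats.
    converged : bool — whether the optimizer met its tolerance.
    n_iter : int — Newton iterations used.
    """

    mode: np.ndarray
    covariance: np.ndarray
    free_energy: float
    converged: bool
    n_iter: int
    objective_history: list = field(default_factory=list)

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


@dataclass
class LogJointSpec:
    """An unnormalized log joint density to be approximated.

    ``evaluate`` maps a length-``dimension`` vector to a float; ``-inf``
    signals zero density.  ``gradient``/``hessian`` are optional exact
    derivatives; central finite differences are used when absent.
    """

    evaluate: Callable[[np.ndarray], float]
    dimension: int
    gradient: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hessian: Optional[Callable[[np.ndarray], np.ndarray]] = None


def _fd_gradient(f: Callable, x: np.ndarray, rel_step: float = GRAD_REL_STEP) -> np.ndarray:
    g = np.empty_like(x, dtype=float)
    for i in range(x.size):
        h = rel_step * (1.0 + abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def _fd_hessian(f: Callable, x: np.ndarray, rel_step: float = HESS_REL_STEP) -> np.ndarray:
    d = x.size
    H = np.empty((d, d), dtype=float)
    steps = np.array([rel_step * (1.0 + abs(x[i])) for i in range(d)])
    f0 = f(x)
    for i in range(d):
        hi = steps[i]
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / hi**2
    for i in range(d):
        for j in range(i + 1, d):
            hi, hj = steps[i], steps[j]
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[i, j]] += [hi, hj]
            xpm[i] += hi
            xpm[j] -= hj
            xmp[i] -= hi
            xmp[j] += hj
            xmm[[i, j]] -= [hi, hj]
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * hi * hj)
    return H


def _symmetrize(H: np.ndarray) -> np.ndarray:
    return 0.5 * (H + H.T)


def _safe_inverse(A: np.ndarray, context: str = "") -> np.ndarray:
    """Invert a nominally positive-definite matrix, jittering if ill-conditioned."""
    A = _symmetrize(A)
    eigvals = np.linalg.eigvalsh(A)
    if eigvals[0] <= 0.0:
        raise DegenerateCurvatureError(-eigvals[0])
    cond = eigvals[-1] / eigvals[0]
    if cond > 1e12:
        jitter = 1e-10 * np.trace(A) / A.shape[0]
        logger.warning(
            "%scondition number %.3g > 1e12; adding jitter %.3g", context, cond, jitter
        )
        A = A + jitter * np.eye(A.shape[0])
    return _symmetrize(np.linalg.inv(A))


def laplace_free_energy(log_joint_at_mode: float, covariance: np.ndarray) -> float:
    """Laplace evidence bound from the log joint at the mode and the covariance."""
    sign, logdet = np.linalg.slogdet(covariance)
    if sign <= 0:
        raise DegenerateCurvatureError(sign, "covariance has non-positive determinant")
    d = covariance.shape[0]
    return float(log_joint_at_mode + 0.5 * logdet + 0.5 * d * _LOG_2PI)


def laplace_fit(
    target: LogJointSpec,
    init: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    grad_tol: float = 1e-6,
    max_halvings: int = 32,
) -> GaussianApprox:
    """Fit a Gaussian to ``target`` by damped Newton ascent from ``init``.

    The mode is a local maximizer of ``target.evaluate``; the covariance is the
    inverse negative (symmetrized) Hessian at the mode; the free energy is the
    Laplace bound.  Step-halving guarantees the objective never decreases.
    Convergence: absolute objective change < ``tol`` or gradient sup-norm
    < ``grad_tol``.  Exceeding ``max_iter`` returns ``converged=False``.
    """
    x = np.atleast_1d(np.asarray(init, dtype=float)).copy()
    if x.size != target.dimension:
        raise InvalidInputError(
            f"init has length {x.size}, expected {target.dimension}"
        )
    f = float(target.evaluate(x))
    if not np.isfinite(f):
        raise InvalidInputError("objective is not finite at the initial point")
    history = [f]

    grad = target.gradient or (lambda z: _fd_gradient(target.evaluate, z))
    hess = target.hessian or (lambda z: _fd_hessian(target.evaluate, z))

    converged = False
    n_iter = 0
    from .errors import NumericalPrecisionError

    for n_iter in range(1, max_iter + 1):
        g = np.atleast_1d(np.asarray(grad(x), dtype=float))
        if not np.all(np.isfinite(g)):
            raise NumericalPrecisionError(
                "gradient not finite (finite differences reached a zero-density region)"
            )
        if np.max(np.abs(g)) < grad_tol:
            converged = True
            break
        H = _symmetrize(np.atleast_2d(np.asarray(hess(x), dtype=float)))
        if not np.all(np.isfinite(H)):
            raise NumericalPrecisionError("Hessian not finite")
        A = -H
        # Regularize indefinite curvature for the step only (Levenberg shift).
        eigmin = float(np.linalg.eigvalsh(A)[0])
        if eigmin <= 0.0:
            A = A + (abs(eigmin) + 1e-6 * (1.0 + abs(np.trace(A)) / A.shape[0])) * np.eye(
                A.shape[0]
            )
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError as exc:
            raise NumericalPrecisionError(f"Newton system singular: {exc}") from exc
        alpha = 1.0
        improved = False
        for _ in range(max_halvings + 1):
            x_new = x + alpha * step
            f_new = float(target.evaluate(x_new))
            if np.isfinite(f_new) and f_new >= f:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            # No uphill step along the Newton direction: treat as terminal.
            converged = np.max(np.abs(g)) < np.sqrt(grad_tol)
            break
        delta = f_new - f
        x, f = x_new, f_new
        history.append(f)
        if delta < tol:
            converged = True
            break
    else:
        converged = False

    H = _symmetrize(np.atleast_2d(np.asarray(hess(x), dtype=float)))
    A = -H
    eigvals = np.linalg.eigvalsh(A)
    if eigvals[0] <= 0.0:
        raise DegenerateCurvatureError(-eigvals[0])
    covariance = _safe_inverse(A, context="laplace_fit: ")
    free_energy = laplace_free_energy(f, covariance)
    return GaussianApprox(
        mode=x, covariance=covariance, free_energy=free_energy,
        converged=converged, n_iter=n_iter, objective_history=history,
    )


def fit_with_hyperparameters(
    target_builder: Callable[[float], LogJointSpec],
    init: np.ndarray,
    hyper_init: float,
    tol: float = 1e-6,
    max_outer: int = 50,
    hyper_bounds: tuple[float, float] = (1e-6, 1e8),
    optimize_hyper: bool = True,
    **laplace_kwargs,
) -> tuple[GaussianApprox, float]:
    """Alternate Laplace fits of the parameters with 1-D noise-level updates.

    ``target_builder(h)`` returns the log joint at noise hyperparameter
    ``h > 0`` (typically a residual variance).  The hyperparameter maximizes
    the Laplace free energy at the current mode, searched on the log scale to
    enforce positivity; the alternation stops when the free-energy change
    falls below ``tol``.  With ``optimize_hyper=False`` this reduces exactly
    to ``laplace_fit(target_builder(hyper_init), ...)``.
    """
    if hyper_init <= 0:
        raise InvalidInputError("hyper_init must be positive")
    h = float(hyper_init)
    fit = laplace_fit(target_builder(h), init, **laplace_kwargs)
    if not optimize_hyper:
        return fit, h

    lo, hi = np.log(hyper_bounds[0]), np.log(hyper_bounds[1])
    converged = False
    for _ in range(max_outer):
        mode = fit.mode

        def neg_f(log_h: float) -> float:
            t = target_builder(float(np.exp(log_h)))
            val = float(t.evaluate(mode))
            if not np.isfinite(val):
                return 1e300
            hess = t.hessian or (lambda z: _fd_hessian(t.evaluate, z))
            A = -_symmetrize(np.atleast_2d(np.asarray(hess(mode), dtype=float)))
            eigs = np.linalg.eigvalsh(A)
            if eigs[0] <= 0:
                return 1e300
            sign, logdet = np.linalg.slogdet(A)
            return -(val - 0.5 * logdet + 0.5 * A.shape[0] * _LOG_2PI)

        res = minimize_scalar(
            neg_f, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-9},
        )
        h = float(np.exp(res.x))
        new_fit = laplace_fit(target_builder(h), mode, **laplace_kwargs)
        if abs(new_fit.free_energy - fit.free_energy) < tol:
            fit = new_fit
            converged = True
            break
        fit = new_fit
    if not converged:
        logger.warning("hyperparameter alternation hit max_outer=%d", max_outer)
        fit = GaussianApprox(fit.mode, fit.covariance, fit.free_energy, False, fit.n_iter)
    if h <= hyper_bounds[0] * (1.0 + 1e-6) or h >= hyper_bounds[1] * (1.0 - 1e-6):
        warnings.warn(
            f"noise hyperparameter pinned at bound ({h:.3g}); "
            "residuals may be degenerate", RuntimeWarning,
        )
    return fit, h
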