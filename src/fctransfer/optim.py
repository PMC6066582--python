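"""Scaled conjugate gradient (SCG) minimization.

SCG (Møller, 1993) is a batch second-order-ish conjugate gradient method that
replaces the line search with a scalar model-trust-region mechanism: curvature
along the search direction is estimated by a one-sided finite difference of the
gradient, regularized by an adaptive Levenberg-Marquardt scale, and each step is
accepted or rejected from the comparison parameter Δ (ratio of actual to
predicted decrease).  It is the workhorse optimizer for every training stage in
this package: sparse-autoencoder pretraining, softmax-head fitting, and joint
fine-tuning.

One "epoch" of network training corresponds to one SCG iteration (one proposed
step, accepted or rejected); the optimizer is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import InvalidInputError, OptimizationError

__all__ = ["OptimResult", "scg_minimize", "gd_minimize"]

# Møller's recommended initial constants.
_SIGMA0 = 1e-4      # finite-difference step scale for curvature estimation
_LAMBDA0 = 1e-6     # initial trust-region (Levenberg-Marquardt) scale
_LAMBDA_MAX = 1e20  # beyond this the step size underflows; treat as stalled


@dataclass
class OptimResult:
    """Outcome of a deterministic batch minimization.

    Attributes
    ----------
    w_star : ndarray
        Final parameter vector.
    f_star : float
        Objective value at ``w_star``.
    n_iter : int
        Iterations used (accepted or rejected steps).
    converged : bool
        True iff the objective goal or the gradient tolerance was reached
        before ``max_iter``.
    trace : ndarray
        Objective value at the current iterate after each iteration
        (``trace[0]`` is the value at ``w0``); non-increasing.
    """

    w_star: np.ndarray
    f_star: float
    n_iter: int
    converged: bool
    trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def _check_finite_scalar(f: float, where: str) -> None:
    if not np.isfinite(f):
        raise OptimizationError(f"non-finite objective value at {where}")


def _check_finite_vec(g: np.ndarray, where: str) -> None:
    if not np.all(np.isfinite(g)):
        raise OptimizationError(f"non-finite gradient at {where}")


def scg_minimize(
    objective: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray],
    w0: np.ndarray,
    goal: float = 1e-5,
    max_iter: int = 1000,
    grad_tol: float = 1e-8,
) -> OptimResult:
    """Minimize ``objective`` starting from ``w0`` by scaled conjugate gradient.

    Stops at the first of: ``objective <= goal``, infinity-norm of the gradient
    below ``grad_tol``, or ``max_iter`` iterations.  The first two set
    ``converged=True``.

    Raises
    ------
    InvalidInputError
        If the objective or gradient is non-finite at ``w0``.
    OptimizationError
        If non-finite values appear mid-run (the message names the iteration).
    """
    if max_iter < 1:
        raise InvalidInputError("max_iter must be >= 1")
    w = np.array(w0, dtype=float).ravel().copy()
    f = float(objective(w))
    g = np.asarray(gradient(w), dtype=float).ravel()
    if not np.isfinite(f):
        raise InvalidInputError("objective is non-finite at w0")
    if g.shape != w.shape or not np.all(np.isfinite(g)):
        raise InvalidInputError("gradient is non-finite or mis-shaped at w0")

    trace = [f]
    r = -g
    if f <= goal or np.max(np.abs(r)) < grad_tol:
        return OptimResult(w, f, 0, True, np.asarray(trace))

    p = r.copy()
    success = True
    lam = _LAMBDA0
    lam_bar = 0.0
    delta = 0.0
    restart_period = max(w.size, 1)
    n_iter = 0
    converged = False

    for k in range(1, max_iter + 1):
        n_iter = k
        p_norm2 = float(p @ p)
        if p_norm2 <= 0.0:
            converged = True
            break
        mu = float(p @ r)
        if mu <= 0.0:
            # p lost the descent property (numerical drift); restart from the
            # steepest-descent direction and retry on the next iteration.
            p = r.copy()
            success = True
            trace.append(f)
            continue
        if success:
            sigma = _SIGMA0 / np.sqrt(p_norm2)
            g_probe = np.asarray(gradient(w + sigma * p), dtype=float).ravel()
            _check_finite_vec(g_probe, f"iteration {k} (curvature probe)")
            s = (g_probe - (-r)) / sigma
            delta = float(p @ s)

        # Scale the curvature estimate by the current trust-region parameter.
        delta = delta + (lam - lam_bar) * p_norm2
        if delta <= 0.0:  # make the Hessian model positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar

        alpha = mu / delta
        f_new = float(objective(w + alpha * p))
        _check_finite_scalar(f_new, f"iteration {k}")
        comparison = 2.0 * delta * (f - f_new) / (mu * mu)

        if comparison >= 0.0:  # accept the step
            w = w + alpha * p
            f = f_new
            g = np.asarray(gradient(w), dtype=float).ravel()
            _check_finite_vec(g, f"iteration {k} (post-step)")
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % restart_period == 0:
                p = r_new.copy()
            else:
                beta_cg = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta_cg * p
            r = r_new
            if comparison >= 0.75:
                lam = 0.25 * lam
        else:  # reject: raise the trust-region scale and retry
            lam_bar = lam
            success = False

        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2
        trace.append(f)

        if f <= goal or np.max(np.abs(r)) < grad_tol:
            converged = True
            break
        if lam > _LAMBDA_MAX:
            break  # step sizes underflowed; no further progress possible

    return OptimResult(w, f, n_iter, converged, np.asarray(trace))


def gd_minimize(
    objective: Callable[[np.ndarray], float],
    gradient: Callable[[np.ndarray], np.ndarray],
    w0: np.ndarray,
    goal: float = 1e-5,
    max_iter: int = 1000,
    step: float = 0.01,
    grad_tol: float = 1e-8,
) -> OptimResult:
    """Fixed-step gradient descent fallback (default step 0.01).

    Provided so that a literal constant-learning-rate backpropagation reading
    of the training procedure is runnable; SCG is the default everywhere.
    Unlike SCG, steps are not guarded against increases in the objective.
    """
    if max_iter < 1:
        raise InvalidInputError("max_iter must be >= 1")
    w = np.array(w0, dtype=float).ravel().copy()
    f = float(objective(w))
    g = np.asarray(gradient(w), dtype=float).ravel()
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise InvalidInputError("objective/gradient non-finite at w0")
    trace = [f]
    converged = f <= goal or np.max(np.abs(g)) < grad_tol
    n_iter = 0
    if not converged:
        for k in range(1, max_iter + 1):
            n_iter = k
            w = w - step * g
            f = float(objective(w))
            _check_finite_scalar(f, f"iteration {k}")
            g = np.asarray(gradient(w), dtype=float).ravel()
            _check_finite_vec(g, f"iteration {k}")
            trace.append(f)
            if f <= goal or np.max(np.abs(g)) < grad_tol:
                converged = True
                break
    return OptimResult(w, f, n_iter, converged, np.asarray(trace))
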