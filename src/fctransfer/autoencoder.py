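"""L2-regularized sparse autoencoder: forward maps, cost, analytic gradients, training.

The autoencoder (AE) reconstructs its input through one sigmoid hidden layer.
Training minimizes

    E(W, b) = (1/p) * sum_samples sum_features (x_hat - x)^2
              + lambda * (1/2) * sum(W1^2)          (encoding weights only)
              + beta * KL(rho || rho_hat)

where ``rho_hat`` is the per-hidden-unit mean activation over the p training
samples and KL is the Bernoulli Kullback-Leibler divergence pulling mean
activations toward the sparsity target ``rho``.  Biases are never penalized.

The decoder output is linear by default: inputs are Pearson correlations in
[-1, 1], which a sigmoid output could not reproduce.  A ``decoder_activation``
switch restores the sigmoid reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.special import expit

from .errors import InvalidInputError, ShapeError
from .optim import OptimResult, scg_minimize

__all__ = [
    "Hyperparams",
    "SparseAE",
    "ae_encode",
    "ae_decode",
    "kl_sparsity",
    "ae_cost_grad",
    "train_sparse_ae",
]

_EPS = 1e-12  # clamp for activations entering logarithms


@dataclass(frozen=True)
class Hyperparams:
    """Tunable training constants shared by all stages.

    Parameters
    ----------
    layer_sizes : tuple of int
        Hidden widths, one per stacked autoencoder.
    lambda_l2 : float
        L2 penalty coefficient on encoding weights (default 0.001).
    beta : float
        Sparsity regularization coefficient (typical values 1-4).
    rho : float
        Sparsity target: the desired mean activation of each hidden unit,
        in (0, 1) (typical values 0.001-0.1).
    cost_goal : float
        Training stops once the cost drops below this threshold (default 1e-5).
    max_epochs : int
        Maximum optimizer iterations per training stage (typical 400-800).
    seed : int
        Seed for parameter initialization.
    decoder_activation : str
        ``"linear"`` (default, correlation-valued inputs) or ``"sigmoid"``.
    feature_scaling : str
        ``"none"`` (default) or ``"unit_interval"`` (affine map of [-1,1]
        features onto [0,1] before the first AE).
    init_scale : str or float
        ``"auto"`` draws each block uniformly in ±1/sqrt(fan_in); ``"unit"``
        draws in ±1; a float gives an explicit half-width.
    softmax_intercept : bool
        Whether the classification head carries per-class intercepts.
    """

    layer_sizes: tuple[int, ...]
    lambda_l2: float = 0.001
    beta: float = 2.0
    rho: float = 0.01
    cost_goal: float = 1e-5
    max_epochs: int = 400
    seed: int = 0
    decoder_activation: str = "linear"
    feature_scaling: str = "none"
    init_scale: str | float = "auto"
    softmax_intercept: bool = True

    def __post_init__(self):
        object.__setattr__(self, "layer_sizes", tuple(int(k) for k in self.layer_sizes))
        if any(k < 1 for k in self.layer_sizes):
            raise InvalidInputError("layer sizes must be positive")
        if not (0.0 < self.rho < 1.0):
            raise InvalidInputError("rho must lie in (0, 1)")
        if self.lambda_l2 < 0 or self.beta < 0:
            raise InvalidInputError("lambda_l2 and beta must be non-negative")
        if self.max_epochs < 0:
            raise InvalidInputError("max_epochs must be >= 0")
        if self.decoder_activation not in ("linear", "sigmoid"):
            raise InvalidInputError("decoder_activation must be 'linear' or 'sigmoid'")
        if self.feature_scaling not in ("none", "unit_interval"):
            raise InvalidInputError("feature_scaling must be 'none' or 'unit_interval'")

    def with_(self, **kw) -> "Hyperparams":
        return replace(self, **kw)


@dataclass
class SparseAE:
    """One sparse autoencoder: encode (W1, b1) and decode (W2, b2) halves."""

    W1: np.ndarray  # (k, n)
    b1: np.ndarray  # (k,)
    W2: np.ndarray  # (n, k)
    b2: np.ndarray  # (n,)
    decoder_activation: str = "linear"
    trace: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def k(self) -> int:
        return self.W1.shape[0]


class AEGrads(NamedTuple):
    """Partial derivatives of the AE cost, one block per parameter array."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray


def _init_scale(spec: str | float, fan_in: int) -> float:
    if spec == "auto":
        return 1.0 / np.sqrt(fan_in)
    if spec == "unit":
        return 1.0
    return float(spec)


def init_sparse_ae(n_in: int, k: int, rng: np.random.Generator, hp: Hyperparams) -> SparseAE:
    """Uniform random initialization; blocks drawn in the order W1, b1, W2, b2."""
    s1 = _init_scale(hp.init_scale, n_in)
    s2 = _init_scale(hp.init_scale, k)
    W1 = rng.uniform(-s1, s1, size=(k, n_in))
    b1 = rng.uniform(-s1, s1, size=k)
    W2 = rng.uniform(-s2, s2, size=(n_in, k))
    b2 = rng.uniform(-s2, s2, size=n_in)
    return SparseAE(W1, b1, W2, b2, decoder_activation=hp.decoder_activation)


def ae_encode(ae: SparseAE, X: np.ndarray) -> np.ndarray:
    """Hidden activations ``Z = sigmoid(X W1' + b1)``; shape (p, k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != ae.n_in:
        raise ShapeError(f"X has {X.shape[1]} columns, expected {ae.n_in}")
    return expit(X @ ae.W1.T + ae.b1)


def ae_decode(ae: SparseAE, Z: np.ndarray) -> np.ndarray:
    """Reconstruction ``X_hat = g(Z W2' + b2)`` with g linear or sigmoid."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != ae.k:
        raise ShapeError(f"Z has {Z.shape[1]} columns, expected {ae.k}")
    A = Z @ ae.W2.T + ae.b2
    return expit(A) if ae.decoder_activation == "sigmoid" else A


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Bernoulli KL divergence sum_i KL(rho || rho_hat_i).

    Non-negative, zero iff every mean activation equals the target.  Mean
    activations at exactly 0 or 1 are clamped to [1e-12, 1-1e-12] with a
    warning (they arise only from saturated units).
    """
    if not (0.0 < rho < 1.0):
        raise InvalidInputError("rho must lie in (0, 1)")
    rho_hat = np.asarray(rho_hat, dtype=float)
    if np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        warnings.warn("mean activations at 0 or 1 clamped for KL sparsity", RuntimeWarning)
        rho_hat = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    return float(
        np.sum(rho * np.log(rho / rho_hat) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat)))
    )


def ae_cost_grad(ae: SparseAE, X: np.ndarray, hp: Hyperparams) -> tuple[float, AEGrads]:
    """Cost of the sparse AE on ``X`` and its exact analytic gradients."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.size == 0:
        raise InvalidInputError("X must be nonempty")
    if X.shape[1] != ae.n_in:
        raise ShapeError(f"X has {X.shape[1]} columns, expected {ae.n_in}")
    p = X.shape[0]

    Z = ae_encode(ae, X)
    X_hat = ae_decode(ae, Z)
    R = X_hat - X
    cost = float(np.sum(R * R)) / p

    # Reconstruction backprop.
    G2 = (2.0 / p) * R
    if ae.decoder_activation == "sigmoid":
        G2 = G2 * X_hat * (1.0 - X_hat)
    gW2 = G2.T @ Z
    gb2 = G2.sum(axis=0)
    dZ = G2 @ ae.W2

    # Sparsity penalty on mean activations.
    if hp.beta > 0:
        rho_hat = Z.mean(axis=0)
        rho_hat_c = np.clip(rho_hat, _EPS, 1.0 - _EPS)
        cost += hp.beta * kl_sparsity(hp.rho, rho_hat)
        dZ = dZ + (hp.beta / p) * (-hp.rho / rho_hat_c + (1.0 - hp.rho) / (1.0 - rho_hat_c))

    G1 = dZ * Z * (1.0 - Z)
    gW1 = G1.T @ X
    gb1 = G1.sum(axis=0)

    # L2 penalty on encoding weights only.
    if hp.lambda_l2 > 0:
        cost += hp.lambda_l2 * 0.5 * float(np.sum(ae.W1 * ae.W1))
        gW1 = gW1 + hp.lambda_l2 * ae.W1

    if not np.isfinite(cost):
        raise InvalidInputError("non-finite autoencoder cost")
    return cost, AEGrads(gW1, gb1, gW2, gb2)


def _pack(ae: SparseAE) -> np.ndarray:
    return np.concatenate([ae.W1.ravel(), ae.b1, ae.W2.ravel(), ae.b2])


def _unpack(w: np.ndarray, n: int, k: int, decoder_activation: str) -> SparseAE:
    i = 0
    W1 = w[i : i + k * n].reshape(k, n); i += k * n
    b1 = w[i : i + k]; i += k
    W2 = w[i : i + n * k].reshape(n, k); i += n * k
    b2 = w[i : i + n]
    return SparseAE(W1, b1, W2, b2, decoder_activation=decoder_activation)


def train_sparse_ae(X: np.ndarray, k: int, hp: Hyperparams) -> SparseAE:
    """Train one sparse AE on ``X`` with SCG from a seeded uniform initialization.

    Stops at ``hp.cost_goal`` or ``hp.max_epochs`` iterations; the returned
    AE's cost never exceeds the cost at initialization and carries the
    per-iteration objective trace in ``.trace``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k < 1:
        raise InvalidInputError("hidden width k must be >= 1")
    if X.shape[0] < 2:
        raise InvalidInputError("training requires at least 2 samples")
    n = X.shape[1]
    rng = np.random.default_rng(hp.seed)
    ae0 = init_sparse_ae(n, k, rng, hp)

    # One-point memo: SCG evaluates the objective and then the gradient at the
    # same accepted point; a single shared forward/backward pass serves both.
    memo: dict = {"key": None, "cost": None, "grad": None}

    def _eval(w: np.ndarray) -> tuple[float, np.ndarray]:
        key = w.tobytes()
        if memo["key"] != key:
            cost, g = ae_cost_grad(_unpack(w, n, k, hp.decoder_activation), X, hp)
            memo.update(
                key=key,
                cost=cost,
                grad=np.concatenate([g.W1.ravel(), g.b1, g.W2.ravel(), g.b2]),
            )
        return memo["cost"], memo["grad"]

    def objective(w: np.ndarray) -> float:
        return _eval(w)[0]

    def gradient(w: np.ndarray) -> np.ndarray:
        return _eval(w)[1]

    res: OptimResult = scg_minimize(
        objective, gradient, _pack(ae0), goal=hp.cost_goal, max_iter=max(hp.max_epochs, 1)
    )
    ae = _unpack(res.w_star, n, k, hp.decoder_activation)
    ae.trace = res.trace
    return ae
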