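"""Softmax head, supervised training, joint fine-tuning, and model assembly.

Two end-to-end training paths share one architecture and one set of
hyperparameters, so any performance difference is attributable to how the
encoder stack was initialized:

* transfer path — the encoder stack is an offline-learned prototype
  (healthy-corpus knowledge), copied by :func:`fctransfer.stacking.transfer_init`;
* conventional baseline — the stack is greedily pretrained on the target
  task's own training features only.

In both paths the deep features feed a softmax regression head, and the whole
network (every encoder layer plus the head) is then fine-tuned jointly against
a binary cross-entropy objective by scaled conjugate gradient.

Note on the objective: the two-term binary form
``-(1/m) sum_i sum_j [y_ij ln h_j + (1-y_ij) ln(1-h_j)]`` is used with the
predicted probabilities ``h`` inside the logarithms (the logarithm of a {0,1}
label is undefined).  Penalties (L2, sparsity) act only during unsupervised
pretraining, never during fine-tuning.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .autoencoder import Hyperparams
from .errors import InvalidInputError, ProvenanceError, ShapeError
from .optim import scg_minimize
from .stacking import (
    PROVENANCE_OFFLINE,
    PROVENANCE_TARGET,
    SSAEModel,
    ssae_extract,
    train_ssae,
    transfer_init,
)

__all__ = [
    "SoftmaxModel",
    "DTLNNModel",
    "softmax_predict",
    "cross_entropy",
    "train_softmax",
    "fine_tune",
    "train_dtl_nn",
    "train_dnn_baseline",
    "predict",
    "MODE_TRANSFER",
    "MODE_BASELINE",
]

_EPS = 1e-12

MODE_TRANSFER = "DTL-NN"
MODE_BASELINE = "DNN"


@dataclass
class SoftmaxModel:
    """Softmax regression head: theta (n_classes x n_features) + intercepts."""

    theta: np.ndarray
    intercept: np.ndarray  # zeros when intercepts are disabled

    @property
    def n_classes(self) -> int:
        return self.theta.shape[0]

    @property
    def n_features(self) -> int:
        return self.theta.shape[1]


@dataclass
class DTLNNModel:
    """Encoder stack + softmax head, with provenance-aware mode bookkeeping.

    ``mode`` is "DTL-NN" when the stack came from offline learning (transfer)
    and "DNN" when it was pretrained on the target data (baseline); the
    invariant between ``mode`` and ``ssae.provenance`` is checked at assembly.
    ``classes`` maps model output columns to label values; column 1 is the
    positive (disease) class.
    """

    ssae: SSAEModel
    head: SoftmaxModel
    mode: str
    fine_tuned: bool = False
    training_log: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    classes: tuple = (0, 1)

    @property
    def architecture(self) -> str:
        """Width string input-hidden...-classes, e.g. ``4005-30-30-30-2``."""
        return "-".join(str(w) for w in (*self.ssae.layer_sizes, len(self.classes)))

    def __post_init__(self):
        if self.head.n_features != self.ssae.top_width:
            raise ShapeError(
                f"head expects {self.head.n_features} features, stack provides "
                f"{self.ssae.top_width}"
            )
        expected = {MODE_TRANSFER: PROVENANCE_OFFLINE, MODE_BASELINE: PROVENANCE_TARGET}
        if self.mode in expected and self.ssae.provenance != expected[self.mode]:
            raise ProvenanceError(
                f"mode {self.mode} is inconsistent with stack provenance "
                f"{self.ssae.provenance!r}"
            )


def softmax_predict(head: SoftmaxModel, Z: np.ndarray) -> np.ndarray:
    """Class probabilities, one row per sample; rows sum to 1.

    Probability of class j is proportional to exp(theta_j' z); the maximum
    logit is subtracted per row before exponentiation to guard overflow.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if np.any(~np.isfinite(Z)):
        raise InvalidInputError("non-finite features passed to softmax")
    if Z.shape[1] != head.n_features:
        raise ShapeError(f"Z has {Z.shape[1]} columns, expected {head.n_features}")
    logits = Z @ head.theta.T + head.intercept
    logits = logits - logits.max(axis=1, keepdims=True)
    E = np.exp(logits)
    return E / E.sum(axis=1, keepdims=True)


def _one_hot(Y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    Y = np.asarray(Y)
    if Y.ndim == 2:
        if Y.shape[1] != n_classes or not np.all(np.isin(Y, (0, 1))):
            raise InvalidInputError("label matrix must be one-hot")
        if not np.all(Y.sum(axis=1) == 1):
            raise InvalidInputError("each label row must be one-hot")
        return Y.astype(float)
    out = np.zeros((Y.shape[0], n_classes))
    out[np.arange(Y.shape[0]), Y.astype(int)] = 1.0
    return out


def cross_entropy(head: SoftmaxModel, Z: np.ndarray, Y: np.ndarray) -> float:
    """Two-term binary cross-entropy averaged over samples (non-negative)."""
    H = softmax_predict(head, Z)
    Yh = _one_hot(Y, head.n_classes)
    Hc = np.clip(H, _EPS, 1.0 - _EPS)
    m = Z.shape[0] if Z.ndim == 2 else 1
    return float(-np.sum(Yh * np.log(Hc) + (1.0 - Yh) * np.log(1.0 - Hc)) / m)


def _ce_grad_logits(H: np.ndarray, Yh: np.ndarray, m: int) -> np.ndarray:
    """d(cross_entropy)/d(logits) for the two-term objective under softmax."""
    Hc = np.clip(H, _EPS, 1.0 - _EPS)
    gH = -(Yh / Hc - (1.0 - Yh) / (1.0 - Hc)) / m
    # Softmax Jacobian: dE/da_l = h_l * (g_l - sum_j g_j h_j)
    return H * (gH - np.sum(gH * H, axis=1, keepdims=True))


def train_softmax(Z: np.ndarray, Y: np.ndarray, hp: Hyperparams) -> SoftmaxModel:
    """Fit the softmax head on fixed deep features by SCG from zero init."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Yh = _one_hot(Y)
    counts = Yh.sum(axis=0)
    if np.any(counts == 0):
        raise InvalidInputError("training requires at least one sample per class")
    m, d = Z.shape
    n_classes = Yh.shape[1]
    use_icpt = hp.softmax_intercept

    def unpack(w):
        theta = w[: n_classes * d].reshape(n_classes, d)
        icpt = w[n_classes * d:] if use_icpt else np.zeros(n_classes)
        return SoftmaxModel(theta, icpt)

    def objective(w):
        return cross_entropy(unpack(w), Z, Yh)

    def gradient(w):
        head = unpack(w)
        H = softmax_predict(head, Z)
        G = _ce_grad_logits(H, Yh, m)
        g_theta = G.T @ Z
        parts = [g_theta.ravel()]
        if use_icpt:
            parts.append(G.sum(axis=0))
        return np.concatenate(parts)

    n_par = n_classes * d + (n_classes if use_icpt else 0)
    res = scg_minimize(objective, gradient, np.zeros(n_par),
                       goal=hp.cost_goal, max_iter=max(hp.max_epochs, 1))
    return unpack(res.w_star)


# ---------------------------------------------------------------------------
# Joint fine-tuning over the fully flattened parameter vector.
# ---------------------------------------------------------------------------

def _flatten(model: DTLNNModel) -> np.ndarray:
    parts = []
    for W, b in model.ssae.encoders:
        parts.extend([W.ravel(), b])
    parts.append(model.head.theta.ravel())
    parts.append(model.head.intercept)
    return np.concatenate(parts)


def _unflatten(w: np.ndarray, template: DTLNNModel) -> tuple[list, SoftmaxModel]:
    i = 0
    encoders = []
    for W, b in template.ssae.encoders:
        encoders.append((w[i : i + W.size].reshape(W.shape), w[i + W.size : i + W.size + b.size]))
        i += W.size + b.size
    th = template.head.theta
    theta = w[i : i + th.size].reshape(th.shape)
    i += th.size
    icpt = w[i : i + template.head.intercept.size]
    return encoders, SoftmaxModel(theta, icpt)


def _forward_cost_grad(w: np.ndarray, template: DTLNNModel,
                       X: np.ndarray, Yh: np.ndarray) -> tuple[float, np.ndarray]:
    """End-to-end cross-entropy and its gradient w.r.t. every parameter."""
    encoders, head = _unflatten(w, template)
    m = X.shape[0]
    Zs = [X]
    for W, b in encoders:
        Zs.append(expit(Zs[-1] @ W.T + b))
    Z_top = Zs[-1]
    logits = Z_top @ head.theta.T + head.intercept
    logits_s = logits - logits.max(axis=1, keepdims=True)
    E = np.exp(logits_s)
    H = E / E.sum(axis=1, keepdims=True)
    Hc = np.clip(H, _EPS, 1.0 - _EPS)
    cost = float(-np.sum(Yh * np.log(Hc) + (1.0 - Yh) * np.log(1.0 - Hc)) / m)

    G = _ce_grad_logits(H, Yh, m)
    g_theta = G.T @ Z_top
    g_icpt = G.sum(axis=0)
    dZ = G @ head.theta
    grads_enc = []
    for l in range(len(encoders) - 1, -1, -1):
        W, _ = encoders[l]
        Z = Zs[l + 1]
        Gl = dZ * Z * (1.0 - Z)
        grads_enc.append((Gl.T @ Zs[l], Gl.sum(axis=0)))
        dZ = Gl @ W
    grads_enc.reverse()
    parts = []
    for gW, gb in grads_enc:
        parts.extend([gW.ravel(), gb])
    parts.append(g_theta.ravel())
    parts.append(g_icpt if template.head.intercept.size else np.empty(0))
    return cost, np.concatenate(parts)


def fine_tune(model: DTLNNModel, X: np.ndarray, Y: np.ndarray, hp: Hyperparams) -> DTLNNModel:
    """Jointly tune all encoder layers and the head against cross-entropy.

    Returns a new model; the input model is never mutated.  With
    ``hp.max_epochs == 0`` this is a no-op (``fine_tuned`` stays False).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.ssae.hyperparams.feature_scaling == "unit_interval":
        X = 0.5 * (X + 1.0)
    Yh = _one_hot(Y, model.head.n_classes)
    if X.shape[0] != Yh.shape[0]:
        raise ShapeError("X and Y sample counts differ")
    out = copy.deepcopy(model)
    if hp.max_epochs == 0:
        return out

    memo: dict = {"key": None, "cost": None, "grad": None}

    def _eval(w):
        key = w.tobytes()
        if memo["key"] != key:
            cost, grad = _forward_cost_grad(w, model, X, Yh)
            memo.update(key=key, cost=cost, grad=grad)
        return memo["cost"], memo["grad"]

    def objective(w):
        return _eval(w)[0]

    def gradient(w):
        return _eval(w)[1]

    res = scg_minimize(objective, gradient, _flatten(model),
                       goal=hp.cost_goal, max_iter=hp.max_epochs)
    encoders, head = _unflatten(res.w_star, model)
    out.ssae.encoders = [(W.copy(), b.copy()) for W, b in encoders]
    out.head = head
    out.fine_tuned = True
    out.training_log = res.trace
    return out


def _assemble_and_tune(ssae: SSAEModel, X: np.ndarray, Y: np.ndarray,
                       hp: Hyperparams, mode: str) -> DTLNNModel:
    Z = ssae_extract(ssae, X)
    head = train_softmax(Z, Y, hp)
    model = DTLNNModel(ssae=ssae, head=head, mode=mode)
    return fine_tune(model, X, Y, hp)


def train_dtl_nn(prototype: SSAEModel, X: np.ndarray, Y: np.ndarray,
                 hp: Hyperparams) -> DTLNNModel:
    """Transfer path: copy the offline prototype, fit the head, fine-tune all.

    ``prototype`` must carry offline provenance; the target data must be
    disjoint (by subject) from the offline corpus, which is enforced upstream
    where subject identifiers are available.
    """
    if prototype.provenance != PROVENANCE_OFFLINE:
        raise ProvenanceError("train_dtl_nn requires an offline-learned prototype")
    ssae = transfer_init(prototype)
    return _assemble_and_tune(ssae, np.atleast_2d(np.asarray(X, float)), Y, hp, MODE_TRANSFER)


def train_dnn_baseline(X: np.ndarray, Y: np.ndarray, hp: Hyperparams) -> DTLNNModel:
    """Conventional baseline: greedy pretraining on the target features only.

    Identical architecture, hyperparameters and supervised stages as the
    transfer path, so performance differences isolate the initialization.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ssae = train_ssae(X, hp, PROVENANCE_TARGET)
    return _assemble_and_tune(ssae, X, Y, hp, MODE_BASELINE)


def predict(model: DTLNNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and positive-class probabilities for new subjects.

    A probability of exactly 0.5 is assigned to the positive class.
    """
    Z = ssae_extract(model.ssae, X)
    P = softmax_predict(model.head, Z)
    pos = P[:, 1]
    labels = np.where(pos >= 0.5, model.classes[1], model.classes[0])
    return labels, pos
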