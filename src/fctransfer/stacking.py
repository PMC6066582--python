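"""Greedy stacking of sparse autoencoders into an SSAE and prototype transfer.

A stacked sparse autoencoder (SSAE) is built layer by layer: the first AE is
trained on the input features, each subsequent AE on the hidden activations of
the stack trained so far.  Only the encoding halves (W, b) are retained; the
decoders exist solely during their own greedy stage.

"Offline learning" trains such a stack, unsupervised, on a corpus of healthy
connectomes; the resulting prototype carries the reusable structure of healthy
functional connectivity and can be transferred to initialize a supervised
classifier on a small disease cohort.  The function signature enforces that
offline learning never sees task labels: it receives a feature matrix only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import Hyperparams, SparseAE, ae_encode, train_sparse_ae
from .errors import ProvenanceError, ShapeError, StageError

__all__ = ["SSAEModel", "train_ssae", "ssae_extract", "transfer_init",
           "PROVENANCE_OFFLINE", "PROVENANCE_TARGET"]

PROVENANCE_OFFLINE = "offline"
PROVENANCE_TARGET = "target-pretrained"


@dataclass
class SSAEModel:
    """Ordered encoder stack: the transferable prototype.

    ``encoders[l]`` is the (W, b) pair of layer l+1, with W of shape
    (k_{l+1}, k_l) so consecutive widths chain.  ``provenance`` records whether
    the stack was learned offline on a healthy corpus or pretrained on the
    target task's own training data.
    """

    encoders: list[tuple[np.ndarray, np.ndarray]]
    layer_sizes: tuple[int, ...]  # (n_in, k1, ..., kL)
    hyperparams: Hyperparams
    provenance: str
    seed: int = 0
    stage_traces: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_layers(self) -> int:
        return len(self.encoders)

    @property
    def n_in(self) -> int:
        return self.layer_sizes[0]

    @property
    def top_width(self) -> int:
        return self.layer_sizes[-1]

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ShapeError("SSAE must have at least one layer")
        for l, (W, b) in enumerate(self.encoders):
            if W.shape != (self.layer_sizes[l + 1], self.layer_sizes[l]):
                raise ShapeError(
                    f"layer {l + 1} weights {W.shape} break the width chain "
                    f"{self.layer_sizes}"
                )
            if b.shape != (self.layer_sizes[l + 1],):
                raise ShapeError(f"layer {l + 1} bias has shape {b.shape}")
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise StageError(f"layer {l + 1} contains non-finite parameters")


def _stage_seed(seed: int, stage: int) -> int:
    """Per-stage initialization seed derived deterministically, < 2^31."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def train_ssae(X: np.ndarray, hp: Hyperparams, provenance: str) -> SSAEModel:
    """Greedy layer-wise unsupervised training of the full stack on ``X``.

    AE 1 is trained on ``X``; AE l on the hidden activations produced by
    encoders 1..l-1.  All layers share one ``Hyperparams`` (per-layer seeds are
    derived from ``hp.seed``).  Decoding halves are discarded after each stage.
    """
    if provenance not in (PROVENANCE_OFFLINE, PROVENANCE_TARGET):
        raise ProvenanceError(f"unknown provenance tag {provenance!r}")
    X_cur = np.atleast_2d(np.asarray(X, dtype=float))
    if hp.feature_scaling == "unit_interval":
        X_cur = 0.5 * (X_cur + 1.0)
    n_in = X_cur.shape[1]
    encoders: list[tuple[np.ndarray, np.ndarray]] = []
    traces: list[np.ndarray] = []
    for l, k in enumerate(hp.layer_sizes, start=1):
        stage_hp = hp.with_(seed=_stage_seed(hp.seed, l))
        ae: SparseAE = train_sparse_ae(X_cur, k, stage_hp)
        encoders.append((ae.W1.copy(), ae.b1.copy()))
        traces.append(ae.trace if ae.trace is not None else np.empty(0))
        X_cur = ae_encode(ae, X_cur)
        if not np.all(np.isfinite(X_cur)):
            raise StageError(f"greedy stage {l} produced non-finite activations")
    model = SSAEModel(
        encoders=encoders,
        layer_sizes=(n_in, *hp.layer_sizes),
        hyperparams=hp,
        provenance=provenance,
        seed=hp.seed,
        stage_traces=traces,
    )
    model.validate()
    return model


def ssae_extract(model: SSAEModel, X: np.ndarray) -> np.ndarray:
    """Top-layer deep features: composition of all L sigmoid encoders."""
    from scipy.special import expit

    Z = np.atleast_2d(np.asarray(X, dtype=float))
    if model.hyperparams.feature_scaling == "unit_interval":
        Z = 0.5 * (Z + 1.0)
    if Z.shape[1] != model.n_in:
        raise ShapeError(f"X has {Z.shape[1]} columns, expected {model.n_in}")
    for W, b in model.encoders:
        Z = expit(Z @ W.T + b)
    return Z


def transfer_init(prototype: SSAEModel) -> SSAEModel:
    """Independent deep copy of an offline-learned prototype for transfer.

    Refuses stacks that were not learned offline: transferring a
    target-pretrained stack would silently collapse the transfer comparison
    into its baseline, which is a pipeline wiring bug.
    """
    if prototype.provenance != PROVENANCE_OFFLINE:
        raise ProvenanceError(
            f"transfer_init requires an offline-learned prototype, got "
            f"provenance={prototype.provenance!r}"
        )
    return copy.deepcopy(prototype)
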