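"""Run configuration, architecture strings, and shipped presets.

An architecture string such as ``"4005-100-100-100-2"`` reads: input width
(number of FC features), hidden widths of the stacked encoders, and the number
of output classes (always 2 here).  Four presets are shipped, one per
benchmark site of the multi-site ASD evaluation; all share lambda = 0.001 and
a cost goal of 1e-5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .autoencoder import Hyperparams
from .errors import InvalidInputError

__all__ = ["RunConfig", "PRESETS", "load_preset", "parse_architecture",
           "format_architecture", "load_config", "save_config"]


def parse_architecture(arch: str) -> tuple[int, tuple[int, ...], int]:
    """Split ``"n-k1-...-kL-c"`` into (input width, hidden widths, classes)."""
    try:
        widths = [int(w) for w in arch.split("-")]
    except ValueError as exc:
        raise InvalidInputError(f"architecture {arch!r} does not parse to integers") from exc
    if len(widths) < 3 or any(w <= 0 for w in widths):
        raise InvalidInputError(f"architecture {arch!r} needs positive input/hidden/output widths")
    if widths[-1] != 2:
        raise InvalidInputError("the output layer must have 2 classes")
    return widths[0], tuple(widths[1:-1]), widths[-1]


def format_architecture(n_in: int, hidden: tuple[int, ...], n_classes: int = 2) -> str:
    return "-".join(str(w) for w in (n_in, *hidden, n_classes))


@dataclass
class RunConfig:
    """Everything needed to re-run a pipeline stage bit-identically."""

    architecture: str = "4005-100-100-100-2"
    lambda_l2: float = 0.001
    beta: float = 1.0
    rho: float = 0.1
    max_epochs: int = 800
    cost_goal: float = 1e-5
    k_folds: int = 5
    seed: int = 0
    decoder_activation: str = "linear"
    feature_scaling: str = "none"
    init_scale: str = "auto"
    preset: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        parse_architecture(self.architecture)  # validates

    @property
    def input_width(self) -> int:
        return parse_architecture(self.architecture)[0]

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return parse_architecture(self.architecture)[1]

    def hyperparams(self, seed: int | None = None) -> Hyperparams:
        return Hyperparams(
            layer_sizes=self.hidden_sizes,
            lambda_l2=self.lambda_l2,
            beta=self.beta,
            rho=self.rho,
            cost_goal=self.cost_goal,
            max_epochs=self.max_epochs,
            seed=self.seed if seed is None else seed,
            decoder_activation=self.decoder_activation,
            feature_scaling=self.feature_scaling,
            init_scale=self.init_scale,
        )


# Shipped per-site presets (lambda = 0.001 everywhere).
PRESETS: dict[str, RunConfig] = {
    "UM": RunConfig(architecture="4005-100-100-100-2", beta=1.0, rho=0.1,
                    max_epochs=800, preset="UM"),
    "UCLA": RunConfig(architecture="4005-70-70-70-2", beta=2.0, rho=0.01,
                      max_epochs=400, preset="UCLA"),
    "USM": RunConfig(architecture="4005-30-30-30-2", beta=2.0, rho=0.01,
                     max_epochs=400, preset="USM"),
    "LEUVEN": RunConfig(architecture="4005-50-50-50-2", beta=3.0, rho=0.01,
                        max_epochs=400, preset="LEUVEN"),
}


def load_preset(name: str) -> RunConfig:
    """Preset by site name; unknown names list the available alternatives."""
    key = name.upper()
    if key not in PRESETS:
        raise InvalidInputError(
            f"unknown preset {name!r}; available presets: {', '.join(sorted(PRESETS))}"
        )
    cfg = PRESETS[key]
    return RunConfig(**{**asdict(cfg)})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides win over file values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
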