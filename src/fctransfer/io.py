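"""Portable model containers and delimited-text dataset I/O.

Model files are HDF5.  Layout for an encoder stack (SSAE):

    attrs: format_version, kind ("ssae" | "dtlnn"), layer_sizes, provenance,
           seed, hyperparams (JSON string)
    /encoders/<l>/W, /encoders/<l>/b   little-endian float64 datasets

A full classifier ("dtlnn") adds:

    attrs: mode, fine_tuned, classes
    /head/theta, /head/intercept, /training_log

Dataset text formats:

* FC matrix files: whitespace- or comma-delimited n x n numeric text, one
  subject per file, filename (stem) = subject_id;
* feature table: one TSV, first column subject_id, remaining n(n-1)/2 columns
  in upper-triangle order;
* phenotype TSV: subject_id, site, group, age, sex, handedness (empty cell =
  missing); ``group`` is the disease label column.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .autoencoder import Hyperparams
from .classify import DTLNNModel, SoftmaxModel
from .connectome import ConnectomeDataset, edge_index_pairs
from .errors import InvalidInputError
from .stacking import SSAEModel

__all__ = [
    "save_ssae", "load_ssae", "save_dtlnn", "load_dtlnn",
    "read_fc_matrix_file", "read_feature_table", "write_feature_table",
    "read_phenotype", "dataset_from_tables",
]

_FORMAT_VERSION = 1


def _write_common(f: h5py.File, model: SSAEModel, kind: str) -> None:
    f.attrs["format_version"] = _FORMAT_VERSION
    f.attrs["kind"] = kind
    f.attrs["layer_sizes"] = np.asarray(model.layer_sizes, dtype=np.int64)
    f.attrs["provenance"] = model.provenance
    f.attrs["seed"] = int(model.seed)
    f.attrs["hyperparams"] = json.dumps(asdict(model.hyperparams))
    grp = f.create_group("encoders")
    for l, (W, b) in enumerate(model.encoders):
        g = grp.create_group(str(l))
        g.create_dataset("W", data=np.asarray(W, dtype="<f8"))
        g.create_dataset("b", data=np.asarray(b, dtype="<f8"))


def _read_common(f: h5py.File) -> SSAEModel:
    hp_dict = json.loads(f.attrs["hyperparams"])
    hp_dict["layer_sizes"] = tuple(hp_dict["layer_sizes"])
    hp = Hyperparams(**hp_dict)
    n_layers = len(f["encoders"])
    encoders = []
    for l in range(n_layers):
        g = f["encoders"][str(l)]
        encoders.append((np.asarray(g["W"], dtype=float), np.asarray(g["b"], dtype=float)))
    model = SSAEModel(
        encoders=encoders,
        layer_sizes=tuple(int(x) for x in f.attrs["layer_sizes"]),
        hyperparams=hp,
        provenance=str(f.attrs["provenance"]),
        seed=int(f.attrs["seed"]),
    )
    model.validate()
    return model


def save_ssae(model: SSAEModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _write_common(f, model, "ssae")


def load_ssae(path: str | Path) -> SSAEModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "ssae":
            raise InvalidInputError(f"{path} is not an encoder-stack model file")
        return _read_common(f)


def save_dtlnn(model: DTLNNModel, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _write_common(f, model.ssae, "dtlnn")
        f.attrs["mode"] = model.mode
        f.attrs["fine_tuned"] = bool(model.fine_tuned)
        f.attrs["classes"] = np.asarray(model.classes, dtype=np.int64)
        g = f.create_group("head")
        g.create_dataset("theta", data=np.asarray(model.head.theta, dtype="<f8"))
        g.create_dataset("intercept", data=np.asarray(model.head.intercept, dtype="<f8"))
        f.create_dataset("training_log", data=np.asarray(model.training_log, dtype="<f8"))


def load_dtlnn(path: str | Path) -> DTLNNModel:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "dtlnn":
            raise InvalidInputError(f"{path} is not a classifier model file")
        ssae = _read_common(f)
        head = SoftmaxModel(
            theta=np.asarray(f["head"]["theta"], dtype=float),
            intercept=np.asarray(f["head"]["intercept"], dtype=float),
        )
        return DTLNNModel(
            ssae=ssae,
            head=head,
            mode=str(f.attrs["mode"]),
            fine_tuned=bool(f.attrs["fine_tuned"]),
            training_log=np.asarray(f["training_log"], dtype=float),
            classes=tuple(int(c) for c in f.attrs["classes"]),
        )


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def read_fc_matrix_file(path: str | Path) -> tuple[str, np.ndarray]:
    """One subject's n x n FC matrix from delimited text; id = filename stem."""
    path = Path(path)
    try:
        M = np.loadtxt(path, delimiter=",")
    except ValueError:
        M = np.loadtxt(path)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InvalidInputError(f"{path} does not contain a square matrix")
    return path.stem, M


def read_feature_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str).tolist()
    return ids, df.iloc[:, 1:].to_numpy(float)


def write_feature_table(path: str | Path, subject_ids: list[str],
                        features: np.ndarray, n_rois: int) -> None:
    iu, ju = edge_index_pairs(n_rois)
    cols = [f"fc_{i + 1}_{j + 1}" for i, j in zip(iu, ju)]
    df = pd.DataFrame(features, columns=cols)
    df.insert(0, "subject_id", subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "site", "group"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"phenotype table lacks columns: {sorted(missing)}")
    return df


def dataset_from_tables(feature_path: str | Path, phenotype_path: str | Path,
                        positive_group: str | None = None) -> ConnectomeDataset:
    """Assemble a labeled dataset from a feature TSV and a phenotype TSV.

    ``positive_group`` names the phenotype ``group`` value coded as the
    disease (positive) class; by default the lexicographically larger of the
    two group values is positive, which maps naturally onto e.g.
    healthy/patient coding.  Unlabeled corpora (single group value "healthy"
    or "NA") keep ``labels=None``.
    """
    ids, X = read_feature_table(feature_path)
    pheno = read_phenotype(phenotype_path).set_index("subject_id")
    missing = [s for s in ids if s not in pheno.index]
    if missing:
        raise InvalidInputError(f"phenotype rows missing for subjects: {missing[:5]}")
    pheno = pheno.loc[ids]
    n_edges = X.shape[1]
    n_rois = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if n_rois * (n_rois - 1) // 2 != n_edges:
        raise InvalidInputError(f"{n_edges} columns is not n(n-1)/2 for any integer n")
    groups = pheno["group"].astype(str)
    uniq = sorted(groups.dropna().unique())
    labels = None
    if len(uniq) == 2:
        pos = positive_group if positive_group is not None else uniq[-1]
        if pos not in uniq:
            raise InvalidInputError(f"positive group {pos!r} not among {uniq}")
        labels = (groups == pos).to_numpy(int)
    elif len(uniq) > 2:
        raise InvalidInputError(f"expected at most 2 group values, got {uniq}")
    cov_cols = [c for c in ("site", "age", "sex", "handedness") if c in pheno.columns]
    cov = pheno[cov_cols].reset_index(drop=True)
    return ConnectomeDataset(
        features=X, subject_ids=ids, n_rois=n_rois, labels=labels, covariates=cov
    )
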