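"""Synthetic connectome cohorts with the statistical structure the method assumes.

The generator emulates, at desk scale, the data regime of a multi-site
resting-state FC study:

* healthy connectivity vectors share a low-rank latent factor structure on the
  Fisher-z scale (this is the transferable "prior knowledge" that offline
  learning is supposed to capture);
* a disease group differs from healthy controls by an additive mean shift on a
  small planted set of edges (z-scale, so correlations never leave (-1, 1));
* acquisition site adds a per-site, per-edge offset; age, sex and handedness
  add small global effects; covariate cells go missing at a configurable rate;
* the offline healthy corpus lives in its own subject-id and site namespace,
  so corpus/target disjointness holds by construction.

All effects are applied in Fisher-z space and mapped through z -> tanh(z) = r,
keeping the correlation semantics of the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectomeDataset, ROITimeSeries
from .errors import InvalidInputError

__all__ = ["SimScenario", "simulate_cohort", "simulate_offline_corpus", "simulate_timeseries"]


@dataclass(frozen=True)
class SimScenario:
    """Generator settings for one synthetic study population.

    Defaults mirror the magnitudes of a typical multi-site cohort: tens of
    subjects per group per site, an offline healthy corpus of ~400, ten truly
    discriminative edges shifted by 0.6 on the Fisher-z scale, between-subject
    edge noise of 0.3 z, and modest site/demographic effects.
    """

    n_rois: int = 90
    n_per_group: int = 30          # subjects per group per target site
    n_sites: int = 2               # target sites
    latent_dim: int = 10           # shared healthy factor structure
    n_planted: int = 10            # discriminative edges (ignored if planted_edges given)
    planted_edges: tuple[tuple[int, int], ...] | None = None
    effect_size: float = 0.6       # mean z-shift on planted edges (disease group)
    planted_factor_sd: float = 0.2  # healthy-population loading on planted edges (z); the
                                    # disease-relevant direction also varies in health, so
                                    # reconstruction-driven offline learning can capture it
    site_shift: float = 0.1        # sd of per-site per-edge offsets (z)
    age_effect: float = 0.004      # z per year of age (global)
    sex_effect: float = 0.05       # z offset for male sex (global)
    handedness_effect: float = 0.02  # z offset for right-handedness (global)
    loading_scale: float = 0.08    # sd of latent factor loadings (z)
    noise_sd: float = 0.1          # unstructured edge noise, ~ Fisher-z SE of a typical scan
    missing_rate: float = 0.05     # covariate missingness probability
    n_offline: int = 400           # healthy offline-corpus size
    n_offline_sites: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise InvalidInputError("effect_size must be >= 0")
        for name in ("missing_rate",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        if self.planted_edges is not None:
            pairs = set()
            for i, j in self.planted_edges:
                if not (0 <= i < j < self.n_rois):
                    raise InvalidInputError("planted edges must satisfy 0 <= i < j < n_rois")
                pairs.add((i, j))
            if len(pairs) != len(self.planted_edges):
                raise InvalidInputError("planted edges must be distinct")

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2


@dataclass
class _Population:
    """Shared population structure sampled once per scenario."""

    mu: np.ndarray          # baseline edge means (z)
    loadings: np.ndarray    # latent_dim x n_edges
    planted_idx: np.ndarray  # edge indices of planted effects
    planted_pairs: tuple[tuple[int, int], ...]


def _edge_index(i: int, j: int, n: int) -> int:
    """Row-major upper-triangle index of edge (i, j), i < j."""
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def _population(sc: SimScenario) -> _Population:
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 0]))
    mu = rng.normal(0.1, 0.2, size=sc.n_edges)
    loadings = rng.normal(0.0, sc.loading_scale, size=(sc.latent_dim, sc.n_edges))
    if sc.planted_edges is not None:
        pairs = tuple(tuple(p) for p in sc.planted_edges)
    else:
        flat = rng.choice(sc.n_edges, size=sc.n_planted, replace=False)
        iu, ju = np.triu_indices(sc.n_rois, k=1)
        pairs = tuple((int(iu[e]), int(ju[e])) for e in flat)
    idx = np.array([_edge_index(i, j, sc.n_rois) for i, j in pairs])
    return _Population(mu, loadings, idx, pairs)


def _draw_group(
    sc: SimScenario,
    pop: _Population,
    rng: np.random.Generator,
    n: int,
    diseased: bool,
    site_offset: np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame]:
    factors = rng.normal(size=(n, sc.latent_dim))
    Z = pop.mu + factors @ pop.loadings + rng.normal(0.0, sc.noise_sd, size=(n, sc.n_edges))
    if sc.planted_factor_sd > 0:
        g = rng.normal(size=(n, 1))
        Z[:, pop.planted_idx] += sc.planted_factor_sd * g
    Z += site_offset
    if diseased and sc.effect_size > 0:
        Z[:, pop.planted_idx] += sc.effect_size

    age = np.clip(rng.normal(15.0, 4.0, size=n), 8.0, 40.0)
    male = rng.random(n) < 0.8
    right = rng.random(n) < 0.85
    Z += sc.age_effect * (age - 15.0)[:, None]
    Z += sc.sex_effect * male[:, None]
    Z += sc.handedness_effect * right[:, None]

    R = np.tanh(Z)
    if np.any(np.abs(R) > 0.999):
        warnings.warn("extreme correlations clipped to +/-0.999", RuntimeWarning)
        R = np.clip(R, -0.999, 0.999)
    cov = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(male, "M", "F"),
            "handedness": np.where(right, "R", "L"),
        }
    )
    return R, cov


def _apply_missingness(cov: pd.DataFrame, rng: np.random.Generator, rate: float) -> pd.DataFrame:
    if rate <= 0:
        return cov
    cov = cov.copy()
    for col in ("age", "sex", "handedness"):
        mask = rng.random(len(cov)) < rate
        cov.loc[mask, col] = np.nan
    return cov


def simulate_cohort(sc: SimScenario) -> tuple[ConnectomeDataset, tuple[tuple[int, int], ...]]:
    """Target cohort: healthy + disease groups across ``sc.n_sites`` sites.

    Returns the labeled dataset (labels: 1 = disease) and the ground-truth
    planted edge set as (i, j) pairs (0-based, i < j).
    """
    pop = _population(sc)
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 1]))
    feats, labels, covs, ids = [], [], [], []
    counter = 1
    for s in range(sc.n_sites):
        site_name = f"SITE{s + 1}"
        site_off = rng.normal(0.0, sc.site_shift, size=sc.n_edges) if sc.site_shift > 0 else 0.0
        for diseased in (False, True):
            R, cov = _draw_group(sc, pop, rng, sc.n_per_group, diseased, site_off)
            cov.insert(0, "site", site_name)
            feats.append(R)
            covs.append(cov)
            labels.extend([int(diseased)] * sc.n_per_group)
            ids.extend(f"TGT{counter + i:04d}" for i in range(sc.n_per_group))
            counter += sc.n_per_group
    cov_all = _apply_missingness(pd.concat(covs, ignore_index=True), rng, sc.missing_rate)
    ds = ConnectomeDataset(
        features=np.vstack(feats),
        subject_ids=ids,
        n_rois=sc.n_rois,
        labels=np.asarray(labels),
        covariates=cov_all,
    )
    return ds, pop.planted_pairs


def simulate_offline_corpus(sc: SimScenario) -> ConnectomeDataset:
    """Healthy-only corpus in a disjoint subject/site namespace (no labels).

    Shares the population structure (baseline means and latent loadings) with
    :func:`simulate_cohort` for the same scenario, which is precisely what
    makes offline learning transferable.
    """
    pop = _population(sc)
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 2]))
    per_site = np.full(sc.n_offline_sites, sc.n_offline // sc.n_offline_sites)
    per_site[: sc.n_offline % sc.n_offline_sites] += 1
    feats, covs, ids = [], [], []
    counter = 1
    for s in range(sc.n_offline_sites):
        site_off = rng.normal(0.0, sc.site_shift, size=sc.n_edges) if sc.site_shift > 0 else 0.0
        R, cov = _draw_group(sc, pop, rng, int(per_site[s]), False, site_off)
        cov.insert(0, "site", f"OFFSITE{s + 1}")
        feats.append(R)
        covs.append(cov)
        ids.extend(f"OFF{counter + i:04d}" for i in range(int(per_site[s])))
        counter += int(per_site[s])
    cov_all = _apply_missingness(pd.concat(covs, ignore_index=True), rng, sc.missing_rate)
    return ConnectomeDataset(
        features=np.vstack(feats),
        subject_ids=ids,
        n_rois=sc.n_rois,
        labels=None,
        covariates=cov_all,
    )


def simulate_timeseries(Sigma: np.ndarray, T: int, seed: int) -> ROITimeSeries:
    """T multivariate-Gaussian draws with target correlation ``Sigma``.

    A non-positive-definite ``Sigma`` is repaired to the nearest valid
    correlation matrix (eigenvalue clipping + unit-diagonal renormalization)
    with a warning.  Empirical correlations converge to ``Sigma`` as T grows.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
        raise InvalidInputError("Sigma must be square")
    if np.max(np.abs(Sigma - Sigma.T)) > 1e-10:
        raise InvalidInputError("Sigma must be symmetric")
    vals = np.linalg.eigvalsh(Sigma)
    if vals.min() <= 0:
        warnings.warn("Sigma is not positive definite; repairing", RuntimeWarning)
        w, V = np.linalg.eigh(Sigma)
        w = np.clip(w, 1e-6, None)
        Sigma = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(Sigma))
        Sigma = Sigma / np.outer(d, d)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal(size=(T, Sigma.shape[0])) @ L.T
    return ROITimeSeries(subject_id=f"SIM{seed}", data=X)
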