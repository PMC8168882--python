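"""Collaborative-filtering (KNN) prediction of interaction frequencies.

Where the random forest matches host traits against parasitoid traits,
KNN instead asks which *training* parasitoids are most similar to a
focal parasitoid (Gower similarity over its traits) and recommends the
host-use profile of those neighbours, averaged.  Host species never
seen in training ("new" hosts, the cold-start problem) are first
inserted into the training meta-network by the mirror-image procedure:
their row is imputed from their nearest training hosts by host-trait
similarity.

A parasitoid present in both training and test data is never used as a
neighbour of itself (self-exclusion), mimicking the biocontrol use case
where no interaction data exist for the proposed agent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .networks import (
    MetaNetwork,
    PhyloCoordinates,
    TraitTable,
    phenological_overlap,
)

#: traits that can enter the Gower similarity
SIMILARITY_TRAITS = ("body_size", "phenology", "nd", "status", "phylogeny")

DEFAULT_PARASITOID_MASK = ("body_size", "phenology", "nd")
DEFAULT_HOST_MASK = ("body_size", "phenology", "nd", "status", "phylogeny")


@dataclass(frozen=True)
class KNNHyperparams:
    k: int = 3
    weighting: str = "similarity"  # "uniform" or "similarity"
    mask: tuple = DEFAULT_PARASITOID_MASK
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weighting not in ("uniform", "similarity"):
            raise ValueError("weighting must be 'uniform' or 'similarity'")


def gower_similarity(
    traits: TraitTable,
    guild: str,
    mask: Sequence[str] = DEFAULT_PARASITOID_MASK,
    coords: PhyloCoordinates | None = None,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Gower similarity (1 - dissimilarity) among one guild.

    Continuous traits are range-normalised over the table; the
    phenology block contributes 1 - Schoener overlap; biogeographic
    status is a 0/1 mismatch; phylogeny contributes Euclidean distance
    over the principal-coordinate axes normalised by its maximum.
    Components are averaged over the included traits.  A continuous
    trait with zero range is dropped with a warning.
    """
    import warnings

    if species is None:
        species = traits.species(guild)
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least two species for a similarity matrix")
    unknown = [t for t in mask if t not in SIMILARITY_TRAITS]
    if unknown:
        raise ValueError(f"unknown similarity traits: {unknown}")
    if "phylogeny" in mask and coords is None:
        raise ValueError("phylogeny in mask but no coordinates supplied")
    n = len(species)
    components: list[np.ndarray] = []

    for trait in ("body_size", "nd"):
        if trait not in mask:
            continue
        values = np.array([float(traits.trait(s, trait)) for s in species])
        rng = values.max() - values.min()
        if rng <= 0:
            warnings.warn(f"trait {trait} has zero range; dropped from similarity")
            continue
        components.append(np.abs(values[:, None] - values[None, :]) / rng)

    if "status" in mask:
        status = np.array(
            [float(traits.trait(s, "biogeographic_status") == "exotic") for s in species]
        )
        components.append((status[:, None] != status[None, :]).astype(float))

    if "phenology" in mask:
        block = np.zeros((n, n))
        phenos = [traits.phenology(s) for s in species]
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - phenological_overlap(phenos[i], phenos[j])
                block[i, j] = block[j, i] = d
        components.append(block)

    if "phylogeny" in mask:
        X = np.vstack([coords.row(s) for s in species])
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        if dist.max() <= 0:
            warnings.warn("phylogenetic distances have zero range; dropped")
        else:
            components.append(dist / dist.max())

    if not components:
        raise ValueError("no usable traits for similarity")
    dissim = np.mean(components, axis=0)
    np.fill_diagonal(dissim, 0.0)
    sim = 1.0 - np.clip(dissim, 0.0, 1.0)
    return pd.DataFrame(sim, index=species, columns=species)


def _neighbours(
    sim: pd.DataFrame,
    focal: str,
    candidates: Sequence[str],
    k: int,
    exclude_self: bool,
    seed: int,
) -> list[str]:
    """k most similar candidates; similarity ties broken in seeded random order."""
    import warnings

    if focal not in sim.index:
        raise KeyError(f"{focal!r} has no similarity row")
    pool = [c for c in candidates if c in sim.columns]
    if exclude_self:
        pool = [c for c in pool if c != focal]
    if not pool:
        raise ValueError(f"no eligible neighbours for {focal!r}")
    if len(pool) < k:
        warnings.warn(f"only {len(pool)} neighbours available for {focal!r} (k={k})")
        k = len(pool)
    rng = np.random.default_rng(seed)
    jitter = {c: r for c, r in zip(pool, rng.permutation(len(pool)))}
    ranked = sorted(pool, key=lambda c: (-float(sim.loc[focal, c]), jitter[c]))
    return ranked[:k]


def knn_predict(
    meta: MetaNetwork,
    sim: pd.DataFrame,
    hp: KNNHyperparams,
    focal_parasitoid: str,
    hosts: Sequence[str],
    exclude_self: bool = True,
) -> pd.Series:
    """Predicted attack frequency of one parasitoid on each listed host.

    The prediction is a (uniform or similarity-weighted) mean of the
    k nearest training parasitoids' meta-network rows, hence always a
    convex combination of observed neighbour frequencies.
    """
    if meta.mode != "weighted":
        raise ValueError("KNN requires a weighted meta-network")
    neigh = _neighbours(
        sim, focal_parasitoid, list(meta.parasitoids), hp.k, exclude_self, hp.seed
    )
    freqs = np.vstack(
        [meta.counts[p].reindex(list(hosts), fill_value=0).to_numpy(dtype=float) for p in neigh]
    )
    if hp.weighting == "uniform":
        weights = np.ones(len(neigh))
    else:
        weights = np.array([max(float(sim.loc[focal_parasitoid, p]), 0.0) for p in neigh])
        if weights.sum() <= 0:
            weights = np.ones(len(neigh))
    weights = weights / weights.sum()
    return pd.Series(weights @ freqs, index=list(hosts))


def add_new_hosts(
    meta: MetaNetwork,
    new_hosts: Sequence[str],
    host_sim: pd.DataFrame,
    hp: KNNHyperparams,
) -> MetaNetwork:
    """Cold-start insertion of test-only hosts into the meta-network.

    Each new host's row is the (weighted) mean of its k most similar
    training hosts' parasitoid profiles; existing rows are untouched.
    Imputed frequencies are kept fractional.
    """
    counts = meta.counts.copy().astype(float)
    for h in new_hosts:
        if h in counts.index:
            raise ValueError(f"host {h!r} already present in meta-network")
        neigh = _neighbours(host_sim, h, list(meta.hosts), hp.k, exclude_self=True, seed=hp.seed)
        rows = np.vstack([counts.loc[nb].to_numpy(dtype=float) for nb in neigh])
        if hp.weighting == "uniform":
            weights = np.ones(len(neigh))
        else:
            weights = np.array([max(float(host_sim.loc[h, nb]), 0.0) for nb in neigh])
            if weights.sum() <= 0:
                weights = np.ones(len(neigh))
        weights = weights / weights.sum()
        counts.loc[h] = weights @ rows
    return MetaNetwork(
        counts=counts, mode="weighted", provenance=meta.provenance, sites=meta.sites
    )


def predict_site_frequencies(
    meta_augmented: MetaNetwork,
    sim: pd.DataFrame,
    hp: KNNHyperparams,
    site_id: str,
    hosts: Sequence[str],
    parasitoids: Sequence[str],
    exclude_self: bool = True,
) -> pd.DataFrame:
    """Predicted frequency matrix for a site via knn_predict per parasitoid."""
    missing = [h for h in hosts if h not in meta_augmented.counts.index]
    if missing:
        raise KeyError(f"hosts absent from augmented meta-network: {missing}")
    missing_p = [p for p in parasitoids if p not in sim.index]
    if missing_p:
        raise KeyError(f"parasitoids without similarity rows: {missing_p}")
    cols = {}
    for p in parasitoids:
        cols[p] = knn_predict(meta_augmented, sim, hp, p, hosts, exclude_self=exclude_self)
    matrix = pd.DataFrame(cols, index=list(hosts))
    matrix.attrs["site_id"] = site_id
    return matrix


def tune_knn(
    meta: MetaNetwork,
    sim_builder,
    grid: Sequence[KNNHyperparams],
    folds: int = 4,
) -> tuple[KNNHyperparams, pd.DataFrame]:
    """Leave-species-out cross-validation over (k, trait mask) grid cells.

    ``sim_builder(mask)`` must return a parasitoid similarity matrix
    for a trait mask.  Each held-out parasitoid's meta-network row is
    predicted from the remaining species and scored by RMSE; the cell
    with the lowest mean error wins, ties towards smaller k then grid
    order.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    paras = list(meta.parasitoids)
    if folds > len(paras):
        raise ValueError("more folds than parasitoid species")
    results = []
    for idx, hp in enumerate(grid):
        sim = sim_builder(hp.mask)
        errors = []
        for p in paras:
            observed = meta.counts[p].to_numpy(dtype=float)
            try:
                predicted = knn_predict(meta, sim, hp, p, meta.hosts, exclude_self=True)
            except ValueError:
                continue
            errors.append(float(np.sqrt(np.mean((predicted.to_numpy() - observed) ** 2))))
        results.append(
            {
                "grid_index": idx,
                "k": hp.k,
                "weighting": hp.weighting,
                "mask": "+".join(hp.mask),
                "cv_rmse": float(np.mean(errors)) if errors else np.inf,
            }
        )
    table = pd.DataFrame(results)
    best_idx = sorted(
        range(len(grid)), key=lambda i: (table.loc[i, "cv_rmse"], grid[i].k, i)
    )[0]
    return grid[best_idx], table
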