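"""Random-forest prediction of host-parasitoid interaction occurrence.

The model learns, from a binary training meta-network, which
combinations of host and parasitoid traits (body size, biogeographic
status, monthly phenology, normalised degree), phylogenetic positions
(principal-coordinate axes) and pairwise phenological overlap
correspond to an interaction occurring.  It then scores every
host x parasitoid pair at a test site with a probability of interaction
occurrence, used downstream as a quantitative predictor of interaction
frequency.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .networks import MetaNetwork, PhyloCoordinates, TraitTable, phenological_overlap

#: trait blocks the grid-search mask can switch on or off
TRAIT_BLOCKS = ("body_size", "status", "phenology", "nd", "phylogeny", "overlap")


@dataclass(frozen=True)
class RFHyperparams:
    n_trees: int = 500
    max_depth: int | None = None
    features_per_split: str = "sqrt"  # "sqrt" or "all"
    min_leaf: int = 1
    trait_mask: tuple = TRAIT_BLOCKS
    phylo_axes: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.features_per_split not in ("sqrt", "all"):
            raise ValueError("features_per_split must be 'sqrt' or 'all'")

    @property
    def sklearn_max_features(self):
        return "sqrt" if self.features_per_split == "sqrt" else None


def default_grid(seed: int = 0) -> list[RFHyperparams]:
    """Default hyperparameter grid; overridable from config."""
    grid = []
    for n_trees, depth, feats, m in itertools.product(
        (200, 500), (None, 10), ("sqrt", "all"), (3, 5)
    ):
        grid.append(
            RFHyperparams(
                n_trees=n_trees,
                max_depth=depth,
                features_per_split=feats,
                phylo_axes=m,
                seed=seed,
            )
        )
    return grid


def feature_names(mask: Sequence[str], m: int, n_months: int = 7) -> list[str]:
    """Canonical feature order for a trait mask and phylo dimension."""
    names: list[str] = []
    if "body_size" in mask:
        names.append("host_body_size")
    if "status" in mask:
        names.append("host_exotic")
    if "phenology" in mask:
        names += [f"host_pheno_m{i}" for i in range(1, n_months + 1)]
    if "nd" in mask:
        names.append("host_nd")
    if "body_size" in mask:
        names.append("para_body_size")
    if "phenology" in mask:
        names += [f"para_pheno_m{i}" for i in range(1, n_months + 1)]
    if "nd" in mask:
        names.append("para_nd")
    if "phylogeny" in mask:
        names += [f"host_phylo_{k + 1}" for k in range(m)]
        names += [f"para_phylo_{k + 1}" for k in range(m)]
    if "overlap" in mask:
        names.append("pheno_overlap")
    if not names:
        raise ValueError("trait mask selects no features")
    return names


def build_pair_features(
    hosts: Sequence[str],
    parasitoids: Sequence[str],
    traits: TraitTable,
    host_coords: PhyloCoordinates,
    para_coords: PhyloCoordinates,
    labels: MetaNetwork | None = None,
    mask: Sequence[str] = TRAIT_BLOCKS,
    m: int = 3,
) -> pd.DataFrame:
    """Featurise every host x parasitoid pair.

    Returns a DataFrame with one row per pair (|hosts| * |parasitoids|
    rows), columns in the canonical :func:`feature_names` order plus
    ``host_id``/``parasitoid_id`` identifiers and, when a binary
    meta-network is supplied, a 0/1 ``label`` column.
    """
    missing = [s for s in list(hosts) + list(parasitoids) if s not in traits.df.index]
    if missing:
        raise KeyError(f"species lacking trait rows: {missing}")
    if labels is not None and labels.mode != "binary":
        raise ValueError("labels must come from a binary meta-network")
    for h in hosts:
        if pd.isna(traits.trait(h, "body_size")):
            raise ValueError(f"host {h} has missing body_size")
    names = feature_names(mask, m)
    rows = []
    for h in hosts:
        h_pheno = traits.phenology(h)
        h_coord = host_coords.row(h)[:m] if "phylogeny" in mask else None
        for p in parasitoids:
            p_pheno = traits.phenology(p)
            feat: dict[str, float] = {"host_id": h, "parasitoid_id": p}
            if "body_size" in mask:
                feat["host_body_size"] = float(traits.trait(h, "body_size"))
                feat["para_body_size"] = float(traits.trait(p, "body_size"))
            if "status" in mask:
                feat["host_exotic"] = float(traits.trait(h, "biogeographic_status") == "exotic")
            if "phenology" in mask:
                for i, v in enumerate(h_pheno, start=1):
                    feat[f"host_pheno_m{i}"] = float(v)
                for i, v in enumerate(p_pheno, start=1):
                    feat[f"para_pheno_m{i}"] = float(v)
            if "nd" in mask:
                feat["host_nd"] = float(traits.trait(h, "nd"))
                feat["para_nd"] = float(traits.trait(p, "nd"))
            if "phylogeny" in mask:
                for k, v in enumerate(h_coord, start=1):
                    feat[f"host_phylo_{k}"] = float(v)
                for k, v in enumerate(para_coords.row(p)[:m], start=1):
                    feat[f"para_phylo_{k}"] = float(v)
            if "overlap" in mask:
                feat["pheno_overlap"] = phenological_overlap(h_pheno, p_pheno)
            if labels is not None:
                feat["label"] = int(labels.counts.loc[h, p]) if (
                    h in labels.counts.index and p in labels.counts.columns
                ) else 0
            rows.append(feat)
    cols = ["host_id", "parasitoid_id"] + names + (["label"] if labels is not None else [])
    df = pd.DataFrame(rows, columns=cols)
    if df[names].isna().any().any():
        bad = df[names].columns[df[names].isna().any()].tolist()
        raise ValueError(f"missing values in features: {bad}")
    return df


@dataclass
class RFModel:
    """Fitted classifier plus the manifest needed to reproduce it."""

    classifier: RandomForestClassifier
    hp: RFHyperparams
    feature_names: list[str]
    provenance: str = ""

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        proba = self.classifier.predict_proba(X)
        pos = list(self.classifier.classes_).index(1)
        return proba[:, pos]

    def manifest(self) -> dict:
        return {
            "hyperparams": {
                "n_trees": self.hp.n_trees,
                "max_depth": self.hp.max_depth,
                "features_per_split": self.hp.features_per_split,
                "min_leaf": self.hp.min_leaf,
                "trait_mask": list(self.hp.trait_mask),
                "phylo_axes": self.hp.phylo_axes,
                "seed": self.hp.seed,
            },
            "feature_order": self.feature_names,
            "training_provenance": self.provenance,
        }

    def save(self, path) -> None:
        """Persist the fitted model plus its manifest (joblib format)."""
        import json
        from pathlib import Path

        import joblib

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier, path / "forest.joblib")
        (path / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))

    @classmethod
    def load(cls, path) -> "RFModel":
        import json
        from pathlib import Path

        import joblib

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        hp = manifest["hyperparams"]
        return cls(
            classifier=joblib.load(path / "forest.joblib"),
            hp=RFHyperparams(
                n_trees=hp["n_trees"],
                max_depth=hp["max_depth"],
                features_per_split=hp["features_per_split"],
                min_leaf=hp["min_leaf"],
                trait_mask=tuple(hp["trait_mask"]),
                phylo_axes=hp["phylo_axes"],
                seed=hp["seed"],
            ),
            feature_names=manifest["feature_order"],
            provenance=manifest["training_provenance"],
        )


def train_rf(features: pd.DataFrame, hp: RFHyperparams, provenance: str = "") -> RFModel:
    """Fit a random forest on labelled pair features.

    Deterministic for a fixed seed; requires both interaction and
    non-interaction pairs in the labels.
    """
    if "label" not in features.columns:
        raise ValueError("features carry no labels; build them with a binary meta-network")
    y = features["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: labels contain a single class")
    names = feature_names(hp.trait_mask, hp.phylo_axes)
    missing = [n for n in names if n not in features.columns]
    if missing:
        raise KeyError(f"feature columns absent: {missing}")
    clf = RandomForestClassifier(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        max_features=hp.sklearn_max_features,
        min_samples_leaf=hp.min_leaf,
        random_state=hp.seed,
        n_jobs=1,
    )
    clf.fit(features[names].to_numpy(dtype=float), y)
    return RFModel(classifier=clf, hp=hp, feature_names=names, provenance=provenance)


def grid_search(
    features: pd.DataFrame,
    grid: Sequence[RFHyperparams],
    folds: int = 5,
    metric=roc_auc_score,
) -> tuple[RFHyperparams, pd.DataFrame]:
    """Stratified k-fold grid search scored by ranking AUC.

    Ties are broken towards the smaller model (fewer trees, then
    shallower), then by grid order.  Returns the winning cell and the
    per-cell mean CV scores.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = features["label"].to_numpy(dtype=int)
    if min(np.bincount(y)) < folds:
        raise ValueError("a fold would lack both classes; reduce folds")
    scores = []
    for idx, hp in enumerate(grid):
        names = feature_names(hp.trait_mask, hp.phylo_axes)
        X = features[names].to_numpy(dtype=float)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=hp.seed)
        fold_scores = []
        for train_idx, test_idx in cv.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=hp.n_trees,
                max_depth=hp.max_depth,
                max_features=hp.sklearn_max_features,
                min_samples_leaf=hp.min_leaf,
                random_state=hp.seed,
                n_jobs=1,
            )
            clf.fit(X[train_idx], y[train_idx])
            pos = list(clf.classes_).index(1)
            p_hat = clf.predict_proba(X[test_idx])[:, pos]
            fold_scores.append(metric(y[test_idx], p_hat))
        scores.append(
            {
                "grid_index": idx,
                "n_trees": hp.n_trees,
                "max_depth": hp.max_depth,
                "features_per_split": hp.features_per_split,
                "phylo_axes": hp.phylo_axes,
                "trait_mask": "+".join(hp.trait_mask),
                "cv_score": float(np.mean(fold_scores)),
            }
        )
    table = pd.DataFrame(scores)
    best_idx = sorted(
        range(len(grid)),
        key=lambda i: (
            -table.loc[i, "cv_score"],
            grid[i].n_trees,
            grid[i].max_depth if grid[i].max_depth is not None else np.inf,
            i,
        ),
    )[0]
    return grid[best_idx], table


def predict_probabilities(
    model: RFModel,
    site_id: str,
    hosts: Sequence[str],
    parasitoids: Sequence[str],
    traits: TraitTable,
    host_coords: PhyloCoordinates,
    para_coords: PhyloCoordinates,
) -> pd.DataFrame:
    """Probability-of-occurrence matrix for a site's hosts x parasitoids."""
    features = build_pair_features(
        hosts,
        parasitoids,
        traits,
        host_coords,
        para_coords,
        mask=model.hp.trait_mask,
        m=model.hp.phylo_axes,
    )
    p_hat = model.predict_proba(features)
    matrix = pd.DataFrame(
        p_hat.reshape(len(hosts), len(parasitoids)),
        index=list(hosts),
        columns=list(parasitoids),
    )
    matrix.attrs["site_id"] = site_id
    return matrix


def gini_importances(model: RFModel) -> pd.Series:
    """Mean-decrease-in-impurity importance per feature (sums to 1)."""
    if model.classifier is None or not hasattr(model.classifier, "feature_importances_"):
        raise ValueError("model is not trained")
    imp = pd.Series(model.classifier.feature_importances_, index=model.feature_names)
    return imp
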