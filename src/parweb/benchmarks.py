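"""Recovery benchmarks on synthetic communities.

These are the package's standard checks that each stage recovers the
structure the generator put in: held-out link-prediction AUC under
trait matching and in the neutral limit, direct-validation slope
recovery, and indirect-effect (apparent competition) recovery with a
host-reduction treatment, plus its permutation null for type-I-error
calibration.

The AUC benchmarks use the trait-matching feature mask only (body
size, phylogeny, phenological overlap): normalised degree and raw
monthly phenology magnitudes are derived from abundances and the
training network, so including them would mix neutral
(marginal-abundance) predictability into what is meant to measure
trait matching.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import evaluate, indirect, rf
from .networks import patristic_coordinates
from .simulate import CommunityConfig, generate_community

#: feature blocks measuring trait/phylogeny matching only
MATCHING_MASK = ("body_size", "phylogeny", "overlap")


def strong_sharing_config(seed: int = 0, **overrides) -> CommunityConfig:
    """Community preset with generalist parasitoids (strong parasitoid
    sharing among hosts) and the experimental host reduction, sized for
    replicated benchmarking."""
    base = CommunityConfig(
        n_hosts=20,
        n_parasitoids=10,
        training_sites_per_habitat=4,
        test_sites_per_habitat=8,
        beta_size=2.0,
        sigma_size=0.5,
        beta_phen=1.0,
        beta_phylo=1.0,
        phylo_bandwidth=1.5,
        beta0=-7.0,
        host_abundance_mu=math.log(60.0),
        host_abundance_sigma=0.5,
        rho=0.2,
        seed=seed,
    )
    return replace(base, **overrides)


def rf_holdout_auc(
    config: CommunityConfig, folds: int = 5, n_trees: int = 300, m: int = 3
) -> float:
    """Cross-validated held-out pair AUC of the random forest on the
    binary training meta-network, matching features only."""
    com = generate_community(config)
    meta_b = com.training_meta(mode="binary")
    hc = patristic_coordinates(com.host_tree, m=min(5, config.n_hosts - 1))
    pc = patristic_coordinates(com.para_tree, m=min(5, config.n_parasitoids - 1))
    feats = rf.build_pair_features(
        meta_b.hosts, meta_b.parasitoids, com.traits, hc, pc,
        labels=meta_b, mask=MATCHING_MASK, m=m,
    )
    y = feats["label"].to_numpy()
    cv = StratifiedKFold(folds, shuffle=True, random_state=config.seed)
    scores = []
    for train_idx, test_idx in cv.split(feats, y):
        model = rf.train_rf(
            feats.iloc[train_idx],
            rf.RFHyperparams(n_trees=n_trees, trait_mask=MATCHING_MASK,
                             phylo_axes=m, seed=config.seed),
        )
        scores.append(roc_auc_score(y[test_idx], model.predict_proba(feats.iloc[test_idx])))
    return float(np.mean(scores))


def _indirect_tables(config: CommunityConfig):
    """Expected and observed parasitism records via the data-based route
    (observed combined meta-network for d, observed time-t attack rates)."""
    com = generate_community(config)
    meta = com.training_meta("combined", "weighted")
    d = indirect.potential_apparent_competition(meta)
    expected, observed = [], []
    for (site, step), net in com.test_networks.items():
        if step != "t":
            continue
        if net.counts.to_numpy().sum() == 0:
            continue
        net_t1 = com.test_networks[(site, "t_plus_1")]
        alpha = net.counts.astype(float)
        expected += indirect.expected_parasitism(
            d, alpha, net.host_sample, net_t1.host_sample, site_id=site
        )
        observed += indirect.observed_parasitism(net_t1)
    return expected, observed


def indirect_recovery_pvalue(config: CommunityConfig) -> tuple[float, float]:
    """(slope, p) of the indirect validation on one community replicate."""
    expected, observed = _indirect_tables(config)
    result = evaluate.validate_indirect(expected, observed)
    coef = result["fit"].coefficients.loc["expected"]
    return float(coef["estimate"]), float(coef["p"])


def indirect_null_pvalue(config: CommunityConfig, perm_seed: int) -> float:
    """p-value of the slope after permuting E across hosts within each
    site, destroying any true coupling while keeping the marginals."""
    expected, observed = _indirect_tables(config)
    rng = np.random.default_rng(perm_seed)
    by_site: dict[str, list] = {}
    for r in expected:
        if r.eligible:
            by_site.setdefault(r.site_id, []).append(r)
    permuted = []
    for site, recs in sorted(by_site.items()):
        values = [r.E for r in recs]
        order = rng.permutation(len(values))
        for r, idx in zip(recs, order):
            permuted.append(
                indirect.ExpectedParasitismRecord(r.site_id, r.host_id, values[idx], True)
            )
    result = evaluate.validate_indirect(permuted, observed)
    return float(result["fit"].coefficients.loc["expected", "p"])
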