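"""Config-driven orchestration of the full analysis.

Stages: simulate (or load) a study bundle -> pool training
meta-networks -> train the link predictors -> predict test-site
networks at time t -> project d_ij -> attack rates -> expected
parasitism at t+1 -> validation fits -> consolidated report.  Every
stage's outputs are written and hashed so a rerun with the same config
and seed reproduces the manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import evaluate, indirect, knn, rf
from .networks import (
    MetaNetwork,
    TraitTable,
    patristic_coordinates,
    pool_meta_network,
    read_interactions,
    site_networks_from_records,
)
from .simulate import CommunityConfig, generate_community

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    community: CommunityConfig = field(default_factory=CommunityConfig)
    bundle_path: str | None = None  # load instead of simulate when set
    training_pool: str = "combined"  # native | plantation | combined
    engine: str = "both"  # rf | knn | both
    d_source: str = "observed_meta"  # observed_meta | predicted
    alpha_source: str = "auto"  # auto (per engine) | observed
    criterion: str = "aic"
    leverage_threshold: float = 2.0
    alpha_level: float = 0.05
    tune: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.engine not in ("rf", "knn", "both"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.d_source not in ("observed_meta", "predicted"):
            raise ValueError(f"unknown d source {self.d_source!r}")
        if self.training_pool not in ("native", "plantation", "combined"):
            raise ValueError(f"unknown training pool {self.training_pool!r}")


def write_predictions_csv(predictions: dict, path, value_name: str) -> None:
    """Long-format CSV of per-site predicted matrices:
    site_id, host_id, parasitoid_id, <value_name>."""
    rows = []
    for site_id, matrix in predictions.items():
        for h in matrix.index:
            for p in matrix.columns:
                rows.append(
                    {
                        "site_id": site_id,
                        "host_id": h,
                        "parasitoid_id": p,
                        value_name: float(matrix.loc[h, p]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def _load_bundle(path: str):
    """Reload a study bundle written by make_study_bundle."""
    p = Path(path)
    records = read_interactions(p / "interactions.csv")
    traits = TraitTable.read_csv(p / "traits.csv")
    host_tree = (p / "host.nwk").read_text()
    para_tree = (p / "parasitoid.nwk").read_text()
    samples = pd.read_csv(p / "host_samples.csv")
    host_samples = {
        (site, step): dict(zip(grp["host_id"], grp["n"]))
        for (site, step), grp in samples.groupby(["site_id", "time_step"])
    }
    return records, traits, host_tree, para_tree, host_samples


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute the full analysis; returns results plus a run manifest."""
    t_start = time.time()
    timings = {}
    results: dict = {"config": asdict(config)}

    def stage(name):
        timings[name] = time.time() - t_start

    # --- stage: simulate or load -----------------------------------------
    if config.bundle_path:
        records, traits, host_tree, para_tree, host_samples = _load_bundle(
            config.bundle_path
        )
        training_records = [r for r in records if r.time_step == "training"]
        test_records = [r for r in records if r.time_step != "training"]
        hosts = traits.species("host")
        paras = traits.species("parasitoid")
        test_networks = site_networks_from_records(
            test_records, host_samples, hosts, paras
        )
        site_habitat = {r.site_id: r.habitat for r in records}
    else:
        community = generate_community(config.community)
        training_records = community.training_records
        traits = community.traits
        host_tree, para_tree = community.host_tree, community.para_tree
        test_networks = community.test_networks
        host_samples = community.host_samples
        site_habitat = community.site_habitat
        hosts = traits.species("host")
        paras = traits.species("parasitoid")
    stage("load")

    # --- stage: pool meta-networks ----------------------------------------
    meta_w = pool_meta_network(training_records, config.training_pool, "weighted")
    meta_b = meta_w.binarize()
    combined_meta = pool_meta_network(training_records, "combined", "weighted")
    stage("pool")

    # --- stage: phylogenetic coordinates ----------------------------------
    m = 3
    host_coords = patristic_coordinates(host_tree, m=min(5, len(hosts) - 1))
    para_coords = patristic_coordinates(para_tree, m=min(5, len(paras) - 1))
    stage("coords")

    # test sites with at least one parasitoid observed at time t
    test_sites = sorted({s for (s, step) in test_networks if step == "t"})
    usable_sites = [
        s for s in test_sites if test_networks[(s, "t")].counts.to_numpy().sum() > 0
    ]
    excluded = [s for s in test_sites if s not in usable_sites]
    if excluded:
        logger.info("excluding %d test sites with no parasitoids at t: %s",
                    len(excluded), excluded)
    results["excluded_sites"] = excluded

    def site_species(site_id):
        net = test_networks[(site_id, "t")]
        site_hosts = [h for h in hosts if net.host_sample.get(h, 0) > 0]
        site_paras = [p for p in paras if net.counts[p].sum() > 0]
        return site_hosts, site_paras

    engines = ["rf", "knn"] if config.engine == "both" else [config.engine]
    predictions: dict[str, dict] = {}

    # --- stage: train + predict -------------------------------------------
    if "rf" in engines:
        feats = rf.build_pair_features(
            meta_b.hosts, meta_b.parasitoids, traits, host_coords, para_coords,
            labels=meta_b, m=m,
        )
        if config.tune:
            hp, _ = rf.grid_search(feats, rf.default_grid(seed=config.seed))
        else:
            hp = rf.RFHyperparams(n_trees=300, phylo_axes=m, seed=config.seed)
        model = rf.train_rf(feats, hp, provenance=config.training_pool)
        results["rf_importances"] = rf.gini_importances(model).to_dict()
        predictions["rf"] = {}
        for s in usable_sites:
            sh, sp = site_species(s)
            if not sh or not sp:
                continue
            predictions["rf"][s] = rf.predict_probabilities(
                model, s, sh, sp, traits, host_coords, para_coords
            )
    if "knn" in engines:
        para_sim = knn.gower_similarity(
            traits, "parasitoid", knn.DEFAULT_PARASITOID_MASK,
            coords=para_coords, species=paras,
        )
        host_sim = knn.gower_similarity(
            traits, "host", knn.DEFAULT_HOST_MASK, coords=host_coords, species=hosts,
        )
        hp_knn = knn.KNNHyperparams(k=3, seed=config.seed)
        if config.tune:
            grid = [
                knn.KNNHyperparams(k=k, mask=mask, seed=config.seed)
                for k in (1, 3, 5)
                for mask in (knn.DEFAULT_PARASITOID_MASK, ("body_size", "phenology"))
            ]
            hp_knn, _ = knn.tune_knn(
                meta_w,
                lambda mask: knn.gower_similarity(
                    traits, "parasitoid", mask, coords=para_coords, species=paras
                ),
                grid,
            )
        new_hosts = [h for h in hosts if h not in meta_w.counts.index]
        meta_aug = knn.add_new_hosts(meta_w, new_hosts, host_sim, hp_knn) if new_hosts else meta_w
        predictions["knn"] = {}
        for s in usable_sites:
            sh, sp = site_species(s)
            if not sh or not sp:
                continue
            predictions["knn"][s] = knn.predict_site_frequencies(
                meta_aug, para_sim, hp_knn, s, sh, sp
            )
    stage("predict")

    # --- stage: indirect effects ------------------------------------------
    observed_t = {s: test_networks[(s, "t")] for s in usable_sites}
    results["fits"] = {}
    for engine in engines:
        if config.d_source == "observed_meta":
            d = indirect.potential_apparent_competition(combined_meta)
        else:
            pooled = None
            for s, matrix in predictions[engine].items():
                frame = matrix.reindex(index=hosts, columns=paras, fill_value=0.0)
                pooled = frame if pooled is None else pooled + frame
            d = indirect.potential_apparent_competition(
                MetaNetwork(pooled, "weighted", f"predicted_{engine}")
            )
        expected, observed = [], []
        for s in usable_sites:
            if s not in predictions[engine]:
                continue
            net_t = test_networks[(s, "t")]
            net_t1 = test_networks.get((s, "t_plus_1"))
            if net_t1 is None:
                continue
            if config.alpha_source == "observed":
                alpha = indirect.attack_rates_from_predictions(
                    predictions[engine][s], net_t.host_sample, "observed", observed_t=net_t
                )
            else:
                alpha = indirect.attack_rates_from_predictions(
                    predictions[engine][s], net_t.host_sample,
                    "rf" if engine == "rf" else "knn",
                )
            expected += indirect.expected_parasitism(
                d, alpha, net_t.host_sample, net_t1.host_sample, site_id=s
            )
            observed += indirect.observed_parasitism(net_t1)
        eligible = sum(r.eligible for r in expected)
        results[f"{engine}_eligible_hosts"] = eligible
        logger.info("%s: %d eligible host records", engine, eligible)

        direct = evaluate.validate_direct(
            predictions[engine], observed_t, traits,
            {s: site_habitat[s] for s in usable_sites}, criterion=config.criterion,
        )
        indirect_fit = evaluate.validate_indirect(
            expected, observed, criterion=config.criterion,
            leverage_threshold=config.leverage_threshold,
        )
        results["fits"][engine] = {
            "direct": direct,
            "indirect": indirect_fit,
            "expected_records": expected,
        }
    stage("evaluate")

    # --- Bernoulli multiple-test summary over the model family ------------
    slope_ps = []
    for engine in engines:
        for kind in ("direct", "indirect"):
            fit = results["fits"][engine][kind]["fit"]
            term = "predicted" if kind == "direct" else "expected"
            if term in fit.coefficients.index:
                slope_ps.append(float(fit.coefficients.loc[term, "p"]))
    k_sig = sum(p < config.alpha_level for p in slope_ps)
    results["bernoulli"] = {
        "n_tests": len(slope_ps),
        "k_significant": k_sig,
        "alpha": config.alpha_level,
        "tail_probability": evaluate.bernoulli_multiple_tests(
            len(slope_ps), k_sig, config.alpha_level
        )
        if slope_ps
        else None,
    }
    results["timings"] = timings

    if outdir is not None:
        results["manifest"] = write_report(results, outdir)
    return results


def _fit_summary(fit) -> dict:
    coef = {
        term: {
            "estimate": round(float(row["estimate"]), 10),
            "se": round(float(row["se"]), 10),
            "z": round(float(row["z"]), 10),
            "p": round(float(row["p"]), 10),
        }
        for term, row in fit.coefficients.iterrows()
    }
    m, c = (fit.marginal_r2, fit.conditional_r2)
    return {
        "coefficients": coef,
        "aic": round(float(fit.aic), 10),
        "aicc": round(float(fit.aicc), 10),
        "dispersion": round(float(fit.dispersion), 10),
        "marginal_r2": round(float(m), 10) if m is not None else "undefined",
        "conditional_r2": round(float(c), 10) if c is not None else "undefined",
        "n_obs": fit.n_obs,
        "converged": fit.converged,
    }


def write_report(results: dict, outdir) -> dict:
    """Write JSON + text report and a manifest of output hashes."""
    if not results.get("fits"):
        raise ValueError("no fits to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": results["config"],
        "excluded_sites": results.get("excluded_sites", []),
        "bernoulli": results.get("bernoulli"),
        "models": {},
    }
    lines = ["Host-parasitoid network prediction report", "=" * 42, ""]
    for engine, fits in results["fits"].items():
        block: dict = {}
        direct, indir = fits["direct"], fits["indirect"]
        block["direct"] = _fit_summary(direct["fit"])
        block["direct"]["selection"] = direct["selection"].table.to_dict("records")
        block["direct"]["inclusion_fractions"] = (
            direct["selection"].inclusion_fractions.round(6).to_dict()
        )
        block["direct"]["dispersion_check"] = {
            k: (round(v, 10) if isinstance(v, float) else v)
            for k, v in direct["dispersion"].items()
        }
        block["indirect"] = _fit_summary(indir["fit"])
        block["indirect"]["outliers"] = [
            str(i) for i in indir["leverage"].index[indir["leverage"]["flagged"]]
        ]
        if indir.get("fit_no_outliers") is not None:
            block["indirect"]["without_outliers"] = _fit_summary(indir["fit_no_outliers"])
        block["eligible_hosts"] = results.get(f"{engine}_eligible_hosts")
        report["models"][engine] = block

        lines.append(f"[{engine}] direct validation (Poisson, scaled predictor)")
        slope = direct["fit"].coefficients.loc["predicted"]
        lines.append(
            f"  slope={slope['estimate']:+.4f}  z={slope['z']:.2f}  p={slope['p']:.4g}"
        )
        m, c = direct["fit"].marginal_r2, direct["fit"].conditional_r2
        lines.append(
            f"  marginal R2={'undefined' if m is None else f'{m:.3f}'}  "
            f"conditional R2={'undefined' if c is None else f'{c:.3f}'}"
        )
        lines.append(f"[{engine}] indirect validation (binomial, scaled E)")
        if "expected" in indir["fit"].coefficients.index:
            s2 = indir["fit"].coefficients.loc["expected"]
            lines.append(
                f"  slope={s2['estimate']:+.4f}  z={s2['z']:.2f}  p={s2['p']:.4g}"
            )
        lines.append(f"  eligible hosts: {block['eligible_hosts']}")
        lines.append("")
    if results.get("bernoulli") and results["bernoulli"]["tail_probability"] is not None:
        b = results["bernoulli"]
        lines.append(
            f"Bernoulli summary: {b['k_significant']}/{b['n_tests']} slopes significant "
            f"at alpha={b['alpha']}; tail probability {b['tail_probability']:.3g}"
        )
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    text_path = outdir / "report.txt"
    text_path.write_text("\n".join(lines) + "\n")
    manifest = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        for name in ("report.json", "report.txt")
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps({"outputs": manifest, "config": results["config"]},
                   indent=2, sort_keys=True, default=str)
    )
    return manifest
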