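"""Synthetic host-parasitoid metacommunities for end-to-end testing.

The generator emulates the statistical structure the analysis assumes:
phylogenetically structured traits (Brownian-motion log body size on
pure-birth trees, Dirichlet monthly phenology), interaction
propensities combining niche terms (a Gaussian body-size matching
kernel, phenological overlap, a parasitoid preference for host clades)
with a neutral abundance term, two forest types, pooled training
sites, and test sites sampled at times t and t+1 with a host-reduction
perturbation (multiplier rho) at half the plantation test sites.

Parasitoid abundances at t+1 respond numerically to the realised
changes in the abundance of the hosts they recruited from at time t,
which is the mechanism that makes apparent competition (and hence the
expected-parasitism projection) detectable downstream.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .networks import (
    HOST_PREFIX,
    N_MONTHS,
    PARASITOID_PREFIX,
    PHENO_COLUMNS,
    InteractionRecord,
    MetaNetwork,
    SiteNetwork,
    TraitTable,
    normalised_degree,
    patristic_coordinates,
    pool_meta_network,
    write_interactions,
)


@dataclass(frozen=True)
class CommunityConfig:
    """Generating conditions for one synthetic metacommunity.

    Defaults mirror the study design: 40 host and 20 parasitoid
    species, 8 training sites per forest type sampled over 7 monthly
    occasions on edge and interior transects, 16 test sites per forest
    type sampled at t and t+1 (edge only), and an experimental
    host-abundance reduction (x ``rho``) at half of the plantation test
    sites at t+1.
    """

    n_hosts: int = 40
    n_parasitoids: int = 20
    training_sites_per_habitat: int = 8
    test_sites_per_habitat: int = 16
    n_months: int = N_MONTHS
    # tree and trait models
    birth_rate: float = 1.0
    bm_sigma2: float = 0.15  # Brownian variance of log body size per unit depth
    pheno_concentration: float = 1.2  # Dirichlet concentration over months
    exotic_fraction: float = 0.3
    host_nd_alpha: float = 2.0  # host plant-generality ~ Beta(alpha, beta)
    host_nd_beta: float = 5.0
    # propensity coefficients: log lambda = beta0 + niche kernels + log n_i + log a_l
    beta0: float = -13.0
    beta_size: float = 6.0  # body-size matching kernel weight (dominant)
    sigma_size: float = 0.5  # kernel width on log body-size difference
    beta_phen: float = 2.0  # phenological overlap weight
    beta_phylo: float = 3.0  # parasitoid preference for host clades
    phylo_bandwidth: float = 0.5
    # abundance model
    host_abundance_mu: float = math.log(12.0)
    host_abundance_sigma: float = 0.4
    para_abundance_sigma: float = 0.35
    temporal_sigma: float = 0.4  # lognormal abundance drift between t and t+1
    habitat_effect: float = 0.2  # log-scale plantation abundance shift
    # sampling effort
    training_exposure: float = 1.0  # per occasion
    test_exposure: float = 2.0  # per time step (two pooled occasions)
    # experimental host reduction at treated sites at t+1
    rho: float = 0.2
    numerical_response: bool = True
    #: what sets attack pressure at t+1: "recruitment" (parasitoids
    #: forage according to where they developed at time t, the dynamics
    #: the apparent-competition projection assumes) or "mass_action"
    #: (pressure tracks current host abundance)
    t1_attack_basis: str = "recruitment"
    holdout_host_fraction: float = 0.1  # hosts absent from training sites
    seed: int = 0

    def __post_init__(self):
        if min(self.n_hosts, self.n_parasitoids) < 2:
            raise ValueError("need at least two species per guild")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")
        if self.sigma_size <= 0:
            raise ValueError("sigma_size must be positive")

    def neutral(self, beta0: float = -7.9) -> "CommunityConfig":
        """Matching coefficients switched off: interactions are driven
        purely by the baseline rate and species abundances.  The
        baseline is raised to compensate for the removed mean kernel
        mass so the overall interaction density stays comparable."""
        return replace(self, beta_size=0.0, beta_phen=0.0, beta_phylo=0.0, beta0=beta0)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tree(n_taxa: int, rate: float, seed: int, prefix: str) -> str:
    """Pure-birth (Yule) ultrametric tree with guild-prefixed tip labels."""
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace(
        [f"{prefix}sp{i + 1:03d}" for i in range(n_taxa)]
    )
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    # the simulator stops at the n-th speciation, leaving that sister pair
    # on zero-length branches; extend every tip by the waiting time to the
    # (unrealised) next event so the present lies strictly after it
    extra = rng.expovariate(rate * n_taxa)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def _brownian_log_trait(tree: dendropy.Tree, sigma2: float, rng: np.random.Generator,
                        root_value: float) -> dict[str, float]:
    values: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_value
        else:
            edge = node.edge.length or 0.0
            values[id(node)] = values[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(sigma2 * edge)
            )
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def simulate_traits(
    newick: str, guild: str, config: CommunityConfig, seed: int
) -> pd.DataFrame:
    """Species traits evolved on the guild tree.

    Log body size follows Brownian motion; monthly phenology rows are
    Dirichlet proportions scaled by a lognormal species activity total;
    biogeographic status is Bernoulli(exotic_fraction) for hosts; host
    ND (plant generality) is Beta-distributed.  Parasitoid ND is left
    unset here and computed later from the training meta-network.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    rngs = _spawn(seed, 4)
    root = np.log(5.0) if guild == "host" else np.log(2.0)
    log_size = _brownian_log_trait(tree, config.bm_sigma2, rngs[0], root)
    species = sorted(log_size)
    n = len(species)
    pheno_prop = rngs[1].dirichlet(
        np.full(config.n_months, config.pheno_concentration), size=n
    )
    activity = rngs[1].lognormal(np.log(50.0), 0.5, size=n)
    rows = []
    for i, sp in enumerate(species):
        row = {
            "species_id": sp,
            "guild": guild,
            "body_size": float(np.exp(log_size[sp])),
            "biogeographic_status": "",
            "nd": np.nan,
            "total_abundance": 0,
        }
        for m, col in enumerate(PHENO_COLUMNS[: config.n_months]):
            row[col] = float(pheno_prop[i, m] * activity[i])
        if guild == "host":
            row["biogeographic_status"] = (
                "exotic" if rngs[2].random() < config.exotic_fraction else "native"
            )
            row["nd"] = float(rngs[3].beta(config.host_nd_alpha, config.host_nd_beta))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class LatentPropensity:
    """Ground-truth per-individual attack kernel exp(beta0 + niche terms)."""

    kernel: pd.DataFrame  # hosts x parasitoids
    coefficients: dict


@dataclass
class Community:
    """Everything one synthetic metacommunity comprises."""

    config: CommunityConfig
    host_tree: str
    para_tree: str
    traits: TraitTable
    latent: LatentPropensity
    training_records: list
    test_records: list
    test_networks: dict  # (site_id, time_step) -> SiteNetwork
    host_samples: dict  # (site_id, time_step) -> {host: n}
    site_habitat: dict
    treated_sites: tuple

    @property
    def records(self) -> list:
        return self.training_records + self.test_records

    def training_meta(self, habitat: str = "combined", mode: str = "weighted") -> MetaNetwork:
        return pool_meta_network(self.training_records, habitat, mode)


def _propensity_kernel(
    traits_df: pd.DataFrame,
    hosts: list[str],
    paras: list[str],
    host_coord1: dict[str, float],
    para_pref: dict[str, float],
    config: CommunityConfig,
) -> np.ndarray:
    hb = np.log(traits_df.loc[hosts, "body_size"].to_numpy(dtype=float))
    pb = np.log(traits_df.loc[paras, "body_size"].to_numpy(dtype=float))
    delta = hb[:, None] - pb[None, :]
    size_kernel = np.exp(-(delta**2) / (2 * config.sigma_size**2))
    pheno = traits_df.loc[hosts + paras, PHENO_COLUMNS[: config.n_months]].to_numpy(dtype=float)
    prop = pheno / pheno.sum(axis=1, keepdims=True)
    hp, pp = prop[: len(hosts)], prop[len(hosts):]
    overlap = np.minimum(hp[:, None, :], pp[None, :, :]).sum(axis=2)
    hc = np.array([host_coord1[h] for h in hosts])
    pref = np.array([para_pref[p] for p in paras])
    phylo_kernel = np.exp(
        -((hc[:, None] - pref[None, :]) ** 2) / (2 * config.phylo_bandwidth**2)
    )
    log_k = (
        config.beta0
        + config.beta_size * size_kernel
        + config.beta_phen * overlap
        + config.beta_phylo * phylo_kernel
    )
    return np.exp(log_k)


def generate_community(config: CommunityConfig) -> Community:
    """Simulate trees, traits, abundances and all site networks."""
    master = np.random.SeedSequence(config.seed)
    seeds = master.generate_state(8)
    host_tree = simulate_tree(config.n_hosts, config.birth_rate, int(seeds[0]), HOST_PREFIX)
    para_tree = simulate_tree(
        config.n_parasitoids, config.birth_rate, int(seeds[1]), PARASITOID_PREFIX
    )
    host_traits = simulate_traits(host_tree, "host", config, int(seeds[2]))
    para_traits = simulate_traits(para_tree, "parasitoid", config, int(seeds[3]))
    traits_df = pd.concat([host_traits, para_traits]).set_index("species_id")
    hosts = sorted(host_traits["species_id"])
    paras = sorted(para_traits["species_id"])
    rng = np.random.default_rng(int(seeds[4]))

    # parasitoid clade preference anchored on the first host PCoA axis
    host_coords = patristic_coordinates(host_tree, m=min(3, config.n_hosts - 1))
    axis1 = {s: host_coords.coords[i, 0] for i, s in enumerate(host_coords.species)}
    scale = max(np.std(list(axis1.values())), 1e-9)
    axis1 = {s: v / scale for s, v in axis1.items()}
    pref = {p: rng.normal(0.0, 1.0) for p in paras}
    kernel = _propensity_kernel(traits_df, hosts, paras, axis1, pref, config)
    latent = LatentPropensity(
        kernel=pd.DataFrame(kernel, index=hosts, columns=paras),
        coefficients={
            "beta0": config.beta0,
            "beta_size": config.beta_size,
            "beta_phen": config.beta_phen,
            "beta_phylo": config.beta_phylo,
        },
    )

    # regional abundances
    para_abund = rng.lognormal(0.0, config.para_abundance_sigma, size=len(paras))
    n_hold = int(round(config.holdout_host_fraction * config.n_hosts))
    holdout = set(rng.choice(hosts, size=n_hold, replace=False)) if n_hold else set()

    pheno_prop = traits_df.loc[hosts, PHENO_COLUMNS[: config.n_months]].to_numpy(dtype=float)
    pheno_prop = pheno_prop / pheno_prop.sum(axis=1, keepdims=True)

    training_records: list[InteractionRecord] = []
    site_habitat: dict[str, str] = {}

    def habitat_shift(habitat: str) -> float:
        return config.habitat_effect if habitat == "plantation" else 0.0

    # --- training sites: 7 occasions, edge + interior transects -----------
    for habitat in ("native", "plantation"):
        for s in range(config.training_sites_per_habitat):
            site_id = f"train_{habitat[:3]}_{s + 1:02d}"
            site_habitat[site_id] = habitat
            n_site = rng.lognormal(
                config.host_abundance_mu + habitat_shift(habitat),
                config.host_abundance_sigma,
                size=len(hosts),
            )
            n_site[[h in holdout for h in hosts]] = 0.0
            for transect in ("edge", "interior"):
                for occ in range(1, config.n_months + 1):
                    n_occ = rng.poisson(n_site * pheno_prop[:, occ - 1])
                    lam = (
                        kernel
                        * n_occ[:, None]
                        * para_abund[None, :]
                        * config.training_exposure
                    )
                    counts = rng.poisson(lam)
                    for i, j in zip(*np.nonzero(counts)):
                        training_records.append(
                            InteractionRecord(
                                site_id=site_id,
                                habitat=habitat,
                                transect=transect,
                                occasion=occ,
                                time_step="training",
                                host_id=hosts[i],
                                parasitoid_id=paras[j],
                                count=int(counts[i, j]),
                            )
                        )

    # --- test sites: times t and t+1, edge transects only -----------------
    test_records: list[InteractionRecord] = []
    test_networks: dict[tuple, SiteNetwork] = {}
    host_samples: dict[tuple, dict] = {}
    treated: list[str] = []
    for habitat in ("native", "plantation"):
        for s in range(config.test_sites_per_habitat):
            site_id = f"test_{habitat[:3]}_{s + 1:02d}"
            site_habitat[site_id] = habitat
            # the biopesticide treatment hits half the plantation test sites
            is_treated = habitat == "plantation" and s < config.test_sites_per_habitat // 2
            if is_treated:
                treated.append(site_id)
            n_expected_t = rng.lognormal(
                config.host_abundance_mu + habitat_shift(habitat),
                config.host_abundance_sigma,
                size=len(hosts),
            )
            drift = rng.lognormal(0.0, config.temporal_sigma, size=len(hosts))
            n_expected_t1 = n_expected_t * drift * (config.rho if is_treated else 1.0)
            n_t = rng.poisson(n_expected_t)
            n_t1 = rng.poisson(n_expected_t1)

            a_t = para_abund.copy()
            if config.numerical_response:
                # recruitment-share-weighted host abundance change
                recruit = kernel * n_t[:, None]
                col = recruit.sum(axis=0)
                ratio = np.divide(
                    n_t1.astype(float), n_t.astype(float),
                    out=np.ones(len(hosts)), where=n_t > 0,
                )
                with np.errstate(invalid="ignore", divide="ignore"):
                    share = np.where(col[None, :] > 0, recruit / col[None, :], 0.0)
                response = np.where(col > 0, (share * ratio[:, None]).sum(axis=0), 1.0)
                a_t1 = para_abund * response
            else:
                a_t1 = para_abund.copy()

            # attack pressure at t+1: recruitment basis allocates
            # parasitoid effort by time-t host abundance (the structure
            # the d_ij projection assumes); mass action tracks n(t+1)
            n_basis_t1 = n_t if config.t1_attack_basis == "recruitment" else n_t1
            for step, n_step, n_basis, a_step, occ in (
                ("t", n_t, n_t, a_t, 4),
                ("t_plus_1", n_t1, n_basis_t1, a_t1, 6),
            ):
                lam = kernel * n_basis[:, None] * a_step[None, :] * config.test_exposure
                counts = rng.poisson(lam)
                sample = {}
                for i, h in enumerate(hosts):
                    attacked = int(counts[i].sum())
                    collected = int(max(n_step[i], attacked))
                    if collected > 0:
                        sample[h] = collected
                host_samples[(site_id, step)] = sample
                for i, j in zip(*np.nonzero(counts)):
                    test_records.append(
                        InteractionRecord(
                            site_id=site_id,
                            habitat=habitat,
                            transect="edge",
                            occasion=occ,
                            time_step=step,
                            host_id=hosts[i],
                            parasitoid_id=paras[j],
                            count=int(counts[i, j]),
                        )
                    )
                counts_df = pd.DataFrame(counts, index=hosts, columns=paras)
                test_networks[(site_id, step)] = SiteNetwork(
                    site_id=site_id,
                    time_step=step,
                    counts=counts_df,
                    host_sample=pd.Series(sample, dtype=float).reindex(hosts, fill_value=0),
                    habitat=habitat,
                )

    # --- finalise the trait table -----------------------------------------
    if not training_records:
        raise RuntimeError("no training interactions generated; raise beta0 or exposure")
    meta = pool_meta_network(training_records, "combined", "weighted")
    for p in paras:
        traits_df.loc[p, "nd"] = (
            normalised_degree(meta, p, "parasitoid") if p in meta.parasitoids else 0.0
        )
        traits_df.loc[p, "total_abundance"] = sum(
            r.count for r in training_records + test_records if r.parasitoid_id == p
        )
    host_totals = {h: 0 for h in hosts}
    for sample in host_samples.values():
        for h, n in sample.items():
            host_totals[h] += n
    # training-site host collections contribute too (attacked hosts observed)
    for r in training_records:
        host_totals[r.host_id] += r.count
    for h in hosts:
        traits_df.loc[h, "total_abundance"] = host_totals[h]

    return Community(
        config=config,
        host_tree=host_tree,
        para_tree=para_tree,
        traits=TraitTable(traits_df.reset_index()),
        latent=latent,
        training_records=training_records,
        test_records=test_records,
        test_networks=test_networks,
        host_samples=host_samples,
        site_habitat=site_habitat,
        treated_sites=tuple(treated),
    )


def make_study_bundle(config: CommunityConfig, outdir) -> dict:
    """Write a complete study bundle to disk and return its manifest.

    Files: interactions.csv, traits.csv, host.nwk, parasitoid.nwk,
    host_samples.csv, config.yaml, manifest.json (content hashes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = generate_community(config)
    write_interactions(community.records, outdir / "interactions.csv")
    community.traits.write_csv(outdir / "traits.csv")
    (outdir / "host.nwk").write_text(community.host_tree + "\n")
    (outdir / "parasitoid.nwk").write_text(community.para_tree + "\n")
    sample_rows = [
        {"site_id": site, "time_step": step, "host_id": h, "n": n}
        for (site, step), table in sorted(community.host_samples.items())
        for h, n in sorted(table.items())
    ]
    pd.DataFrame(sample_rows, columns=["site_id", "time_step", "host_id", "n"]).to_csv(
        outdir / "host_samples.csv", index=False
    )
    cfg = {
        k: (float(v) if isinstance(v, (np.floating, float)) else v)
        for k, v in asdict(config).items()
    }
    cfg["treated_sites"] = list(community.treated_sites)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    manifest = {}
    for name in (
        "interactions.csv",
        "traits.csv",
        "host.nwk",
        "parasitoid.nwk",
        "host_samples.csv",
        "config.yaml",
    ):
        digest = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        manifest[name] = digest
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
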