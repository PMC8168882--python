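"""Data model and I/O for quantitative bipartite host-parasitoid networks.

A quantitative network records, for every host species i and parasitoid
species l, the number of attacks (parasitism events) observed: link
strength alpha_il.  Networks exist at two granularities: per-site,
per-time-step :class:`SiteNetwork` objects, and pooled
:class:`MetaNetwork` objects aggregated over sites and sampling dates
(the training object for the link-prediction models and for the
apparent-competition projection).

Species identifiers carry a mandatory guild prefix (``H:`` for hosts,
``P:`` for parasitoids) so the two namespaces can never collide in
files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

HOST_PREFIX = "H:"
PARASITOID_PREFIX = "P:"

#: number of monthly phenology slots (the study calendar has seven
#: sampling months spread over two austral summer seasons)
N_MONTHS = 7

HABITATS = ("native", "plantation")
TRANSECTS = ("edge", "interior")
TIME_STEPS = ("t", "t_plus_1", "training")

INTERACTION_COLUMNS = [
    "site_id",
    "habitat",
    "transect",
    "occasion",
    "time_step",
    "host_id",
    "parasitoid_id",
    "count",
]

PHENO_COLUMNS = [f"pheno_m{i}" for i in range(1, N_MONTHS + 1)]

TRAIT_COLUMNS = (
    ["species_id", "guild", "body_size", "biogeographic_status"]
    + PHENO_COLUMNS
    + ["nd", "total_abundance"]
)


class SchemaError(ValueError):
    """A file is missing a required column."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


@dataclass(frozen=True)
class InteractionRecord:
    """One observed host-parasitoid link at a site and sampling occasion."""

    site_id: str
    habitat: str
    transect: str
    occasion: int
    time_step: str
    host_id: str
    parasitoid_id: str
    count: int

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValidationError(f"unknown habitat {self.habitat!r}")
        if self.transect not in TRANSECTS:
            raise ValidationError(f"unknown transect {self.transect!r}")
        if self.time_step not in TIME_STEPS:
            raise ValidationError(f"unknown time_step {self.time_step!r}")
        if self.count < 0:
            raise ValidationError(f"negative count {self.count}")
        if not self.host_id.startswith(HOST_PREFIX):
            raise ValidationError(f"host id {self.host_id!r} lacks '{HOST_PREFIX}' prefix")
        if not self.parasitoid_id.startswith(PARASITOID_PREFIX):
            raise ValidationError(
                f"parasitoid id {self.parasitoid_id!r} lacks '{PARASITOID_PREFIX}' prefix"
            )


def read_interactions(path) -> list[InteractionRecord]:
    """Read an interaction edge list from CSV.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ValidationError` citing the 1-based data row of the first
    invalid count.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"interaction file missing column(s): {', '.join(missing)}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        for col, caster in (("count", int), ("occasion", int)):
            raw = row[col]
            try:
                value = caster(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"row {pos}: {col} {raw!r} is not an integer"
                ) from None
            if value < 0:
                raise ValidationError(f"row {pos}: {col} {raw!r} is negative")
        try:
            records.append(
                InteractionRecord(
                    site_id=row["site_id"],
                    habitat=row["habitat"],
                    transect=row["transect"],
                    occasion=int(row["occasion"]),
                    time_step=row["time_step"],
                    host_id=row["host_id"],
                    parasitoid_id=row["parasitoid_id"],
                    count=int(row["count"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {pos}: {exc}") from None
    return records


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=INTERACTION_COLUMNS)
    df.to_csv(path, index=False)


@dataclass
class SiteNetwork:
    """Quantitative network for one site at one time step.

    ``host_sample`` maps every collected host to the number of
    individuals collected (n_it); hosts that were attacked must have
    been collected.
    """

    site_id: str
    time_step: str
    counts: pd.DataFrame  # hosts x parasitoids, attack counts
    host_sample: pd.Series  # host -> individuals collected
    habitat: str = ""

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative attack count in site network")
        attacked = self.counts.sum(axis=1)
        for host, total in attacked.items():
            if total > 0 and self.host_sample.get(host, 0) <= 0:
                raise ValidationError(
                    f"host {host} attacked at {self.site_id} but not in host_sample"
                )


@dataclass
class MetaNetwork:
    """Host x parasitoid attack matrix pooled over sites and dates."""

    counts: pd.DataFrame
    mode: str  # "weighted" or "binary"
    provenance: str  # "native", "plantation" or "combined"
    sites: tuple = field(default_factory=tuple)

    @property
    def hosts(self) -> list[str]:
        return list(self.counts.index)

    @property
    def parasitoids(self) -> list[str]:
        return list(self.counts.columns)

    def binarize(self) -> "MetaNetwork":
        """Occurrence (0/1) version; idempotent."""
        return MetaNetwork(
            counts=(self.counts > 0).astype(int),
            mode="binary",
            provenance=self.provenance,
            sites=self.sites,
        )


def pool_meta_network(
    records: Sequence[InteractionRecord],
    habitat_filter: str = "combined",
    mode: str = "weighted",
) -> MetaNetwork:
    """Pool interaction records into a training meta-network.

    ``habitat_filter`` selects records from one forest type or, for
    ``"combined"``, all of them.  Weighted entries sum attack counts;
    binary entries indicate occurrence.  Pooling is order-independent.
    """
    if habitat_filter not in ("native", "plantation", "combined"):
        raise ValueError(f"unknown habitat filter {habitat_filter!r}")
    if mode not in ("weighted", "binary"):
        raise ValueError(f"unknown mode {mode!r}")
    if habitat_filter == "combined":
        selected = list(records)
    else:
        selected = [r for r in records if r.habitat == habitat_filter]
    if not selected:
        raise ValueError(f"no interaction records match habitat filter {habitat_filter!r}")
    hosts = sorted({r.host_id for r in selected})
    paras = sorted({r.parasitoid_id for r in selected})
    counts = pd.DataFrame(0, index=hosts, columns=paras, dtype=int)
    for r in selected:
        counts.loc[r.host_id, r.parasitoid_id] += r.count
    meta = MetaNetwork(
        counts=counts,
        mode="weighted",
        provenance=habitat_filter,
        sites=tuple(sorted({r.site_id for r in selected})),
    )
    return meta.binarize() if mode == "binary" else meta


def normalised_degree(network: MetaNetwork, species_id: str, guild: str) -> float:
    """Fraction of possible partners a species interacts with (ND in [0, 1])."""
    if guild == "host":
        if species_id not in network.counts.index:
            raise KeyError(f"host {species_id!r} not in network")
        row = network.counts.loc[species_id]
        return float((row > 0).sum() / network.counts.shape[1])
    if guild == "parasitoid":
        if species_id not in network.counts.columns:
            raise KeyError(f"parasitoid {species_id!r} not in network")
        col = network.counts[species_id]
        return float((col > 0).sum() / network.counts.shape[0])
    raise ValueError(f"unknown guild {guild!r}")


def phenological_overlap(p: np.ndarray, q: np.ndarray) -> float:
    """Schoener overlap of two monthly activity profiles.

    Both vectors are normalised internally to proportions, so the
    overlap is invariant to rescaling either input; the result is
    sum_m min(p_m, q_m) in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("phenology vectors differ in length")
    if (p < 0).any() or (q < 0).any():
        raise ValidationError("phenology entries must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp <= 0 or sq <= 0:
        raise ValidationError("phenology unknown: all-zero monthly vector")
    return float(np.minimum(p / sp, q / sq).sum())


def parasitism_rate(events: int, sampled: int) -> float:
    """Parasitism events divided by hosts sampled."""
    if sampled <= 0:
        raise ValidationError("host not collected: sampled must be positive")
    if events < 0:
        raise ValidationError("negative event count")
    return events / sampled


class TraitTable:
    """Per-species trait table for one or both guilds.

    Columns: guild, body_size, biogeographic_status (hosts only),
    pheno_m1..pheno_m7 (monthly abundances), nd (normalised degree in
    [0, 1]) and total_abundance.  Host ND is an input column measured on
    the hosts' resource plants, never derived from the host-parasitoid
    network itself.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TRAIT_COLUMNS if c != "species_id" and c not in df.columns]
        if missing:
            raise SchemaError(f"trait table missing column(s): {', '.join(missing)}")
        if df.index.name != "species_id":
            if "species_id" not in df.columns:
                raise SchemaError("trait table missing column(s): species_id")
            df = df.set_index("species_id")
        self.df = df
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species ids: {dupes}")
        bad_guild = df.loc[~df["guild"].isin(["host", "parasitoid"])]
        if len(bad_guild):
            raise ValidationError(f"unknown guild for {bad_guild.index.tolist()}")
        if (df["body_size"] <= 0).any():
            offenders = df.index[df["body_size"] <= 0].tolist()
            raise ValidationError(f"non-positive body size for {offenders}")
        nd = df["nd"].astype(float)
        if ((nd < 0) | (nd > 1)).any():
            offenders = df.index[(nd < 0) | (nd > 1)].tolist()
            raise ValidationError(f"nd outside [0, 1] for {offenders}")
        pheno = df[PHENO_COLUMNS].astype(float)
        if (pheno.to_numpy() < 0).any():
            raise ValidationError("negative phenology entries")

    @classmethod
    def read_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.df.reset_index().to_csv(path, index=False)

    def species(self, guild: str | None = None) -> list[str]:
        if guild is None:
            return list(self.df.index)
        return list(self.df.index[self.df["guild"] == guild])

    def phenology(self, species_id: str) -> np.ndarray:
        self._require(species_id)
        return self.df.loc[species_id, PHENO_COLUMNS].to_numpy(dtype=float)

    def trait(self, species_id: str, name: str):
        self._require(species_id)
        return self.df.loc[species_id, name]

    def _require(self, species_id: str) -> None:
        if species_id not in self.df.index:
            raise KeyError(f"species {species_id!r} not in trait table")

    def pairwise_overlap(self, a: str, b: str) -> float:
        return phenological_overlap(self.phenology(a), self.phenology(b))


def total_abundance(
    records: Sequence[InteractionRecord],
    host_samples: Mapping[tuple, Mapping[str, int]] | pd.DataFrame,
    species_id: str,
) -> int:
    """Summed abundance of a species across all sites and sampling dates.

    Hosts: total individuals collected (from ``host_samples``, keyed by
    (site_id, time_step) -> {host: n} or a long DataFrame with columns
    site_id, time_step, host_id, n).  Parasitoids: total rearing events
    (sum of attack counts).
    """
    if species_id.startswith(PARASITOID_PREFIX):
        total = sum(r.count for r in records if r.parasitoid_id == species_id)
        if not any(r.parasitoid_id == species_id for r in records):
            raise KeyError(f"parasitoid {species_id!r} absent from all records")
        return total
    if species_id.startswith(HOST_PREFIX):
        if isinstance(host_samples, pd.DataFrame):
            rows = host_samples[host_samples["host_id"] == species_id]
            if rows.empty:
                raise KeyError(f"host {species_id!r} absent from all sample tables")
            return int(rows["n"].sum())
        total, seen = 0, False
        for table in host_samples.values():
            if species_id in table:
                seen = True
                total += int(table[species_id])
        if not seen:
            raise KeyError(f"host {species_id!r} absent from all sample tables")
        return total
    raise ValidationError(f"species id {species_id!r} lacks a guild prefix")


@dataclass
class PhyloCoordinates:
    """Principal-coordinate embedding of a patristic distance matrix.

    ``coords`` has one row per species and ``m`` columns ordered by
    decreasing eigenvalue; ``variance_fractions`` gives each axis'
    share of the total positive eigenvalue mass.
    """

    species: list[str]
    coords: np.ndarray
    variance_fractions: np.ndarray

    def row(self, species_id: str) -> np.ndarray:
        try:
            i = self.species.index(species_id)
        except ValueError:
            raise KeyError(f"species {species_id!r} not in coordinates") from None
        return self.coords[i]


def patristic_distance_matrix(newick: str) -> tuple[list[str], np.ndarray]:
    """Parse a Newick tree and return tip labels with patristic distances."""
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick tree: {exc}") from None
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate tip labels in tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    dist = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                dist[i, j] = dist[j, i] = d
    return labels, dist


def patristic_coordinates(newick: str, m: int) -> PhyloCoordinates:
    """Embed tree tips in m principal-coordinate axes.

    Classical PCoA of the patristic distance matrix: axes with negative
    eigenvalues are dropped (patristic distances on small trees are
    typically Euclidean-embeddable so little is lost); if fewer than m
    positive axes exist the remainder are zero-padded so the embedding
    dimension is always exactly m.
    """
    labels, dist = patristic_distance_matrix(newick)
    n = len(labels)
    if not 1 <= m <= n - 1:
        raise ValueError(f"m={m} out of range [1, {n - 1}] for {n} tips")
    d2 = dist**2
    centered = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * centered @ d2 @ centered
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(eigvals.max(), 1.0)
    positive = eigvals > tol
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    coords_full = pos_vecs * np.sqrt(pos_vals)
    coords = np.zeros((n, m))
    k = min(m, coords_full.shape[1])
    coords[:, :k] = coords_full[:, :k]
    fractions = np.zeros(m)
    if pos_vals.sum() > 0:
        fractions[:k] = pos_vals[:k] / pos_vals.sum()
    return PhyloCoordinates(species=labels, coords=coords, variance_fractions=fractions)


def site_networks_from_records(
    records: Sequence[InteractionRecord],
    host_samples: Mapping[tuple, Mapping[str, int]],
    hosts: Sequence[str],
    parasitoids: Sequence[str],
) -> dict[tuple, SiteNetwork]:
    """Group records into per-(site, time_step) networks on fixed axes."""
    keys = sorted({(r.site_id, r.time_step) for r in records} | set(host_samples))
    habitats = {r.site_id: r.habitat for r in records}
    out = {}
    for site_id, step in keys:
        counts = pd.DataFrame(0, index=list(hosts), columns=list(parasitoids), dtype=int)
        for r in records:
            if r.site_id == site_id and r.time_step == step:
                counts.loc[r.host_id, r.parasitoid_id] += r.count
        sample = pd.Series(host_samples.get((site_id, step), {}), dtype=float).reindex(
            list(hosts), fill_value=0
        )
        out[(site_id, step)] = SiteNetwork(
            site_id=site_id,
            time_step=step,
            counts=counts,
            host_sample=sample,
            habitat=habitats.get(site_id, ""),
        )
    return out
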