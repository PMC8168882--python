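"""Indirect effects via shared parasitoids (apparent competition).

A quantitative host-parasitoid network is projected into a unipartite
host network whose links d_ij give the proportion of the parasitoids
attacking host i that recruited from host j.  Combined with time-t
attack rates and the observed change in host abundances, d_ij yields
an expected parasitism rate for each host at time t+1:

    E_i(t+1) = (1 / n_i(t+1)) * sum_j d_ij * (sum_l alpha_ilt)
                                     * (n_j(t+1) / n_jt)

which is validated against observed parasitism (events / hosts
sampled) at t+1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass


import numpy as np
import pandas as pd

from .networks import MetaNetwork, SiteNetwork, ValidationError, parasitism_rate

logger = logging.getLogger(__name__)


@dataclass
class ApparentCompetitionMatrix:
    """H x H matrix of d_ij with validity flags.

    Rows of hosts with at least one recruited parasitoid sum to one;
    unparasitized hosts get an all-zero, flagged row.
    """

    d: pd.DataFrame
    valid: pd.Series  # host -> bool

    def to_csv(self, path) -> None:
        self.d.to_csv(path)


def potential_apparent_competition(meta: MetaNetwork) -> ApparentCompetitionMatrix:
    """Potential for apparent competition d_ij from a weighted network.

    d_ij = sum_k [alpha_ik / sum_l alpha_il] * [alpha_jk / sum_m alpha_mk]:
    the share of host i's parasitoids contributed by parasitoid species
    k, times the share of k's recruitment that came from host j, summed
    over parasitoid species.  Scale-free in total counts.
    """
    if meta.mode != "weighted":
        raise ValueError("d_ij requires a weighted meta-network")
    alpha = meta.counts.to_numpy(dtype=float)
    hosts = meta.hosts
    row_tot = alpha.sum(axis=1)  # parasitoids attacking host i
    col_tot = alpha.sum(axis=0)  # recruitment of parasitoid k
    valid = row_tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        share_i = np.where(valid[:, None], alpha / np.where(row_tot[:, None] > 0, row_tot[:, None], 1.0), 0.0)
        recruit = np.where(col_tot[None, :] > 0, alpha / np.where(col_tot[None, :] > 0, col_tot[None, :], 1.0), 0.0)
    d = share_i @ recruit.T
    d[~valid, :] = 0.0
    return ApparentCompetitionMatrix(
        d=pd.DataFrame(d, index=hosts, columns=hosts),
        valid=pd.Series(valid, index=hosts),
    )


def attack_rates_from_predictions(
    prediction: pd.DataFrame,
    host_sample_t: pd.Series,
    source: str,
    observed_t: SiteNetwork | None = None,
) -> pd.DataFrame:
    """Attack-rate matrix alpha_ilt at time t for one test site.

    ``source``:

    - ``"rf"`` -- the probability of occurrence is read as a
      per-individual attack risk, so alpha = p_hat * n_it (an expected
      attack count commensurate with observed link strengths);
    - ``"rf_raw"`` -- the probability used unscaled;
    - ``"knn"`` -- the predicted frequency passes through unchanged;
    - ``"observed"`` -- counts copied from the observed time-t network.
    """
    if source == "observed":
        if observed_t is None:
            raise ValueError("source 'observed' requires the time-t site network")
        return observed_t.counts.astype(float)
    if source not in ("rf", "rf_raw", "knn"):
        raise ValueError(f"unknown attack-rate source {source!r}")
    alpha = prediction.astype(float).copy()
    if source == "rf":
        n = host_sample_t.reindex(prediction.index)
        missing = n.index[(prediction.sum(axis=1) > 0) & n.isna()].tolist()
        if missing:
            raise ValidationError(f"hosts with predictions but no time-t sample: {missing}")
        alpha = alpha.mul(n.fillna(0.0), axis=0)
    return alpha


@dataclass
class ExpectedParasitismRecord:
    site_id: str
    host_id: str
    E: float | None
    eligible: bool
    exclusion_reason: str | None = None


def expected_parasitism(
    d: ApparentCompetitionMatrix,
    attacks_t: pd.DataFrame,
    n_t: pd.Series,
    n_t1: pd.Series,
    site_id: str = "",
) -> list[ExpectedParasitismRecord]:
    """Expected parasitism rate at t+1 for every host at a site.

    A host is eligible iff it was collected at both time steps and has
    a non-zero attack rate at time t.  Donor hosts absent at time t
    (n_jt = 0) contribute nothing (their abundance ratio is undefined)
    and are logged.  Hosts never entered in the d matrix contribute a
    zero d_ij, equivalent to no parasitoid sharing with them.
    """
    hosts = list(attacks_t.index)
    attack_sum = attacks_t.sum(axis=1)
    records = []
    # abundance ratios for donor hosts
    ratio = {}
    for j in hosts:
        njt = float(n_t.get(j, 0))
        if njt > 0:
            ratio[j] = float(n_t1.get(j, 0)) / njt
        else:
            logger.warning("site %s: donor host %s absent at t; term skipped", site_id, j)
    for i in hosts:
        nit = float(n_t.get(i, 0))
        nit1 = float(n_t1.get(i, 0))
        a_i = float(attack_sum[i])
        if nit <= 0 or nit1 <= 0:
            records.append(
                ExpectedParasitismRecord(
                    site_id, i, None, False, "not collected at both time steps"
                )
            )
            continue
        if a_i <= 0:
            records.append(
                ExpectedParasitismRecord(
                    site_id, i, None, False, "zero predicted attack rate at t"
                )
            )
            continue
        total = 0.0
        for j, r in ratio.items():
            if i in d.d.index and j in d.d.columns:
                dij = float(d.d.loc[i, j])
            else:
                dij = 0.0
            total += dij * a_i * r
        records.append(ExpectedParasitismRecord(site_id, i, total / nit1, True))
    return records


@dataclass
class ObservedParasitismRecord:
    site_id: str
    host_id: str
    events: int
    sampled: int

    @property
    def rate(self) -> float:
        return parasitism_rate(self.events, self.sampled)


def observed_parasitism(site_t1: SiteNetwork) -> list[ObservedParasitismRecord]:
    """Observed parasitism per host at t+1: events / hosts sampled.

    Each collected host individual is counted at most once as a
    parasitism event (rearing semantics), so events are capped at the
    number sampled.  Hosts not collected at t+1 yield no record.
    """
    records = []
    events_by_host = site_t1.counts.sum(axis=1)
    for host, sampled in site_t1.host_sample.items():
        sampled = int(sampled)
        if sampled <= 0:
            continue
        events = int(min(int(events_by_host.get(host, 0)), sampled))
        records.append(
            ObservedParasitismRecord(site_t1.site_id, host, events, sampled)
        )
    return records


def write_parasitism_csv(expected, observed, path) -> None:
    """Long-format CSV of expected and observed parasitism per
    (site, host): E with eligibility flag and reason, events, sampled,
    rate."""
    obs_map = {(r.site_id, r.host_id): r for r in observed}
    rows = []
    for r in expected:
        o = obs_map.get((r.site_id, r.host_id))
        rows.append(
            {
                "site_id": r.site_id,
                "host_id": r.host_id,
                "E": r.E,
                "eligible": r.eligible,
                "reason": r.exclusion_reason or "",
                "events": o.events if o else "",
                "sampled": o.sampled if o else "",
                "rate": o.rate if o else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def expected_parasitism_oracle(
    d: ApparentCompetitionMatrix,
    attacks_t: pd.DataFrame,
    n_t: pd.Series,
    n_t1: pd.Series,
) -> dict[str, float]:
    """Naive triple-loop evaluation of the expectation, for cross-checks."""
    out = {}
    for i in attacks_t.index:
        nit, nit1 = float(n_t.get(i, 0)), float(n_t1.get(i, 0))
        a_i = sum(float(attacks_t.loc[i, l]) for l in attacks_t.columns)
        if nit <= 0 or nit1 <= 0 or a_i <= 0:
            continue
        total = 0.0
        for j in attacks_t.index:
            njt = float(n_t.get(j, 0))
            if njt <= 0:
                continue
            dij = float(d.d.loc[i, j]) if (i in d.d.index and j in d.d.columns) else 0.0
            total += dij * a_i * (float(n_t1.get(j, 0)) / njt)
        out[i] = total / nit1
    return out
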