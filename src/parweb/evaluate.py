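"""Statistical validation of predicted direct and indirect effects.

Predicted interaction probabilities/frequencies are regressed against
observed interaction frequencies (Poisson), and expected parasitism
rates against observed parasitism (binomial, events-of-trials), with
scaled predictors, all-subsets information-criterion selection,
overdispersion checks, Nakagawa-style marginal/conditional R2, a
Bernoulli multiple-testing summary and leverage-based outlier
screening.

Grouping factors (site, parasitoid identity) are handled by an
approximate strategy rather than a full random-effects fit: either
cluster-robust (sandwich) standard errors over the grouping factor
with a t reference on G - 1 degrees of freedom, or fixed group
intercepts that absorb group means (the within-group estimator,
closest in spirit to a random intercept).  The group variance entering
the conditional R2 comes from the fitted intercepts or, in cluster
mode, from between-group variation of working residuals.  The
contract is the sign and significance of the focal slope and the
information-criterion ranking, not coefficient-level parity with a
full random-effects fit; random slopes are not modelled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


def scale_center(values) -> np.ndarray:
    """Standardise to mean 0 and sample standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to scale")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale a constant vector")
    return (x - x.mean()) / sd


def bernoulli_multiple_tests(n_tests: int, k_significant: int, alpha: float = 0.05) -> float:
    """P(X >= k) for X ~ Binomial(N, alpha): the chance of k or more of
    N independent tests being significant at level alpha by chance alone.
    Exact summation."""
    if not 0 <= k_significant <= n_tests:
        raise ValueError("k must satisfy 0 <= k <= N")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k_significant == 0:
        return 1.0
    total = 0.0
    for x in range(k_significant, n_tests + 1):
        total += math.comb(n_tests, x) * alpha**x * (1 - alpha) ** (n_tests - x)
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure for a GLM validation fit.

    ``terms`` are main effects (column names) or interactions written
    ``"a:b"``; an interaction may only appear alongside all its
    lower-order terms (marginality).  ``response`` is a column name
    (counts) or a pair (events, trials) for binomial data.
    ``groups`` names an optional grouping column used for
    cluster-robust inference and the conditional R2.
    """

    family: str  # "poisson", "binomial", "gaussian"
    response: str | tuple
    terms: tuple = ()
    groups: str | None = None
    scale_terms: tuple = ()
    #: how the grouping factor enters: "cluster" leaves the mean
    #: structure alone and robustifies the covariance; "fixed_intercepts"
    #: additionally absorbs group means with dummy intercepts (the
    #: within-group estimator, closest to a random-intercept fit)
    group_effects: str = "cluster"

    def __post_init__(self):
        if self.family not in ("poisson", "binomial", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        for t in self.terms:
            if ":" in t:
                parts = set(t.split(":"))
                for r in range(1, len(parts)):
                    for sub in itertools.combinations(sorted(parts), r):
                        name = _match_term(self.terms, sub)
                        if name is None:
                            raise ValueError(
                                f"interaction {t!r} requires lower-order term {':'.join(sub)!r}"
                            )


def _match_term(terms: Sequence[str], variables) -> str | None:
    want = set(variables)
    for t in terms:
        if set(t.split(":")) == want:
            return t
    return None


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for t in terms:
        parts = t.split(":")
        col = np.ones(len(data))
        for p in parts:
            if p not in data.columns:
                raise KeyError(f"term {t!r}: column {p!r} not in data")
            col = col * data[p].to_numpy(dtype=float)
        X[t] = col
    return X


def _family(name: str):
    return {
        "poisson": sm.families.Poisson(),
        "binomial": sm.families.Binomial(),
        "gaussian": sm.families.Gaussian(),
    }[name]


@dataclass
class FitResult:
    """Coefficients, information criteria, dispersion and R2 for one fit."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # estimate, se, z, p per term
    aic: float
    aicc: float
    dispersion: float
    df_resid: int
    marginal_r2: float | None
    conditional_r2: float | None
    converged: bool
    n_obs: int
    extra: dict = field(default_factory=dict)
    _sm_result: object = None
    _X: pd.DataFrame = None
    _data: pd.DataFrame = None

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.loc[term]


def _working_residuals(family: str, y_prop: np.ndarray, mu: np.ndarray,
                       trials: np.ndarray | None) -> np.ndarray:
    if family == "poisson":
        return (y_prop - mu) / np.clip(mu, 1e-12, None)
    if family == "binomial":
        v = np.clip(mu * (1 - mu), 1e-12, None)
        return (y_prop - mu) / v
    return y_prop - mu


def _irls_weights(family: str, mu: np.ndarray, trials: np.ndarray | None) -> np.ndarray:
    if family == "poisson":
        return np.clip(mu, 1e-12, None)
    if family == "binomial":
        w = np.clip(mu * (1 - mu), 1e-12, None)
        return w * (trials if trials is not None else 1.0)
    return np.ones_like(mu)


def _group_variance(groups: np.ndarray, resid: np.ndarray) -> float:
    """Moment estimate of the between-group intercept variance on the
    link scale from working residuals; clamped at zero."""
    df = pd.DataFrame({"g": groups, "r": resid})
    stats = df.groupby("g")["r"].agg(["mean", "var", "count"])
    if len(stats) < 2:
        return 0.0
    between = float(stats["mean"].var(ddof=1))
    within = float((stats["var"].fillna(0.0) / stats["count"]).mean())
    return max(0.0, between - within)


def fit_glm(spec: ModelSpec, data: pd.DataFrame, olre: bool = False) -> FitResult:
    """Iteratively-reweighted GLM fit of the fixed-effect structure.

    ``olre=True`` applies the robust-covariance analogue of an
    observation-level random factor: a heteroscedasticity-consistent
    (HC3) covariance absorbs extra-Poisson/binomial variation in the
    standard errors, and the Pearson dispersion inflates the
    observation-level variance entering the R2 denominator.
    """
    if isinstance(spec.response, tuple):
        events = data[spec.response[0]].to_numpy(dtype=float)
        trials = data[spec.response[1]].to_numpy(dtype=float)
        if (events > trials).any():
            raise ValueError("events exceed trials")
        endog = np.column_stack([events, trials - events])
        y_prop = np.where(trials > 0, events / np.clip(trials, 1, None), 0.0)
    else:
        endog = data[spec.response].to_numpy(dtype=float)
        y_prop = endog
        trials = None
    if np.asarray(y_prop).std() == 0:
        raise ValueError("degenerate response: zero variance")

    work = data.copy()
    for t in spec.scale_terms:
        work[t] = scale_center(work[t])
    X = _design_matrix(work, spec.terms)
    fixed_cols = list(X.columns)
    if (
        spec.groups is not None
        and spec.group_effects == "fixed_intercepts"
        and work[spec.groups].nunique() > 1
    ):
        dummies = pd.get_dummies(
            work[spec.groups], prefix=f"g[{spec.groups}]", drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    model = sm.GLM(endog, X, family=_family(spec.family))
    clustered = (
        spec.groups is not None
        and spec.group_effects == "cluster"
        and work[spec.groups].nunique() > 1
    )
    if clustered:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": work[spec.groups].to_numpy()}
        )
    elif olre:
        # heteroscedasticity-robust covariance: the observation-level
        # analogue of an observation-level random factor
        res = model.fit(cov_type="HC3")
    else:
        res = model.fit()
    converged = bool(getattr(res, "converged", True))

    mu = np.asarray(res.mu)
    df_resid = int(res.df_resid)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    dispersion = float(res.pearson_chi2 / df_resid)

    # sandwich standard errors (cluster or HC1) are already consistent
    # under overdispersion; nothing further to scale
    bse = res.bse
    z = res.params / bse
    if clustered:
        # small-sample cluster correction: t reference with G-1 df
        df_cl = int(work[spec.groups].nunique()) - 1
        pvals = 2 * scipy.stats.t.sf(np.abs(z), df_cl)
    else:
        pvals = 2 * scipy.stats.t.sf(np.abs(z), df_resid)
    coef = pd.DataFrame(
        {"estimate": res.params, "se": bse, "z": z, "p": pvals}, index=X.columns
    )

    k = X.shape[1]
    n = len(work)
    aic = float(res.aic)
    aicc = aic + (2 * k * (k + 1) / (n - k - 1)) if n - k - 1 > 0 else float("inf")

    # variance decomposition for Nakagawa-style R2: fixed-effect share
    # from the non-group columns; group share either from the fitted
    # group intercepts or from between-group working residuals
    params = pd.Series(res.params, index=X.columns)
    eta_fixed = X[fixed_cols].to_numpy() @ params[fixed_cols].to_numpy()
    var_f = float(np.var(eta_fixed))
    wr = _working_residuals(spec.family, np.asarray(y_prop, dtype=float), mu, trials)
    var_g = 0.0
    if spec.groups is not None and work[spec.groups].nunique() > 1:
        group_cols = [c for c in X.columns if c not in fixed_cols]
        if group_cols:
            eta_group = X[group_cols].to_numpy() @ params[group_cols].to_numpy()
            var_g = float(np.var(eta_group))
        else:
            var_g = _group_variance(work[spec.groups].to_numpy(), wr)
    var_d = _distribution_variance(spec.family, mu, y_prop, trials)
    if olre:
        var_d = var_d * max(dispersion, 1.0)
    denom = var_f + var_g + var_d
    marginal = var_f / denom if denom > 0 else None
    conditional = (var_f + var_g) / denom if denom > 0 else None

    return FitResult(
        spec=spec,
        coefficients=coef,
        aic=aic,
        aicc=aicc,
        dispersion=dispersion,
        df_resid=df_resid,
        marginal_r2=marginal,
        conditional_r2=conditional,
        converged=converged,
        n_obs=n,
        extra={"olre": olre},
        _sm_result=res,
        _X=X,
        _data=work,
    )


def _distribution_variance(family: str, mu, y_prop, trials) -> float:
    """Observation-level variance on the link scale (delta method)."""
    if family == "poisson":
        lam = float(np.mean(mu))
        return 1.0 / max(lam, 1e-12)
    if family == "binomial":
        p = float(np.mean(mu))
        return 1.0 / max(p * (1 - p), 1e-12)
    resid = np.asarray(y_prop, dtype=float) - np.asarray(mu, dtype=float)
    return float(np.var(resid))


def nakagawa_r2(fit: FitResult) -> tuple[float, float]:
    """(marginal, conditional) variance explained; marginal <= conditional."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.marginal_r2 is None or fit.conditional_r2 is None:
        raise ValueError("R2 undefined for this fit")
    m = min(max(fit.marginal_r2, 0.0), 1.0)
    c = min(max(fit.conditional_r2, 0.0), 1.0)
    return m, max(m, c)


def overdispersion_check(fit: FitResult) -> tuple[float, float, bool]:
    """Pearson chi-squared dispersion ratio, its tail probability and a
    flag set when the ratio is >= 2 or the test is significant."""
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    chi2 = fit.dispersion * fit.df_resid
    p = float(scipy.stats.chi2.sf(chi2, fit.df_resid))
    flag = fit.dispersion >= 2.0 or p < 0.05
    return fit.dispersion, p, flag


def leverage_outliers(fit: FitResult, threshold_factor: float = 2.0) -> pd.DataFrame:
    """Hat-matrix diagonal from the final weighted least-squares step.

    Observations with hat value above ``threshold_factor * p / n`` are
    flagged as high-influence outliers.
    """
    X = fit._X.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    res = fit._sm_result
    mu = np.asarray(res.mu)
    trials = None
    if isinstance(fit.spec.response, tuple):
        trials = fit._data[fit.spec.response[1]].to_numpy(dtype=float)
    w = _irls_weights(fit.spec.family, mu, trials)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    hat = np.einsum("ij,ij->i", Xw @ np.linalg.inv(Xw.T @ Xw), Xw)
    thresh = threshold_factor * p / n
    return pd.DataFrame(
        {"hat": hat, "flagged": hat > thresh}, index=fit._X.index
    ).assign(threshold=thresh)


# ---------------------------------------------------------------------------
# all-subsets selection
# ---------------------------------------------------------------------------


def _valid_subsets(terms: Sequence[str]) -> list[tuple]:
    """All marginality-respecting subsets of the term list (incl. empty)."""
    terms = list(terms)
    if len(terms) > 16:
        raise ValueError("all-subsets enumeration capped at 16 terms")
    requirement = {}
    for t in terms:
        parts = set(t.split(":"))
        req = []
        for other in terms:
            op = set(other.split(":"))
            if op < parts:
                req.append(other)
        requirement[t] = req
    subsets = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            chosen = set(combo)
            if all(set(requirement[t]) <= chosen for t in combo):
                subsets.append(combo)
    return subsets


@dataclass
class SelectionResult:
    table: pd.DataFrame  # one row per candidate model
    best: FitResult
    criterion: str
    inclusion_fractions: pd.Series  # per-term share of delta<2 candidates

    @property
    def best_terms(self) -> tuple:
        return self.best.spec.terms


def all_subsets_selection(
    spec: ModelSpec, data: pd.DataFrame, criterion: str = "aic", olre: bool = False
) -> SelectionResult:
    """Fit every marginality-respecting fixed-effect subset and rank by
    AIC (or AICc); report the delta < 2 candidate set and per-term
    inclusion fractions (the collinearity audit)."""
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    fits = []
    rows = []
    for subset in _valid_subsets(spec.terms):
        sub_spec = ModelSpec(
            family=spec.family,
            response=spec.response,
            terms=subset,
            groups=spec.groups,
            scale_terms=tuple(t for t in spec.scale_terms if t in _flat_vars(subset)),
            group_effects=spec.group_effects,
        )
        fit = fit_glm(sub_spec, data, olre=olre)
        fits.append(fit)
        rows.append(
            {
                "terms": " + ".join(subset) if subset else "(intercept)",
                "n_terms": len(subset),
                "aic": fit.aic,
                "aicc": fit.aicc,
            }
        )
    table = pd.DataFrame(rows)
    table["delta"] = table[criterion] - table[criterion].min()
    order = np.lexsort((table["n_terms"].to_numpy(), table[criterion].to_numpy()))
    table = table.iloc[order].reset_index(drop=True)
    best = fits[order[0]]
    candidates = table[table["delta"] < 2]
    fractions = {}
    for t in spec.terms:
        hits = candidates["terms"].apply(lambda s: t in s.split(" + "))
        fractions[t] = float(hits.mean()) if len(candidates) else 0.0
    return SelectionResult(
        table=table,
        best=best,
        criterion=criterion,
        inclusion_fractions=pd.Series(fractions),
    )


def _flat_vars(terms) -> set:
    out = set()
    for t in terms:
        out |= set(t.split(":"))
    return out


# ---------------------------------------------------------------------------
# validation drivers
# ---------------------------------------------------------------------------


def build_direct_table(
    predictions: dict,
    observed: dict,
    traits,
    habitats: dict,
) -> pd.DataFrame:
    """Long table, one row per host-parasitoid pair per test site.

    ``predictions`` maps site_id -> predicted matrix (probability or
    frequency), ``observed`` maps site_id -> time-t SiteNetwork,
    ``habitats`` maps site_id -> forest type.
    """
    rows = []
    for site_id, pred in predictions.items():
        if site_id not in observed:
            raise KeyError(f"no observed network for site {site_id!r}")
        obs = observed[site_id]
        for h in pred.index:
            for p in pred.columns:
                obs_count = int(obs.counts.loc[h, p]) if (
                    h in obs.counts.index and p in obs.counts.columns
                ) else 0
                rows.append(
                    {
                        "site": site_id,
                        "host": h,
                        "parasitoid": p,
                        "predicted": float(pred.loc[h, p]),
                        "observed": obs_count,
                        "host_nd": float(traits.trait(h, "nd")),
                        "para_nd": float(traits.trait(p, "nd")),
                        "host_abundance": float(traits.trait(h, "total_abundance")),
                        "para_abundance": float(traits.trait(p, "total_abundance")),
                        "forest": float(habitats[site_id] == "plantation"),
                    }
                )
    return pd.DataFrame(rows)


#: the moderated fixed-effect structure: full factorial of the focal
#: predictor with host and parasitoid ND, and with host and parasitoid
#: abundance; forest type enters as a main effect interacting with the
#: predictor only (no forest x ND and no abundance x ND interactions).
MODERATED_TERMS = (
    "predicted",
    "host_nd",
    "para_nd",
    "predicted:host_nd",
    "predicted:para_nd",
    "host_nd:para_nd",
    "predicted:host_nd:para_nd",
    "host_abundance",
    "para_abundance",
    "forest",
    "predicted:host_abundance",
    "predicted:para_abundance",
    "predicted:forest",
    "host_abundance:para_abundance",
    "predicted:host_abundance:para_abundance",
)


def validate_direct(
    predictions: dict,
    observed: dict,
    traits,
    habitats: dict,
    criterion: str = "aic",
    moderated: bool = False,
) -> dict:
    """Poisson validation of predicted against observed interaction
    frequencies, with the parasitoid-identity grouping factor.

    Returns the predictor-only fit, its all-subsets selection, the
    overdispersion check (with a quasi-likelihood refit when flagged)
    and, optionally, the moderated model with ND/abundance/forest
    interactions.
    """
    table = build_direct_table(predictions, observed, traits, habitats)
    simple = ModelSpec(
        family="poisson",
        response="observed",
        terms=("predicted",),
        groups="parasitoid",
        scale_terms=("predicted",),
    )
    fit = fit_glm(simple, table)
    ratio, p_disp, flagged = overdispersion_check(fit)
    if flagged:
        fit = fit_glm(simple, table, olre=True)
    selection = all_subsets_selection(simple, table, criterion=criterion, olre=flagged)
    out = {
        "table": table,
        "fit": fit,
        "selection": selection,
        "dispersion": {"ratio": ratio, "p": p_disp, "olre": flagged},
        "r2": nakagawa_r2(fit),
    }
    if moderated:
        mod_spec = ModelSpec(
            family="poisson",
            response="observed",
            terms=MODERATED_TERMS,
            groups="parasitoid",
            scale_terms=(
                "predicted",
                "host_nd",
                "para_nd",
                "host_abundance",
                "para_abundance",
            ),
        )
        mod_fit = fit_glm(mod_spec, table, olre=flagged)
        out["moderated_fit"] = mod_fit
        out["moderated_selection"] = all_subsets_selection(
            mod_spec, table, criterion=criterion, olre=flagged
        )
    return out


def build_indirect_table(expected, observed) -> pd.DataFrame:
    """Join eligible expected-parasitism records with observed records
    on (site, host)."""
    obs_map = {(r.site_id, r.host_id): r for r in observed}
    rows = []
    for rec in expected:
        if not rec.eligible:
            continue
        key = (rec.site_id, rec.host_id)
        if key not in obs_map:
            continue
        o = obs_map[key]
        rows.append(
            {
                "site": rec.site_id,
                "host": rec.host_id,
                "expected": rec.E,
                "events": o.events,
                "trials": o.sampled,
            }
        )
    if not rows:
        raise ValueError("empty join between expected and observed parasitism")
    return pd.DataFrame(rows)


def validate_indirect(
    expected,
    observed,
    criterion: str = "aic",
    leverage_threshold: float = 2.0,
) -> dict:
    """Binomial validation of expected against observed parasitism.

    Events-of-trials response, scaled expected parasitism as the fixed
    effect, site as grouping factor; high-leverage points are flagged
    and the model refitted without them, with both fits reported.
    """
    table = build_indirect_table(expected, observed)
    spec = ModelSpec(
        family="binomial",
        response=("events", "trials"),
        terms=("expected",),
        groups="site",
        scale_terms=("expected",),
        group_effects="fixed_intercepts",
    )
    fit = fit_glm(spec, table)
    ratio, p_disp, flagged = overdispersion_check(fit)
    if flagged:
        fit = fit_glm(spec, table, olre=True)
    lev = leverage_outliers(fit, threshold_factor=leverage_threshold)
    result = {
        "table": table,
        "fit": fit,
        "dispersion": {"ratio": ratio, "p": p_disp, "olre": flagged},
        "leverage": lev,
        "r2": nakagawa_r2(fit),
        "selection": all_subsets_selection(spec, table, criterion=criterion, olre=flagged),
    }
    kept = table.loc[~lev["flagged"].to_numpy()]
    if lev["flagged"].any() and kept["site"].nunique() >= 1 and len(kept) > 2:
        try:
            result["fit_no_outliers"] = fit_glm(spec, kept, olre=flagged)
        except ValueError:
            result["fit_no_outliers"] = None
    else:
        result["fit_no_outliers"] = fit
    return result
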