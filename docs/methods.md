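# Methods

`parweb` implements a two-stage analysis of quantitative host–parasitoid
networks: (1) machine-learning prediction of pairwise interactions from
species traits, phylogenies and abundances, and (2) projection of the
predicted (or observed) networks into expected parasitism rates driven by
apparent competition, validated against observed parasitism. A synthetic
community generator supplies data with the statistical structure the
analysis assumes, so every stage is testable without field data.

## Data model

Interactions are attack counts α_il between host *i* and parasitoid *l*,
recorded per site, transect, sampling occasion and time step. Pooling
records over sites and dates yields a **meta-network** (weighted counts or
a binary occurrence matrix). Species identifiers carry guild prefixes
(`H:`/`P:`) so host and parasitoid namespaces cannot collide in files.
Traits per species: body size, biogeographic status (hosts), a 7-slot
monthly phenology vector, normalised degree (ND) and total abundance. Host
ND is an *input* trait (generality on the hosts' food plants); deriving it
from the host–parasitoid network itself would be circular. Parasitoid ND
is computed from the training meta-network. Phylogenies enter as Newick
trees; "phylogenetic position" is made concrete by classical principal
coordinates of the patristic distance matrix, with negative-eigenvalue
axes dropped (small patristic matrices are essentially Euclidean, so this
loses almost nothing; retained-variance fractions are reported, and the
embedding is zero-padded to the requested dimension).

Phenological overlap is Schoener's index, Σ_m min(p_m, q_m) on
month-proportion vectors: bounded in [0, 1], symmetric and invariant to
rescaling either input.

## Direct-effect prediction

**Random forest.** Every host × parasitoid pair is featurised as the
concatenation of host traits, parasitoid traits, both species'
principal-coordinate positions and the pairwise phenological overlap. A
`RandomForestClassifier` trained on the binary meta-network predicts the
probability of interaction occurrence for all pairs at a test site. A
stratified k-fold (k = 5) grid search scored by ranking AUC tunes tree
count, depth, features per split, phylogeny dimension and the trait
inclusion mask; AUC is used because link data are imbalanced and the
product of interest is a ranking of pair probabilities, not a
classification threshold. Gini (mean-decrease-impurity) importances report
which traits carry the signal. All fits are seeded and bit-reproducible.

**KNN recommender.** Collaborative filtering in the recommender-system
sense: a focal parasitoid's predicted frequency on each host is the
similarity-weighted mean of the meta-network rows of its k most similar
*training* parasitoids. Similarity is Gower's coefficient over the trait
mask (range-normalised continuous traits, 0/1 status mismatch, 1 − Schoener
for the phenology block, max-normalised Euclidean distance over phylo
axes); the default parasitoid mask uses body size, phenology and ND, with
phylogeny excluded by default but available through the mask.
A parasitoid present in both training and test data is never its own
neighbour. Hosts unseen in training (cold start) are first inserted into
the meta-network with the mirror-image procedure using host-trait
similarity (all host traits including phylogeny); imputed rows stay
fractional. Similarity ties are broken in seeded random order. Tuning is
leave-one-parasitoid-out RMSE over a (k, mask) grid.

## Indirect-effect projection

The **potential for apparent competition** between hosts i and j,

d_ij = Σ_k [α_ik / Σ_l α_il] · [α_jk / Σ_m α_mk],

is the proportion of the parasitoids attacking host i that recruited from
host j. Rows of parasitized hosts sum to exactly 1; unparasitized hosts
get flagged zero rows; the index is scale-free in total counts. By default
d comes from the observed combined training meta-network; a configuration
switch computes it from the pooled machine-learning-predicted networks
instead.

Attack rates α̂ at a test site at time t come from the random forest
(p̂ × n_it, reading the occurrence probability as a per-individual attack
risk so the product is commensurate with observed attack counts; raw p̂ is
available as a switch), from KNN (frequencies pass through unchanged), or
from the observed time-t network (the purely data-based route).

The **expected parasitism rate** at t+1 is

E_i(t+1) = (1 / n_i(t+1)) · Σ_j d_ij · (Σ_l α̂_ilt) · (n_j(t+1) / n_jt),

i.e. host i's time-t attack load, redistributed by the abundance changes of
the hosts that share its parasitoids. With constant abundances E collapses
exactly to the time-t parasitism rate (valid d rows sum to 1). A host is
eligible iff collected at both time steps with a non-zero time-t attack
rate; donor terms with n_jt = 0 are skipped with a logged warning.
Observed parasitism at t+1 is events / hosts sampled, with each collected
individual counted at most once (events capped at the sample size).

## Statistical validation

Predictors are centred and scaled to unit standard deviation. Direct
validation fits a Poisson regression of observed interaction frequency on
the scaled predicted probability (or frequency), one row per pair per
site; indirect validation fits an events-of-trials binomial regression of
observed parasitism on scaled E. All-subsets (marginality-respecting)
selection ranks models by AIC (or AICc for small samples) and reports the
ΔIC < 2 candidate set plus per-term inclusion fractions as a collinearity
audit; the moderated direct model adds host/parasitoid ND and abundance
and forest type with the factorial interaction structure, minus forest×ND
and abundance×ND terms. Enumeration is capped at 16 terms; the default
run dredges the predictor-only structure and fits the moderated structure
on demand.

Grouping factors are approximated rather than fitted as formal random
effects: site enters the indirect model as fixed intercepts (the
within-site estimator, mirroring a site random intercept), with
heteroscedasticity-consistent (HC3) covariance absorbing extra-binomial
variation when the Pearson dispersion flags overdispersion; parasitoid
identity in the direct model enters through cluster-robust standard errors
with a t reference on G − 1 degrees of freedom. Random slopes are not
modelled. The contract of these fits is the sign and significance of the
focal slope and the information-criterion ranking, not coefficient-level
parity with a full mixed-model fit — validated by the permutation-null
calibration below.

Overdispersion is checked as the ratio of summed squared Pearson residuals
to residual degrees of freedom (flag at ≥ 2 or a significant χ² tail).
Marginal and conditional R² follow the variance-decomposition approach for
GLMMs: fixed-effect variance of the linear predictor, group-intercept
variance (from fitted intercepts, or a moment estimate on working
residuals in cluster mode), and a distribution-specific observation
variance by the delta method (1/λ̄ for log-Poisson, 1/(p̄(1−p̄)) for
logit-binomial, residual variance for Gaussian — where the marginal R²
reduces exactly to the classical R²). Leverage screening flags hat values
above 2p/n from the final weighted least-squares step and reports fits
with and without the flagged points. The probability of k of N slope tests
being significant by chance alone is the exact binomial tail
P(X ≥ k), X ~ Bin(N, α), with α = 0.05 per test.

## Synthetic communities

The generator emulates the study design: two forest types (native,
plantation), 8 training sites per type sampled over 7 monthly occasions on
edge and interior transects, and 16 test sites per type (edge only)
sampled at t and t+1, with host abundance multiplied by ρ = 0.2 at half
the plantation test sites at t+1 (the biopesticide treatment). Defaults:
40 hosts, 20 parasitoids.

Trees are pure-birth (Yule) simulations; tip branches are extended by the
waiting time to the next (unrealised) speciation so no sister pair sits at
zero distance. Log body size evolves by Brownian motion; phenology rows
are Dirichlet proportions scaled by a lognormal activity total; host ND is
Beta-distributed; biogeographic status is Bernoulli. Interaction
propensity combines niche kernels with a neutral abundance term:

log λ_il = β0 + β_size·exp(−Δ²/2σ²) + β_phen·overlap + β_phylo·K_phylo
           + log n_i + log a_l,

with counts Poisson(λ·exposure). The phylogenetic kernel gives each
parasitoid a Gaussian preference along the first host principal-coordinate
axis, so related hosts share parasitoids. Default coefficients make the
body-size matching kernel dominant — a strong-niche regime in which
trait-based link prediction is expected to work; the `neutral()` variant
zeroes all matching coefficients and raises the baseline so overall
density stays comparable, leaving interactions driven purely by
abundance. A fraction of hosts (10%) is withheld from the training sites
to exercise the cold-start path.

At t+1, parasitoid abundances respond numerically to their recruitment:
a_l(t+1) = a_l · Σ_i share_il · (n_i(t+1)/n_it), with recruitment shares
proportional to kernel × time-t abundance — this is the mechanism that
makes apparent competition real in the generated data. Attack pressure at
t+1 is allocated by *time-t* host abundances by default ("recruitment"
basis): this is exactly the dynamic regime the d_ij projection assumes
(attack loads follow past recruitment, not the focal host's current
abundance); a "mass_action" switch instead tracks current abundance, which
injects the focal host's own abundance drift into the projection error and
is useful for robustness probes. Host sample sizes conflate abundance and
sampling effort (collected counts), and are floored at the attack total so
rearing semantics (events ≤ individuals) hold; interaction counts remain
exactly Poisson.

What the generator does **not** emulate: plant-layer structure behind host
ND, species-selective treatment effects, transect effects (labels only),
observation-driven taxonomic error, and multi-generation dynamics.
Passing recovery tests therefore show that the pipeline recovers the
structure it assumes, not that field data satisfy those assumptions.

## Benchmark problem sizes

The shipped recovery benchmarks run at sizes chosen to give stable
statistics from a desk machine: held-out AUC is 5-fold cross-validated on
the default 40 × 20 community; AUC benchmarks use the trait-matching
feature blocks only (body size, phylogeny, overlap), because ND and raw
phenology magnitudes are derived from abundances and the training network
and would mix neutral predictability into a measure of trait matching.
Indirect-effect recovery uses a 20-host × 10-parasitoid community with
generalist parasitoids (wide kernels), larger host collections
(mean 60 individuals) over 4 training and 16 test sites, 50 replicates
for power and 200 within-site permutation replicates for type-I-error
calibration.

## Known limitations

- Random-effect structures are approximated (see above); lme4-style
  random slopes and formal variance components are out of scope.
- The all-subsets dredge is exhaustive and hence capped at 16 terms.
- The observation-level random factor is represented by robust
  covariances plus a dispersion-inflated R² denominator, not a latent
  per-row intercept.
- KNN tuning uses leave-one-parasitoid-out error rather than grouped
  k-fold; with dozens of parasitoid species this is cheap and has the
  lowest variance.
- d_ij from predicted networks pools the per-site predicted matrices by
  summation before projection; alternative poolings are not explored.
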