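# parweb

Predicting direct and indirect effects in quantitative host–parasitoid
networks from species traits, phylogenies and abundances.

Parasitoid biocontrol agents can harm non-target hosts directly (attack)
and indirectly, through **apparent competition**: two host species that
share a parasitoid are coupled, because a change in one host's abundance
changes the shared enemy's abundance and hence attack rates on the other
host. Risk assessment would like to anticipate both kinds of effect
*before* an agent is released — that is, without quantitative interaction
data for the recipient community. `parweb` is a tested, config-driven
implementation of a two-stage analysis for this problem, aimed at
community ecologists and biocontrol researchers:

1. **Direct effects.** Predict the quantitative host × parasitoid network
   at a site from species traits (body size, phenology, normalised degree
   ND, biogeographic status) and phylogenies, using two machine-learning
   routes: a random forest trained on a binary pooled "meta-network"
   (predicting the probability p̂ of each pairwise interaction) and a
   k-nearest-neighbour recommender over parasitoid trait similarity
   (predicting interaction frequencies ŵ, with cold-start insertion of
   hosts unseen in training and self-exclusion of focal parasitoids).

2. **Indirect effects.** Project the network into the potential for
   apparent competition between hosts i and j,

       d_ij = Σ_k (α_ik / Σ_l α_il) · (α_jk / Σ_m α_mk),

   the proportion of host i's parasitoids that recruited from host j, and
   combine it with time-t attack rates α and observed host abundance
   changes into an expected parasitism rate at the next time step,

       E_i(t+1) = (1/n_i(t+1)) · Σ_j d_ij · (Σ_l α_ilt) · n_j(t+1)/n_jt ,

   which is validated against observed parasitism (events / hosts
   sampled) with binomial regression.

Validation statistics follow standard quantitative-ecology practice:
scaled predictors, Poisson/binomial GLM fits with approximate handling of
site and parasitoid grouping factors, all-subsets AIC/AICc selection with
inclusion-fraction reporting, Pearson-dispersion checks, marginal and
conditional R² by variance decomposition, leverage-based outlier
screening, and an exact binomial (Bernoulli-process) correction for
multiple slope tests.

Because real field data of this kind are expensive, the package includes a
first-class synthetic community generator (`parweb.simulate`) producing
phylogenies, trait tables, training networks and perturbed test sites with
the structure the analysis assumes — including an experimental
host-reduction treatment and a parasitoid numerical response — so every
stage is verifiable end to end. See `docs/methods.md` for the model
details and assumptions.

## Worked example

Run the full analysis on the default simulated metacommunity (40 hosts,
20 parasitoids, 8 training and 16 test sites per forest type; about 20 s
on one CPU):

```python
from parweb import CommunityConfig, PipelineConfig, run_pipeline

results = run_pipeline(
    PipelineConfig(community=CommunityConfig(seed=1), engine="both", seed=1),
    outdir="run",
)
print(open("run/report.txt").read())
```

which prints:

```
Host-parasitoid network prediction report
==========================================

[rf] direct validation (Poisson, scaled predictor)
  slope=+1.4864  z=14.91  p=6.13e-12
  marginal R2=0.096  conditional R2=0.103
[rf] indirect validation (binomial, scaled E)
  slope=+1.2105  z=6.97  p=5.154e-12
  eligible hosts: 1257

[knn] direct validation (Poisson, scaled predictor)
  slope=+0.4854  z=8.29  p=9.84e-08
  marginal R2=0.013  conditional R2=0.014
[knn] indirect validation (binomial, scaled E)
  slope=+1.1472  z=9.15  p=2.444e-19
  eligible hosts: 1219

Bernoulli summary: 4/4 slopes significant at alpha=0.05; tail probability 6.25e-06
```

The direct-validation slope is the Poisson coefficient of observed
interaction frequency on the scaled predicted probability (random forest)
or frequency (KNN): positive and significant means pairs predicted as
likely really do interact more often, and the random forest separates
pairs better than KNN here, as the R² values show. The indirect slope
plays the same role for expected vs. observed parasitism over the 1257
(site, host) records eligible for the projection. The Bernoulli line is
the exact probability that at least that many of the slope tests would be
significant by chance. `run/` also contains
`report.json` and a manifest of output hashes; rerunning with the same
config and seed reproduces the hashes exactly.

The same pipeline is exposed on the command line:

```bash
parweb simulate --seed 11 bundle/        # write CSV + Newick study bundle
parweb run --bundle bundle --engine both --seed 11 out/
```

Recovery benchmarks live in `parweb.benchmarks`: held-out link-prediction
AUC on the default trait-matching community (and its neutral limit), and
replicated recovery/permutation-null calibration of the indirect-effect
test under a ρ = 0.2 host-reduction treatment.

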