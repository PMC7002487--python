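# finsoc

Social-structure analysis for photo-identified dolphin populations: from
survey sighting records and genetic data to **generalized affiliation
indices (GAIs)**, preferred/avoided-companionship tests, modularity-based
social clusters, and kinship / reproductive-condition correlates of female
associations.

The package is aimed at behavioural ecologists working with fission-fusion
societies (bottlenose dolphins and similar systems) where the raw data are
a stream of group sightings: one row per *(survey day, group, individual)*
with a group position, plus microsatellite genotypes, mtDNA haplotypes and
a per-female reproductive-condition category. Because such field datasets
are rarely public, the package ships a synthetic-population simulator with
known social clusters, pedigree and homophily effects, so every stage of
the pipeline can be validated by parameter recovery.

## The method

Association is measured per dyad with the **half-weight index**

    HWI = x / (x + yAB + (yA + yB)/2)

over daily sampling periods (`x` days together in a group, `yA`/`yB` days
only one seen, `yAB` both seen apart). Raw association confounds social
preference with structure — two females sharing a bay, or two highly
gregarious ones, co-occur regardless of any affinity — so three structural
predictor matrices (kernel home-range overlap **UDOI**, gregariousness,
joint sighting effort) are screened with an **MRQAP** (node-permutation
matrix regression, Dekker double-semi-partialing). Retained predictors
enter a binomial regression of the co-occurrence counts,

    x_ij ~ Binomial(d_ij, mu_ij),  logit(mu_ij) = b0 + sum_k b_k P_k,ij

and each dyad's **GAI** is its signed deviance residual — the association
left over once structure is accounted for. Downstream: a Bejder-style
data-stream permutation test for non-random companionship (restricted
checkerboard swaps preserving group sizes, individual sighting totals and
the day structure; SD of the indices as statistic), dyad classification at
±2.5 (preferred / casual / avoided), Newman leading-eigenvector modularity
for social clusters, and kinship tests built on a maximum-likelihood
pairwise relatedness `r = k1/2 + k2` (IBD coefficients maximized on the
2-simplex per dyad from microsatellite allele frequencies) and binary
mtDNA haplotype sharing.

## Worked example

Simulate a study (55 females, 7 latent clusters in 2 communities, 150
survey days, kin/cluster/reproductive-state homophily), run the full
pipeline, and summarize:

```bash
finsoc simulate --seed 7 --out data
finsoc run --config config.yaml --base-dir data --out results
finsoc report results/report.json
```

with `config.yaml`:

```yaml
min_sightings: 11
n_perm_mrqap: 1000
n_perm_bejder: 500
flips_per_perm: 100
n_perm_mantel: 10000
relatedness_mode: triadic
seed: 7
```

prints:

```
individuals: 55   groups: 456   dyads: 1485
  predictor dyad_sightings   partial r = +0.116  p = 0.0010  [retained]
  predictor gregariousness   partial r = +0.135  p = 0.0010  [retained]
  predictor overlap          partial r = +0.389  p = 0.0010  [retained]
GAI range [-3.19, 3.07]  mean -0.07  SD 0.99
permutation test: observed SD 0.9855 vs random 0.9306  p = 0.0020
clusters: 4  Qmax = 0.194  sizes [9, 15, 15, 16]
```

Reading this: home-range overlap is the dominant structural confound
(partial r = 0.39) and all three predictors are controlled; the observed
SD of the affiliation indices exceeds its permutation null (p ≈ 0.002), so
the simulated females have preferred/avoided companions — as they should,
since the generator planted cluster, kin and reproductive-state homophily.
The full JSON report additionally shows the planted effects being
detected: GAI is higher among same-condition females (medians +0.15 vs
−0.23, Mann-Whitney p < 1e-12), correlates with ML relatedness (Mantel
r = 0.10, p < 1e-3) and with haplotype sharing (r = 0.05, p = 0.03), and
relatedness is higher within than between the recovered clusters
(0.078 vs 0.063, p = 0.03) while home-range overlap is uncorrelated with
haplotype sharing (the confound check). Note the cluster partition under
these fully confounded conditions is coarser than the 7 planted clusters:
controlling for spatial overlap deliberately removes the spatially
confounded part of the social signal (see `docs/methods.md`).

The same analyses are available as a library, centred on a model/results
pair:

```python
from finsoc import (SimulationConfig, simulate_pedigree, simulate_surveys,
                    filter_sightings, dyad_counts, GeneralizedAffiliationModel)

cfg = SimulationConfig(seed=7)
truth = simulate_pedigree(cfg)
records, ids = filter_sightings(simulate_surveys(truth, cfg))
model = GeneralizedAffiliationModel(dyad_counts(records, ids))
result = model.fit()              # GAIResults
print(result.summary())
classes = result.classify(2.5)    # preferred / casual / avoided
```

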