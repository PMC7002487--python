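# Methods

This note documents the statistical machinery, the synthetic-data
generator, the numerical choices, and what the validation suite does and
does not establish.

## Dyadic association and its structural confounds

All statistics are defined over unordered dyads of photo-identified
females. The sampling period is the survey day. After filtering (groups
with under 75% of the estimated members identified are dropped; each
individual keeps only its first group per day, which also discards
identical groups resighted within a day; individuals must be seen on
*strictly more than* `min_sightings` days, default 11; optionally only
sexed females are kept), the half-weight index for a dyad is
`x / (x + yAB + (yA+yB)/2)`. Because each individual occupies at most one
group per day after filtering, the denominator reduces to the mean of the
two individuals' sighting-day counts — a fact the permutation test
exploits, since restricted swaps leave it invariant.

Three structural predictors are computed:

- **Home-range overlap (UDOI).** Each female's utilization distribution is
  a fixed-bandwidth bivariate Gaussian product-kernel density (default
  h = 550 m, the value used for this study system; an `href`-style rule
  sigma·n^(-1/6) is available) on one shared 50 m grid padded 3h beyond
  the data, every group member inheriting the group's position.
  UDOI_ij = A_ij · Σ UD_i·UD_j·cell_area with A_ij the intersection area
  of the 95% ranges; identical uniform UDs give exactly 1. The grid is
  shared across individuals so no resampling is ever needed. Densities are
  not land-masked — a deliberate simplification (the estuary geometry is
  not modelled) that shifts UDOI magnitudes but not their rank structure.
- **Gregariousness**, as summed association strength in the dyadic
  log-product form log(g_i·g_j), each sum excluding the focal dyad's own
  HWI. The raw-associate-count alternative exists in the literature; the
  continuous form is used because the methodology the index derives from
  operationalizes it this way. Dyads with a zero exclusive sum are flagged
  and assigned (matrix minimum − 1).
- **Joint sighting effort**: sighting-day count of i plus that of j.

## MRQAP screen and the GAI

Predictors are screened against the HWI matrix with Dekker
double-semi-partialing MRQAP: the statistic for predictor k is the partial
correlation of the response and predictor residual vectors (each
residualized on the remaining predictors), and its null comes from joint
row/column permutations of the predictor's residual *matrix* — node
permutations respect the non-independence of dyads sharing an individual.
p-values are add-one corrected, two-sided; predictors with p < alpha
(default 0.05, default 10,000 permutations) are retained. Near-collinear
predictor pairs (|r| > 0.999) or an ill-conditioned design abort with the
offending pair named.

The GAI model is a binomial GLM with logit link: successes `x_ij` out of
`d_ij` half-weight "trials" (non-integer trials are handled as variance
weights on the proportion, the standard GLM device), intercept plus the
retained predictors. The affiliation index of a dyad is its signed
deviance residual with the 0·ln(0/·) ≡ 0 convention; a dyad at exactly its
fitted mean gets 0 and a never-together dyad is strictly negative. The
residuals agree with the GLM implementation's own deviance residuals to
1e-9 (dual-route test). Deviance residuals are only *approximately*
orthogonal to the retained predictors — the transform is nonlinear, so a
strong covariate leaves a small skewness-driven trace; at the effect sizes
association data produce, |r| stays below 0.02 (asserted on ≥1000 dyads),
but a contrived fixture with a large coefficient can reach ~0.04. With an
empty retained set the model reduces to a single shared co-occurrence
rate, computed in closed form.

Dyads are classified preferred (> 2.5), avoided (< −2.5) or casual (the
closed interval, boundaries included).

## Preferred/avoided companionship test

The group×individual incidence matrix is permuted by checkerboard swaps
restricted to pairs of groups observed on the same day, preserving group
sizes, individual sighting totals and the day structure. After each batch
of swaps (default 1,000 between saved permutations; 10,000 saved) the
affiliation indices are recomputed from the permuted stream and the SD of
the dyadic indices saved; p is the fraction of permuted statistics ≥ the
observed, add-one corrected. A fixed permutation count replaces
"permute until the p stabilizes", which is not reproducible. The statistic
can be computed on GAIs (default) or HWIs; when GAIs are used,
gregariousness is recomputed from each permuted association matrix, while
the effort predictor (sighting totals are a swap invariant) and the
spatial overlap predictor (swaps reassign individuals among same-day
groups, which would perturb individual kernel ranges only marginally at
enormous cost) are held at their observed values.

## Clusters

Newman's leading-eigenvector method on the GAI matrix with negative
weights clamped to zero (modularity assumes non-negative weights; the raw
matrix is preserved for every other analysis). Bisection uses the sign
pattern of the leading eigenvector of the group's generalized modularity
matrix, refined by Kernighan–Lin fine-tuning: each pass tentatively flips
every node once (largest gain first, ties to the lowest index, downhill
moves allowed) and keeps the best intermediate state. A purely greedy
refinement was tried first and got stuck in local optima on planted data;
the tentative-move version is deterministic and strictly better. Splits
are accepted only if they increase global Q, so the returned Q is
monotone along the recursion; it is re-verified against a direct
evaluation of the modularity sum to 1e-10.

Cluster ranges pool each cluster's group positions (one per group per
cluster) into a UD and report 95%/50% areas. Network export thresholds
edges at 2×|mean GAI| by default: the mean affiliation index is typically
negative, so the published "twice the mean" edge rule only works on the
magnitude — this is a design reading, not a fact of the source tables.

## Kinship

- **Haplotype sharing**: binary matrilineal proxy; individuals without a
  label are dropped from the matrix (and all tests) with a warning.
- **ML relatedness**: per dyad the multilocus likelihood
  Π_l (k0·P0 + k1·P1 + k2·P2) is maximized over the IBD simplex, with the
  genotype-pair probabilities P_m given m alleles IBD under no inbreeding;
  r = k1/2 + k2, clipped to [0,1]. The log-likelihood is concave in k, so
  a 0.02-step simplex grid followed by a 0.001-step local grid finds the
  global optimum deterministically (verified against an exhaustive
  0.001 grid). The **triadic mode** re-estimates each dyad with up to
  `max_references` third individuals, adding each reference's alleles as
  pseudo-counts to the frequency estimate and averaging with weights
  proportional to the reference's typed-locus fraction; with error rate 0
  and uninformative references it approaches the dyadic estimate. This is
  this package's own light-weight triadic variant, not a re-implementation
  of any published triadic estimator. A small genotyping error rate
  (≤ 0.1) mixes each IBD-state likelihood toward the unrelated state.
  Dyads under 2 jointly typed loci are reported missing.
- **Tests**: class means vs a dyad-label permutation null (two-sided,
  add-one); Monte-Carlo Pearson chi-square for sharing×class tables with
  class margins fixed; within/between-cluster mean difference vs a node
  permutation of cluster labels (one-sided, within > between); Mantel
  confound checks of overlap vs both genetic matrices. Mantel tests fix
  the tail a priori (default "greater", since every directional
  hypothesis here predicts a positive correlation); choosing the tail
  from the observed sign would double the type-I error, and the null
  calibration below would fail. Dyads are treated as independent in the
  class-mean and Mann–Whitney comparisons, as is conventional for these
  procedures; the p-values are therefore descriptive.

## The synthetic population

The generator emulates the study conditions: 55 females, 150 survey days,
7 social clusters whose centers sit in 2 spatial communities 8 km apart,
11 microsatellite loci (8 Dirichlet(1)-frequency alleles each), 2 mtDNA
haplotypes at near-equal founder frequency, reproductive category 1 with
probability 24/55, detection probability 0.25 per female per day (median
sightings ≈ 37, ≈ 450–550 retained groups — the scale of the emulated
study). Pedigrees are shallow (≤3 generations): non-founder females get a
mother among earlier same-cluster females and a father from a small
per-cluster male pool, excluding the mother's male-line ancestors so all
matings are outbred and parent–offspring relatedness is exactly 0.5;
full-sibs 0.5 and half-sibs 0.25 arise through the shared male pool.
Genotypes are Mendelian; haplotypes follow the maternal line exactly.

Groups form per day by greedy agglomeration on the affinity
`beta_cluster·[same cluster] + beta_kin·r + beta_repro·[same state] +
noise`, candidates joining while their mean affinity to the members
exceeds a per-group threshold drawn from `group_threshold` (default
U(0, 1.5) against N(0,1) noise, giving fission-fusion-like sizes of 1–15
and partial cluster mixing). Default effects beta = (3, 2, 1) make
cluster the dominant axis with kin and reproductive homophily on top.
One RNG stream per run, seeded from the config.

What the simulator does **not** reproduce: demographic turnover, males,
observation heterogeneity (mark quality, survey effort gradients),
spatially structured detection, and calf age classes. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted effects under idealized sampling, not field-data performance.

## Validation experiments and their design

- **Null calibration**: with all betas 0 the grouping is pure noise; the
  Bejder test, Mantel test, MRQAP screen and within/between test each
  reject at 5% ± 2% over 200 replicates (small 20-female populations keep
  this cheap).
- **Planted-partition recovery** uses a scenario with *spatially
  homogeneous* clusters (shared centers), a strong cluster effect
  (beta_cluster = 6, other betas 0) and a grouping threshold above the
  noise scale (U(2.5, 4)), so groups essentially never mix clusters.
  Spatial homogeneity matters: when each cluster has its own center,
  cluster membership and home range are perfectly confounded, and the GAI
  — by design — attributes the shared-range part of co-occurrence to the
  overlap predictor, so no method operating on the residuals can (or
  should) fully recover spatially confounded clusters. The full pipeline
  (screen included) recovers the planted partition with mean adjusted
  Rand index ≈ 0.99 and the planted cluster count in most replicates.
- **Kin-homophily power**: under default conditions the GAI-vs-relatedness
  Mantel test (ML-estimated relatedness, not the pedigree truth) is
  significant in ≥ 80% of runs.
- **Relatedness recovery**: 200 simulated parent–offspring dyads at
  8 loci × 8 alleles give mean r̂ within 0.05 of 0.5; unrelated dyads show
  the expected small positive boundary bias with median ≈ 0.

Problem sizes in the validation suite (20-female null populations,
100-permutation chains, 10 recovery replicates) were chosen as the
smallest at which the binomial noise of a rejection-rate estimate over
200 replicates stays within the ±2% band; the pipeline itself defaults to
10,000 permutations for all one-shot tests.

## Degenerate inputs and tie-breaks

Empty sighting tables after filtering raise; an all-zero weight matrix
yields one cluster with Q = 0 and a warning; dyads with a zero HWI
denominator get index 0 with a warning; a monomorphic locus is retained
(uninformative) with a warning; contingency tables with a zero margin are
rejected. All permutation p-values are add-one corrected, (1+c)/(1+N).
Cluster labels are renumbered by lowest member index, making partitions,
reports and exports byte-reproducible for a fixed config and seed.
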