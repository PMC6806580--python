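# Methods

This note documents the statistical procedures implemented in
`riverneutral`, the assumptions behind them, the defaults that matter, and
the known limitations — in particular what the synthetic-data generators do
and do not emulate about real river metacommunity data.

## 1. The neutral community model fit (`ncm`)

**Model.** Local communities of effective size *N* receive immigrants from
a shared metacommunity with probability *m* per birth-death event.  The
diffusion limit of this process gives, for a taxon at metacommunity
relative abundance *p*, a stationary beta law for its local relative
abundance, `x ~ Beta(Nm·p, Nm·(1−p))`.  With a detection limit *d* the
expected occurrence frequency over sites is `1 − BetaCDF(d; Nm·p, Nm·(1−p))`.

**Inputs.** `p` is each OTU's mean relative abundance over the samples of
the analysed subset; `freq` is the fraction of samples in which it appears;
OTUs never detected are excluded (they carry no information about the
curve).  All samples must share a depth *N*, which is why rarefaction
precedes fitting.

**Estimation.** *Nm* is the least-squares minimiser of
`Σ (freq_i − predicted(p_i))²`, optimised in log10 space over
[1e−2, 1e9]: a 56-point grid locates the basin, then bounded scalar
minimisation (tolerance 1e−8 in log10 Nm) refines it.  The problem is
one-dimensional and smooth, so this is both deterministic and fast.  R² is
`1 − SSE/SStot` with SStot about the mean observed frequency; it can be
negative when the curve fits worse than a constant.  The immigration rate
is reported as `m = Nm/N` exactly.

**Detection limit.** `d = 1/N` — one read at the rarefied depth — the
convention of the standard implementations of this fit.  It is exposed as a
parameter.

**Known bias (important).**  When detection is "at least one read of a
multinomial sample of depth N" — which is what sequencing does, and what
the beta-binomial zero class describes exactly — the continuous
approximation `P(x > 1/N)` is not the true detection probability, and the
least-squares fit inherits an Nm-dependent bias.  Measured on data drawn
exactly from the Dirichlet-multinomial stationary law (30 sites, depth
10^4, 2000 taxa): roughly −2% at Nm = 100, +25% at Nm = 1000, +12% at
Nm = 10^4, larger in between (+41% at Nm = 3000).  With deterministic
threshold detection (`x > 1/N` on the latent composition) the same
estimator is unbiased to ±1%, which isolates the cause: the continuum
approximation of discrete detection, not the optimiser.  The bias is a
property of the published method itself; we report it rather than altering
the estimator, and parameter-recovery figures in the acceptance report
should be read with this in mind.  A continuity-corrected detection limit
(`d = 1/(2N)`) makes matters worse at every Nm tested and is not used.

**Partition envelope.**  Per OTU the envelope answers: "is an observed
frequency k/n (n = number of sites) consistent with the predicted detection
probability?"  The calibrated 95% acceptance region for that question is
the binomial quantile band `[Binom.ppf(0.025, n, pred), Binom.ppf(0.975, n,
pred)]/n`, which is the default (`envelope="binomial"`).  The Wilson score
interval centred on the prediction — the shape used by several published
fits — is also available (`envelope="wilson"`), but note it is a
*confidence-interval* construction used backwards and measures ~91.6%
coverage on the model's own data versus ~97.8% for the binomial band;
pipeline reports record which envelope produced the partition.  A
bootstrap envelope over refitted curves (`bootstrap_envelope`) is provided
for auditability.  Bootstrap confidence intervals for Nm and R² resample
OTUs with replacement (default 1000 replicates, seeded).

**Per-partition migration rates.** Each partition (above/neutral/below)
with at least 10 distinct-p OTUs is refitted on its own, giving the
partition-specific Nm and m; smaller partitions are reported as missing.

## 2. Rarity classification (`rarity`)

Thresholds: rare = 0.01% (strict `<`), abundant = 1% (inclusive `>=`), per
sample on relative abundances of the rarefied table so proportions are
comparable across samples.  The six categories are mutually exclusive and
exhaustive over the lattice of which threshold zones an OTU visits;
a boundary value of exactly 0.01% counts as *not* rare, exactly 1% counts
as abundant.  "Dominant" pools AAT + CAT + CRAT.  An empty pool (e.g. no
always-abundant OTUs, common in hyperdiverse communities) is a warning,
not an error.

## 3. Alpha diversity (`alpha`)

Chao1 is reported in both the classic `S + F1²/(2F2)` and bias-corrected
`S + F1(F1−1)/(2(F2+1))` variants (bias-corrected is the headline value;
which variant a given legacy pipeline used is often unrecorded, so both are
emitted).  ACE uses the standard rare/abundant cutoff of 10 reads
(parameter).  Shannon is in nats; Pielou is `H/ln S` and undefined
(missing, with a warning) for single-OTU samples; Simpson is the
Gini-Simpson `1 − Σp²`; Good's coverage is `1 − F1/N`.  Numerical kernels
come from scikit-bio and are pinned by hand-value tests.  Rarefaction
curves are means over seeded without-replacement subsamples, with an exact
hypergeometric closed form (`expected_rarefied_richness`) used as the test
oracle.

## 4. Distances, Mantel statistics, ordination (`beta`)

* Bray-Curtis on counts; similarity = 1 − dissimilarity.
* Geographic distance is great-circle (haversine, mean Earth radius
  6371.0088 km).  At a river-basin extent (~50 km) the difference from a
  projected planar distance is negligible and the computation needs no GIS.
* Dendritic distance is the shortest path along the undirected river tree
  (sum of edge lengths), the natural "as the water flows" metric.
* Mantel correlation (Spearman with average ranks, or Pearson) of condensed
  upper triangles; p-value by simultaneous row/column permutation of the
  second matrix, `p = (1 + #{r_perm ≥ r_obs})/(1 + B)`, one-tailed for
  positive association by default (two-tailed available).  Partial Mantel
  residualises both (rank-transformed) triangles on the third matrix and
  permutes the residualised second matrix; a vanishing residual (e.g. all
  three matrices identical) is reported as degenerate (r = 0, p = 1) with a
  warning.  The permutation engine is shared with the distance-matrix
  variation partitioning; scikit-bio's independent Mantel implementation
  cross-checks the statistic in the test suite.
* ANOSIM and PCoA delegate to scikit-bio (seeded).  PCoA reports negative
  eigenvalues as-is rather than correcting them.
* Distance-decay fits OLS of pairwise similarity on pairwise distance for
  the slope/intercept, but takes significance from a Mantel test — pairs
  are not independent, so a naive regression p-value would overstate
  evidence.  The tested alternative is negative association (decay).

## 5. Spatial eigenfunctions (`eigenfunctions`)

**PCNM.** Distances beyond the truncation threshold are replaced by 4×
the threshold; principal coordinates of the truncated matrix with positive
eigenvalues form the basis.  The automatic threshold is the longest edge of
the minimum spanning tree — the smallest value keeping all sites connected.
No Moran's-I screening is applied; downstream forward selection decides
which vectors matter.

**AEM.** A binary site-by-edge matrix marks which directed edges lie on the
path from the network origin down to each site (requires a dendritic,
acyclic network).  Columns are weighted by `w = 1 − (d/d_max)²` (d = edge
length, d_max = the maximum edge length), centred, and the left singular
vectors with positive singular values form the basis.  The longest edge
receives weight 0 — distant links carry no influence.  Degenerate corner
case: if *every* edge has the maximum length the weighting would annihilate
the matrix, so unit weights are used with a warning (the weighting is
uninformative there by construction).  Eigenvector signs are fixed by
making the largest-magnitude loading positive, for reproducibility.  AEM
bases are intentionally not invariant to flow reversal; that asymmetry is
the point of the method.

## 6. Variation partitioning (`varpart`)

RDA R² is the trace of the fitted sum of squares over the total for
centred (Hellinger-transformed) Y on centred X, adjusted by Ezekiel's
`1 − (1 − R²)(n − 1)/(n − p − 1)`.  For predictor unions that are rank
deficient by construction, p is the column-space rank.  The two-set
partition reports pure environment `a = adjR²(E∪S) − adjR²(S)`, pure space
`c = adjR²(E∪S) − adjR²(E)`, shared `b = adjR²(E) − a` and unexplained
`d = 1 − adjR²(E∪S)`; `a+b+c+d = 1` holds to machine precision and slightly
negative adjusted fractions are reported as-is (flagged, never clipped).

VIF filtering iteratively removes the highest-VIF column until all
`VIF_j = 1/(1 − R²_j) ≤ 20`.

Forward selection first requires the global model to be significant under
Y-row permutation; candidates are then added greedily by R² gain, each
tested by residual permutation under the current model (Freedman-Lane
style).  Selection stops when a candidate's p-value exceeds α or when the
cumulative adjusted R² reaches the global model's adjusted R²; the crossing
variable is retained, matching the reference implementations of the
double-stopping procedure.  (Rejecting the crossing variable instead would
systematically discard a single strong predictor diluted by noise
candidates, because the one-variable adjusted R² generically exceeds the
noise-penalised global value.)

Environmental variables are square-root transformed (except pH, already on
a log scale) and standardised before use — the convention for skewed water
chemistry panels.

The distance-matrix analogue (`varpart_mantel`) builds the combined
fraction from the multiple regression of community distances on both
explanatory distance vectors and the marginal fractions from squared Mantel
correlations, with partial-Mantel tests attached; it is reported alongside,
never mixed with, the RDA version.

## 7. Synthetic data (`simulate`)

**Neutral generator.** Local compositions are drawn
`Dirichlet(Nm · p_meta)` — the exact stationary law of the finite
Moran-with-immigration chain — then sequenced as a multinomial of N reads.
A deliberately slow explicit birth-death-immigration chain
(`simulate_neutral_chain`) is included and cross-checked against the
Dirichlet shortcut's across-site variance `p(1−p)/(Nm+1)` in the tests.
Defaults mirror the study design at desk scale: 30 sites, depth 10^4,
S = 2000 taxa, lognormal metacommunity with σ = 2 (a typical microbial
species-abundance spread: a few dominant taxa over a long rare tail).

**River networks.** A random tree grows from one headwater source; edge
length = straight-line distance × sinuosity (default 1.3, ≥ 1 by
construction), so dendritic distance ≥ straight-line distance always — as
in real rivers.  Coordinates are laid out on a local tangent plane around
(116.5° E, 25.2° N).

**Niche generator.** Expected abundances follow Gaussian responses to a
gradient (distance downstream from the source), multiplied by lognormal
noise whose log has an exponential spatial correlation on the network, then
multinomial sequencing.  The emitted environment table has the informative
gradient, its square, and 22 noise columns (24 total, the width of a
typical river physicochemistry panel).

**What the generators do not emulate:** seasonal succession dynamics,
species interactions, mass effects, hydrodynamic transport, taxon-specific
detection efficiency, and PCR/sequencing noise beyond multinomial
sampling.  Tests passing on these simulations therefore validate the
*statistical machinery* (estimator calibration, type-I error, algebraic
identities), not the ecological completeness of the neutral model on any
real river.

## 8. Pipeline

Seasons are analysed independently and pooled ("all"); rarity
classification uses the season-level rarefied table and precedes
subsetting, so subcommunity analyses share the parent table's depth (the
NCM detection limit stays one read at that depth even though subcommunity
rows no longer sum to it).  Every stage logs wall-clock and status; any
failure aborts with the stage name and retains partial outputs; the JSON
report embeds the resolved config and all seeds.  Reruns with the same
config reproduce every analysis number exactly (timings excepted).

## 9. Problem sizes and determinism

All randomness flows through explicit integer seeds (NumPy `SeedSequence`
spawning; no global state).  The simulation scales used by the test suite
and the acceptance script — 50 seeds × 3 dispersal regimes for parameter
recovery, 6 × 5000-taxon runs for envelope calibration, 1000–2000 null
simulations at 99 permutations for Mantel/ANOSIM calibration, 100 random
designs for the partitioning algebra, 50 paired runs at the published
Nm ratio for the seasonal contrast — were chosen so the full battery
completes in a few minutes on a single CPU while keeping Monte-Carlo
standard errors small relative to every acceptance band.

## 10. Known limitations

* The NCM fit's continuum-approximation bias (§1) means absolute Nm values
  from sequencing data should be interpreted comparatively (e.g. wet vs dry
  season at equal depth), not as unbiased chain parameters.
* R² of the NCM is descriptive, not a hypothesis test; high R² on
  simulated niche data is possible when the gradient correlates with
  abundance weakly.
* Partial Mantel inherits the well-known liberal behaviour under strong
  spatial autocorrelation of the controlled matrix.
* PCNM truncation uses the MST rule; with strongly clustered sites other
  truncations can change the resolved spatial scales.
* BIOM/HDF5 and phylogenetic diversity are out of scope; TSV/JSON are the
  interchange formats.
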