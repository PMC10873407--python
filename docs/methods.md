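# Methods

This note documents the models, the numerical choices, and what the
synthetic test beds do and do not establish.

## Neutral community model

The Sloan NCM predicts a taxon's occurrence frequency across samples
from its mean relative abundance: the local abundance is
Beta(*Nm·p*, *Nm*(1−*p*)) distributed, so the probability of exceeding
a detection limit *d* is the Beta survival function
F(p) = 1 − I_d(Nm·p, Nm(1−p)). *Nm* (community size × immigration
rate, dimensionless) is the only fitted parameter; *m* is derived only
when the caller supplies *N*, since fit quality alone never identifies
the two factors separately.

**Fitting.** Least squares of observed frequencies *f* against F(p) is
performed over log *Nm* with four starts (10, 10², 10³, 10⁴) and a box
constraint Nm ∈ [1, 10⁹]; the curve flattens for extreme *Nm*, and the
restarts guard against the optimizer stalling in a flat tail. R² is
computed on untransformed frequencies about the mean of *f* and may be
negative; when *f* is exactly constant, R² is reported as 0 by
convention (the total sum of squares vanishes).

**Detection limit.** The automatic rule is one read at the median
sample depth (d = 1/median depth) when depths are known, else the
smallest positive abundance. Detection is inclusive (abundance ≥ d),
so a single read at the automatic limit counts as presence — the usual
one-read detectability reading. Taxa never detected are dropped, as
they must be on real data.

**Confidence bands.** Two band styles are provided because they answer
different questions:

- *bootstrap* (default): taxa are resampled with replacement
  (1000 replicates by default), each replicate refits *Nm*, and the
  bands are the pointwise percentile envelope of the replicate curves.
  This is an uncertainty band for the fitted curve; with hundreds of
  taxa it is narrow.
- *binomial*: the Wilson 95% interval for a proportion observed over
  *n_samples* trials at the predicted frequency. This is the scatter a
  single taxon's frequency should show around the curve, and is the
  natural reference for partitioning taxa into above / neutral / below.

The partition compares each taxon's observed frequency with the bands
at its own mean abundance.

**Known biases.** Two small upward biases affect fitted *Nm* on count
data: (i) one-read detection smooths the occupancy step over a width
set by the sampling depth, noticeable for taxa with Nm·p ≲ 1; and
(ii) the abscissa is the *estimated* mean abundance, an
errors-in-variables effect that shrinks with sample count. Together
they amount to roughly 10–20% at 150 samples and depth 5×10⁴ — well
inside the factor-of-two recovery the package tests, but the reason
the narrow bootstrap envelope should not be expected to contain the
true curve taxon-by-taxon. The simulator–model consistency check is
therefore run on a metacommunity grid with Nm·p ≳ 1, where the
detection smoothing is negligible.

## Co-occurrence networks

Edges join taxa with |Spearman ρ| ≥ 0.8 and two-sided p < 0.05 (raw
p-values; an optional Benjamini–Hochberg flag exists but the default
follows the plain p < 0.05 convention). Both correlation signs are
kept, with the sign stored on the edge; magnitude thresholding is the
common convention for molecular ecological networks. The correlation
matrix is computed from midranks with the large-sample t
approximation; constant taxa yield undefined correlations that are
stored as missing and can never form edges. No prevalence or abundance
pre-filter is applied by default. Networks are built per
(region, ecosystem) stratum.

- **Modules** come from deterministic greedy (Clauset–Newman–Moore)
  modularity maximization — reproducibility was preferred over
  stochastic methods; on graphs of ≤ 8 nodes the tests compare against
  brute-force enumeration over all partitions (greedy is a lower
  bound and attains the optimum on the clique fixtures). The edgeless
  graph gets one module per node and Q = 0 by convention.
- **Relative modularity** RM = (Q − mean Q_null)/mean Q_null with 100
  Erdős–Rényi G(n, L) nulls matched on node and edge counts, each
  scored by the same detection; a degree-preserving rewiring null is
  available behind a flag. RM centers on 0 when the input is itself an
  ER draw.
- **"Number of clusters"** is reported as connected components,
  distinct from the number of modules.
- **Centralizations** (degree, betweenness, closeness) use Freeman's
  normalization — the sum of differences from the most central node
  over the maximum of that sum, attained by a star, so a star scores 1
  on all three.
- **Vulnerability** is the worst-case relative drop of global
  efficiency (mean reciprocal shortest-path length over pairs,
  disconnected pairs contributing 0) after deleting one node. This
  efficiency-based max-impact definition is an interpretation — the
  measure is conventionally delegated to network toolboxes that do not
  print their formula — and a mean-impact variant sits behind a flag
  would be a one-line change; the max form is what the closed-form
  oracles (star → 1, complete graph → 0) pin down.
- **Extinction simulation** removes round(fraction·n) random nodes for
  fractions 0, 0.1, …, 0.9 with 50 repeats, recording the residual
  network's vulnerability; draws whose residual efficiency is zero are
  skipped and counted. Fraction 0 is deterministic.

## Biogeography

Bray–Curtis dissimilarity on relative abundances; similarity is
1 − Bray–Curtis. Geographic distance is haversine with Earth radius
6371 km; altitude is a separate |Δalt| matrix in metres, never folded
into a 3-D distance, because horizontal and vertical decay are
analyzed separately. PCoA eigendecomposes the Gower-centered matrix;
negative eigenvalues are reported, not corrected, and coordinates are
returned for positive eigenvalues only.

Permutation tests use the (1 + more-extreme)/(1 + n) convention, so p
is never zero, and every test takes an explicit seed. PERMANOVA
follows the distance-based sums-of-squares formulation with free
label permutation. Mantel defaults to Pearson on the unrolled upper
triangles (Spearman by flag); the partial Mantel uses the residual
method, permuting the first matrix, and falls back to the simple test
with a warning when the control matrix is constant. When the full
permutation lattice is no larger than the requested count (tiny n),
it is enumerated exactly. Geography for the geography-vs-environment
partial Mantel is encoded as Euclidean distance on (great-circle km,
altitude km), each scaled to unit variance over pairs — one defensible
encoding of "latitude, longitude and altitude", kept configurable.

**Distance decay** retains sample pairs that share an ecosystem label
and have at least one member in a caller-chosen reference subset (the
reference-anchored filter: within-reference pairs and
reference-to-elsewhere pairs qualify, pairs wholly outside it do not).
Compositional similarity and shared-gene counts go through the same
pair-selection code path, and the statistic is the Spearman
correlation of response versus distance. The decay is computed on
similarity, so a negative R means communities diverge with distance.

**Environmental association** tests each variable by a simple Mantel
between Bray–Curtis and the Euclidean distance of the z-scored
variable, dropping samples missing that variable only (per-variable
complete case); q-values are Benjamini–Hochberg across tested
variables and a variable is flagged iff p < 0.05 and q < 0.1.

**Gene accumulation** subsamples the ORF set without replacement in 5%
steps, 10 repeats each, counting distinct unigenes; the 100% point is
exact with zero spread.

## Synthetic generators

All generators are pure functions of their config including the seed.

- *Neutral*: per-sample compositions are drawn directly from the
  model's stationary law, Dirichlet(Nm·p) around a log-series
  metacommunity, then multinomial counts at the configured depth.
  Sampling the stationary distribution instead of running birth–death
  dynamics gives exact correspondence with the fitted model, enabling
  sharp recovery tests; a dynamic neutral walker is out of scope.
  Defaults (300 taxa, 150 samples, depth 5×10⁴) represent a
  profiler-scale survey stratum.
- *Niche*: Gaussian responses to a 0–1 environmental gradient with
  per-taxon optima, narrow tolerance 0.05 by default, lognormal noise
  — the environmentally filtered alternative. Its occupancy–abundance
  cloud fits the NCM poorly (R² ≤ 0.3 in the discrimination test).
- *Modular*: one latent factor per module plus taxon noise calibrated
  so the within-module latent correlation hits the target (0.95 by
  default; the noise SD is √(1/ρ − 1)). Independent background taxa
  (20 by default) pad the composition the way module-free taxa do in
  real profiles; without them, row-closure induces strong spurious
  negative correlation between a small number of modules, which
  magnitude thresholding would pick up as edges.
- *Transect*: samples sit along one great-circle bearing (so haversine
  reproduces configured distances to machine precision), altitude
  falls linearly, composition performs a log-abundance random walk
  with per-km step variance `drift`, and each sample's gene set
  retains a reference-pool gene at distance x with probability
  exp(−λx), topped up with sample-private novel genes. The expected
  reference-to-sample shared-gene count is therefore
  pool·exp(−λx). Defaults (40 samples over 2500 km, 2000 genes,
  λ = 0.0015/km, drift = 0.005/km) give decay correlations in the
  −0.4 to −0.8 range.

**What the generators do not emulate:** compositional correlation
induced by closure beyond the mechanisms above, phylogenetic signal,
sequencing error, variable library size, spatial autocorrelation in
two dimensions, or interactions between assembly processes. Passing
the recovery tests shows the estimators are correct on data satisfying
their assumptions, not that real communities satisfy them.

## Pipeline

Per-stage seeds are SHA-256 hashes of (master seed, stage name,
stratum label) reduced below 2³¹, so one user-facing seed drives every
stochastic stage without correlating them. Reports carry no
timestamps; identical inputs and master seed give identical bytes
apart from the configuration hash (which encodes paths). The report
layout is validated against `report_schema.json` shipped with the
package.

## Problem sizes in the test suite

The suite exercises the full battery at survey-stratum scale: NCM
recovery at 150 samples × 300 taxa, occupancy consistency at 10⁴
samples, modularity calibration over 20 random graphs × 100 nulls,
permutation calibration over 500 null simulations × 99 permutations,
and a 40-sample transect. These sizes give stable statistics while
keeping a full run around two minutes.
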