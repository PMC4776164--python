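# Methods

`rivst` implements the statistical workflow used to ask whether the spatial
structure of a river's bacterioplankton community (urban reach → agricultural
reach → estuary) is stronger than its seasonal structure, together with the
community-ecology computations that surround that question: alpha diversity
with rarefaction, Dice/Bray–Curtis/unweighted-UniFrac dissimilarities, PCoA,
environmental PCA and UPGMA clustering, BIOENV and ANOSIM, and moving-window
analysis of DGGE fingerprints. Everything runs on synthetic surveys produced
by a seeded generator, so the full pipeline is testable without any sequence
data.

## The spatial-vs-seasonal SSE-difference test

Samples sit on a complete grid of I seasons × J spatial units. For each taxon
k the per-sample values X_ij(k) (relative abundances, z-scored per taxon) are
fit by two one-way ANOVA models:

* seasonal: X_ij(k) = S_i(k) + ε, residual SS
  `SSE_S(k) = Σ_i Σ_j (X_ij − X̄_i)²`, where X̄_i pools the J units of
  season i;
* spatial: X_ij(k) = L_g(j)(k) + ε, residual SS
  `SSE_L(k) = Σ over samples (X_ij − X̄^(g))²`, where each spatial-group mean
  X̄^(g) pools all seasons and all units of the group (with groups
  riverine = units {1,2} and estuarial = {3}, those are 8- and 4-sample
  means).

The statistic aggregates over all p taxa:

```
T = [ Σ_k {SSE_L(k) − SSE_S(k)} − 2p(n−1)/(n−3) ] / sqrt( 4p(n−1)³ / ((n−3)²(n−5)) )
```

with n = I·J the number of samples per taxon. Strongly negative T means the
spatial grouping leaves far less residual variation than the seasonal one;
the reported p-value is one-sided lower-tail (a two-sided option exists).
`n > 5` is required or the scale term is undefined.

### Calibration, and why Monte Carlo is the default

The N(0,1) reference for T rests on a p → ∞ argument that additionally
treats the per-taxon sample variance as independent of the between-group
sums of squares. With same-sample z-scoring that independence fails, and the
failure is not small at n = 12. Exactly: after z-scoring,
SSE_L − SSE_S = (n−1)(SSB_S − SSB_L)/SST, and under an iid normal null
(SSB_S, SSB_L, remainder)/σ² are independent χ² variables with I−1, G−1 and
n−I−G+1 degrees of freedom (the seasonal and spatial between-group spaces
are orthogonal on a complete crossing). The Dirichlet expectation then gives
E[SSE_L − SSE_S] = (I−1) − (G−1) = 2 per taxon — i.e. 2p in total, not the
centering constant 2p(n−1)/(n−3) ≈ 1222.2 at n = 12, p = 500 (which would
follow if the variance estimate were independent of the numerator). The
empirical variance of the sum is likewise below the asymptotic constant
(≈ 6.15p versus 9.39p at n = 12). `calibrate_null` measures both from
simulation and is the module's own oracle for these claims.

Consequences, by p-value method:

* **asymptotic** — keeps the printed constants (they define T, and the
  worked mapping T = −2.38 → p = 0.0087 reproduces), but at n = 12 the
  centering bias of ≈ 3 null standard deviations makes the lower-tail test
  reject massively under the null. It is retained for reference, not as the
  default.
* **permutation** — re-randomizes the unit → group assignment with seasons
  kept intact; exact when the assignment space is enumerable. It is robust
  but extremely coarse at small J: with 3 units split 2|1 there are only 3
  assignments, so p ∈ {1/3, 2/3, 1} and rejection at α = 0.05 is impossible.
* **montecarlo (default)** — parametric calibration: simulate iid standard
  normal cubes of the observed (I, J, p), z-score, and use the simulated
  distribution of Σ_k{SSE_L − SSE_S} as the null; p = (1 + #{null ≤ obs}) /
  (1 + n_sim). This is exact (up to Monte-Carlo error) under the iid normal
  null and, on generated surveys, holds its size well even though real
  relative-abundance cubes are compositional rather than iid: measured
  rejection at α = 0.05 is ≈ 0.04–0.06 with both effects at zero, and power
  against spatial_effect = 2 × seasonal_effect exceeds 0.95 at p = 500.

The asymptotic argument also assumes independence across taxa, which
compositional data violate; the Monte-Carlo null shares that assumption, and
the permutation method is the fallback that does not. This tension is
documented rather than resolved; at the default design the calibrated
Monte-Carlo null is the only method that is both usable and near-nominal.

Zero-variance taxa are dropped (z-scoring is undefined) with p reduced
accordingly; the input values are OTU relative abundances for taxa present
in at least one sample, typically after rarefaction.

## Synthetic surveys

The generator emulates a one-year, nine-site river survey: 4 seasons ×
9 sites (1–2 urban, 3–7 rural, 8–9 estuarial), with per-sample read depths
drawn from Normal(9206, 957²) truncated at 1 — the scale of a 454
pyrosequencing campaign. Per taxon, latent log-relative abundances follow
the additive model `base_k + spatial_effect·L_g(k) + seasonal_effect·S_i(k)
+ ε` with standard-normal `L`, `S`, ε drawn once per taxon per group/season
from a single seeded generator; a softmax maps them to proportions and a
multinomial to counts (log-normal-style rank-abundance with realistic
sparsity at `base_log_sd = 2`). Effect scales are deliberately user-visible
parameters; the defaults `spatial_effect = 2.0`, `seasonal_effect = 1.0`
encode a survey in which spatial structure dominates seasonal structure
two-to-one on the latent scale, the regime the test is meant to detect.
Because no field-calibrated magnitude exists, power statements should be
read across a grid of effect sizes, not just at the defaults.

The environmental table mirrors the survey's Table-1-scale contrasts:
a 4-point seasonal temperature cycle (≈ 8.5–29.5 °C, site mean ≈ 19.5,
across-season sd ≈ 8), salinity ≈ 2 ‰ at riverine sites versus ≈ 11 ‰ (sd
4.5) at estuarial sites, nutrients (TN, TP, DTP, TSS) elevated in the rural
reach, TOC in the urban reach, chl a in the estuary, all with ~35 %
within-group noise truncated above zero. Trees are random binary topologies
with exponential branch lengths; DGGE lanes draw 12–28 bands per lane, with
a configurable fraction of band positions shared within a spatial group (and
group pools disjoint), so fingerprints change sharply at group boundaries.

What the generator does **not** emulate: taxon–taxon ecological
correlations beyond the compositional constraint, sequencing noise/chimeras,
phylogenetic signal in the effects (spatial shifts are independent of the
random tree), temporal autocorrelation beyond the season factor, or any fit
to data from any real river survey. Passing tests therefore demonstrate correctness
and calibration of the machinery under a plausible generative model, not
agreement with any real survey.

## Numerical and design choices

* **Diversity.** Shannon uses −Σ (n_i/N) log(n_i/N) over positive entries,
  natural log by default with the base recorded in every result (base 2 via
  flag). Chao1 defaults to the bias-corrected form
  S_obs + F1(F1−1)/(2(F2+1)) (finite at F2 = 0); the classic form
  S_obs + F1²/(2F2) is available, falling back to F1(F1−1)/2 when F2 = 0.
  Rarefaction is a single seeded multivariate-hypergeometric draw per sample
  (subsampling without replacement), not an average over draws.
* **Distances.** Presence means count ≥ 1 — no minimum-abundance filter.
  UniFrac uses the tree rooted as given (no midpoint re-rooting; re-rooting
  silently changes results). Dice of two empty sets is defined as 1 and
  logged, avoiding NaN in all-absent gel windows.
* **Fingerprints.** Band matching is single-linkage along gel position with
  a 0.01 relative-migration tolerance: sort all bands, cut where consecutive
  gaps exceed the tolerance. It is deterministic, order-independent and
  idempotent. MWA similarities are presence-based Dice in percent;
  height-weighted curve correlation would be a possible extension.
* **Ordination.** PCoA drops negative-eigenvalue axes, reports their
  magnitudes, and uses the sum of positive eigenvalues as the
  percent-explained denominator. Environmental PCA z-scores each variable
  and eigendecomposes the correlation matrix; components with eigenvalue > 1
  are retained (Kaiser), and |loading| > 0.70 is flagged as the conventional
  "correlated with this component" threshold. Component signs are fixed by
  making the largest-magnitude loading positive. UPGMA heights are rescaled
  to Dlink/Dmax × 25 so dendrogram cuts can be stated on a 0–25 axis;
  distance ties resolve by scipy's deterministic condensed ordering.
  Environmental clustering is Euclidean on log-transformed variables; zeros
  are shifted by half the smallest positive observed value, logged.
* **BIOENV.** Variables are log-transformed (temperature excluded by
  default — log °C is physically odd; the skip list is configurable), then
  z-scored; every non-empty subset up to the size cap is scored by the
  Spearman correlation between its Euclidean inter-sample distances and the
  community dissimilarities, and the full ranking is returned (ties broken
  toward smaller subsets, then lexicographically). The community matrix
  defaults to unweighted UniFrac in the CLI workflow, with Bray–Curtis
  selectable.
* **ANOSIM.** R = (mean between-group rank − mean within-group rank)/(M/2)
  on average-ranked distances; upper-tail permutation p with exact
  enumeration whenever the number of distinct label vectors is ≤ n_perm
  (default 999, +1 correction when sampled).
* **Degenerate inputs.** All-zero abundance vectors, constant variables,
  zero-variance taxa, samples below rarefaction depth, unknown tree taxa and
  incomplete season × site crossings raise named errors rather than
  propagating NaN.

## Problem sizes used in the checks

The shipped checks run at desk scale: surveys of 300–500 taxa × 12–36
samples, 10,000 null simulations for calibration at n = 12, p = 500, and 500
replicate surveys for power/size with 199-draw Monte-Carlo nulls per
replicate. These sizes put the Monte-Carlo standard error comfortably below
the tolerances asserted.

## Known limitations

* The asymptotic reference for T is biased at small n (see above); its
  printed constants are reproduced for fidelity but should not be used for
  inference at n = 12.
* The Monte-Carlo null assumes independent taxa; strong positive
  correlations between taxa would widen the true null beyond it. The
  unit-permutation method is assumption-free but needs enough spatial units
  to have any resolution.
* The generator's environmental covariates are group-level stereotypes with
  independent noise; BIOENV results on synthetic data show machinery
  correctness, not realistic effect rankings.
* Weighted UniFrac, NMDS, PERMANOVA and Mantel-type tests are out of scope.
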