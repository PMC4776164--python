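# rivst

Spatio-temporal analysis of river bacterioplankton communities: does the
spatial structure of a community (e.g. urban reach → agricultural reach →
estuary, along a salinity gradient) outweigh its seasonal structure?

`rivst` is aimed at microbial ecologists working with OTU tables from
repeated transect surveys (seasons × sites). It bundles the statistical
workflow such a survey needs — alpha diversity with rarefaction,
Dice/Bray–Curtis/unweighted-UniFrac dissimilarities, PCoA, environmental PCA,
UPGMA clustering, BIOENV, ANOSIM, moving-window analysis of DGGE
fingerprints — around one purpose-built test of spatial versus seasonal
variance, and ships a seeded synthetic-survey generator so the entire
pipeline is testable end to end without sequence data.

## The core test

Samples sit on a complete grid of I seasons × J spatial units. For each of
p taxa, the per-taxon z-scored values X_ij(k) are fit by two one-way ANOVA
models — seasonal, X_ij(k) = S_i(k) + ε, and spatial,
X_ij(k) = L_g(j)(k) + ε (spatial-group means pool all seasons) — giving
residual sums of squares SSE_S(k) and SSE_L(k). The aggregate statistic

    T = [ Σ_k {SSE_L(k) − SSE_S(k)} − 2p(n−1)/(n−3) ]
        / sqrt( 4p(n−1)³ / ((n−3)²(n−5)) ),      n = I·J,

is strongly negative when the spatial grouping explains far more variation
than the seasonal one; the p-value is one-sided lower-tail. Because the
N(0,1) reference for T is an approximation that is visibly biased at
survey-sized n (see `docs/methods.md`), the default p-value is Monte-Carlo
calibrated against simulated iid-normal null grids of the same (I, J, p);
asymptotic and unit-permutation p-values are also available.

## Worked example

```python
from rivst import (
    SyntheticConfig, generate_community, spatial_vs_seasonal_test,
    distance_matrix, anosim, bioenv, alpha_diversity,
)

config = SyntheticConfig(
    n_taxa=300, n_sites=3,
    spatial_groups={1: "riverine", 2: "riverine", 3: "estuarial"},
    seed=7,
)
table, design, env, tree = generate_community(config)

res = spatial_vs_seasonal_test(table, design, seed=1)
print(f"T = {res.T:.2f}, p = {res.p_value:.4f} ({res.method}, "
      f"n = {res.n} samples, p = {res.p} taxa)")

d = distance_matrix(table, "unweighted_unifrac", tree=tree)
groups = {s.sample_id: s.spatial_group for s in design}
an = anosim(d, groups, seed=1)
print(f"ANOSIM R = {an.R:.3f}, p = {an.p_value:.4f} ({an.method})")

be = bioenv(d, env, max_subset_size=3)
print(f"BIOENV best subset: {'+'.join(be.best_subset)} (r = {be.best_r:.3f})")

depth = int(table.sample_sums().min())
div = alpha_diversity(table, depth=depth, seed=1)
print(f"Shannon at depth {depth}: "
      f"{min(r.shannon for r in div):.2f}-{max(r.shannon for r in div):.2f}")
```

Output:

```
T = -5.16, p = 0.0020 (montecarlo, n = 12 samples, p = 278 taxa)
ANOSIM R = 0.869, p = 0.0020 (exact)
BIOENV best subset: temperature+salinity+NO3_N (r = 0.671)
Shannon at depth 7880: 1.84-3.26
```

Reading it: the survey was generated with spatial log-abundance shifts twice
the seasonal ones, and the test agrees — T is far below zero and the
Monte-Carlo p-value is the smallest achievable at 999 simulations, so
spatial variation dominates. ANOSIM confirms riverine and estuarial samples
separate almost perfectly (R near 1; exact p over all 495 labelings).
BIOENV picks temperature and salinity among the covariates whose distances
best rank-match the UniFrac distances, and per-sample Shannon diversity at
a common rarefaction depth spans the range typical of river
bacterioplankton.

The same pipeline is scriptable from the shell:

```sh
rivst simulate --seed 1 --n-taxa 300 --n-sites 3 --out survey/
rivst distance --table survey/otu_table.tsv --metric unweighted_unifrac \
      --tree survey/tree.nwk --out dist.tsv
rivst sptest --table survey/otu_table.tsv --design survey/design.tsv \
      --env survey/env.tsv --method montecarlo --seed 1 --out sptest.json
rivst mwa --bands survey/bands.csv --out mwa.tsv
```

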