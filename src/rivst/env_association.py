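"""Linking community structure to the environment.

BIOENV searches all subsets of environmental variables for the one whose
inter-sample Euclidean distances best rank-correlate (Spearman) with the
community dissimilarities; ANOSIM tests group separation on ranked
dissimilarities by label permutation; Spearman correlations relate diversity
indices to single covariates; shared-OTU counts partition taxa across
habitat groups (Venn regions).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix
from .io import EnvTable, OtuTable, ValidationError
from .ordination import log_transform

logger = logging.getLogger("rivst")

__all__ = [
    "BioenvResult",
    "AnosimResult",
    "bioenv",
    "anosim",
    "spearman_diversity_env",
    "shared_otu_counts",
    "group_relative_abundance",
]


@dataclass
class BioenvResult:
    """All evaluated variable subsets ranked by Spearman r (descending)."""

    ranking: list[tuple[tuple[str, ...], float]]
    transform: str
    metric: str

    @property
    def best_subset(self) -> tuple[str, ...]:
        return self.ranking[0][0]

    @property
    def best_r(self) -> float:
        return self.ranking[0][1]


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_perm: int
    method: str  # 'exact' or 'sampled'
    grouping: dict[str, str]


def bioenv(
    community_d: DistanceMatrix,
    env: EnvTable,
    max_subset_size: int | None = None,
    log_skip: tuple[str, ...] = ("temperature",),
) -> BioenvResult:
    """Rank every non-empty environmental-variable subset by the Spearman
    correlation between its Euclidean inter-sample distances and the
    community dissimilarities.

    Variables are log-transformed (except those in ``log_skip``; log of a
    temperature in deg C is physically odd, so temperature passes through
    unchanged by default) and then z-scored.  Samples with missing values
    are dropped from both matrices.  Ties in r are broken toward smaller
    subsets, then lexicographically, so the ranking is deterministic.
    """
    frame = env.frame.loc[[i for i in community_d.ids if i in env.frame.index]]
    missing_rows = [i for i in community_d.ids if i not in env.frame.index]
    if missing_rows:
        raise ValidationError(f"env table missing samples: {missing_rows}")
    complete = frame.dropna()
    if len(complete) < 4:
        raise ValidationError("bioenv needs >= 4 complete samples")
    if len(complete) < len(frame):
        dropped = sorted(set(frame.index) - set(complete.index))
        logger.info("bioenv: dropping samples with missing env values: %s", dropped)
    keep_idx = [community_d.ids.index(i) for i in complete.index]
    D = community_d.values[np.ix_(keep_idx, keep_idx)]
    iu = np.triu_indices(len(keep_idx), k=1)
    comm_vec = D[iu]

    transformed = log_transform(complete, skip=log_skip)
    z = (transformed - transformed.mean()) / transformed.std(ddof=1)
    variables = list(z.columns)
    if max_subset_size is None:
        max_subset_size = len(variables)
    max_subset_size = min(max_subset_size, len(variables))
    if max_subset_size < 1:
        raise ValidationError("max_subset_size must be >= 1")

    ranking = []
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(variables, size):
            sub = z.loc[:, list(subset)].to_numpy()
            diff = sub[:, None, :] - sub[None, :, :]
            env_vec = np.sqrt((diff * diff).sum(axis=2))[iu]
            r = stats.spearmanr(comm_vec, env_vec).statistic
            ranking.append((subset, float(r)))
    ranking.sort(key=lambda t: (-t[1], len(t[0]), t[0]))
    return BioenvResult(
        ranking=ranking,
        transform=f"log (skip {','.join(log_skip) or 'none'}) + z-score",
        metric="euclidean/spearman",
    )


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = rank_matrix.shape[0]
    within = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    ranks = rank_matrix[iu]
    w = within[iu]
    m = n * (n - 1) / 2
    return float((ranks[~w].mean() - ranks[w].mean()) / (m / 2.0))


def anosim(
    community_d: DistanceMatrix,
    groups: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: R = (mean between-group rank - mean
    within-group rank) / (M/2) with M = n(n-1)/2 pairwise distances ranked
    with average ranks for ties.

    p is the upper-tail permutation probability of R.  All distinct label
    arrangements are enumerated exactly when there are at most ``n_perm`` of
    them; otherwise ``n_perm`` random permutations with the +1 correction.
    """
    ids = community_d.ids
    missing = [i for i in ids if i not in groups]
    if missing:
        raise ValidationError(f"samples without group labels: {missing}")
    labels = np.array([groups[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("anosim needs >= 2 groups")
    if (counts < 2).any():
        raise ValidationError(
            f"every group needs >= 2 samples; too small: "
            f"{list(uniq[counts < 2])}"
        )
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    rank_matrix = np.zeros((n, n))
    rank_matrix[iu] = stats.rankdata(community_d.values[iu])
    rank_matrix = rank_matrix + rank_matrix.T
    r_obs = _anosim_r(rank_matrix, labels)

    from ._perm import distinct_arrangements, n_distinct_arrangements

    n_distinct = n_distinct_arrangements(labels)
    if n_distinct <= n_perm:
        null = np.array(
            [
                _anosim_r(rank_matrix, np.array(perm))
                for perm in distinct_arrangements(labels)
            ]
        )
        p = float((null >= r_obs - 1e-12).sum() / len(null))
        method = "exact"
        n_used = len(null)
    else:
        rng = np.random.default_rng(seed)
        null = np.array(
            [_anosim_r(rank_matrix, rng.permutation(labels)) for _ in range(n_perm)]
        )
        p = float((1 + (null >= r_obs - 1e-12).sum()) / (1 + n_perm))
        method = "sampled"
        n_used = n_perm
    return AnosimResult(
        R=r_obs, p_value=p, n_perm=n_used, method=method,
        grouping=dict(zip(ids, labels)),
    )


def spearman_diversity_env(values, env_var) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) between a per-sample diversity
    index and one covariate, with the two-sided t-approximation p-value.
    Pairs with a missing member are dropped."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(env_var, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValidationError("need >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined: all values tied")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def shared_otu_counts(
    table: OtuTable, groups: dict[str, str]
) -> dict[tuple[str, ...], int]:
    """Venn-region counts of OTU membership across habitat groups.

    An OTU belongs to a group if it has count >= 1 in any sample of that
    group; the returned dict maps each sorted tuple of group labels (a Venn
    region) to the number of OTUs present in exactly those groups.  Counts
    over all regions sum to the number of OTUs present in >= 1 sample.
    """
    missing = [s for s in table.sample_ids if s not in groups]
    if missing:
        raise ValidationError(f"samples without group labels: {missing}")
    labels = np.array([groups[s] for s in table.sample_ids])
    uniq = sorted({str(g) for g in labels})
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    present = {
        g: (table.counts[:, labels == g] >= 1).any(axis=1) for g in uniq
    }
    regions: dict[tuple[str, ...], int] = {}
    for size in range(1, len(uniq) + 1):
        for combo in itertools.combinations(uniq, size):
            in_these = np.logical_and.reduce([present[g] for g in combo])
            out_others = np.logical_and.reduce(
                [~present[g] for g in uniq if g not in combo]
            ) if len(combo) < len(uniq) else np.ones(table.n_taxa, bool)
            regions[combo] = int((in_these & out_others).sum())
    return regions


def group_relative_abundance(
    table: OtuTable,
    groups: dict[str, str],
    taxonomy: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean relative abundance per group, optionally aggregated by an
    externally supplied taxonomy mapping (OTU id -> taxon name); OTUs absent
    from the mapping are pooled under 'unclassified'."""
    labels = np.array([groups[s] for s in table.sample_ids])
    rel = table.relative_abundance()
    df = pd.DataFrame(rel, index=table.taxon_ids, columns=table.sample_ids)
    if taxonomy is not None:
        df.index = [taxonomy.get(t, "unclassified") for t in table.taxon_ids]
        df = df.groupby(level=0).sum()
    out = {}
    for g in sorted(set(labels)):
        out[g] = df.loc[:, labels == g].mean(axis=1)
    return pd.DataFrame(out)
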