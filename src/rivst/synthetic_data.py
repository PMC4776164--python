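"""Synthetic OTU tables, designs, environmental tables, trees and DGGE lanes.

The generator emulates the sampling design of a one-year, nine-site survey of
an exorheic river running from an urban reach through agricultural land into
an estuary: 4 seasons x 9 sites, ~9206 +/- 957 reads per sample, a salinity
gradient separating riverine from estuarial sites, and a seasonal temperature
cycle.  Community structure follows the additive per-taxon model

    x_ij(k) = base_k + spatial_effect * L_{g(j)}(k) + seasonal_effect * S_i(k) + eps

on the latent log-relative-abundance scale, with ``L`` and ``S`` drawn once
per taxon per group/season from a standard normal, softmax-normalised per
sample and converted to reads by a multinomial draw at a truncated-normal
depth.  All draws come from a single seeded generator, so identical configs
yield bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .io import BandPattern, EnvTable, OtuTable, SampleDesign, ENV_VARIABLES

import pandas as pd

__all__ = ["SyntheticConfig", "generate_community", "generate_band_patterns",
           "random_tree"]


def _default_spatial_groups() -> dict[int, str]:
    # sites 1-2 urban, 3-7 rural (both riverine reaches), 8-9 estuarial
    groups = {}
    for site in range(1, 10):
        groups[site] = "urban" if site <= 2 else ("rural" if site <= 7 else "estuarial")
    return groups


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic river survey.

    ``spatial_effect`` and ``seasonal_effect`` scale per-taxon log-abundance
    shifts between spatial groups and seasons; 0 disables the corresponding
    structure.  Depth defaults reproduce the 9206 +/- 957 reads-per-sample
    scale of the pyrosequencing survey the generator emulates.
    """

    n_taxa: int = 500
    n_seasons: int = 4
    n_sites: int = 9
    spatial_groups: dict[int, str] = field(default_factory=_default_spatial_groups)
    spatial_effect: float = 2.0
    seasonal_effect: float = 1.0
    depth_mean: float = 9206.0
    depth_sd: float = 957.0
    base_log_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.spatial_effect < 0 or self.seasonal_effect < 0:
            raise ValueError("effects must be non-negative")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        missing = [j for j in range(1, self.n_sites + 1) if j not in self.spatial_groups]
        if missing:
            raise ValueError(f"spatial_groups missing sites: {missing}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_depths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Truncated-normal (>= 1) read depths, rounded to integers."""
    depths = np.round(rng.normal(mean, sd, size=n))
    return np.maximum(depths, 1).astype(np.int64)


def random_tree(taxon_ids: list[str], rng: np.random.Generator,
                branch_scale: float = 0.1) -> TreeNode:
    """Random rooted binary tree over ``taxon_ids`` with exponential branch
    lengths, built by successive random joins (a simple coalescent-style
    topology)."""
    nodes = [TreeNode(name=t, length=float(rng.exponential(branch_scale)))
             for t in taxon_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(branch_scale)),
                          children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# Per-season temperature cycle (deg C): autumn, winter, spring, summer.
# Site means ~19.4-20.7 with across-season sd ~8, as in a temperate river.
_SEASON_TEMP = np.array([20.5, 8.5, 19.5, 29.5])
# (mean, sd) of lognormal-ish covariates by spatial group; magnitudes follow
# the urban/rural/estuarial contrasts of the survey (nutrients elevated in
# rural reaches, salinity and chl a elevated in the estuary, TOC in the city).
_ENV_GROUP_MEANS = {
    #            TN    NO3   TP    DTP   TOC   chla   TSS   salinity
    "urban":     (5.1,  2.27, 0.41, 0.28, 27.5, 54.0,  3.2,  1.9),
    "rural":     (6.0,  2.04, 1.25, 0.42, 20.0, 65.0, 18.0,  2.1),
    "estuarial": (6.0,  1.85, 0.93, 0.40, 24.2, 95.0, 12.7, 11.3),
}
_ENV_GROUP_CV = 0.35  # within-group coefficient of variation
_SALINITY_SD = {"urban": 0.6, "rural": 0.6, "estuarial": 4.5}


def _riverine_like(group: str) -> bool:
    return group != "estuarial"


def generate_community(
    config: SyntheticConfig,
) -> tuple[OtuTable, list[SampleDesign], EnvTable, TreeNode]:
    """Generate one full synthetic survey: OTU table, design, env table, tree."""
    rng = config.rng()
    I, J, p = config.n_seasons, config.n_sites, config.n_taxa
    taxon_ids = [f"OTU{k + 1:04d}" for k in range(p)]

    groups = [config.spatial_groups[j] for j in range(1, J + 1)]
    group_labels = sorted(set(groups))
    base = rng.normal(0.0, config.base_log_sd, size=p)
    spatial_shift = {g: rng.standard_normal(p) for g in group_labels}
    seasonal_shift = rng.standard_normal((I, p))

    design: list[SampleDesign] = []
    sample_ids: list[str] = []
    depths = _draw_depths(rng, I * J, config.depth_mean, config.depth_sd)
    counts = np.zeros((p, I * J), dtype=np.int64)
    col = 0
    for i in range(1, I + 1):
        for j in range(1, J + 1):
            g = config.spatial_groups[j]
            sid = f"S{j}_T{i}"
            sample_ids.append(sid)
            design.append(
                SampleDesign(sample_id=sid, season=i, site=j, spatial_group=g)
            )
            latent = (
                base
                + config.spatial_effect * spatial_shift[g]
                + config.seasonal_effect * seasonal_shift[i - 1]
                + rng.standard_normal(p)
            )
            latent -= latent.max()  # softmax stability
            prob = np.exp(latent)
            prob /= prob.sum()
            counts[:, col] = rng.multinomial(depths[col], prob)
            col += 1

    table = OtuTable(taxon_ids=taxon_ids, sample_ids=sample_ids, counts=counts)

    env_rows = []
    for d in design:
        g = d.spatial_group
        tn, no3, tp, dtp, toc, chla, tss, sal = _ENV_GROUP_MEANS.get(
            g, _ENV_GROUP_MEANS["rural"]
        )
        temp = _SEASON_TEMP[(d.season - 1) % len(_SEASON_TEMP)] + rng.normal(0, 0.6)
        row = {
            "temperature": temp,
            "salinity": max(rng.normal(sal, _SALINITY_SD.get(g, 0.6)), 0.05),
            "TN": max(rng.normal(tn, tn * _ENV_GROUP_CV), 0.01),
            "NO3_N": max(rng.normal(no3, no3 * _ENV_GROUP_CV), 0.01),
            "TP": max(rng.normal(tp, tp * _ENV_GROUP_CV), 0.01),
            "DTP": max(rng.normal(dtp, dtp * _ENV_GROUP_CV), 0.01),
            "TOC": max(rng.normal(toc, toc * _ENV_GROUP_CV), 0.01),
            "chl_a": max(rng.normal(chla, chla * _ENV_GROUP_CV), 0.01),
            "TSS": max(rng.normal(tss, tss * _ENV_GROUP_CV), 0.01),
        }
        env_rows.append(row)
    env = EnvTable(
        pd.DataFrame(env_rows, index=[d.sample_id for d in design])[
            list(ENV_VARIABLES)
        ]
    )

    tree = random_tree(taxon_ids, rng)
    return table, design, env, tree


def generate_band_patterns(
    config: SyntheticConfig,
    n_bands_range: tuple[int, int] = (12, 28),
    share_fraction: float = 0.7,
) -> list[BandPattern]:
    """One DGGE lane per site.

    Lanes within a spatial group draw ``share_fraction`` of their bands from a
    shared group-specific pool of gel positions, so fingerprints change
    sharply at group boundaries; band heights are log-normal.  The default
    band-count range (12, 28) matches fingerprints of river bacterioplankton.
    """
    lo, hi = n_bands_range
    if not (1 <= lo <= hi):
        raise ValueError("n_bands_range must satisfy max >= min >= 1")
    if not 0.0 <= share_fraction <= 1.0:
        raise ValueError("share_fraction must lie in [0, 1]")
    rng = config.rng()
    groups = [config.spatial_groups[j] for j in range(1, config.n_sites + 1)]
    # per group: one band count and one shared set of gel positions drawn from
    # a group-specific disjoint grid, so the shared part is identical across
    # lanes of the group and disjoint between groups
    group_labels = sorted(set(groups))
    pool_size = max(hi * 2, 40)
    grid = (np.arange(pool_size * len(group_labels)) + 0.5) / (
        pool_size * len(group_labels)
    )
    group_n_bands: dict[str, int] = {}
    group_shared: dict[str, np.ndarray] = {}
    for gi, g in enumerate(group_labels):
        pool = grid[gi :: len(group_labels)]
        n_bands = int(rng.integers(lo, hi + 1))
        n_shared = int(round(share_fraction * n_bands))
        group_n_bands[g] = n_bands
        group_shared[g] = np.sort(rng.choice(pool, size=n_shared, replace=False))
    patterns = []
    for j, g in enumerate(groups, start=1):
        n_bands = group_n_bands[g]
        positions = group_shared[g]
        # lane-private bands at continuous positions (a.s. unique)
        while len(positions) < n_bands:
            extra = rng.uniform(0, 1, size=n_bands - len(positions))
            positions = np.unique(np.concatenate([positions, extra]))
        heights = rng.lognormal(mean=3.0, sigma=0.6, size=len(positions))
        patterns.append(
            BandPattern(lane_id=f"S{j}", positions=np.sort(positions), heights=heights)
        )
    return patterns
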