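"""Readers and writers for the tabular and tree formats used across the package.

Canonical table dialect is TSV (tab-separated, UTF-8, '.' decimal separator);
trees are newick; DGGE band patterns are CSV with columns
``lane_id,position,height``.  Missing environmental values are encoded as an
empty cell or ``NA`` and are propagated as missing, never imputed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("rivst")

__all__ = [
    "OtuTable",
    "SampleDesign",
    "EnvTable",
    "BandPattern",
    "FormatError",
    "ValidationError",
    "ENV_VARIABLES",
    "read_otu_table",
    "write_otu_table",
    "read_newick",
    "write_newick",
    "read_design_and_env",
    "write_design",
    "write_env",
    "read_band_patterns",
    "write_band_patterns",
]

#: Environmental covariates carried by :class:`EnvTable`, with units.
#: temperature °C, salinity ‰, TN/NO3_N/TP/DTP/TOC/TSS mg/L, chl_a µg/L.
ENV_VARIABLES = (
    "temperature",
    "salinity",
    "TN",
    "NO3_N",
    "TP",
    "DTP",
    "TOC",
    "chl_a",
    "TSS",
)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


@dataclass
class OtuTable:
    """Taxa x samples table of non-negative integer read counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_taxa, n_samples), integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            t, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} ids")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.sample_sums().astype(float)
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts / totals

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SampleDesign:
    """Design row: which season and site a sample comes from.

    ``season`` and ``site`` are 1-based indices (the i and j of the sampling
    grid); ``spatial_group`` is a label such as ``riverine``/``estuarial`` and
    must be a function of ``site`` only.
    """

    sample_id: str
    season: int
    site: int
    spatial_group: str


@dataclass
class EnvTable:
    """Per-sample environmental covariates (see :data:`ENV_VARIABLES`).

    Backed by a DataFrame indexed by sample id; NaN marks a missing value.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in ENV_VARIABLES if c not in self.frame.columns]
        if missing_cols:
            raise ValidationError(f"env table missing variables: {missing_cols}")
        self.frame = self.frame.loc[:, list(ENV_VARIABLES)].astype(float)
        nonneg = [c for c in ENV_VARIABLES if c != "temperature"]
        bad = (self.frame[nonneg] < 0).any()
        if bad.any():
            raise ValidationError(
                f"negative values in non-negative variables: {list(bad[bad].index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()


@dataclass
class BandPattern:
    """One DGGE lane: band positions (relative migration in [0,1]) and heights."""

    lane_id: str
    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape or self.positions.ndim != 1:
            raise ValidationError("positions and heights must be equal-length vectors")
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValidationError(
                f"band positions must be strictly increasing in lane {self.lane_id!r}"
            )
        if (self.heights < 0).any():
            raise ValidationError(f"negative band height in lane {self.lane_id!r}")

    @property
    def n_bands(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# OTU tables


def read_otu_table(path: str | Path) -> OtuTable:
    """Read a taxa x samples TSV with a header row of sample ids.

    Row and column order are preserved.  Non-integer or negative cells raise
    :class:`FormatError` naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = [str(c) for c in df.columns]
    taxon_ids = [str(i) for i in df.index]
    counts = np.empty(df.shape, dtype=np.int64)
    for jj, col in enumerate(df.columns):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = df.index[int(np.argmax(parsed.isna().to_numpy()))]
            raise FormatError(
                f"non-numeric cell at row {row!r}, column {col!r} in {path}"
            )
        vals = parsed.to_numpy()
        if np.any(vals != np.floor(vals)):
            row = df.index[int(np.argmax(vals != np.floor(vals)))]
            raise FormatError(
                f"non-integer cell at row {row!r}, column {col!r} in {path}"
            )
        if np.any(vals < 0):
            row = df.index[int(np.argmax(vals < 0))]
            raise ValidationError(
                f"negative cell at row {row!r}, column {col!r} in {path}"
            )
        counts[:, jj] = vals.astype(np.int64)
    return OtuTable(taxon_ids=taxon_ids, sample_ids=sample_ids, counts=counts)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# Trees


def read_newick(source: str | Path) -> TreeNode:
    """Parse a rooted newick tree (string or file path).

    Missing branch lengths default to 0 with a warning; malformed newick
    raises :class:`FormatError`.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).is_file()
    ):
        text = Path(source).read_text().strip()
    else:
        text = str(source).strip()
    try:
        tree = TreeNode.read([text])
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"malformed newick: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError("negative branch length")
    if n_missing:
        warnings.warn(
            f"{n_missing} branch length(s) missing; defaulted to 0", stacklevel=2
        )
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValidationError("duplicate leaf labels")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Design and environment


def read_design_and_env(
    path_design: str | Path, path_env: str | Path
) -> tuple[list[SampleDesign], EnvTable]:
    """Read design and environmental TSVs and join them on sample_id.

    Samples present in only one file are reported with a warning; env rows
    absent from the env file are added as all-missing so downstream code sees
    a consistent sample set.
    """
    ddf = pd.read_csv(path_design, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "season", "site", "spatial_group"):
        if col not in ddf.columns:
            raise FormatError(f"design file missing column {col!r}")
    design = [
        SampleDesign(
            sample_id=str(r.sample_id),
            season=int(r.season),
            site=int(r.site),
            spatial_group=str(r.spatial_group),
        )
        for r in ddf.itertuples()
    ]
    validate_design(design)

    edf = pd.read_csv(
        path_env, sep="\t", dtype={"sample_id": str}, na_values=["NA", ""]
    )
    if "sample_id" not in edf.columns:
        raise FormatError("env file missing column 'sample_id'")
    edf = edf.set_index("sample_id")

    design_ids = [d.sample_id for d in design]
    only_design = sorted(set(design_ids) - set(edf.index))
    only_env = sorted(set(edf.index) - set(design_ids))
    if only_design:
        warnings.warn(
            f"samples missing from env file (flagged all-missing): {only_design}",
            stacklevel=2,
        )
        edf = edf.reindex(list(edf.index) + only_design)
    if only_env:
        warnings.warn(f"samples present only in env file: {only_env}", stacklevel=2)
    env = EnvTable(edf.reindex(design_ids))
    return design, env


def validate_design(design: Sequence[SampleDesign]) -> None:
    """Check design invariants: unique (season, site) cells; spatial_group a
    function of site."""
    seen: dict[tuple[int, int], str] = {}
    site_group: dict[int, str] = {}
    for d in design:
        cell = (d.season, d.site)
        if cell in seen:
            raise ValidationError(f"duplicate (season, site) cell {cell}")
        seen[cell] = d.sample_id
        if d.site in site_group and site_group[d.site] != d.spatial_group:
            raise ValidationError(
                f"site {d.site} assigned to both {site_group[d.site]!r} "
                f"and {d.spatial_group!r}"
            )
        site_group[d.site] = d.spatial_group


def write_design(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "season": [d.season for d in design],
            "site": [d.site for d in design],
            "spatial_group": [d.spatial_group for d in design],
        }
    ).to_csv(path, sep="\t", index=False)


def write_env(env: EnvTable, path: str | Path) -> None:
    env.frame.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# DGGE band patterns


def read_band_patterns(path: str | Path) -> list[BandPattern]:
    """Read band patterns from CSV with columns lane_id,position,height.

    Lanes appear in order of first occurrence; bands are sorted by position
    within each lane.
    """
    df = pd.read_csv(path, dtype={"lane_id": str})
    for col in ("lane_id", "position", "height"):
        if col not in df.columns:
            raise FormatError(f"band pattern file missing column {col!r}")
    patterns = []
    for lane_id in df["lane_id"].unique():
        sub = df[df["lane_id"] == lane_id].sort_values("position")
        patterns.append(
            BandPattern(
                lane_id=str(lane_id),
                positions=sub["position"].to_numpy(float),
                heights=sub["height"].to_numpy(float),
            )
        )
    return patterns


def write_band_patterns(patterns: Iterable[BandPattern], path: str | Path) -> None:
    rows = [
        (p.lane_id, pos, h)
        for p in patterns
        for pos, h in zip(p.positions, p.heights)
    ]
    pd.DataFrame(rows, columns=["lane_id", "position", "height"]).to_csv(
        path, index=False
    )
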