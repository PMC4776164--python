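"""Pairwise community dissimilarities: Dice, Bray-Curtis, unweighted UniFrac.

Unweighted UniFrac is the fraction of tree branch length leading exclusively
to taxa of one of the two communities; it ignores abundance (counts are
converted to presence at count >= 1).  The tree is used rooted as given — no
midpoint re-rooting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skbio import TreeNode

from .io import BandPattern, OtuTable, ValidationError

logger = logging.getLogger("rivst")

__all__ = [
    "DistanceMatrix",
    "dice_similarity",
    "bray_curtis",
    "unweighted_unifrac",
    "distance_matrix",
]

METRICS = ("dice", "bray_curtis", "unweighted_unifrac")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, None)

    def condensed(self) -> np.ndarray:
        """Lower-triangle values in scipy's condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.ids)


def dice_similarity(a: Iterable, b: Iterable) -> float:
    """Dice coefficient 2|a n b| / (|a| + |b|); two empty sets count as
    identical (similarity 1), which avoids NaN in all-absent gel windows."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        logger.info("Dice of two empty sets: defined as 1")
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum min(x_i, y_i) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def unweighted_unifrac(tree: TreeNode, a: Iterable[str], b: Iterable[str]) -> float:
    """Unweighted UniFrac distance between two presence sets of tree leaves.

    unique branch length (subtends exactly one community) divided by total
    branch length subtending either community.  A branch subtends a community
    if any of its descendant leaves is present in it.
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValidationError("both communities must be non-empty")
    tip_names = {t.name for t in tree.tips()}
    for s in (sa, sb):
        missing = s - tip_names
        if missing:
            raise ValidationError(
                f"taxa not found in tree: {sorted(missing)}"
            )
    unique = 0.0
    total = 0.0
    # postorder accumulation of which communities each branch subtends
    reach: dict[int, tuple[bool, bool]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            in_a, in_b = node.name in sa, node.name in sb
        else:
            in_a = any(reach[id(c)][0] for c in node.children)
            in_b = any(reach[id(c)][1] for c in node.children)
        reach[id(node)] = (in_a, in_b)
        if node.is_root() or node.length is None:
            continue
        if in_a or in_b:
            total += node.length
            if in_a != in_b:
                unique += node.length
    if total == 0:
        return 0.0
    return unique / total


def _presence_sets(table: OtuTable) -> list[set]:
    return [
        {table.taxon_ids[k] for k in np.flatnonzero(table.counts[:, j] >= 1)}
        for j in range(table.n_samples)
    ]


def distance_matrix(
    data: OtuTable | Sequence[BandPattern],
    metric: str,
    tree: TreeNode | None = None,
    position_tolerance: float = 0.01,
) -> DistanceMatrix:
    """All-pairs dissimilarity matrix.

    ``metric`` is one of ``dice`` (returned as 1 - similarity),
    ``bray_curtis`` or ``unweighted_unifrac`` (requires ``tree``).  ``data``
    is an OTU table, or a list of band patterns for ``dice`` (bands matched
    across lanes within ``position_tolerance`` first).
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if isinstance(data, OtuTable):
        ids = list(data.sample_ids)
        if metric == "unweighted_unifrac":
            if tree is None:
                raise ValidationError("unweighted_unifrac requires a tree")
            sets = _presence_sets(data)
            f = lambda i, j: unweighted_unifrac(tree, sets[i], sets[j])
        elif metric == "dice":
            sets = _presence_sets(data)
            f = lambda i, j: 1.0 - dice_similarity(sets[i], sets[j])
        else:
            f = lambda i, j: bray_curtis(data.counts[:, i], data.counts[:, j])
    else:
        if metric != "dice":
            raise ValidationError("band patterns support only the dice metric")
        from .fingerprint import match_bands

        presence = match_bands(list(data), position_tolerance)
        ids = list(presence.columns)
        sets = [set(presence.index[presence[c]]) for c in presence.columns]
        f = lambda i, j: 1.0 - dice_similarity(sets[i], sets[j])
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = f(i, j)
    return DistanceMatrix(ids=ids, values=vals)
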