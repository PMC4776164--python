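"""DGGE densitometric fingerprint analysis.

Band matching across gel lanes, moving-window analysis (MWA) of adjacent-site
similarity along the river, and the peak-height Shannon index.  Similarities
are Dice coefficients on matched band presence, reported in percent as is
conventional for MWA curves; dips in the curve mark community transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diversity
from .distances import dice_similarity
from .io import BandPattern, ValidationError

__all__ = ["MwaSeries", "match_bands", "moving_window", "lane_shannon"]


@dataclass
class MwaSeries:
    """Adjacent-pair similarity series, e.g. labels ['S1-S2', 'S2-S3', ...]."""

    pair_labels: list[str]
    similarity: np.ndarray  # percent, in [0, 100]

    def turning_points(self) -> list[str]:
        """Labels of strict local minima of the similarity curve (both curve
        ends excluded)."""
        s = self.similarity
        return [
            self.pair_labels[i]
            for i in range(1, len(s) - 1)
            if s[i] < s[i - 1] and s[i] < s[i + 1]
        ]


def match_bands(
    patterns: list[BandPattern], position_tolerance: float = 0.01
) -> pd.DataFrame:
    """Merge bands across lanes into reference bands; return presence matrix.

    Bands whose gel positions chain within ``position_tolerance`` are merged
    by single linkage along the position axis (sort all bands, cut where the
    gap between consecutive positions exceeds the tolerance).  The result is
    a boolean DataFrame indexed by reference-band label (mean position),
    columns in lane order.
    """
    if position_tolerance <= 0:
        raise ValidationError("position_tolerance must be > 0")
    lane_ids = [p.lane_id for p in patterns]
    if len(set(lane_ids)) != len(lane_ids):
        raise ValidationError("duplicate lane ids")
    records = [
        (pos, lane_idx)
        for lane_idx, p in enumerate(patterns)
        for pos in p.positions
    ]
    if not records:
        return pd.DataFrame(index=pd.Index([], name="band"), columns=lane_ids,
                            dtype=bool)
    records.sort()
    positions = np.array([r[0] for r in records])
    lanes = np.array([r[1] for r in records])
    # single-linkage clusters = runs of consecutive gaps <= tolerance
    cluster = np.zeros(len(positions), dtype=int)
    cluster[1:] = np.cumsum(np.diff(positions) > position_tolerance)
    n_clusters = cluster[-1] + 1
    presence = np.zeros((n_clusters, len(patterns)), dtype=bool)
    labels = []
    for c in range(n_clusters):
        mask = cluster == c
        presence[c, lanes[mask]] = True
        labels.append(f"b{positions[mask].mean():.4f}")
    # mean positions can collide after rounding; disambiguate
    idx = pd.Index(labels, name="band")
    if idx.has_duplicates:
        idx = pd.Index(
            [f"{lab}_{i}" for i, lab in enumerate(labels)], name="band"
        )
    return pd.DataFrame(presence, index=idx, columns=lane_ids)


def moving_window(
    patterns: list[BandPattern], position_tolerance: float = 0.01
) -> MwaSeries:
    """Similarity of each adjacent lane pair, in lane (site) order.

    Bands are matched globally across all lanes first; each adjacent pair is
    then scored as 100 x Dice on the matched presence sets.
    """
    if len(patterns) < 2:
        raise ValidationError("moving-window analysis needs at least 2 lanes")
    presence = match_bands(patterns, position_tolerance)
    sets = [set(presence.index[presence[c]]) for c in presence.columns]
    labels = []
    sims = []
    for i in range(len(patterns) - 1):
        labels.append(f"{patterns[i].lane_id}-{patterns[i + 1].lane_id}")
        sims.append(100.0 * dice_similarity(sets[i], sets[i + 1]))
    return MwaSeries(pair_labels=labels, similarity=np.array(sims))


def lane_shannon(pattern: BandPattern, log_base: float = np.e) -> float:
    """Shannon index of one lane's densitometric curve: n_i are peak heights,
    N their sum."""
    if pattern.n_bands == 0:
        raise ValidationError(f"lane {pattern.lane_id!r} has no bands")
    return diversity.shannon(pattern.heights, log_base=log_base)
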