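"""Alpha diversity: Shannon index, Chao1 richness, rarefaction.

Shannon is computed as H = -sum (n_i/N) log(n_i/N) over positive entries,
the form used for both OTU counts and DGGE densitometric peak heights.  The
log base defaults to e and is recorded in every result so comparisons across
tools are explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OtuTable, ValidationError

__all__ = ["DiversityResult", "shannon", "chao1", "rarefy", "alpha_diversity"]


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    shannon: float
    log_base: float
    chao1: float
    observed_taxa: int
    rarefaction_depth: int | None = None


def shannon(abundances, log_base: float = np.e) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i with p_i = n_i / N.

    Zero entries are skipped; an all-zero vector is undefined.  ``abundances``
    may be counts or any non-negative magnitudes (e.g. peak heights): H is
    invariant to rescaling.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValidationError("Shannon index undefined for an all-zero vector")
    p = x / x.sum()
    return float(-(p * (np.log(p) / np.log(log_base))).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton (F1) and doubleton (F2) counts.

    Classic form: S_obs + F1^2 / (2 F2) when F2 > 0 (S_obs when F1 = 0);
    bias-corrected form: S_obs + F1 (F1 - 1) / (2 (F2 + 1)), finite even when
    F2 = 0, which is why it is the default.
    """
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.all(np.equal(np.mod(x, 1), 0)):
            raise ValidationError("chao1 requires integer counts")
        x = x.astype(np.int64)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 == 0:
        return float(s_obs)
    if f2 == 0:
        # classic estimator degenerates; fall back to the common F2=0 form
        return s_obs + f1 * (f1 - 1) / 2.0
    return s_obs + f1 * f1 / (2.0 * f2)


def rarefy(table: OtuTable, depth: int, seed: int = 0,
           rng: np.random.Generator | None = None) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    A single multivariate-hypergeometric draw per sample (not an average over
    draws); seeded and reproducible.  Raises if any sample has fewer than
    ``depth`` reads, naming the sample.
    """
    depth = int(depth)
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    totals = table.sample_sums()
    if (totals < depth).any():
        bad = table.sample_ids[int(np.argmax(totals < depth))]
        raise ValidationError(
            f"sample {bad!r} has {int(totals[np.argmax(totals < depth)])} reads, "
            f"fewer than rarefaction depth {depth}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        if totals[j] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return OtuTable(
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        counts=out,
    )


def alpha_diversity(table: OtuTable, depth: int | None = None,
                    log_base: float = np.e, seed: int = 0,
                    bias_corrected: bool = True) -> list[DiversityResult]:
    """Per-sample Shannon, Chao1 and observed richness, optionally after
    rarefying all samples to a common depth."""
    if depth is not None:
        table = rarefy(table, depth, seed=seed)
    results = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        results.append(
            DiversityResult(
                sample_id=sid,
                shannon=shannon(col, log_base=log_base),
                log_base=float(log_base),
                chao1=chao1(col, bias_corrected=bias_corrected),
                observed_taxa=int((col > 0).sum()),
                rarefaction_depth=depth,
            )
        )
    return results
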