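"""Ordination and clustering: PCoA of community distances, PCA of z-scored
environmental data with Kaiser retention, UPGMA clustering with dendrogram
heights rescaled to Dlink/Dmax x 25.

PCoA is classical scaling: double-centre -D^2/2, eigendecompose, scale
eigenvectors by sqrt(eigenvalue).  Axes with negative eigenvalues (possible
for non-Euclidean dissimilarities) are dropped; their magnitudes are
reported, and the percent-explained denominator is the sum of the positive
eigenvalues only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.linalg

from .distances import DistanceMatrix
from .io import EnvTable, ValidationError

logger = logging.getLogger("rivst")

__all__ = [
    "OrdinationResult",
    "Dendrogram",
    "pcoa",
    "pca_env",
    "hierarchical_cluster",
    "log_transform",
]


@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray        # samples x retained axes
    eigenvalues: np.ndarray        # retained (positive) axes
    percent_explained: np.ndarray  # per retained axis, sums to <= 100
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))
    loadings: pd.DataFrame | None = None   # PCA only: variables x components
    retained: np.ndarray | None = None     # PCA only: Kaiser mask over all axes


@dataclass
class Dendrogram:
    """UPGMA merge tree.  ``linkage`` is a scipy linkage matrix; ``rescaled``
    holds merge heights mapped to Dlink/Dmax x 25, so the deepest merge sits
    at 25."""

    ids: list[str]
    linkage: np.ndarray
    rescaled: np.ndarray

    def cut(self, threshold: float) -> dict[str, int]:
        """Cluster labels from cutting at a rescaled (0-25) height."""
        dmax = self.linkage[:, 2].max()
        t = threshold * dmax / 25.0
        labels = sch.fcluster(self.linkage, t=t, criterion="distance")
        return dict(zip(self.ids, (int(x) for x in labels)))


def pcoa(d: DistanceMatrix, eps: float = 1e-10) -> OrdinationResult:
    """Principal coordinate analysis (classical scaling) of a distance
    matrix."""
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = eps * max(abs(eigvals).max(), 1.0)
    pos = eigvals > tol
    neg = eigvals < -tol
    if neg.any():
        logger.info(
            "PCoA: %d negative eigenvalue(s), largest magnitude %.3g; "
            "axes dropped", int(neg.sum()), float(-eigvals[neg].min())
        )
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    denom = lam.sum()
    percent = 100.0 * lam / denom if denom > 0 else np.zeros_like(lam)
    return OrdinationResult(
        ids=list(d.ids),
        coordinates=coords,
        eigenvalues=lam,
        percent_explained=percent,
        negative_eigenvalues=-eigvals[neg],
    )


def pca_env(env: EnvTable) -> OrdinationResult:
    """PCA of the z-scored environmental table on its correlation matrix.

    Rows with any missing value are excluded (and reported); components with
    eigenvalue > 1 are retained (Kaiser criterion); loadings are eigenvectors
    scaled by sqrt(eigenvalue), with |loading| > 0.70 conventionally read as
    'correlated with' the component.
    """
    frame = env.frame
    complete = frame.dropna()
    n_dropped = len(frame) - len(complete)
    if n_dropped:
        logger.info("pca_env: %d sample(s) with missing values excluded",
                    n_dropped)
    if len(complete) < 3:
        raise ValidationError("pca_env needs >= 3 complete samples")
    sd = complete.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValidationError(
            f"constant variable(s), z-score undefined: {list(constant.index)}"
        )
    z = (complete - complete.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = scipy.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 0, None), eigvecs[:, order]
    # deterministic sign: largest-magnitude loading positive
    for a in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, a]))
        if eigvecs[i, a] < 0:
            eigvecs[:, a] = -eigvecs[:, a]
    k = corr.shape[0]
    retained = eigvals > 1.0
    loadings = pd.DataFrame(
        eigvecs * np.sqrt(eigvals),
        index=list(complete.columns),
        columns=[f"PC{a + 1}" for a in range(k)],
    )
    scores = z.to_numpy() @ eigvecs
    return OrdinationResult(
        ids=list(complete.index),
        coordinates=scores[:, retained],
        eigenvalues=eigvals[retained],
        percent_explained=100.0 * eigvals[retained] / k,
        loadings=loadings,
        retained=retained,
    )


def log_transform(frame: pd.DataFrame, skip: tuple[str, ...] = ()) -> pd.DataFrame:
    """Log-transform columns, replacing zeros by half the smallest positive
    observed value of that column; columns in ``skip`` pass through
    unchanged."""
    out = frame.copy()
    for col in frame.columns:
        if col in skip:
            continue
        x = frame[col].to_numpy(float)
        positive = x[np.isfinite(x) & (x > 0)]
        if positive.size == 0:
            raise ValidationError(f"no positive values to log-transform in {col!r}")
        floor = positive.min() / 2.0
        if np.any(x[np.isfinite(x)] <= 0):
            logger.info("log_transform: zeros in %r shifted by %.3g", col, floor)
        out[col] = np.log(np.where(x <= 0, floor, x))
    return out


def hierarchical_cluster(d: DistanceMatrix) -> Dendrogram:
    """UPGMA (unweighted average linkage between groups) of a distance
    matrix, with heights rescaled to Dlink/Dmax x 25.

    Distance ties are resolved by scipy's deterministic ordering of the
    condensed matrix (earliest pair first).
    """
    Z = sch.linkage(d.condensed(), method="average")
    dmax = Z[:, 2].max()
    rescaled = Z[:, 2] / dmax * 25.0 if dmax > 0 else np.zeros(len(Z))
    return Dendrogram(ids=list(d.ids), linkage=Z, rescaled=rescaled)
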