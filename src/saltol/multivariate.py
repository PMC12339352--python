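"""Standardization, correlation-matrix PCA and Ward clustering.

Applied per (year, treatment) group to the trait matrix, and reused by the
tolerance-score pipeline on the stress/control index matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (mean 0, sample SD 1); mean-imputes missing cells.

    The imputation count is logged so it is visible in provenance.  A
    zero-variance column cannot be scaled and raises, naming the column.
    """
    df = matrix.astype(float).copy()
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.info("standardize: mean-imputing %d missing cells", n_missing)
        df = df.fillna(df.mean())
    sd = df.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        raise ValueError(f"zero-variance column(s): {list(dead)}")
    return (df - df.mean()) / sd


@dataclass
class PcaResult:
    """Correlation-matrix PCA of a standardized accession x trait matrix."""

    eigenvalues: np.ndarray
    proportion: np.ndarray           # PVi, sums to 1
    loadings: pd.DataFrame           # trait x component (eigenvectors)
    scores: pd.DataFrame             # accession x component
    sign_flips: np.ndarray = field(default=None)
    n_retained: int = None

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.proportion)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues,
            "proportion": self.proportion,
            "cumulative": self.cumulative,
        }, index=self.loadings.columns)


def pca(standardized: pd.DataFrame) -> PcaResult:
    """Eigendecomposition of the sample correlation matrix.

    Components are ordered by descending eigenvalue.  Sign convention:
    each component is flipped so its largest-|loading| entry is positive —
    downstream membership scoring is not sign-invariant, so the flip
    pattern is recorded.
    """
    X = standardized.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries; standardize/impute first")
    n = X.shape[0]
    corr = (X.T @ X) / (n - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    flips = np.ones(evecs.shape[1])
    for j in range(evecs.shape[1]):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
            flips[j] = -1.0
    comps = [f"PC{j + 1}" for j in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=standardized.columns, columns=comps)
    scores = pd.DataFrame(X @ evecs, index=standardized.index, columns=comps)
    return PcaResult(
        eigenvalues=evals,
        proportion=evals / evals.sum(),
        loadings=loadings,
        scores=scores,
        sign_flips=flips,
    )


def retain_components(result: PcaResult, rule: str = "cumulative_ge",
                      threshold: float = 0.8) -> int:
    """Smallest component count satisfying a retention rule.

    rule='eigenvalue_gt': all components with eigenvalue > threshold
    (Kaiser criterion at threshold 1).  rule='cumulative_ge': smallest k
    whose cumulative variance proportion reaches threshold.
    rule='fixed': exactly ``int(threshold)`` components.
    """
    if rule == "eigenvalue_gt":
        k = int(np.sum(result.eigenvalues > threshold))
        if k == 0:
            raise ValueError(f"no eigenvalue exceeds {threshold}")
        return k
    if rule == "cumulative_ge":
        cum = result.cumulative
        hit = np.where(cum >= threshold - 1e-12)[0]
        if len(hit) == 0:
            raise ValueError(f"cumulative proportion never reaches {threshold}")
        return int(hit[0]) + 1
    if rule == "fixed":
        k = int(threshold)
        if not 1 <= k <= len(result.eigenvalues):
            raise ValueError(f"fixed rule k={k} outside 1..{len(result.eigenvalues)}")
        return k
    raise ValueError(f"unknown retention rule {rule!r}")


@dataclass
class ClusterAssignment:
    """Ward hierarchical clustering cut at k groups."""

    labels: pd.Series                # accession -> 1..k
    linkage: np.ndarray              # scipy linkage matrix (Ward.D2 heights)
    k: int

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def ward_cluster(standardized: pd.DataFrame, k: int) -> ClusterAssignment:
    """Ward minimum-variance clustering on Euclidean distances (Ward.D2).

    Labels are renumbered 1..k in order of first appearance down the input
    rows, making the assignment deterministic for a given row order.
    """
    n = standardized.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in 1..{n}")
    X = standardized.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel, nxt = {}, 1
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in relabel:
            relabel[lab] = nxt
            nxt += 1
        labels[i] = relabel[lab]
    return ClusterAssignment(
        labels=pd.Series(labels, index=standardized.index, name="cluster"),
        linkage=Z, k=k,
    )
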