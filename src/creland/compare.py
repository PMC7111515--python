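"""Cross-cell-type comparisons of signal and expression matrices.

Correlation matrices (Pearson or Spearman), hierarchical clustering with
1 - r as the distance, PCA with variance-explained fractions, quantile
normalization, expressed-gene counting at TPM thresholds, and the
expressed-genes versus dynamic-cCREs association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


def correlation_matrix(m: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Samples x samples correlation matrix of the columns of ``m``.

    Constant columns yield NaN ("undefined") correlations and are logged;
    the diagonal is forced to exactly 1.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method {method!r}")
    if len(m) < 2:
        raise ValueError("need at least two rows to correlate columns")
    constant = m.columns[m.nunique() <= 1]
    if len(constant):
        log.warning("correlation_matrix: constant columns with undefined correlations: %s",
                    ", ".join(map(str, constant)))
    corr = m.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass
class ClusteringResult:
    """Agglomerative clustering of samples on correlation distance (1 - r)."""

    method: str                  # correlation flavour used upstream
    linkage_method: str
    linkage: np.ndarray          # scipy linkage matrix (merge history)
    labels: list                 # sample names in input order
    leaf_order: np.ndarray       # permutation of range(n_samples)
    cophenetic: np.ndarray       # condensed cophenetic distances

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) for the top-level k-cut."""
        return sch.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.10g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def hierarchical_cluster(corr: pd.DataFrame, linkage: str = "average") -> ClusteringResult:
    """Cluster samples agglomeratively with distance 1 - r."""
    if linkage not in {"average", "complete", "single"}:
        raise ValueError(f"unsupported linkage {linkage!r}")
    values = corr.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = corr.columns[np.isnan(values).any(axis=0)]
        raise ValueError(f"undefined correlation distances for samples: {list(bad)}")
    dist = 1.0 - values
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    Z = sch.linkage(condensed, method=linkage)
    coph = sch.cophenet(Z)
    return ClusteringResult(method="correlation", linkage_method=linkage, linkage=Z,
                            labels=list(corr.columns), leaf_order=sch.leaves_list(Z),
                            cophenetic=coph)


@dataclass
class PcaResult:
    """PCA of samples (columns) after per-column centering."""

    variance_fractions: np.ndarray   # sums to 1 over all components
    scores: pd.DataFrame             # samples x components
    components: np.ndarray           # (n_components, n_units) loadings


def pca_variance(m: pd.DataFrame, scale: bool = False) -> PcaResult:
    """Column-centred SVD of a units x samples matrix.

    Each sample (column) is centred; with ``scale=True`` columns are also
    scaled to unit variance.  Variance fractions are the normalised squared
    singular values and sum to 1 over all components.
    """
    if m.shape[1] < 2:
        raise ValueError("PCA needs at least two samples")
    X = m.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = X / sd
    # samples as observations: SVD of the (samples x units) matrix
    U, S, Vt = np.linalg.svd(X.T, full_matrices=False)
    # deterministic sign: make the largest-|.| loading of each component positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total = (S ** 2).sum()
    fractions = (S ** 2) / total if total > 0 else np.zeros_like(S)
    scores = pd.DataFrame(U * S, index=m.columns,
                          columns=[f"PC{k + 1}" for k in range(len(S))])
    return PcaResult(variance_fractions=fractions, scores=scores, components=Vt)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the cross-column mean of sorted values.

    Ties receive the mean of their target quantiles (average ranks are
    linearly interpolated into the target vector), which makes the operation
    idempotent.
    """
    X = m.to_numpy(dtype=float)
    n = X.shape[0]
    if n == 0:
        return m.copy()
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(n, dtype=float)
    for j in range(X.shape[1]):
        ranks = scipy.stats.rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, target)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def expressed_gene_counts(tpm: pd.DataFrame, thresholds: Sequence[float] = (1.0, 5.0, 10.0)) -> pd.DataFrame:
    """count(t, tau) = number of genes with TPM strictly above tau."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("negative TPM values in expression matrix")
    rows = {}
    for tau in thresholds:
        rows[tau] = (tpm > tau).sum(axis=0)
    out = pd.DataFrame(rows)
    out.columns = [f"tpm_gt_{tau:g}" for tau in thresholds]
    out.index.name = "cell_type"
    return out


@dataclass
class AssociationFit:
    r: float
    slope: float
    intercept: float
    n: int
    excluded: Tuple[str, ...]


def expression_ccre_association(expressed: pd.Series, dynamic: pd.Series,
                                exclude: Optional[Iterable[str]] = None) -> AssociationFit:
    """Pearson r and least-squares line between expressed-gene and dynamic-cCRE counts."""
    common = expressed.index.intersection(dynamic.index)
    exclude = list(exclude or [])
    missing = [e for e in exclude if e not in common]
    if missing:
        warnings.warn(f"excluded samples not present: {missing}", stacklevel=2)
    keep = [c for c in common if c not in exclude]
    if len(keep) < 3:
        raise ValueError("need at least 3 paired samples after exclusions")
    x = dynamic.loc[keep].to_numpy(dtype=float)
    y = expressed.loc[keep].to_numpy(dtype=float)
    fit = scipy.stats.linregress(x, y)
    return AssociationFit(r=float(fit.rvalue), slope=float(fit.slope),
                          intercept=float(fit.intercept), n=len(keep),
                          excluded=tuple(e for e in exclude if e in common))
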