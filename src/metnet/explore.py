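"""Exploratory analysis of score matrices: PCA, silhouette, clustering.

Score tables are feature x sample throughout the package; here samples
are the observations. PCA mean-centers by default but does not scale to
unit variance, since activity scores already share the [0, 1] scale and
scaling would inflate near-constant features. Group separation in the
low-dimensional space is summarized by the mean silhouette coefficient
(Euclidean distance on the leading components). Heatmap ordering uses
agglomerative clustering on rows and columns independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import SchemaError


@dataclass
class PcaResult:
    """PCA of samples in score space.

    ``coordinates`` is sample x component; ``loadings`` is feature x
    component; both follow a deterministic sign convention (the
    largest-magnitude loading of each component is positive).
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class ClusterOrder:
    """Leaf orders and linkage records from hierarchical clustering."""

    row_order: list[int]
    column_order: list[int]
    row_linkage: np.ndarray
    column_linkage: np.ndarray


def pca_scores(
    scores: pd.DataFrame,
    n_components: int = 2,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA with samples as observations and score features as variables."""
    M = scores.to_numpy(dtype=float).T  # samples x features
    n, p = M.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not np.isfinite(M).all():
        raise ValueError("scores contain non-finite values")
    if np.allclose(M, M[0], atol=0) or M.std() == 0:
        raise ValueError("constant score matrix: no variance to decompose")
    k = min(n_components, n, p)
    work = M - M.mean(axis=0) if center else M.copy()
    if scale:
        sd = work.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        work = work / sd
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(work)
    load = pca.components_.T  # features x components
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1
            coords[:, j] *= -1
    comp = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        coordinates=pd.DataFrame(coords, index=scores.columns, columns=comp),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(load, index=scores.index, columns=comp),
    )


def silhouette_of_groups(
    pca: PcaResult,
    metadata: pd.DataFrame,
    group_column: str,
    n_components: int = 2,
) -> float:
    """Mean silhouette of metadata groups in leading-PC space.

    Euclidean distance on the first ``n_components`` coordinates;
    singleton-group samples contribute a silhouette of 0 (the standard
    convention).
    """
    if group_column not in metadata.columns:
        raise SchemaError(f"metadata has no column {group_column!r}")
    labels = [metadata[group_column].get(s) for s in pca.sample_ids]
    if any(lab is None or str(lab).strip() == "" for lab in labels):
        raise SchemaError("sample(s) missing a group label")
    if len(set(labels)) < 2:
        raise ValueError("silhouette requires at least 2 groups")
    k = min(n_components, pca.coordinates.shape[1])
    coords = pca.coordinates.iloc[:, :k].to_numpy()
    return float(silhouette_score(coords, labels, metric="euclidean"))


def hierarchical_order(
    scores: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterOrder:
    """Agglomerative leaf ordering of rows and columns independently."""
    M = scores.to_numpy(dtype=float)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("clustering requires at least 2 rows and 2 columns")
    if not np.isfinite(M).all():
        raise ValueError("scores contain non-finite values")

    def _one(mat: np.ndarray) -> tuple[list[int], np.ndarray]:
        Z = hierarchy.linkage(pdist(mat, metric=metric), method=linkage)
        return [int(i) for i in hierarchy.leaves_list(Z)], Z

    row_order, row_Z = _one(M)
    col_order, col_Z = _one(M.T)
    return ClusterOrder(row_order, col_order, row_Z, col_Z)


def group_ellipses(
    pca: PcaResult, metadata: pd.DataFrame, group_column: str
) -> pd.DataFrame:
    """1-SD covariance ellipse parameters per group in PC1/PC2 space.

    Returns one row per group with the ellipse center, semi-axes
    (sqrt of covariance eigenvalues), and orientation in degrees.
    Rendering is left to the caller.
    """
    if group_column not in metadata.columns:
        raise SchemaError(f"metadata has no column {group_column!r}")
    coords = pca.coordinates.iloc[:, :2]
    labels = pd.Series(
        [metadata[group_column].get(s) for s in coords.index],
        index=coords.index,
    )
    rows = []
    for g, idx in labels.groupby(labels).groups.items():
        pts = coords.loc[idx].to_numpy()
        center = pts.mean(axis=0)
        if len(pts) > 1:
            cov = np.cov(pts.T)
            evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
            semi = np.sqrt(np.maximum(evals, 0.0))
        else:
            angle, semi = 0.0, np.zeros(2)
        rows.append(
            {"group": g, "center_x": center[0], "center_y": center[1],
             "semi_major": semi[0], "semi_minor": semi[1],
             "angle_deg": angle, "n": len(pts)}
        )
    return pd.DataFrame(rows)
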