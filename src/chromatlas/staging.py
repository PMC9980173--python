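"""Structure typing and lifespan staging from scA/B profiles.

Cells are embedded (PCA, then optionally t-SNE/UMAP on the PCs), grouped
into 3D genome structure types by Ward hierarchical clustering, and — for
granule cells — ordered into five structural stages S1..S5 along the
lifespan by ascending mean donor age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .scab import ScABMatrix

__all__ = [
    "EmbeddingResult",
    "TypeAssignment",
    "embed_cells",
    "cluster_structure_types",
    "stage_granule_cells",
    "stage_abundance",
]


@dataclass
class EmbeddingResult:
    """2D coordinates plus the PC scores they were computed from."""

    coords: np.ndarray
    pcs: np.ndarray
    method: str
    explained_variance_ratio: np.ndarray | None = None


def _top_variable_bins(X: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Column indices of the top-``frac`` most variable bins (stable ties)."""
    var = X.var(axis=0)
    n_keep = max(1, int(round(frac * X.shape[1])))
    order = np.lexsort((np.arange(len(var)), -var))
    return np.sort(order[:n_keep])


def embed_cells(
    matrix: ScABMatrix,
    n_pcs: int = 20,
    method: str = "pca",
    seed: int = 0,
    ages: np.ndarray | None = None,
) -> EmbeddingResult:
    """Embed cells in 2D; PCA is always computed first.

    PC signs are deterministic; if ``ages`` is given, PC1 is oriented so the
    oldest cells score positive (the lifespan transformation is the dominant
    scA/B axis, so this pins its direction).
    """
    X = matrix.dense()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells to embed")
    max_pcs = min(X.shape[0], X.shape[1])
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs reduced from {n_pcs} to {max_pcs}")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full")
    pcs = pca.fit_transform(X)
    # deterministic sign convention: largest-magnitude loading positive
    for k in range(pcs.shape[1]):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            pcs[:, k] *= -1
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        oldest = ages >= np.nanmedian(ages)
        if pcs[oldest, 0].mean() < pcs[~oldest, 0].mean():
            pcs[:, 0] *= -1

    if method == "pca":
        coords = pcs[:, :2]
    elif method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (X.shape[0] - 1) / 3.0))
        coords = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(pcs)
    elif method == "umap":
        import umap

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(pcs)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return EmbeddingResult(coords, pcs, method, pca.explained_variance_ratio_)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first occurrence."""
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def cluster_structure_types(
    matrix: ScABMatrix,
    k: int,
    linkage_method: str = "ward",
    top_var_frac: float = 0.5,
) -> np.ndarray:
    """Ward hierarchical clustering of scA/B rows into ``k`` structure types.

    Clustering runs on the top half most-variable bins (variance filtering
    stabilises high-dimensional Ward linkage).  Labels are integers 0..k-1
    in order of first occurrence, so the partition is deterministic and
    invariant to cell order up to relabeling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > matrix.n_cells:
        raise ValueError("k exceeds number of cells")
    if k == 1:
        return np.zeros(matrix.n_cells, dtype=int)
    X = matrix.dense()
    X = X[:, _top_variable_bins(X, top_var_frac)]
    Z = linkage(X, method=linkage_method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _canonical_labels(raw)


def stage_granule_cells(
    matrix: ScABMatrix,
    ages: np.ndarray | None = None,
    k: int = 5,
) -> np.ndarray:
    """Cluster granule cells into ``k`` lifespan-ordered stages S1..Sk.

    Clusters are ordered by ascending mean donor age (ties broken by mean
    PC1); without ages the ordering falls back to mean PC1 with a warning.
    Returns an array of stage labels ("S1".."Sk") per cell.
    """
    labels = cluster_structure_types(matrix, k)
    pcs = embed_cells(matrix, n_pcs=min(5, matrix.n_cells, matrix.n_bins), ages=ages).pcs
    pc1 = pcs[:, 0]
    if ages is None:
        warnings.warn("no ages provided; ordering stages by mean PC1")
        keys = [(pc1[labels == c].mean(), 0.0) for c in range(k)]
    else:
        ages = np.asarray(ages, dtype=float)
        keys = [(ages[labels == c].mean(), pc1[labels == c].mean()) for c in range(k)]
    order = sorted(range(k), key=lambda c: keys[c])
    stage_of_cluster = {c: f"S{rank + 1}" for rank, c in enumerate(order)}
    return np.array([stage_of_cluster[c] for c in labels])


@dataclass
class TypeAssignment:
    """Per-cell structure type, optional stage, and 2D embedding coords."""

    cell_ids: list
    type_labels: np.ndarray
    stage_labels: np.ndarray | None = None
    coords: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "type": self.type_labels})
        if self.stage_labels is not None:
            df["stage"] = self.stage_labels
        if self.coords is not None:
            df["x"] = self.coords[:, 0]
            df["y"] = self.coords[:, 1]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AbundanceResult:
    """Stage-composition curves over age with per-stage peak ages."""

    curves: pd.DataFrame  # index: age grid; columns: stages; values: fractions
    peaks: dict  # stage -> age of maximum abundance (NaN if stage empty)


def stage_abundance(
    stage_labels: np.ndarray,
    ages: np.ndarray,
    age_grid: np.ndarray | None = None,
) -> AbundanceResult:
    """Fraction of cells in each stage at each age point, plus peak ages.

    With no explicit grid the distinct observed ages are used; with a grid,
    cells are pooled to the nearest grid point.  At every age point with at
    least one cell the stage fractions sum to 1.
    """
    stage_labels = np.asarray(stage_labels)
    ages = np.asarray(ages, dtype=float)
    if len(stage_labels) != len(ages):
        raise ValueError("stage labels and ages differ in length")
    if age_grid is None:
        grid = np.unique(ages)
        assigned = ages
    else:
        grid = np.asarray(sorted(age_grid), dtype=float)
        assigned = grid[np.argmin(np.abs(ages[:, None] - grid[None, :]), axis=1)]

    stages = sorted(np.unique(stage_labels))
    curves = pd.DataFrame(0.0, index=grid, columns=stages)
    for a in grid:
        at = assigned == a
        n = at.sum()
        if n == 0:
            curves.loc[a] = np.nan
            continue
        for s in stages:
            curves.loc[a, s] = (stage_labels[at] == s).sum() / n
    peaks = {}
    for s in stages:
        col = curves[s]
        peaks[s] = float(col.idxmax()) if col.notna().any() and col.max() > 0 else float("nan")
    return AbundanceResult(curves, peaks)
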