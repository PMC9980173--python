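"""Stage-resolved scA/B trajectories: dynamic regions and temporal modes.

Mean scA/B per 1-Mb autosomal region is computed at each structural stage;
the top 20% of regions by between-stage variance are the dynamic regions,
which cluster into two temporal modes (continuous up- or down-regulation
across the lifespan).  Marker-gene region sets are aggregated the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .genome import BinIndex
from .scab import ScABMatrix

__all__ = [
    "StageMeans",
    "GeneRegionSet",
    "stage_mean_scab",
    "select_dynamic_regions",
    "temporal_modes",
    "gene_set_trajectory",
]


@dataclass
class StageMeans:
    """Region x stage matrix of mean scA/B with per-stage cell counts.

    ``means`` is indexed by global bin ordinal with one column per stage in
    lifespan order.
    """

    means: pd.DataFrame
    n_cells: dict

    @property
    def stages(self) -> list:
        return list(self.means.columns)

    @property
    def regions(self) -> np.ndarray:
        return self.means.index.to_numpy()


def stage_mean_scab(matrix: ScABMatrix, stage_labels) -> StageMeans:
    """Mean scA/B of each region at each stage, ignoring missing entries.

    Stages with zero cells are flagged by an absent column.
    """
    stage_labels = np.asarray(stage_labels)
    if len(stage_labels) != matrix.n_cells:
        raise ValueError("one stage label per cell required")
    stages = sorted(np.unique(stage_labels))
    cols, n_cells = {}, {}
    for s in stages:
        rows = matrix.values[stage_labels == s]
        n_cells[s] = rows.shape[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
            cols[s] = np.nanmean(rows, axis=0)
    means = pd.DataFrame(cols, index=matrix.bin_ordinals)
    return StageMeans(means, n_cells)


@dataclass
class DynamicRegions:
    """Variance ranking over regions and the selected top fraction."""

    variance: pd.Series  # indexed by region, NaN when any stage missing
    selected: np.ndarray  # region ordinals, highest variance first


def select_dynamic_regions(stage_means: StageMeans, top_frac: float = 0.20) -> DynamicRegions:
    """Top ``top_frac`` of regions by between-stage (population) variance.

    Stages are weighted equally regardless of cell counts.  Exactly
    ``floor(top_frac * R)`` regions are returned; ties break toward the
    lower region ordinal, and regions unobserved in any stage rank last.
    """
    if stage_means.means.shape[1] < 2:
        raise ValueError("need at least two stages")
    var = stage_means.means.var(axis=1, ddof=0, skipna=False)
    n_select = int(np.floor(top_frac * len(var)))
    sortable = var.fillna(-np.inf).to_numpy()
    order = np.lexsort((np.arange(len(var)), -sortable))
    selected = stage_means.regions[order[:n_select]]
    return DynamicRegions(var, selected)


def temporal_modes(stage_means: StageMeans, regions, k: int = 2) -> pd.Series:
    """Cluster selected region trajectories into temporal modes.

    Average-linkage hierarchical clustering on correlation distance, k=2 by
    default; each cluster is named "up" or "down" by the sign of its mean
    last-minus-first stage difference.  Returns a Series region -> mode.
    """
    traj = stage_means.means.loc[regions]
    if traj.isna().any().any():
        raise ValueError("selected regions must be observed in every stage")
    X = traj.to_numpy()
    if len(X) < k:
        raise ValueError("fewer regions than modes")
    if np.allclose(X.std(axis=1), 0):
        raise ValueError("all trajectories are flat; correlation undefined")
    D = pdist(X, metric="correlation")
    labels = fcluster(linkage(D, method="average"), t=k, criterion="maxclust")
    diffs = X[:, -1] - X[:, 0]
    names = {}
    used = set()
    for c in np.unique(labels):
        base = "up" if diffs[labels == c].mean() > 0 else "down"
        name = base
        i = 2
        while name in used:
            name = f"{base}{i}"
            i += 1
        used.add(name)
        names[c] = name
    return pd.Series([names[c] for c in labels], index=traj.index, name="mode")


@dataclass
class GeneRegionSet:
    """Gene symbols mapped to 1-Mb bins by the gene-body midpoint rule."""

    genes: pd.DataFrame  # columns: gene, chrom, start, end, bin

    @property
    def bins(self) -> np.ndarray:
        return self.genes["bin"].to_numpy()

    @classmethod
    def from_bed(cls, path, bin_index: BinIndex) -> "GeneRegionSet":
        """Read a BED file (chrom, start, end, name) and assign each gene to
        the bin containing its midpoint."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 4:
                    raise ValueError(f"line {lineno}: expected 4 BED columns")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                mid = (start + end) // 2
                rows.append(
                    {
                        "gene": name,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "bin": bin_index.locate(chrom, mid + 1),
                    }
                )
        if not rows:
            raise ValueError("no genes in BED file")
        return cls(pd.DataFrame(rows))


@dataclass
class GeneTrajectory:
    """Aggregated per-stage scA/B over a gene region set."""

    aggregated: pd.Series  # stage -> mean scA/B over gene bins
    per_region: pd.DataFrame  # gene bin x stage
    frac_increasing: float  # fraction of regions with last stage > first


def gene_set_trajectory(stage_means: StageMeans, gene_set) -> GeneTrajectory:
    """Mean scA/B trajectory of the regions harbouring a gene set.

    ``gene_set`` may be a :class:`GeneRegionSet` or an array of bin
    ordinals.  Raises when no gene bin is present in the matrix.
    """
    bins = gene_set.bins if isinstance(gene_set, GeneRegionSet) else np.asarray(gene_set)
    present = np.intersect1d(bins, stage_means.regions)
    if len(present) == 0:
        raise ValueError("no overlap between gene set and scA/B regions")
    per_region = stage_means.means.loc[present]
    aggregated = per_region.mean(axis=0)
    first, last = per_region.columns[0], per_region.columns[-1]
    frac_increasing = float((per_region[last] > per_region[first]).mean())
    return GeneTrajectory(aggregated, per_region, frac_increasing)
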