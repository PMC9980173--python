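"""Single-cell chromatin A/B compartment values (scA/B).

For each 1-Mb bin of a cell, scA/B is the mean reference value (CpG density
by default) of the partner bins of all qualifying contacts touching that
bin: intra-chromosomal contacts at or beyond ``min_distance`` plus all
inter-chromosomal contacts.  Bins in the A compartment preferentially
contact other A bins, which are CpG-rich, so a high scA/B marks a
euchromatic (A-like) local environment in that single cell.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinIndex, BinTrack, CellContacts

__all__ = ["ScABMatrix", "compute_scab", "build_scab_matrix"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_DISTANCE = 1_000_000
DEFAULT_MIN_CONTACTS_PER_BIN = 5
DEFAULT_MIN_CONTACTS_PER_CELL = 5_000


def compute_scab(
    cell: CellContacts,
    reference: BinTrack,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    min_contacts_per_bin: int = DEFAULT_MIN_CONTACTS_PER_BIN,
) -> np.ndarray:
    """Per-bin scA/B vector over the reference's bin grid (NaN = missing).

    Each qualifying contact contributes the reference value of its partner
    bin to both endpoint bins (contacts with both ends in the same bin are
    excluded by the ``exactly one end`` rule).  Bins with fewer than
    ``min_contacts_per_bin`` partners are missing.
    """
    bins = reference.bin_index
    n = bins.n_bins
    intra = cell.is_intra
    dist = cell.pos_b - cell.pos_a
    keep = ~intra | (dist >= min_distance)
    if not keep.any():
        warnings.warn(f"cell {cell.cell_id!r}: no qualifying contacts")
        return np.full(n, np.nan)

    bi = bins.locate(cell.chrom_a[keep], cell.pos_a[keep])
    bj = bins.locate(cell.chrom_b[keep], cell.pos_b[keep])
    same_bin = bi == bj
    bi, bj = bi[~same_bin], bj[~same_bin]

    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    ref = reference.values
    np.add.at(sums, bi, ref[bj])
    np.add.at(sums, bj, ref[bi])
    np.add.at(counts, bi, 1)
    np.add.at(counts, bj, 1)

    with np.errstate(invalid="ignore"):
        scab = sums / counts
    scab[counts < min_contacts_per_bin] = np.nan
    return scab


@dataclass
class ScABMatrix:
    """Cells x autosomal 1-Mb bins matrix of scA/B values.

    ``values`` may contain NaN for unobserved bins; ``bin_ordinals`` maps
    columns back to global bin ordinals of ``bin_index``.  ``normalization``
    is ``"none"`` or ``"per-cell z-score"``.
    """

    bin_index: BinIndex
    bin_ordinals: np.ndarray
    cell_ids: list
    values: np.ndarray
    normalization: str = "none"
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.bin_ordinals)):
            raise ValueError("matrix shape does not match cells x bins")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bin_ordinals)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def dense(self, fill: float = 0.0) -> np.ndarray:
        """Matrix with missing entries imputed (0 is the post-normalization
        mean, so this is the embedding-ready form)."""
        return np.nan_to_num(self.values, nan=fill)

    def to_tsv(self, path, params_path=None) -> None:
        cols = [f"bin{int(b)}" for b in self.bin_ordinals]
        pd.DataFrame(self.values, index=self.cell_ids, columns=cols).to_csv(
            path, sep="\t", index_label="cell_id"
        )
        if params_path is not None:
            with open(params_path, "w") as fh:
                json.dump(
                    {
                        "bin_size": self.bin_index.bin_size,
                        "normalization": self.normalization,
                        "n_cells": self.n_cells,
                        "n_bins": self.n_bins,
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def from_tsv(cls, path, bin_index: BinIndex, normalization: str = "none") -> "ScABMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell_id")
        ordinals = np.array([int(c[3:]) for c in df.columns])
        return cls(bin_index, ordinals, list(df.index), df.to_numpy(), normalization)


def build_scab_matrix(
    cells: list,
    reference: BinTrack,
    min_distance: int = DEFAULT_MIN_DISTANCE,
    min_contacts_per_bin: int = DEFAULT_MIN_CONTACTS_PER_BIN,
    min_contacts: int = DEFAULT_MIN_CONTACTS_PER_CELL,
    normalize: bool = True,
    autosomes_only: bool = True,
) -> ScABMatrix:
    """Assemble the cells x bins scA/B matrix with QC and normalization.

    Cells with fewer than ``min_contacts`` total contacts, or with no
    observed bin, are dropped (logged).  With ``normalize`` each retained
    row is z-scored over its observed bins (mean 0, s.d. 1).  Sex
    chromosomes are excluded by default so sex does not drive clustering.
    """
    bins = reference.bin_index
    col_mask = bins.autosomal_mask if autosomes_only else np.ones(bins.n_bins, bool)
    ordinals = np.flatnonzero(col_mask)

    rows, kept_ids, meta_rows = [], [], []
    for cell in cells:
        if cell.n_contacts < min_contacts:
            logger.info("dropping %s: %d contacts < QC floor", cell.cell_id, cell.n_contacts)
            continue
        scab = compute_scab(cell, reference, min_distance, min_contacts_per_bin)[col_mask]
        if np.isnan(scab).all():
            logger.info("dropping %s: no observed bins", cell.cell_id)
            continue
        rows.append(scab)
        kept_ids.append(cell.cell_id)
        meta_rows.append(dict(cell.meta))
    if not rows:
        raise ValueError("no cells passed QC")

    values = np.vstack(rows)
    normalization = "none"
    if normalize:
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = (values - mean) / sd
        normalization = "per-cell z-score"
    meta = pd.DataFrame(meta_rows, index=kept_ids) if meta_rows else None
    return ScABMatrix(bins, ordinals, kept_ids, values, normalization, meta)
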