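"""Pooled-sample (Pop-C style) demultiplexing.

Cells from a pooled reaction are assigned back to donors three ways:

* sex from the X:A contact-density ratio (~0.5 in males, ~1.0 in females),
* maximum-likelihood donor assignment against known SNP genotypes, with an
  explicit 50/50 two-donor doublet model,
* genotype-free clustering of allele observations with a binomial-mixture EM
  when donor genotypes are unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genome import Assembly, CellContacts

__all__ = [
    "GenotypeSet",
    "AlleleObservations",
    "DemuxResult",
    "xa_ratio",
    "assign_sex",
    "assign_by_genotype",
    "cluster_by_alleles_em",
]


@dataclass
class GenotypeSet:
    """Donor x SNP biallelic genotypes as alt-allele dosages in {0, 1, 2}.

    ``snps`` is a DataFrame with columns ``snp_id, chrom, pos, ref, alt``;
    ``dosages`` is an int array of shape (n_donors, n_snps).
    """

    donor_ids: list
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.donor_ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match donors x snps")
        if not np.isin(self.dosages, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        dup = {
            tuple(row) for row in self.dosages
        }
        if len(dup) < len(self.donor_ids):
            warnings.warn("unidentifiable: some donors share identical genotypes")

    @property
    def n_donors(self) -> int:
        return len(self.donor_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def to_tsv(self, path) -> None:
        df = self.snps.copy()
        for i, d in enumerate(self.donor_ids):
            df[d] = self.dosages[i]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeSet":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
        donors = [c for c in df.columns if c not in meta_cols]
        return cls(donors, df[meta_cols].copy(), df[donors].to_numpy().T)


@dataclass
class AlleleObservations:
    """Per-cell observed allele counts at known SNPs.

    ``ref`` and ``alt`` are (n_cells, n_snps) count arrays.
    """

    cell_ids: list
    snp_ids: list
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.cell_ids), len(self.snp_ids))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise ValueError("count matrices must be cells x snps")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("negative allele counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_tsv(self, path) -> None:
        ci, si = np.nonzero(self.ref + self.alt)
        pd.DataFrame(
            {
                "cell_id": [self.cell_ids[i] for i in ci],
                "snp_id": [self.snp_ids[j] for j in si],
                "ref_count": self.ref[ci, si],
                "alt_count": self.alt[ci, si],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, snp_ids=None) -> "AlleleObservations":
        df = pd.read_csv(path, sep="\t")
        cells = list(dict.fromkeys(df["cell_id"]))
        if snp_ids is None:
            snp_ids = list(dict.fromkeys(df["snp_id"]))
        c_idx = {c: i for i, c in enumerate(cells)}
        s_idx = {s: j for j, s in enumerate(snp_ids)}
        ref = np.zeros((len(cells), len(snp_ids)), dtype=np.int64)
        alt = np.zeros_like(ref)
        for row in df.itertuples(index=False):
            i, j = c_idx[row.cell_id], s_idx[row.snp_id]
            ref[i, j] += row.ref_count
            alt[i, j] += row.alt_count
        return cls(cells, list(snp_ids), ref, alt)


@dataclass
class DemuxResult:
    """Per-cell donor assignment with supporting log-likelihoods."""

    cell_id: str
    status: str  # donor id, "doublet", "ambiguous", or "unknown"
    donor_loglik: dict = field(default_factory=dict)
    best_pair: tuple | None = None
    pair_loglik: float = np.nan
    sex: str | None = None
    xa: float = np.nan

    def as_row(self) -> dict:
        row = {"cell_id": self.cell_id, "status": self.status, "sex": self.sex, "xa": self.xa}
        row.update({f"ll_{d}": v for d, v in self.donor_loglik.items()})
        return row


def xa_ratio(cell: CellContacts, assembly: Assembly | None = None) -> float:
    """Contact-endpoint density on X divided by autosomal endpoint density.

    Each contact contributes two endpoints.  Raises if the cell has no
    autosomal endpoints or the assembly has no sex chromosome.
    """
    assembly = assembly or cell.assembly
    sex_mask = assembly.sex_mask
    if not sex_mask.any():
        raise ValueError("assembly declares no sex chromosome")
    ends = np.concatenate([cell.chrom_a, cell.chrom_b])
    counts = np.bincount(ends, minlength=assembly.n_chroms)
    L = assembly.lengths_array
    auto_ends = counts[~sex_mask].sum()
    if auto_ends == 0:
        raise ValueError("no autosomal contact endpoints")
    auto_density = auto_ends / L[~sex_mask].sum()
    x_density = counts[sex_mask].sum() / L[sex_mask].sum()
    return float(x_density / auto_density)


def assign_sex(ratio: float, boundary: float = 0.75) -> str:
    """Threshold the X:A ratio: below ``boundary`` is male, else female.

    The default boundary is the midpoint of the expected male (0.5) and
    female (1.0) ratios.
    """
    if ratio is None or np.isnan(ratio):
        return "unknown"
    if ratio < 0:
        raise ValueError("X:A ratio must be nonnegative")
    return "male" if ratio < boundary else "female"


def _allele_logliks(ref: np.ndarray, alt: np.ndarray, p_alt: np.ndarray) -> np.ndarray:
    """Log-likelihood of per-read allele observations for each row of p_alt.

    ``p_alt`` has shape (n_models, n_snps); counts have shape (n_snps,).
    Reads are treated as independent draws; binomial coefficients are
    constant across models and omitted.
    """
    p = np.clip(p_alt, 1e-12, 1 - 1e-12)
    return alt @ np.log(p).T + ref @ np.log1p(-p).T


def genotype_alt_prob(dosages: np.ndarray, error_rate: float) -> np.ndarray:
    """Probability a sequenced read shows the alt allele given dosage.

    A read drawn from a donor with alt dosage ``g`` is alt with probability
    ``(g/2)(1 - e) + (1 - g/2)e`` under a symmetric per-read error ``e``.
    """
    f = np.asarray(dosages, dtype=float) / 2.0
    return f * (1 - error_rate) + (1 - f) * error_rate


def assign_by_genotype(
    obs_ref: np.ndarray,
    obs_alt: np.ndarray,
    genotypes: GenotypeSet,
    error_rate: float = 0.01,
    doublet_margin: float = 2.0,
    ambiguous_margin: float = 2.0,
    cell_id: str = "",
) -> DemuxResult:
    """Assign one cell to a donor, a 50/50 doublet, or "ambiguous".

    Per-donor log-likelihoods treat each read as alt with probability
    ``(g/2)(1-e) + (1-g/2)e``.  All unordered donor pairs are scored as exact
    50/50 mixtures; the cell is a doublet when the best pair beats the best
    single donor by more than ``doublet_margin`` log-units, and ambiguous
    when the top two single donors are within ``ambiguous_margin``.
    """
    obs_ref = np.asarray(obs_ref, dtype=np.int64)
    obs_alt = np.asarray(obs_alt, dtype=np.int64)
    observed = (obs_ref + obs_alt) > 0
    informative = observed & (np.ptp(genotypes.dosages, axis=0) > 0)
    if not informative.any():
        return DemuxResult(cell_id, "ambiguous")

    p_single = genotype_alt_prob(genotypes.dosages, error_rate)
    ll_single = _allele_logliks(obs_ref, obs_alt, p_single)
    order = np.argsort(ll_single)[::-1]
    best, second = order[0], (order[1] if len(order) > 1 else order[0])
    donor_ll = {d: float(v) for d, v in zip(genotypes.donor_ids, ll_single)}

    pairs = list(combinations(range(genotypes.n_donors), 2))
    best_pair, ll_best_pair = None, -np.inf
    if pairs:
        mix = np.stack(
            [(genotypes.dosages[i] + genotypes.dosages[j]) / 2.0 for i, j in pairs]
        )
        p_pair = genotype_alt_prob(mix, error_rate)
        ll_pair = _allele_logliks(obs_ref, obs_alt, p_pair)
        k = int(np.argmax(ll_pair))
        best_pair = (genotypes.donor_ids[pairs[k][0]], genotypes.donor_ids[pairs[k][1]])
        ll_best_pair = float(ll_pair[k])

    if best_pair is not None and ll_best_pair - ll_single[best] > doublet_margin:
        status = "doublet"
    elif len(order) > 1 and ll_single[best] - ll_single[second] < ambiguous_margin:
        status = "ambiguous"
    else:
        status = genotypes.donor_ids[best]
    return DemuxResult(cell_id, status, donor_ll, best_pair, ll_best_pair)


def demux_pool(
    obs: AlleleObservations,
    genotypes: GenotypeSet,
    error_rate: float = 0.01,
    doublet_margin: float = 2.0,
) -> pd.DataFrame:
    """Run :func:`assign_by_genotype` on every cell; tabulate the results."""
    rows = []
    for i, cid in enumerate(obs.cell_ids):
        res = assign_by_genotype(
            obs.ref[i], obs.alt[i], genotypes, error_rate, doublet_margin, cell_id=cid
        )
        rows.append(res.as_row())
    return pd.DataFrame(rows)


def cluster_by_alleles_em(
    obs: AlleleObservations,
    K: int,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
):
    """Genotype-free donor clustering with a binomial-mixture EM.

    Each cluster k carries an alt-allele fraction per SNP; cells are soft-
    assigned by the binomial likelihood of their allele counts.  The best of
    ``n_restarts`` random initialisations (by final log-likelihood) is
    returned as ``(labels, alt_fractions, loglik_trace)``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > obs.n_cells:
        raise ValueError("K exceeds number of cells")
    alt = obs.alt.astype(float)
    tot = (obs.ref + obs.alt).astype(float)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        # initialise cluster allele fractions from random cells plus jitter
        seeds = rng.choice(obs.n_cells, size=K, replace=False)
        with np.errstate(invalid="ignore"):
            f = np.where(tot[seeds] > 0, alt[seeds] / np.maximum(tot[seeds], 1), 0.5)
        f = np.clip(f + rng.normal(0, 0.05, size=f.shape), 1e-3, 1 - 1e-3)
        pi = np.full(K, 1.0 / K)
        trace = []
        for _it in range(max_iter):
            log_f = np.log(f)
            log_1mf = np.log1p(-f)
            ll_cells = alt @ log_f.T + (tot - alt) @ log_1mf.T + np.log(pi)
            m = ll_cells.max(axis=1, keepdims=True)
            log_norm = m[:, 0] + np.log(np.exp(ll_cells - m).sum(axis=1))
            trace.append(float(log_norm.sum()))
            resp = np.exp(ll_cells - log_norm[:, None])
            pi = resp.mean(axis=0)
            num = resp.T @ alt
            den = resp.T @ tot
            f = np.clip(num / np.maximum(den, 1e-12), 1e-4, 1 - 1e-4)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                break
        labels = np.argmax(resp, axis=1)
        if best is None or trace[-1] > best[2][-1]:
            best = (labels, f, trace)
    return best
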