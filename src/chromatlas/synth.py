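"""Synthetic single-cell contact data with planted, calibrated structure.

The generator emulates the statistical phenomena the downstream analyses
measure:

* per-cell intra-chromosomal contacts as a two-component distance mixture —
  a short-range power-law component on [10 kb, 10 Mb) and an ultra-long-range
  log-uniform component on [10 Mb, 100 Mb], mixed with weight ``w_long`` so
  the expected fraction of contacts spanning >= 10 Mb equals ``w_long``
  exactly;
* an A/B compartment checkerboard: long-range and inter-chromosomal contact
  endpoints are accepted with higher odds when their bins share compartment;
* lifespan compartment dynamics: a fraction of bins interpolate linearly
  from one compartment to the other as the structural stage advances;
* inter-chromosomal hubs: selected chromosome pairs receive a fixed
  enrichment multiplier relative to the length-product null;
* sex differences: X-chromosome contact density is halved in males;
* pooled-donor SNP allele observations with per-read errors and 50/50
  doublets.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .demux import AlleleObservations, GenotypeSet
from .genome import Assembly, BinIndex, BinTrack, CellContacts, make_bins

__all__ = [
    "StagePreset",
    "SyntheticGenome",
    "PoolDesign",
    "make_synthetic_genome",
    "simulate_cell",
    "simulate_cohort",
    "simulate_pool",
    "preset_library",
    "random_genotypes",
]

SHORT_MIN = 10_000
LONG_MIN = 10_000_000
LONG_MAX = 100_000_000
_REJECT_CAP = 100


@dataclass(frozen=True)
class StagePreset:
    """Generative parameters for one 3D genome structure type.

    Parameters
    ----------
    name : str
        Preset label, recorded as the truth structure type.
    w_long : float
        Probability that an intra-chromosomal contact is drawn from the
        ultra-long-range (>= 10 Mb) component; equals the expected fraction
        of intra contacts spanning >= 10 Mb.
    decay_exponent : float
        Power-law slope of the short-range component, P(s) ~ s**-a on
        [10 kb, 10 Mb).
    checker_strength : float
        Odds multiplier favouring same-compartment bin pairs for long-range
        and inter-chromosomal contacts (>= 1; 1 disables the checkerboard).
    inter_frac : float
        Fraction of contacts that are inter-chromosomal.
    hub : tuple of (chrom, chrom, multiplier)
        Chromosome pairs whose inter-chromosomal contact probability is
        multiplied relative to the length-product null.
    sex : str
        "male" halves X-chromosome contact density; "female" leaves it.
    stage_scalar : float
        Position along the lifespan axis in [0, 1]; dynamic genome bins
        interpolate their compartment value linearly in this scalar.
    signature_seed : int or None
        Cell types differ in *which* regions are A vs B, not only in
        checkerboard strength; a non-None seed deterministically flips the
        compartment sign of ``flip_frac`` of the static autosomal bins,
        giving the type its own scA/B profile.
    flip_frac : float
        Fraction of static autosomal bins flipped by the type signature.
    """

    name: str
    w_long: float
    decay_exponent: float = 1.5
    checker_strength: float = 1.0
    inter_frac: float = 0.0
    hub: tuple = ()
    sex: str = "female"
    stage_scalar: float = 0.0
    signature_seed: int | None = None
    flip_frac: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.w_long <= 1.0:
            raise ValueError("w_long must be in [0, 1]")
        if self.checker_strength < 1.0:
            raise ValueError("checker_strength must be >= 1")
        if not 0.0 <= self.inter_frac < 1.0:
            raise ValueError("inter_frac must be in [0, 1)")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    def with_(self, **kwargs) -> "StagePreset":
        return replace(self, **kwargs)


@dataclass
class SyntheticGenome:
    """A toy assembly with planted compartments, dynamics, and CpG track.

    ``compartment_sign`` is the basal (stage 0) sign per 1-Mb bin; ``up_bins``
    start B-like and become A-like over the lifespan, ``down_bins`` the
    reverse.  ``cpg_track`` is drawn from two Gaussians so that CpG density
    is positively correlated with the A compartment by construction.
    """

    assembly: Assembly
    bin_index: BinIndex
    compartment_sign: np.ndarray
    cpg_track: BinTrack
    up_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    down_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def compartment_values(self, stage_scalar: float = 0.0) -> np.ndarray:
        """Per-bin compartment value in [-1, 1] at a lifespan position.

        Static bins keep their basal sign; dynamic bins interpolate linearly
        between -1 and +1 (up) or +1 and -1 (down).
        """
        t = float(np.clip(stage_scalar, 0.0, 1.0))
        v = self.compartment_sign.astype(float).copy()
        v[self.up_bins] = -1.0 + 2.0 * t
        v[self.down_bins] = 1.0 - 2.0 * t
        return v

    @property
    def dynamic_bins(self) -> np.ndarray:
        return np.sort(np.concatenate([self.up_bins, self.down_bins]))


def make_synthetic_genome(
    n_chroms: int = 5,
    chrom_length: int = 100_000_000,
    block_size: int = 5_000_000,
    seed: int = 0,
    include_x: bool = True,
    bin_size: int = 1_000_000,
    dynamic_frac: float = 0.2,
    cpg_a: float = 0.012,
    cpg_b: float = 0.008,
    cpg_sd: float = 0.001,
) -> SyntheticGenome:
    """Build a toy genome of equal-length chromosomes with alternating
    A/B compartment blocks.

    ``dynamic_frac`` of autosomal bins are marked dynamic (half up-, half
    down-regulating over the lifespan); their CpG density is intermediate
    between the A and B means.
    """
    if block_size % bin_size != 0:
        raise ValueError("block_size must be a multiple of the bin size")
    if block_size > chrom_length:
        raise ValueError("block_size exceeds chromosome length")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chroms)]
    if include_x:
        names.append("chrX")
    assembly = Assembly.from_dict({n: chrom_length for n in names})
    bins = make_bins(assembly, bin_size)
    sign = np.where((bins.bin_starts // block_size) % 2 == 0, 1, -1).astype(np.int8)

    auto = np.flatnonzero(bins.autosomal_mask)
    n_dyn = int(round(dynamic_frac * len(auto)))
    a_bins = auto[sign[auto] > 0]
    b_bins = auto[sign[auto] < 0]
    n_up = min(n_dyn // 2, len(b_bins))
    n_down = min(n_dyn - n_up, len(a_bins))
    up = rng.choice(b_bins, size=n_up, replace=False)
    down = rng.choice(a_bins, size=n_down, replace=False)

    cpg = np.where(
        sign > 0,
        rng.normal(cpg_a, cpg_sd, bins.n_bins),
        rng.normal(cpg_b, cpg_sd, bins.n_bins),
    )
    # bins that switch compartment over life get intermediate CpG density
    mid = 0.5 * (cpg_a + cpg_b)
    dyn = np.concatenate([up, down]).astype(int)
    cpg[dyn] = rng.normal(mid, cpg_sd, len(dyn))
    cpg = np.clip(cpg, 0.0, None)

    return SyntheticGenome(
        assembly,
        bins,
        sign,
        BinTrack(bins, cpg, kind="cpg_density"),
        np.sort(up).astype(int),
        np.sort(down).astype(int),
    )


def compartment_profile(genome: SyntheticGenome, preset: StagePreset) -> np.ndarray:
    """Per-bin compartment value a preset's cells are simulated under.

    The genome's stage-interpolated values, with the preset's type
    signature (if any) applied: a seed-determined subset of static
    autosomal bins has its sign flipped, so distinct cell types carry
    distinct scA/B profiles.
    """
    v = genome.compartment_values(preset.stage_scalar)
    if preset.signature_seed is not None and preset.flip_frac > 0:
        rng = np.random.default_rng(preset.signature_seed)
        static = np.setdiff1d(
            np.flatnonzero(genome.bin_index.autosomal_mask), genome.dynamic_bins
        )
        n_flip = int(round(preset.flip_frac * len(static)))
        flip = rng.choice(static, size=n_flip, replace=False)
        v[flip] = -v[flip]
    return v


def _sample_short_distances(rng, n: int, a: float) -> np.ndarray:
    """Inverse-CDF draws from a truncated power law s**-a on [10 kb, 10 Mb)."""
    u = rng.random(n)
    s0, s1 = float(SHORT_MIN), float(LONG_MIN)
    if abs(a - 1.0) < 1e-9:
        return np.exp(np.log(s0) + u * (np.log(s1) - np.log(s0)))
    e = 1.0 - a
    return (s0**e + u * (s1**e - s0**e)) ** (1.0 / e)


def _accept_prob(v_i: np.ndarray, v_j: np.ndarray, checker: float) -> np.ndarray:
    """Compartment acceptance probability for an endpoint pair.

    Interpolates between 1 (fully same-compartment) and 1/checker (fully
    cross-compartment) via s = (1 + v_i * v_j) / 2, so binary +/-1 bins give
    same:cross acceptance odds of exactly ``checker``.
    """
    s = 0.5 * (1.0 + v_i * v_j)
    return (1.0 / checker) + (1.0 - 1.0 / checker) * s


def _place_short(rng, genome, ci, d) -> tuple[np.ndarray, np.ndarray]:
    """Uniform left endpoints over valid starts (short range: no bias)."""
    L = genome.assembly.lengths_array[ci]
    pa = rng.integers(1, L - d + 1)
    return pa, pa + d


def _draw_long(rng, genome, ci, checker, v) -> tuple[np.ndarray, np.ndarray]:
    """Ultra-long-range contacts: log-uniform distance on [10 Mb, min(100 Mb,
    L)], uniform left endpoint, with acceptance-rejection favouring
    same-compartment endpoint bins by odds ``checker`` (retry cap 100;
    distance and position are redrawn together so the surviving population's
    same:cross odds equal the multiplier)."""
    L = genome.assembly.lengths_array[ci]
    bins = genome.bin_index
    lo = float(LONG_MIN)
    pa = np.empty(len(ci), dtype=np.int64)
    pb = np.empty(len(ci), dtype=np.int64)
    active = np.arange(len(ci))
    for _ in range(_REJECT_CAP):
        if len(active) == 0:
            break
        La = L[active]
        hi = np.minimum(float(LONG_MAX), La.astype(float))
        u = rng.random(len(active))
        d = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))).astype(np.int64)
        d = np.clip(d, LONG_MIN, La - 1)
        cand = rng.integers(1, La - d + 1)
        pa[active] = cand
        pb[active] = cand + d
        if checker <= 1.0:
            break
        bi = bins.locate(ci[active], cand)
        bj = bins.locate(ci[active], cand + d)
        p = _accept_prob(v[bi], v[bj], checker)
        active = active[rng.random(len(active)) >= p]  # rejected rows redrawn
    return pa, pb


def _inter_pair_probs(genome: SyntheticGenome, preset: StagePreset, weights: np.ndarray):
    """Chromosome-pair probabilities for inter contacts.

    The null assigns pair (i, j) probability proportional to w_i * w_j; hub
    pairs are pinned to multiplier x null, and the remaining mass is spread
    over non-hub pairs, so the planted enrichment over the length-product
    expectation equals the multiplier exactly.
    """
    n = genome.assembly.n_chroms
    iu, ju = np.triu_indices(n, k=1)
    base = weights[iu] * weights[ju]
    base = base / base.sum()
    probs = base.copy()
    if preset.hub:
        idx = genome.assembly.index
        hub_mask = np.zeros(len(iu), dtype=bool)
        for ca, cb, mult in preset.hub:
            if ca not in idx or cb not in idx:
                raise ValueError(f"hub chromosome {ca!r}/{cb!r} not in assembly")
            a, b = sorted((idx[ca], idx[cb]))
            k = np.flatnonzero((iu == a) & (ju == b))
            probs[k] = mult * base[k]
            hub_mask[k] = True
        hub_mass = probs[hub_mask].sum()
        if hub_mass >= 1.0:
            raise ValueError("hub multipliers leave no probability for other pairs")
        probs[~hub_mask] *= (1.0 - hub_mass) / base[~hub_mask].sum()
    return iu, ju, probs


def simulate_cell(
    genome: SyntheticGenome,
    preset: StagePreset,
    n_contacts: int,
    seed,
    cell_id: str | None = None,
) -> CellContacts:
    """Simulate one cell's contact set under a structure-type preset.

    Truth labels (structure type, sex, stage scalar) are recorded in
    ``meta``.  ``seed`` may be an int or a numpy SeedSequence/Generator.
    """
    if n_contacts <= 0:
        raise ValueError("n_contacts must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = genome.assembly.lengths_array
    if preset.w_long > 0 and (lengths < LONG_MIN).any():
        raise ValueError("no long-range support: chromosome shorter than 10 Mb")

    weights = lengths.astype(float).copy()
    if preset.sex == "male":
        weights[genome.assembly.sex_mask] *= 0.5
    v = compartment_profile(genome, preset)

    n_inter = rng.binomial(n_contacts, preset.inter_frac) if preset.inter_frac else 0
    n_intra = n_contacts - n_inter

    # ---- intra-chromosomal component ----
    probs = weights / weights.sum()
    ci = rng.choice(genome.assembly.n_chroms, size=n_intra, p=probs).astype(np.int32)
    is_long = rng.random(n_intra) < preset.w_long
    pa = np.empty(n_intra, dtype=np.int64)
    pb = np.empty(n_intra, dtype=np.int64)
    n_short = n_intra - int(is_long.sum())
    if n_short:
        # short-range contacts carry no compartment bias
        sl = ~is_long
        d = _sample_short_distances(rng, n_short, preset.decay_exponent).astype(np.int64)
        pa[sl], pb[sl] = _place_short(rng, genome, ci[sl], d)
    if is_long.any():
        pa[is_long], pb[is_long] = _draw_long(
            rng, genome, ci[is_long], preset.checker_strength, v
        )

    # ---- inter-chromosomal component ----
    if n_inter:
        iu, ju, pair_probs = _inter_pair_probs(genome, preset, weights)
        k = rng.choice(len(iu), size=n_inter, p=pair_probs)
        ca2 = iu[k].astype(np.int32)
        cb2 = ju[k].astype(np.int32)
        pa2 = np.empty(n_inter, dtype=np.int64)
        pb2 = np.empty(n_inter, dtype=np.int64)
        bins = genome.bin_index
        active = np.arange(n_inter)
        for _ in range(_REJECT_CAP):
            if len(active) == 0:
                break
            pa2[active] = rng.integers(1, lengths[ca2[active]] + 1)
            pb2[active] = rng.integers(1, lengths[cb2[active]] + 1)
            if preset.checker_strength <= 1.0:
                break
            bi = bins.locate(ca2[active], pa2[active])
            bj = bins.locate(cb2[active], pb2[active])
            p = _accept_prob(v[bi], v[bj], preset.checker_strength)
            active = active[rng.random(len(active)) >= p]
        chrom_a = np.concatenate([ci, ca2])
        pos_a = np.concatenate([pa, pa2])
        chrom_b = np.concatenate([ci, cb2])
        pos_b = np.concatenate([pb, pb2])
    else:
        chrom_a, pos_a, chrom_b, pos_b = ci, pa, ci, pb

    meta = {
        "structure_type": preset.name,
        "sex": preset.sex,
        "stage_scalar": preset.stage_scalar,
        "w_long": preset.w_long,
    }
    return CellContacts(
        cell_id or preset.name, genome.assembly, chrom_a, pos_a, chrom_b, pos_b, meta
    )


def simulate_cohort(
    genome: SyntheticGenome,
    design: Sequence[tuple],
    n_contacts: int = 50_000,
    seed: int = 0,
) -> list[CellContacts]:
    """Simulate a cohort from a design of ``(preset, n_cells, age)`` rows.

    Each cell gets an independent child seed of the master seed, so the
    cohort is reproducible and insensitive to generation order.
    """
    if not design:
        raise ValueError("empty cohort design")
    n_total = sum(n for _, n, _ in design)
    children = np.random.SeedSequence(seed).spawn(n_total)
    cells = []
    k = 0
    for preset, n_cells, age in design:
        if n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for i in range(n_cells):
            cell = simulate_cell(
                genome,
                preset,
                n_contacts,
                np.random.default_rng(children[k]),
                cell_id=f"{preset.name}_{k:05d}",
            )
            cell.meta["age"] = age
            cells.append(cell)
            k += 1
    return cells


# ---------------------------------------------------------------------------
# Structure-type preset library
# ---------------------------------------------------------------------------

# Endpoint >=10 Mb contact fractions by cell type (per-cell means reported for
# lifespan cohorts): human granule 19% -> 33%, mouse granule 19% -> 34%,
# human forebrain neurons 15% -> 16%, mouse forebrain 11% -> 13%, mouse
# Purkinje 9% -> 10%, microglia 34%, oligodendrocytes 29% (human) / 27%
# (mouse).  Intermediate granule stages S2-S4 are linear interpolations of
# the S1/S5 endpoints; checkerboard strengths grow monotonically with stage.
_GRANULE_CHECKER = (2.0, 3.0, 4.0, 5.0, 6.0)
_GRANULE_HUB_CHROMS = ("chr1", "chr2", "chr3")


def _granule_presets(species: str, w1: float, w5: float) -> dict:
    presets = {}
    for k in range(5):
        t = k / 4.0
        w = w1 + t * (w5 - w1)
        mult = 1.0 + 2.0 * t  # hub enrichment grows 1x -> 3x across stages
        hub = tuple(
            (a, b, mult)
            for i, a in enumerate(_GRANULE_HUB_CHROMS)
            for b in _GRANULE_HUB_CHROMS[i + 1 :]
        )
        presets[f"{species}_granule_S{k + 1}"] = StagePreset(
            name=f"{species}_granule_S{k + 1}",
            w_long=round(w, 4),
            checker_strength=_GRANULE_CHECKER[k],
            inter_frac=0.1,
            hub=hub,
            stage_scalar=t,
        )
    return presets


def preset_library() -> dict:
    """Named structure-type presets with calibrated >=10 Mb fractions."""
    lib = {}
    lib.update(_granule_presets("human", 0.19, 0.33))
    lib.update(_granule_presets("mouse", 0.19, 0.34))
    # (w_long, checker_strength, stage_scalar, type-signature seed)
    others = {
        "human_forebrain_birth": (0.15, 2.0, 0.0, 104),
        "human_forebrain_mature": (0.16, 2.5, 1.0, 104),
        "mouse_forebrain_birth": (0.11, 2.0, 0.0, 105),
        "mouse_forebrain_mature": (0.13, 2.5, 1.0, 105),
        "mouse_purkinje_birth": (0.09, 1.5, 0.0, 106),
        "mouse_purkinje_mature": (0.10, 1.5, 1.0, 106),
        "microglia": (0.34, 6.0, 1.0, 101),
        "human_oligodendrocyte": (0.29, 5.0, 1.0, 102),
        "mouse_oligodendrocyte": (0.27, 5.0, 1.0, 103),
    }
    for name, (w, c, t, sig) in others.items():
        lib[name] = StagePreset(
            name=name,
            w_long=w,
            checker_strength=c,
            inter_frac=0.1,
            stage_scalar=t,
            signature_seed=sig,
        )
    return lib


# ---------------------------------------------------------------------------
# Pooled-donor simulation
# ---------------------------------------------------------------------------


@dataclass
class PoolDesign:
    """A pooled-reaction scenario: donors, doublets, and SNP sampling depth."""

    genotypes: GenotypeSet
    cells_per_donor: int = 50
    doublet_rate: float = 0.0
    allele_error_rate: float = 0.01
    snp_obs_per_cell: float = 200.0

    def __post_init__(self):
        for r in (self.doublet_rate, self.allele_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


def random_genotypes(
    n_donors: int, n_snps: int, seed: int = 0, maf_range: tuple = (0.1, 0.5)
) -> GenotypeSet:
    """Random biallelic genotypes under Hardy-Weinberg at uniform MAFs."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, size=n_snps)
    dosages = rng.binomial(2, maf, size=(n_donors, n_snps)).astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:05d}" for j in range(n_snps)],
            "chrom": "chr1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    donors = [f"donor{i + 1}" for i in range(n_donors)]
    return GenotypeSet(donors, snps, dosages)


def simulate_pool(design: PoolDesign, seed: int = 0):
    """Simulate per-cell SNP allele observations from a pooled reaction.

    Each cell draws a Poisson number of reads spread uniformly over SNPs;
    each read shows the alt allele with probability ``(g/2)`` (mean dosage
    for 50/50 doublets) flipped by the symmetric per-read error rate.

    Returns ``(AlleleObservations, truth)`` where ``truth`` is a DataFrame
    with columns ``cell_id, donor, is_doublet`` (doublets list both donors
    as ``a+b``).
    """
    gts = design.genotypes
    if gts.n_donors < 1:
        raise ValueError("need at least one donor")
    rng = np.random.default_rng(seed)
    n_cells = design.cells_per_donor * gts.n_donors
    donor_of_cell = np.repeat(np.arange(gts.n_donors), design.cells_per_donor)
    is_doublet = rng.random(n_cells) < design.doublet_rate

    cell_ids, truth_rows = [], []
    ref = np.zeros((n_cells, gts.n_snps), dtype=np.int64)
    alt = np.zeros_like(ref)
    eps = design.allele_error_rate
    for i in range(n_cells):
        d1 = donor_of_cell[i]
        if is_doublet[i]:
            d2 = rng.choice([d for d in range(gts.n_donors) if d != d1])
            mean_dosage = (gts.dosages[d1] + gts.dosages[d2]) / 2.0
            truth = f"{gts.donor_ids[d1]}+{gts.donor_ids[d2]}"
        else:
            mean_dosage = gts.dosages[d1].astype(float)
            truth = gts.donor_ids[d1]
        n_reads = rng.poisson(design.snp_obs_per_cell)
        reads_per_snp = rng.multinomial(n_reads, np.full(gts.n_snps, 1.0 / gts.n_snps))
        p_alt = (mean_dosage / 2.0) * (1 - eps) + (1 - mean_dosage / 2.0) * eps
        alt[i] = rng.binomial(reads_per_snp, p_alt)
        ref[i] = reads_per_snp - alt[i]
        cid = f"cell{i:05d}"
        cell_ids.append(cid)
        truth_rows.append({"cell_id": cid, "donor": truth, "is_doublet": bool(is_doublet[i])})

    obs = AlleleObservations(cell_ids, list(gts.snps["snp_id"]), ref, alt)
    return obs, pd.DataFrame(truth_rows)
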