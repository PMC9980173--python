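import numpy as np
import pytest

from chromatlas.genome import Assembly, CellContacts
from chromatlas.profiles import (
    aggregate_map,
    detect_hub,
    distance_histogram,
    fraction_long_range,
    interchrom_enrichment,
    relative_change_map,
)
from chromatlas.synth import StagePreset, simulate_cohort


@pytest.fixture(scope="module")
def wide_assembly():
    return Assembly.from_dict({"chr1": 100_000_000, "chr2": 100_000_000})


def _intra_cell(assembly, distances, cell_id="c", start=1_000):
    n = len(distances)
    ca = np.zeros(n, dtype=int)
    pa = np.full(n, start)
    return CellContacts(cell_id, assembly, ca, pa, ca, pa + np.asarray(distances))


class TestDistanceHistogram:
    def test_one_count_per_decade(self, wide_assembly):
        cell = _intra_cell(wide_assembly, [100_000, 1_000_000, 10_000_000])
        hist = distance_histogram(cell, n_log_bins=3, d_min=10**4.5, d_max=10**7.5)
        assert list(hist.counts) == [1, 1, 1]

    def test_total_conserved_after_qc_floor(self, wide_assembly):
        distances = [5_000, 20_000, 300_000, 40_000_000]  # first is below floor
        hist = distance_histogram(_intra_cell(wide_assembly, distances), n_log_bins=10)
        assert hist.total == 3

    def test_no_intra_contacts_rejected(self, wide_assembly):
        inter = CellContacts("i", wide_assembly, [0], [100], [1], [200])
        with pytest.raises(ValueError, match="no intra"):
            distance_histogram(inter)

    def test_mature_stage_has_more_ultra_long_mass(self, granule_cohort, granule_truth):
        s1 = [c for c, t in zip(granule_cohort, granule_truth) if t.endswith("S1")]
        s5 = [c for c, t in zip(granule_cohort, granule_truth) if t.endswith("S5")]
        h1 = distance_histogram(s1, n_log_bins=20)
        h5 = distance_histogram(s5, n_log_bins=20)
        assert h5.fraction_in(1e7, 1e8) > h1.fraction_in(1e7, 1e8)


class TestFractionLongRange:
    def test_half_of_contacts_beyond_threshold(self, wide_assembly):
        cell = _intra_cell(wide_assembly, [5_000_000, 15_000_000])
        assert fraction_long_range(cell) == 0.5

    def test_boundary_distance_counts_as_long(self, wide_assembly):
        cell = _intra_cell(wide_assembly, [10_000_000])
        assert fraction_long_range(cell) == 1.0

    def test_all_inter_cell_is_missing(self, wide_assembly):
        inter = CellContacts("i", wide_assembly, [0], [100], [1], [200])
        assert np.isnan(fraction_long_range(inter))


class TestAggregateMap:
    def test_single_contact_populates_both_triangles(self, wide_assembly):
        cell = CellContacts("c", wide_assembly, [0], [100], [0], [600_000])
        amap = aggregate_map(cell, wide_assembly, bin_size=250_000)
        M = amap.to_dense()
        assert M.sum() == 2
        assert M[0, 2] == 1 and M[2, 0] == 1
        assert amap.total == 1

    def test_same_bin_contact_counts_once_on_diagonal(self, wide_assembly):
        cell = CellContacts("c", wide_assembly, [0], [100], [0], [200])
        M = aggregate_map(cell, wide_assembly, bin_size=250_000).to_dense()
        assert M.sum() == 1 and M[0, 0] == 1

    def test_cohort_map_is_sum_of_cell_maps(self, wide_assembly):
        rng = np.random.default_rng(0)
        cells = [
            _intra_cell(wide_assembly, rng.integers(10**4, 5 * 10**7, 50), f"c{i}")
            for i in range(3)
        ]
        pooled = aggregate_map(cells, wide_assembly, bin_size=1_000_000).to_dense()
        summed = sum(
            aggregate_map(c, wide_assembly, bin_size=1_000_000).to_dense() for c in cells
        )
        np.testing.assert_array_equal(pooled, summed)

    def test_region_restriction(self, wide_assembly):
        cell = CellContacts(
            "c", wide_assembly, [0, 0], [100, 100], [0, 1], [600_000, 500]
        )
        amap = aggregate_map(
            cell, wide_assembly, bin_size=250_000, region=("chr1", 0, 1_000_000)
        )
        assert amap.to_dense().shape == (4, 4)
        assert amap.total == 1  # the inter contact falls outside the region

    def test_checkerboard_in_mature_stage_map(self, genome, granule_cohort, granule_truth):
        """Same-compartment >=10 Mb pixels outweigh cross-compartment ones."""
        s5 = [c for c, t in zip(granule_cohort, granule_truth) if t.endswith("S5")]
        amap = aggregate_map(s5, genome.assembly, bin_size=1_000_000)
        M = amap.to_dense().astype(float)
        bins = amap.bin_index
        sign = genome.compartment_values(1.0)
        ii, jj = np.triu_indices(bins.n_bins, k=10)
        intra = bins.bin_chrom[ii] == bins.bin_chrom[jj]
        full = np.abs(sign[ii] * sign[jj]) > 0.99  # static-compartment pairs
        same = sign[ii] * sign[jj] > 0.99
        vals = M[ii, jj]
        assert vals[intra & full & same].mean() > vals[intra & full & ~same].mean()


class TestRelativeChange:
    def _norm_map(self, assembly, distances, cell_id="c"):
        cell = _intra_cell(assembly, distances, cell_id)
        return aggregate_map(cell, assembly, bin_size=1_000_000, normalize=True)

    def test_identical_maps_give_zero(self, wide_assembly):
        a = self._norm_map(wide_assembly, [2_000_000, 30_000_000])
        b = self._norm_map(wide_assembly, [2_000_000, 30_000_000])
        assert np.allclose(relative_change_map(a, b), 0.0)

    def test_uniform_depth_difference_normalized_away(self, wide_assembly):
        d = [2_000_000, 30_000_000, 7_000_000]
        shallow = self._norm_map(wide_assembly, d)
        deep = self._norm_map(wide_assembly, d * 2)  # every contact doubled
        assert np.allclose(relative_change_map(deep, shallow), 0.0, atol=1e-9)

    def test_unnormalized_input_rejected(self, wide_assembly):
        raw = aggregate_map(
            _intra_cell(wide_assembly, [2_000_000]), wide_assembly, bin_size=1_000_000
        )
        with pytest.raises(ValueError, match="normalized"):
            relative_change_map(raw, raw)

    def test_compartment_strengthening_positive_in_late_stage(
        self, genome, granule_cohort, granule_truth
    ):
        """S5 vs S1 log2 map is positive on same-compartment >=10 Mb pixels."""
        groups = {}
        for tag in ("S1", "S5"):
            cells = [c for c, t in zip(granule_cohort, granule_truth) if t.endswith(tag)]
            groups[tag] = aggregate_map(
                cells, genome.assembly, bin_size=1_000_000, normalize=True
            )
        ratio = relative_change_map(groups["S5"], groups["S1"])
        bins = groups["S5"].bin_index
        sign = genome.compartment_sign
        ii, jj = np.triu_indices(bins.n_bins, k=10)
        m = (bins.bin_chrom[ii] == bins.bin_chrom[jj]) & (sign[ii] == sign[jj])
        assert np.median(ratio[ii[m], jj[m]]) > 0


class TestInterchromEnrichment:
    def test_uniform_null_is_flat(self, genome):
        null = StagePreset("null", w_long=0.2, checker_strength=1.0, inter_frac=0.5)
        cells = simulate_cohort(genome, [(null, 20, 0.0)], 20_000, seed=3)
        e = interchrom_enrichment(cells, genome.assembly)
        iu, ju = np.triu_indices(len(e.labels), 1)
        se = 1.0 / np.sqrt(e.expected[iu, ju])
        assert np.all(np.abs(e.enrichment[iu, ju] - 1.0) < 3 * se)

    def test_observed_total_conserved(self, genome):
        p = StagePreset("p", w_long=0.2, inter_frac=0.3)
        cells = simulate_cohort(genome, [(p, 5, 0.0)], 5_000, seed=4)
        e = interchrom_enrichment(cells, genome.assembly)
        n_inter = sum(int((~c.is_intra).sum()) for c in cells)
        assert e.total == n_inter
        assert e.observed.sum() == 2 * n_inter  # symmetric storage

    def test_planted_hub_multiplier_recovered(self, genome):
        hub = StagePreset(
            "hub", w_long=0.2, checker_strength=1.0, inter_frac=0.5,
            hub=(("chr1", "chr3", 3.0),),
        )
        cells = simulate_cohort(genome, [(hub, 20, 0.0)], 20_000, seed=5)
        e = interchrom_enrichment(cells, genome.assembly)
        i, j = e.labels.index("chr1"), e.labels.index("chr3")
        se = np.sqrt(e.observed[i, j]) / e.expected[i, j]
        assert abs(e.pair("chr1", "chr3") - 3.0) < 3 * se

    def test_intra_only_cells_rejected(self, wide_assembly):
        cell = _intra_cell(wide_assembly, [2_000_000])
        with pytest.raises(ValueError, match="no inter"):
            interchrom_enrichment(cell, wide_assembly)


class TestHubDetection:
    def _stage_series(self, genome, mults, seed0=30, hub_chroms=("chr1", "chr3", "chr5")):
        stages = []
        for k, mult in enumerate(mults):
            hub = tuple(
                (a, b, mult)
                for i, a in enumerate(hub_chroms)
                for b in hub_chroms[i + 1 :]
            ) if mult != 1.0 else ()
            p = StagePreset(f"S{k}", w_long=0.2, checker_strength=1.0, inter_frac=0.5, hub=hub)
            cells = simulate_cohort(genome, [(p, 10, 0.0)], 20_000, seed=seed0 + k)
            stages.append(interchrom_enrichment(cells, genome.assembly))
        return stages

    def test_no_planted_hub_detected_nowhere(self, genome):
        stages = self._stage_series(genome, [1.0, 1.0, 1.0])
        res = detect_hub(stages, gain_threshold=0.5)
        assert res.hubs == [] and res.strengthening == []

    def test_growing_hub_recovered_as_clique(self, genome):
        stages = self._stage_series(genome, [1.0, 1.5, 2.0, 2.5, 3.0])
        res = detect_hub(stages, gain_threshold=0.5)
        assert frozenset({"chr1", "chr3", "chr5"}) in res.hubs
        strengthening_pairs = {frozenset((a, b)) for a, b, _ in res.strengthening}
        assert strengthening_pairs == {
            frozenset(p) for p in (("chr1", "chr3"), ("chr1", "chr5"), ("chr3", "chr5"))
        }

    def test_decreasing_pair_reported_as_weakening(self, genome):
        stages = self._stage_series(genome, [3.0, 2.0, 1.5], hub_chroms=("chr2", "chr4"))
        res = detect_hub(stages, gain_threshold=0.5)
        assert any({a, b} == {"chr2", "chr4"} for a, b, _ in res.weakening)
        assert res.hubs == []

    def test_single_stage_rejected(self, genome):
        stages = self._stage_series(genome, [1.0])
        with pytest.raises(ValueError, match="two stages"):
            detect_hub(stages)
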