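import numpy as np
import pytest

from chromatlas.profiles import fraction_long_range
from chromatlas.synth import (
    LONG_MIN,
    PoolDesign,
    StagePreset,
    make_synthetic_genome,
    preset_library,
    random_genotypes,
    simulate_cell,
    simulate_cohort,
    simulate_pool,
)


class TestSyntheticGenome:
    def test_block_structure(self):
        g = make_synthetic_genome(
            n_chroms=2, include_x=False, block_size=5_000_000, dynamic_frac=0.0, seed=1
        )
        assert g.bin_index.n_bins == 200
        # signs alternate in 5-bin blocks on every chromosome
        per_chrom = g.compartment_sign.reshape(2, 100)
        expected = np.tile(np.repeat([1, -1], 5), 10)
        assert (per_chrom == expected).all()
        # CpG correlates positively with compartment by construction
        assert np.corrcoef(g.cpg_track.values, g.compartment_sign)[0, 1] > 0.5

    def test_single_compartment_when_block_equals_chrom(self):
        g = make_synthetic_genome(
            n_chroms=1,
            include_x=False,
            chrom_length=10_000_000,
            block_size=10_000_000,
            dynamic_frac=0.0,
        )
        assert (g.compartment_sign == 1).all()

    def test_same_seed_reproduces_genome(self):
        a = make_synthetic_genome(seed=5)
        b = make_synthetic_genome(seed=5)
        np.testing.assert_array_equal(a.compartment_sign, b.compartment_sign)
        np.testing.assert_array_equal(a.cpg_track.values, b.cpg_track.values)
        np.testing.assert_array_equal(a.up_bins, b.up_bins)

    def test_block_larger_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="block_size"):
            make_synthetic_genome(chrom_length=4_000_000, block_size=5_000_000)

    def test_dynamic_bins_interpolate_between_compartments(self):
        g = make_synthetic_genome(seed=0)
        v0, v1 = g.compartment_values(0.0), g.compartment_values(1.0)
        assert (v0[g.up_bins] == -1).all() and (v1[g.up_bins] == 1).all()
        assert (v0[g.down_bins] == 1).all() and (v1[g.down_bins] == -1).all()
        vh = g.compartment_values(0.5)
        assert np.allclose(vh[g.dynamic_bins], 0.0)


class TestSimulateCell:
    def test_degenerate_mixture_all_long(self, genome):
        p = StagePreset("all_long", w_long=1.0)
        cell = simulate_cell(genome, p, 2_000, seed=0)
        d = cell.intra_distances
        assert (d >= LONG_MIN).all() and (d <= 100_000_000).all()

    def test_degenerate_mixture_all_short(self, genome):
        p = StagePreset("all_short", w_long=0.0)
        d = simulate_cell(genome, p, 2_000, seed=0).intra_distances
        assert (d >= 10_000).all() and (d < LONG_MIN).all()

    def test_long_fraction_matches_mixture_weight(self, genome):
        """Binomial oracle: observed >=10 Mb fraction within 3 s.e. of w_long."""
        n = 50_000
        p = StagePreset("w033", w_long=0.33)
        frac = fraction_long_range(simulate_cell(genome, p, n, seed=1))
        se = np.sqrt(0.33 * 0.67 / n)
        assert abs(frac - 0.33) < 3 * se

    def test_male_x_density_half_of_female(self, genome):
        from chromatlas.demux import xa_ratio

        male = StagePreset("m", w_long=0.2, sex="male")
        female = StagePreset("f", w_long=0.2, sex="female")
        rm = np.mean([xa_ratio(simulate_cell(genome, male, 20_000, s)) for s in range(5)])
        rf = np.mean(
            [xa_ratio(simulate_cell(genome, female, 20_000, 50 + s)) for s in range(5)]
        )
        assert rm == pytest.approx(0.5, abs=0.05)
        assert rf == pytest.approx(1.0, abs=0.05)

    def test_short_chromosome_with_long_component_rejected(self):
        g = make_synthetic_genome(
            n_chroms=1, include_x=False, chrom_length=5_000_000, block_size=5_000_000
        )
        with pytest.raises(ValueError, match="no long-range support"):
            simulate_cell(g, StagePreset("p", w_long=0.5), 100, seed=0)

    def test_checkerboard_odds_match_checker_strength(self):
        """Among >=10 Mb contacts, same-compartment pairs outnumber
        cross-compartment pairs by the planted odds multiplier."""
        g = make_synthetic_genome(n_chroms=2, include_x=False, dynamic_frac=0.0, seed=2)
        bins = g.bin_index

        def same_cross(preset, seed):
            cell = simulate_cell(g, preset, 100_000, seed=seed)
            bi = bins.locate(cell.chrom_a, cell.pos_a)
            bj = bins.locate(cell.chrom_b, cell.pos_b)
            same = g.compartment_sign[bi] == g.compartment_sign[bj]
            return same.sum(), (~same).sum()

        c = 3.0
        s1, x1 = same_cross(StagePreset("flat", w_long=1.0, checker_strength=1.0), 3)
        s2, x2 = same_cross(StagePreset("check", w_long=1.0, checker_strength=c), 3)
        odds_ratio = (s2 / x2) / (s1 / x1)
        assert odds_ratio == pytest.approx(c, rel=0.1)


class TestPresetLibrary:
    @pytest.mark.parametrize(
        "name,w",
        [
            ("human_granule_S1", 0.19),
            ("human_granule_S5", 0.33),
            ("mouse_granule_S1", 0.19),
            ("mouse_granule_S5", 0.34),
            ("human_forebrain_birth", 0.15),
            ("human_forebrain_mature", 0.16),
            ("mouse_forebrain_birth", 0.11),
            ("mouse_forebrain_mature", 0.13),
            ("mouse_purkinje_birth", 0.09),
            ("mouse_purkinje_mature", 0.10),
            ("microglia", 0.34),
            ("human_oligodendrocyte", 0.29),
            ("mouse_oligodendrocyte", 0.27),
        ],
    )
    def test_calibrated_long_range_weights(self, lib, name, w):
        assert lib[name].w_long == pytest.approx(w)

    def test_granule_stages_interpolate_monotonically(self, lib):
        for sp in ("human", "mouse"):
            ws = [lib[f"{sp}_granule_S{k}"].w_long for k in range(1, 6)]
            cs = [lib[f"{sp}_granule_S{k}"].checker_strength for k in range(1, 6)]
            assert all(a < b for a, b in zip(ws, ws[1:]))
            assert all(a < b for a, b in zip(cs, cs[1:]))

    def test_all_presets_satisfy_invariants(self, lib):
        for p in lib.values():
            assert 0 <= p.w_long <= 1
            assert p.checker_strength >= 1
            assert 0 <= p.inter_frac < 1


class TestSimulateCohort:
    def test_balanced_truth_labels_and_ages(self, genome, lib):
        design = [(lib[f"human_granule_S{k}"], 4, float(k)) for k in range(1, 6)]
        cells = simulate_cohort(genome, design, 1_000, seed=0)
        assert len(cells) == 20
        types = [c.meta["structure_type"] for c in cells]
        assert all(types.count(f"human_granule_S{k}") == 4 for k in range(1, 6))
        assert len({c.cell_id for c in cells}) == 20

    def test_same_master_seed_reproduces_cohort(self, genome, lib):
        design = [(lib["human_granule_S3"], 3, 10.0)]
        a = simulate_cohort(genome, design, 1_000, seed=9)
        b = simulate_cohort(genome, design, 1_000, seed=9)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.pos_a, cb.pos_a)
            np.testing.assert_array_equal(ca.chrom_b, cb.chrom_b)

    def test_empty_design_rejected(self, genome):
        with pytest.raises(ValueError, match="empty"):
            simulate_cohort(genome, [], 100, seed=0)

    def test_cohort_fractions_ordered_by_mixture_weight(self, genome, lib):
        means = []
        for k in range(1, 6):
            p = lib[f"human_granule_S{k}"].with_(inter_frac=0.0)
            cells = simulate_cohort(genome, [(p, 10, 0.0)], 20_000, seed=k)
            means.append(np.mean([fraction_long_range(c) for c in cells]))
        assert all(a < b for a, b in zip(means, means[1:]))


class TestSimulatePool:
    def test_zero_error_matches_genotype_exactly(self):
        gts = random_genotypes(2, 100, seed=0)
        pool = PoolDesign(gts, cells_per_donor=5, allele_error_rate=0.0)
        obs, truth = simulate_pool(pool, seed=1)
        d_idx = {d: i for i, d in enumerate(gts.donor_ids)}
        for i, row in truth.iterrows():
            g = gts.dosages[d_idx[row.donor]]
            # homozygous-ref sites yield only ref reads, hom-alt only alt
            assert obs.alt[i][g == 0].sum() == 0
            assert obs.ref[i][g == 2].sum() == 0

    def test_doublet_rate_one_labels_every_cell_doublet(self):
        gts = random_genotypes(3, 50, seed=0)
        pool = PoolDesign(gts, cells_per_donor=4, doublet_rate=1.0)
        _, truth = simulate_pool(pool, seed=2)
        assert truth.is_doublet.all()
        assert truth.donor.str.contains("\\+").all()

    def test_error_rate_recovered_at_homozygous_sites(self):
        """Binomial oracle: mismatch rate at homozygous sites ~ error rate."""
        eps = 0.01
        gts = random_genotypes(1, 200, seed=3)
        pool = PoolDesign(
            gts, cells_per_donor=50, allele_error_rate=eps, snp_obs_per_cell=400
        )
        obs, _ = simulate_pool(pool, seed=4)
        g = gts.dosages[0]
        hom_ref, hom_alt = g == 0, g == 2
        mism = obs.alt[:, hom_ref].sum() + obs.ref[:, hom_alt].sum()
        total = (
            obs.alt[:, hom_ref | hom_alt].sum() + obs.ref[:, hom_ref | hom_alt].sum()
        )
        rate = mism / total
        se = np.sqrt(eps * (1 - eps) / total)
        assert abs(rate - eps) < 3 * se

    def test_identical_donor_genotypes_warn(self):
        import pandas as pd

        from chromatlas.demux import GenotypeSet

        snps = pd.DataFrame(
            {"snp_id": ["s1"], "chrom": ["chr1"], "pos": [100], "ref": ["A"], "alt": ["G"]}
        )
        with pytest.warns(UserWarning, match="unidentifiable"):
            GenotypeSet(["d1", "d2"], snps, np.array([[1], [1]]))
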