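"""Synthetic-population generator: Mendelian, spatial and noise contracts."""

import numpy as np
import pytest
from scipy import stats

from clonekit.distances import iam_distance, pairwise_matrix
from clonekit.model import MISSING, GenotypeTable
from clonekit.sim import (
    Lineage,
    SimConfig,
    make_main_plot_preset,
    make_snp_loci,
    make_validation_preset,
    mutate_and_corrupt,
    sample_grid,
    simulate_clonal_spread,
    simulate_depths,
    simulate_founders,
    simulate_offspring,
)


class TestFounders:
    def test_heterozygosity_matches_hardy_weinberg(self, rng):
        gt = simulate_founders(40, 500, maf_range=(0.5, 0.5), rng=rng)
        het = (gt.calls[:, :, 0] != gt.calls[:, :, 1]).mean()
        # E[het] = 2pq = 0.5; binomial CI over 20000 calls
        assert abs(het - 0.5) < 4 * np.sqrt(0.25 / 20000)

    def test_zero_maf_gives_identical_homozygotes(self, rng):
        gt = simulate_founders(5, 20, maf_range=(0.0, 0.0), rng=rng)
        assert np.all(gt.calls == 0)

    def test_same_seed_identical(self):
        a = simulate_founders(4, 30, rng=np.random.default_rng(7))
        b = simulate_founders(4, 30, rng=np.random.default_rng(7))
        assert np.array_equal(a.calls, b.calls)
        assert [l.id for l in a.loci] == [l.id for l in b.loci]

    def test_invalid_maf_rejected(self, rng):
        with pytest.raises(ValueError, match="allele-frequency"):
            simulate_founders(3, 10, maf_range=(0.4, 0.9), rng=rng)


class TestOffspring:
    def test_fixed_cross_gives_all_heterozygotes(self, rng):
        aa = np.zeros((6, 2), dtype=np.int16)
        bb = np.ones((6, 2), dtype=np.int16)
        off = simulate_offspring(aa, bb, 10, "outcross", rng)
        assert np.all(off[:, :, 0] == 0) and np.all(off[:, :, 1] == 1)

    def test_selfed_heterozygote_segregates_1_2_1(self, rng):
        ab = np.array([[0, 1]], dtype=np.int16)
        off = simulate_offspring(ab, None, 600, "self", rng)
        dosage = off[:, 0, :].sum(axis=1)
        counts = np.bincount(dosage, minlength=3)
        p = stats.chisquare(counts, f_exp=[150, 300, 150]).pvalue
        assert p > 1e-3

    def test_offspring_within_one_allele_of_each_parent_per_locus(self, rng):
        pa = np.sort(rng.integers(0, 2, size=(8, 2)).astype(np.int16), axis=1)
        pb = np.sort(rng.integers(0, 2, size=(8, 2)).astype(np.int16), axis=1)
        off = simulate_offspring(pa, pb, 20, "outcross", rng)
        for o in off:
            for parent in (pa, pb):
                per_locus = [
                    iam_distance(o[j : j + 1], parent[j : j + 1]) for j in range(8)
                ]
                assert max(per_locus) <= 1  # always shares one gamete

    def test_mismatched_parents_rejected(self, rng):
        with pytest.raises(ValueError, match="locus set"):
            simulate_offspring(np.zeros((3, 2)), np.zeros((4, 2)), 1, "outcross", rng)


class TestClonalSpread:
    def test_zero_years_founders_only(self, rng):
        lin = simulate_clonal_spread(np.array([[5.0, 5.0]]), SimConfig(years=0), rng)
        assert lin.n_ramets == 1 and lin.parent[0] == -1

    def test_fixed_step_length(self, rng):
        cfg = SimConfig(years=1, daughters_mean=3.0, rhizome_step_mean=0.7,
                        rhizome_step_sd=1e-12)
        lin = simulate_clonal_spread(np.array([[10.0, 10.0]]), cfg, rng)
        daughters = np.flatnonzero(lin.parent == 0)
        assert len(daughters) > 0
        d = np.linalg.norm(lin.xy[daughters] - lin.xy[0], axis=1)
        assert np.allclose(d, 0.7, atol=1e-6)

    def test_default_step_mean_matches_rhizome_length(self, rng):
        cfg = SimConfig(years=3, daughters_mean=1.6)
        lin = simulate_clonal_spread(np.full((40, 2), 10.0), cfg, rng)
        kids = np.flatnonzero(lin.parent >= 0)
        assert len(kids) > 300
        steps = np.linalg.norm(lin.xy[kids] - lin.xy[lin.parent[kids]], axis=1)
        # mean rhizome length 0.451 m (truncation at 0 adds < 0.01)
        assert abs(steps.mean() - 0.451) < 0.02

    def test_pseudo_annual_mothers_die(self, rng):
        cfg = SimConfig(years=2, daughters_mean=2.0)
        lin = simulate_clonal_spread(np.full((5, 2), 10.0), cfg, rng)
        assert not lin.alive[lin.year < 2].any()

    def test_lineage_is_forest_rooted_at_founders(self, rng):
        cfg = SimConfig(years=3, daughters_mean=1.5)
        lin = simulate_clonal_spread(np.full((3, 2), 10.0), cfg, rng)
        assert (lin.parent < np.arange(lin.n_ramets)).all()
        roots = lin.parent == -1
        assert roots.sum() == 3
        assert np.array_equal(lin.genet[roots], np.arange(3))


class TestSampleGrid:
    def test_ramet_on_grid_point_selected(self):
        sel, pts = sample_grid(np.array([[3.0, 4.0]]), 1.0, 0.5, (20.0, 20.0))
        assert list(sel) == [0]
        assert np.array_equal(pts[0], [3.0, 4.0])

    def test_no_ramet_within_radius_unsampled(self):
        # (3.4, 4.4) is 0.57 m from the nearest grid point: no capture
        sel, _ = sample_grid(np.array([[3.4, 4.4]]), 1.0, 0.5, (20.0, 20.0))
        assert len(sel) == 0
        sel2, _ = sample_grid(np.array([[3.4, 4.0]]), 1.0, 0.5, (20.0, 20.0))
        assert len(sel2) == 1

    def test_equidistant_tie_goes_to_lowest_ramet_id(self):
        xy = np.array([[4.7, 5.0], [5.3, 5.0]])
        sel, pts = sample_grid(xy, 1.0, 0.4, (20.0, 20.0))
        assert list(pts[0]) == [5.0, 5.0]
        assert sel[0] == 0

    def test_ramet_selected_at_most_once(self):
        # one ramet equidistant between two grid points
        sel, pts = sample_grid(np.array([[4.5, 5.0]]), 1.0, 0.6, (20.0, 20.0))
        assert len(sel) == 1


def _chain_lineage(n, genet=0):
    return Lineage(
        parent=np.arange(-1, n - 1),
        genet=np.full(n, genet),
        year=np.arange(n),
        xy=np.zeros((n, 2)),
        alive=np.ones(n, dtype=bool),
    )


class TestMutateAndCorrupt:
    def _founders(self, rng, m=30):
        return simulate_founders(1, m, rng=rng)

    def test_zero_rates_identity(self, rng):
        founders = self._founders(rng)
        cfg = SimConfig(somatic_mutation_rate=0, allele_dropout_rate=0,
                        random_error_rate=0, missing_rate=0)
        gt, log = mutate_and_corrupt(founders, _chain_lineage(5), cfg, rng)
        assert np.array_equal(gt.calls, np.repeat(founders.calls, 5, axis=0))
        assert log["somatic_mutations"] == []

    def test_rate_one_mutates_every_locus_on_every_edge(self, rng):
        founders = self._founders(rng, m=12)
        cfg = SimConfig(somatic_mutation_rate=1.0, allele_dropout_rate=0,
                        random_error_rate=0, missing_rate=0)
        gt, log = mutate_and_corrupt(founders, _chain_lineage(3), cfg, rng)
        assert len(log["somatic_mutations"]) == 2 * 12  # 2 edges x 12 loci
        for child, parent in [(1, 0), (2, 1)]:
            per_locus = 2 - (
                np.sort(gt.calls[child], 1) == np.sort(gt.calls[parent], 1)
            ).sum(1)
            assert (per_locus >= 1).all()

    def test_mutations_inherited_clonally(self, rng):
        founders = self._founders(rng, m=200)
        cfg = SimConfig(somatic_mutation_rate=0.01, allele_dropout_rate=0,
                        random_error_rate=0, missing_rate=0)
        gt, log = mutate_and_corrupt(founders, _chain_lineage(4), cfg, rng)
        # a daughter differs from the founder at least as much as its mother
        d = [iam_distance(gt.calls[i], founders.calls[0]) for i in range(4)]
        assert all(d[i + 1] >= 0 for i in range(3))
        assert len(log["somatic_mutations"]) > 0

    def test_missingness_within_binomial_ci(self, rng):
        founders = self._founders(rng, m=400)
        cfg = SimConfig(somatic_mutation_rate=0, allele_dropout_rate=0,
                        random_error_rate=0, missing_rate=0.05)
        gt, log = mutate_and_corrupt(founders, _chain_lineage(50), cfg, rng)
        n_calls = 50 * 400
        frac = (gt.calls[:, :, 0] == MISSING).mean()
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n_calls)

    def test_dropout_only_homozygoses_heterozygotes(self, rng):
        founders = simulate_founders(1, 300, maf_range=(0.5, 0.5), rng=rng)
        cfg = SimConfig(somatic_mutation_rate=0, allele_dropout_rate=0.5,
                        random_error_rate=0, missing_rate=0)
        gt, log = mutate_and_corrupt(founders, _chain_lineage(20), cfg, rng)
        base = np.repeat(founders.calls, 20, axis=0)
        changed = (gt.calls != base).any(axis=2)
        was_het = base[:, :, 0] != base[:, :, 1]
        assert changed.any()
        assert not changed[~was_het].any()
        assert (gt.calls[changed][:, 0] == gt.calls[changed][:, 1]).all()


class TestDepths:
    def test_empirical_mean_within_ci(self, rng):
        d = simulate_depths(200, 200, depth_mean=40.0, depth_dispersion=8.0, rng=rng,
                            locus_bias_sd=0.2)
        se = d.std() / np.sqrt(d.size)  # cells correlated within locus; loose bound
        assert abs(d.mean() - 40.0) < 0.1 * 40.0

    def test_high_mean_low_noise_never_below_ten(self, rng):
        d = simulate_depths(50, 50, depth_mean=500.0, depth_dispersion=200.0, rng=rng,
                            locus_bias_sd=0.01)
        assert (d < 10).mean() == 0

    def test_same_seed_identical(self):
        a = simulate_depths(10, 10, rng=np.random.default_rng(3))
        b = simulate_depths(10, 10, rng=np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_invalid_params_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_depths(5, 5, depth_mean=-1, rng=rng)
        with pytest.raises(ValueError):
            simulate_depths(5, 5, depth_dispersion=0, rng=rng)


class TestValidationPreset:
    def test_truth_genet_count_is_fifteen(self, rng):
        ds, truth = make_validation_preset(rng)
        assert truth.n_genets == 15
        assert ds.genotypes.n_loci == 264

    def test_zero_noise_clones_at_distance_zero(self):
        cfg = SimConfig(n_loci=264, somatic_mutation_rate=0, allele_dropout_rate=0,
                        random_error_rate=0, missing_rate=0)
        ds, truth = make_validation_preset(np.random.default_rng(0), config=cfg)
        dm = pairwise_matrix(ds.genotypes)
        for g in np.unique(truth.true_genet):
            members = np.flatnonzero(truth.true_genet == g)
            assert np.all(dm.values[np.ix_(members, members)] == 0)

    def test_within_genet_below_between_genet_distances(self, rng):
        ds, truth = make_validation_preset(rng)
        dm = pairwise_matrix(ds.genotypes)
        same = truth.true_genet[:, None] == truth.true_genet[None, :]
        iu = np.triu_indices(len(truth.samples), 1)
        within = dm.values[iu][same[iu]]
        between = dm.values[iu][~same[iu]]
        assert within.max() < between.min()
        assert between.min() >= 15  # related genets stay distinguishable

    def test_determinism(self):
        a, ta = make_validation_preset(np.random.default_rng(5))
        b, tb = make_validation_preset(np.random.default_rng(5))
        assert np.array_equal(a.genotypes.calls, b.genotypes.calls)
        assert np.array_equal(a.depths.depths, b.depths.depths)
        assert np.array_equal(ta.true_genet, tb.true_genet)


class TestMainPlotPreset:
    def test_preset_shape_and_truth(self, rng):
        ds, truth = make_main_plot_preset(rng)
        assert ds.genotypes.n_samples == 372
        assert ds.genotypes.n_loci == 363
        assert truth.n_genets == 61

    def test_dominant_genet_holds_about_one_third(self, rng):
        ds, truth = make_main_plot_preset(rng)
        sizes = np.bincount(truth.true_genet)
        share = sizes.max() / len(truth.samples)
        assert abs(share - 1 / 3) < 0.05

    def test_thirty_singleton_genets(self, rng):
        _, truth = make_main_plot_preset(rng)
        sizes = np.bincount(truth.true_genet)
        assert (sizes == 1).sum() == 30

    def test_missing_fraction_below_two_permille(self, rng):
        ds, _ = make_main_plot_preset(rng)
        assert ds.genotypes.missing_fraction_per_sample().mean() < 0.002

    def test_samples_on_grid_points(self, rng):
        ds, _ = make_main_plot_preset(rng)
        assert np.allclose(ds.sheet.xy, np.round(ds.sheet.xy))
        assert ds.sheet.xy.min() >= 0 and ds.sheet.xy.max() <= 20
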