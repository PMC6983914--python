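"""Locus/sample selection rules against brute-force re-evaluation."""

import numpy as np
import pytest

from clonekit.filtering import (
    FilterParams,
    apply_depth_mask,
    filter_loci,
    filter_samples,
    minor_allele_frequencies,
    run_filters,
    select_single_snp_contigs,
)
from clonekit.model import MISSING, Dataset, DepthTable, GenotypeTable, Locus, LocusKind
from clonekit.sim import make_validation_preset

from conftest import random_snp_table, snp_loci


def make_dataset(rng, n=10, m=20, missing_rate=0.05, depth_mean=20):
    gt = random_snp_table(rng, n, m, missing_rate)
    depths = rng.poisson(depth_mean, size=(n, m)).astype(np.int32)
    dt = DepthTable(gt.samples, [l.id for l in gt.loci], depths)
    return Dataset(gt, dt)


def brute_force_locus_pass(ds, params):
    """Independent re-statement of the locus rules."""
    gt, depths = ds.genotypes, ds.depths.depths
    passes = []
    for j, lc in enumerate(gt.loci):
        if lc.kind == LocusKind.SNP and (lc.snp_count_on_contig != 1 or len(lc.alleles) != 2):
            passes.append(False)
            continue
        frac = np.mean(depths[:, j] >= params.min_depth)
        if not frac > params.min_sample_fraction_at_depth:
            passes.append(False)
            continue
        col = gt.calls[:, j, :].ravel()
        col = col[col != MISSING]
        freqs = np.bincount(col) / len(col) if len(col) else np.array([1.0])
        freqs = np.sort(freqs[freqs > 0])[::-1]
        maf = freqs[1] if len(freqs) > 1 else 0.0
        passes.append(maf > params.min_maf)
    return np.flatnonzero(passes)


class TestSingleSnpContigs:
    def test_two_snps_on_one_contig_both_excluded(self):
        loci = [
            Locus("a", LocusKind.SNP, "c1", 1, ("A", "T"), snp_count_on_contig=2),
            Locus("b", LocusKind.SNP, "c1", 9, ("A", "G"), snp_count_on_contig=2),
            Locus("c", LocusKind.SNP, "c2", 1, ("A", "T"), snp_count_on_contig=1),
        ]
        assert list(select_single_snp_contigs(loci)) == [2]

    def test_triallelic_on_own_contig_excluded(self):
        loci = [Locus("a", LocusKind.SNP, "c1", 1, ("A", "T", "G"))]
        assert len(select_single_snp_contigs(loci)) == 0

    def test_random_loci_match_brute_force(self, rng):
        loci = [
            Locus(f"l{j}", LocusKind.SNP, f"c{j}", 1,
                  ("A", "T", "G")[: int(rng.integers(2, 4))],
                  snp_count_on_contig=int(rng.integers(1, 3)))
            for j in range(10)
        ]
        expected = [
            j for j, lc in enumerate(loci)
            if lc.snp_count_on_contig == 1 and len(lc.alleles) == 2
        ]
        assert list(select_single_snp_contigs(loci)) == expected


class TestFilterLoci:
    def test_exactly_ninety_percent_depth_fails_strict(self, rng):
        n, m = 10, 1
        gt = random_snp_table(rng, n, m, missing_rate=0)
        gt.calls[0, 0] = (0, 1)  # guarantee polymorphism
        depths = np.full((n, m), 50, dtype=np.int32)
        depths[0, 0] = 1  # exactly 9/10 = 90 % at depth
        ds = Dataset(gt, DepthTable(gt.samples, ["L0"], depths))
        with pytest.warns(UserWarning, match="no loci survive"):
            keep, report = filter_loci(ds, FilterParams())
        assert len(keep) == 0
        assert report.locus_fail_reason["L0"] == "depth"

    def test_monomorphic_locus_fails_maf(self, rng):
        gt = GenotypeTable(["a", "b"], snp_loci(1), np.zeros((2, 1, 2), dtype=np.int16))
        ds = Dataset(gt, DepthTable(["a", "b"], ["L0"], np.full((2, 1), 50)))
        with pytest.warns(UserWarning, match="no loci survive"):
            keep, report = filter_loci(ds)
        assert len(keep) == 0
        assert report.locus_fail_reason["L0"] == "maf"

    def test_random_toy_matches_brute_force(self, rng):
        import warnings

        for _ in range(10):
            ds = make_dataset(rng, n=12, m=20, depth_mean=12)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # empty survivor sets ok
                keep, _ = filter_loci(ds, FilterParams(min_depth=10))
            assert np.array_equal(keep, brute_force_locus_pass(ds, FilterParams(min_depth=10)))

    def test_order_preserved(self, rng):
        ds = make_dataset(rng, depth_mean=40)
        keep, _ = filter_loci(ds)
        assert np.all(np.diff(keep) > 0)


class TestFilterSamples:
    def test_fully_called_sample_retained(self, rng):
        ds = make_dataset(rng, n=5, m=10, missing_rate=0, depth_mean=50)
        keep, _ = filter_samples(ds, np.arange(10))
        assert len(keep) == 5

    def test_sample_missing_eleven_percent_dropped(self, rng):
        n, m = 4, 100
        gt = random_snp_table(rng, n, m, missing_rate=0)
        gt.calls[0, :11] = MISSING  # 89 % < 90 %
        ds = Dataset(gt, DepthTable(gt.samples, [l.id for l in gt.loci],
                                    np.full((n, m), 50)))
        keep, report = filter_samples(ds, np.arange(m))
        assert 0 not in keep
        assert report.sample_fail_reason["s0"] == "low_coverage"

    def test_exactly_ninety_percent_retained(self, rng):
        n, m = 4, 100
        gt = random_snp_table(rng, n, m, missing_rate=0)
        gt.calls[0, :10] = MISSING  # exactly 90 %
        ds = Dataset(gt, DepthTable(gt.samples, [l.id for l in gt.loci],
                                    np.full((n, m), 50)))
        keep, _ = filter_samples(ds, np.arange(m))
        assert 0 in keep

    def test_random_toy_matches_brute_force(self, rng):
        ds = make_dataset(rng, n=15, m=30, missing_rate=0.12, depth_mean=13)
        sel = np.arange(30)
        keep, _ = filter_samples(ds, sel, FilterParams(min_depth=10))
        ok = (ds.genotypes.calls[:, :, 0] != MISSING) & (ds.depths.depths >= 10)
        expected = np.flatnonzero(ok.mean(axis=1) >= 0.9)
        assert np.array_equal(keep, expected)


class TestDepthMaskAndIdempotence:
    def test_low_depth_calls_become_missing(self, rng):
        ds = make_dataset(rng, missing_rate=0, depth_mean=12)
        masked = apply_depth_mask(ds, 10)
        low = ds.depths.depths < 10
        assert (masked.calls[low] == MISSING).all()
        assert np.array_equal(masked.calls[~low], ds.genotypes.calls[~low])

    def test_filtering_idempotent_when_no_samples_dropped(self):
        # idempotence holds whenever sample filtering removes nobody; after a
        # sample drop the MAF (computed once, over all samples, with no
        # re-estimation pass) could legitimately change
        ds, _ = make_validation_preset(np.random.default_rng(2))
        filtered, _, report1 = run_filters(ds)
        assert report1.n_samples_retained == report1.n_samples_input
        refiltered, _, report2 = run_filters(filtered)
        assert report2.n_loci_maf == report1.n_loci_maf == filtered.genotypes.n_loci
        assert report2.n_samples_retained == filtered.genotypes.n_samples

    def test_each_excluded_locus_has_one_reason(self, rng):
        ds = make_dataset(rng, n=12, m=40, depth_mean=12)
        keep, report = filter_loci(ds)
        kept_ids = {ds.genotypes.loci[j].id for j in keep}
        assert set(report.locus_fail_reason) == (
            {l.id for l in ds.genotypes.loci} - kept_ids
        )


class TestDepthSensitivity:
    def test_locus_counts_monotone_and_rows_match_scripted_run(self):
        from clonekit.assignment import assign_genets, plateau_threshold
        from clonekit.distances import pairwise_matrix
        from clonekit.filtering import depth_sensitivity

        ds, _ = make_validation_preset(np.random.default_rng(11))
        table = depth_sensitivity(ds, depths=(5, 10, 15))
        assert (np.diff(table["n_loci"]) <= 0).all()
        # independently scripted run for one depth
        _, masked, rep = run_filters(ds, FilterParams(min_depth=15))
        dm = pairwise_matrix(masked)
        a = assign_genets(dm, plateau_threshold(dm).threshold)
        row = table[table["min_depth"] == 15].iloc[0]
        assert row["n_loci"] == rep.n_loci_maf
        assert row["n_genets"] == a.n_genets


class TestMaf:
    def test_maf_counts_alleles_not_genotypes(self):
        calls = np.array(
            [[[0, 1]], [[0, 0]], [[0, 0]], [[0, 0]], [[0, 0]]], dtype=np.int16
        )
        gt = GenotypeTable([f"s{i}" for i in range(5)], snp_loci(1), calls)
        assert minor_allele_frequencies(gt)[0] == pytest.approx(1 / 10)
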