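"""Ground-truth generators: determinism, marginals, and injected effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainchrom import synthgen as sg


class TestGenome:
    def test_dimension_bookkeeping(self):
        lay = sg.gen_genome(2, 1_000_000, 100, 0.02, seed=1)
        assert len(lay.chromosomes) == 4  # 2 autosomes + X + Y
        assert len(lay.tss) == 100
        names = [c for c, _ in lay.chromosomes]
        assert "chrX" in names and "chrY" in names

    def test_blacklist_zero_fraction_empty(self):
        lay = sg.gen_genome(2, 1_000_000, 50, 0.0, seed=1)
        assert len(lay.blacklist) == 0

    def test_same_seed_identical(self):
        a = sg.gen_genome(2, 1_000_000, 100, 0.02, seed=7)
        b = sg.gen_genome(2, 1_000_000, 100, 0.02, seed=7)
        pd.testing.assert_frame_equal(a.tss, b.tss)
        pd.testing.assert_frame_equal(a.blacklist, b.blacklist)

    def test_intervals_within_bounds(self):
        lay = sg.gen_genome(3, 500_000, 80, 0.05, seed=3)
        sizes = lay.chrom_sizes()
        for df in (lay.mappable, lay.blacklist):
            for _, r in df.iterrows():
                assert 0 <= r["start"] < r["end"] <= sizes[r["chrom"]]

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            sg.gen_genome(0, 1_000_000, 10)
        with pytest.raises(ValueError):
            sg.gen_genome(2, 1_000_000, 10, blacklist_fraction=0.6)


class TestGenotypes:
    def test_block1_adjacent_snps_independent(self):
        g = sg.gen_genotypes(200, 100, block_size=1, seed=5)
        d = g.dosages
        rs = [abs(np.corrcoef(d[i], d[i + 1])[0, 1]) for i in range(99)]
        # mean |r| for independent SNPs is ~1/sqrt(n); allow 3 SE
        assert np.mean(rs) < 1 / np.sqrt(200) + 3 * 0.05 / np.sqrt(99)

    def test_within_block_ld_exceeds_between(self):
        g = sg.gen_genotypes(200, 500, block_size=10, maf_low=0.05, maf_high=0.5, seed=7)
        d = g.dosages
        within, between = [], []
        for b in range(0, 490, 10):
            within.append(np.corrcoef(d[b], d[b + 5])[0, 1] ** 2)
            between.append(np.corrcoef(d[b], d[b + 15])[0, 1] ** 2)
        assert np.mean(within) > np.mean(between) + 0.2

    def test_symmetric_maf_mean_dosage_one(self):
        g = sg.gen_genotypes(400, 200, block_size=5, maf_low=0.5, maf_high=0.5, seed=9)
        se = np.sqrt(2 * 0.5 * 0.5 / 400)
        assert abs(g.dosages.mean() - 1.0) < 3 * se

    def test_maf_within_band(self):
        g = sg.gen_genotypes(500, 1000, block_size=10, maf_low=0.1, maf_high=0.4, seed=11)
        freq = g.dosages.mean(axis=1) / 2
        maf = np.minimum(freq, 1 - freq)
        assert (maf > 0.1 - 0.05 - 0.04).all() and (maf < 0.4 + 0.05 + 0.04).all()

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            sg.gen_genotypes(10, 5, block_size=10)
        with pytest.raises(ValueError):
            sg.gen_genotypes(10, 50, block_size=5, maf_low=0.6)


class TestCounts:
    def test_poisson_limit(self, layout):
        samples = sg.gen_samples(60, seed=1)
        peaks = sg.gen_peaks(layout, 200, seed=2)
        truth = sg.gen_truth(peaks, pd.DataFrame(columns=["snp", "chrom", "pos"]),
                             samples, frac_dx=0, frac_age=0, frac_pmi=0, frac_cqtl=0,
                             seed=3)
        cm = sg.gen_counts(layout, peaks, None, truth, dispersion=0.0, mean_depth=100,
                           seed=4)
        # remove the library-offset column effect before the dispersion test
        auto = ~peaks["chrom"].isin(["chrX", "chrY"]).to_numpy()
        scaled = cm.counts[auto] / (cm.counts[auto].mean(axis=0, keepdims=True)
                                    / cm.counts[auto].mean())
        n_ok = 0
        for row in scaled:
            disp = (len(row) - 1) * row.var() / row.mean()
            p = stats.chi2.sf(disp, len(row) - 1)
            n_ok += p > 0.01
        assert n_ok / auto.sum() >= 0.95

    def test_diagnosis_fold_change(self, layout):
        samples = sg.gen_samples(100, seed=5)
        peaks = sg.gen_peaks(layout, 50, seed=6)
        truth = sg.gen_truth(peaks, pd.DataFrame(columns=["snp", "chrom", "pos"]),
                             samples, frac_dx=0, frac_cqtl=0, seed=7)
        auto = ~peaks["chrom"].isin(["chrX", "chrY"])
        target = peaks.loc[auto, "name"].iloc[0]
        truth.peak_effects.loc[truth.peak_effects["peak"] == target, "dx_log2fc"] = 2.0
        cm = sg.gen_counts(layout, peaks, None, truth, dispersion=0.05, mean_depth=100,
                           seed=8)
        gi = list(peaks["name"]).index(target)
        case = samples["diagnosis"] == "case"
        ratio = cm.counts[gi, case.to_numpy()].mean() / cm.counts[gi, (~case).to_numpy()].mean()
        assert 3.0 <= ratio <= 5.3

    def test_cqtl_monotone_dosage_means(self, layout):
        samples = sg.gen_samples(1000, seed=9)
        peaks = sg.gen_peaks(layout, 40, seed=10)
        geno = sg.gen_genotypes(1000, 400, 10, maf_low=0.3, maf_high=0.5, seed=11,
                                layout=layout)
        truth = sg.gen_truth(peaks, geno.snp_map, samples, frac_dx=0, frac_cqtl=0.5,
                             cqtl_beta=0.5, seed=12)
        truth.cqtl_map["beta"] = 0.5  # force positive effects
        cm = sg.gen_counts(layout, peaks, geno, truth, dispersion=0.05, mean_depth=100,
                           seed=13)
        snp_idx = {s: i for i, s in enumerate(geno.snp_map["snp"])}
        peak_idx = {p: i for i, p in enumerate(peaks["name"])}
        checked = 0
        for _, row in truth.cqtl_map.iterrows():
            d = np.rint(geno.dosages[snp_idx[row["snp"]]])
            if min((d == k).sum() for k in (0, 1, 2)) < 20:
                continue
            y = cm.counts[peak_idx[row["peak"]]]
            means = [y[d == k].mean() for k in (0, 1, 2)]
            assert means[0] < means[1] < means[2]
            checked += 1
        assert checked >= 3

    def test_chry_zero_in_females(self, small_cohort):
        cm, samples, peaks = (small_cohort["cm"], small_cohort["samples"],
                              small_cohort["peaks"])
        on_y = (peaks["chrom"] == "chrY").to_numpy()
        female = (samples["sex"] == "F").to_numpy()
        if on_y.any():
            assert cm.counts[np.ix_(on_y, female)].sum() == 0

    def test_unknown_peak_in_truth_rejected(self, layout):
        samples = sg.gen_samples(10, seed=1)
        peaks = sg.gen_peaks(layout, 10, seed=2)
        truth = sg.gen_truth(peaks, pd.DataFrame(columns=["snp", "chrom", "pos"]),
                             samples, frac_cqtl=0, seed=3)
        truth.peak_effects.loc[0, "peak"] = "nonexistent"
        with pytest.raises(ValueError, match="unknown peak"):
            sg.gen_counts(layout, peaks, None, truth, seed=4)

    def test_column_sums_near_expectation(self, small_cohort):
        cm = small_cohort["cm"]
        col = cm.counts.sum(axis=0)
        # library factors have sigma=0.25 on the log scale around mean_depth
        assert 0.2 < col.std() / col.mean() < 1.0
        assert col.min() > 0


@pytest.fixture(scope="module")
def panel():
    return sg.gen_genotypes(300, 20000, 10, seed=21)


@pytest.fixture(scope="module")
def allelic_setup():
    lay = sg.gen_genome(seed=31)
    geno = sg.gen_genotypes(400, 500, 10, maf_low=0.3, maf_high=0.5, seed=32,
                            layout=lay)
    # place one peak on top of each chosen SNP so the SNP is peak-resident
    snps = geno.snp_map.iloc[::25].reset_index(drop=True)
    peaks = pd.DataFrame({
        "chrom": snps["chrom"], "start": snps["pos"] - 150,
        "end": snps["pos"] + 150, "name": [f"pk{i}" for i in range(len(snps))],
        "summit": snps["pos"]})
    return geno, peaks, snps


class TestGwasSumstats:

    def test_null_mean_chi2_one(self, panel):
        A = np.ones((panel.n_snps, 1))
        ss = sg.gen_gwas_sumstats(panel, A, [0.0], 50_000, seed=1)
        chi2 = ss["Z"] ** 2
        se = chi2.std() / np.sqrt(len(chi2))
        assert abs(chi2.mean() - 1.0) < 3 * se

    def test_annotation_enrichment_detected(self, panel):
        rng = np.random.default_rng(2)
        focal = np.zeros(panel.n_snps)
        focal[rng.choice(panel.n_snps, panel.n_snps // 100, replace=False)] = 1
        A = np.column_stack([np.ones(panel.n_snps), focal])
        ss = sg.gen_gwas_sumstats(panel, A, [0.0, 2e-4], 50_000, seed=3)
        chi2 = (ss["Z"] ** 2).to_numpy()
        inside, outside = chi2[focal == 1], chi2[focal == 0]
        t, p = stats.ttest_ind(inside, outside, equal_var=False)
        assert t > 0 and p / 2 < 0.01

    def test_determinism(self, panel):
        A = np.ones((panel.n_snps, 1))
        a = sg.gen_gwas_sumstats(panel, A, [1e-5], 10_000, seed=5)
        b = sg.gen_gwas_sumstats(panel, A, [1e-5], 10_000, seed=5)
        assert (a["Z"] == b["Z"]).all()

    def test_mismatched_annotation_rejected(self, panel):
        with pytest.raises(ValueError):
            sg.gen_gwas_sumstats(panel, np.ones((10, 1)), [0.0], 1000, seed=1)


class TestAllelicReads:
    def test_null_effect_balanced(self, allelic_setup):
        geno, peaks, snps = allelic_setup
        truth = pd.DataFrame({"peak": peaks["name"], "snp": snps["snp"], "beta": 0.0})
        rec, _ = sg.gen_allelic_reads(geno, peaks, truth, depth=50, seed=1)
        frac = rec["alt_reads"].sum() / (rec["alt_reads"].sum() + rec["ref_reads"].sum())
        se = 0.5 / np.sqrt(50 * len(rec))
        assert abs(frac - 0.5) < 3 * se

    def test_strong_effect_shifts_fraction(self, allelic_setup):
        geno, peaks, snps = allelic_setup
        truth = pd.DataFrame({"peak": peaks["name"], "snp": snps["snp"], "beta": 1.0})
        rec, _ = sg.gen_allelic_reads(geno, peaks, truth, depth=50, seed=2)
        assert len(rec) >= 200
        assert rec["alt_fraction"].mean() > 0.55

    def test_homozygotes_emit_no_record(self, allelic_setup):
        geno, peaks, snps = allelic_setup
        truth = pd.DataFrame({"peak": peaks["name"], "snp": snps["snp"], "beta": 0.5})
        rec, _ = sg.gen_allelic_reads(geno, peaks, truth, depth=30, seed=3)
        assert (rec["genotype"] == 1).all()

    def test_snp_outside_peak_skipped(self, allelic_setup):
        geno, peaks, snps = allelic_setup
        far = geno.snp_map.iloc[[1]]  # not under any constructed peak
        truth = pd.DataFrame({"peak": [peaks["name"].iloc[0]], "snp": far["snp"].values,
                              "beta": [0.5]})
        rec, skipped = sg.gen_allelic_reads(geno, peaks, truth, depth=30, seed=4)
        assert skipped == 1 and len(rec) == 0


class TestTruthRoundTrip:
    def test_tsv_round_trip(self, small_cohort, tmp_path):
        truth = small_cohort["truth"]
        truth.cqtl_map.to_csv(tmp_path / "c.tsv", sep="\t", index=False)
        truth.peak_effects.to_csv(tmp_path / "e.tsv", sep="\t", index=False)
        c = pd.read_csv(tmp_path / "c.tsv", sep="\t")
        e = pd.read_csv(tmp_path / "e.tsv", sep="\t")
        pd.testing.assert_frame_equal(c, truth.cqtl_map.reset_index(drop=True))
        pd.testing.assert_frame_equal(e, truth.peak_effects.reset_index(drop=True))
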