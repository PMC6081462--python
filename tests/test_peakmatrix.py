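"""Peak merging, quantification, TMM, enrichment QC, and TSS annotation."""

import numpy as np
import pandas as pd
import pytest

from brainchrom import peakmatrix as pm
from brainchrom import synthgen as sg


def peakset(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])


class TestMergePeaks:
    def test_single_sample_peak_dropped(self):
        a = peakset([("chr1", 1000, 1300, 1150)])
        b = peakset([("chr1", 5000, 5300, 5150)])
        merged = pm.merge_peaks([a, b], min_support=2)
        assert len(merged) == 0

    def test_identical_peak_three_samples(self):
        p = peakset([("chr1", 1000, 1300, 1150)])
        merged = pm.merge_peaks([p, p.copy(), p.copy()], min_support=2)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert (row["start"], row["end"], row["support"]) == (1000, 1300, 3)

    def test_consensus_summit_is_median(self):
        a = peakset([("chr1", 100, 400, 250)])
        b = peakset([("chr1", 150, 450, 300)])
        merged = pm.merge_peaks([a, b], min_support=2, width=300)
        row = merged.iloc[0]
        assert row["summit"] == 275  # median of 250 and 300
        assert (row["start"], row["end"]) == (125, 425)

    def test_idempotent_on_own_output(self):
        a = peakset([("chr1", 100, 400, 250), ("chr1", 900, 1200, 1050),
                     ("chr2", 50, 350, 200)])
        b = peakset([("chr1", 120, 420, 260), ("chr2", 60, 360, 210)])
        merged = pm.merge_peaks([a, b], min_support=1, width=300)
        again = pm.merge_peaks([merged[["chrom", "start", "end", "summit"]]],
                               min_support=1, width=300)
        pd.testing.assert_frame_equal(
            merged[["chrom", "start", "end", "summit"]],
            again[["chrom", "start", "end", "summit"]])

    def test_malformed_interval_raises(self):
        bad = peakset([("chr1", 400, 100, 250)])
        with pytest.raises(ValueError, match="malformed"):
            pm.merge_peaks([bad, bad])

    def test_empty_input_gives_empty_set(self):
        assert len(pm.merge_peaks([])) == 0


class TestQuantify:
    def toy(self):
        peaks = peakset([("chr1", 1000, 1300, 1150)])
        peaks["name"] = ["p0"]
        return peaks[["chrom", "start", "end", "name", "summit"]]

    def test_no_fragments_all_zero(self):
        cm = pm.quantify({"s1": pd.DataFrame(columns=["chrom", "start", "end"])}, self.toy())
        assert cm.counts.sum() == 0

    def test_extension_counts_upstream_fragment(self):
        # fragment starts 50 bp left of the peak start; extension reaches in
        frags = pd.DataFrame([("chr1", 950, 1000)], columns=["chrom", "start", "end"])
        cm = pm.quantify({"s1": frags}, self.toy(), extend=300)
        assert cm.counts[0, 0] == 1
        # without extension past the gap, not counted
        cm2 = pm.quantify({"s1": frags}, self.toy(), extend=40)
        assert cm2.counts[0, 0] == 0

    def test_fragment_conservation(self):
        inside = [("chr1", 1100 + i, 1150 + i) for i in range(10)]
        outside = [("chr1", 500_000, 500_050)]
        frags = pd.DataFrame(inside + outside, columns=["chrom", "start", "end"])
        cm = pm.quantify({"s1": frags}, self.toy())
        assert cm.counts.sum() == 10
        assert cm.lib_size[0] == 11


class TestTMM:
    def test_identical_columns_unit_factors(self):
        peaks = peakset([("chr1", i * 1000, i * 1000 + 300, i * 1000 + 150) for i in range(20)])
        peaks["name"] = [f"p{i}" for i in range(20)]
        counts = np.tile(np.arange(10, 30)[:, None], (1, 2))
        cm = pm.CountMatrix(peaks, ["a", "b"], counts, counts.sum(axis=0))
        f = pm.tmm_factors(cm)
        np.testing.assert_allclose(f, [1.0, 1.0], atol=1e-12)

    def test_doubled_column_sqrt2_factors(self):
        peaks = peakset([("chr1", i * 1000, i * 1000 + 300, i * 1000 + 150) for i in range(4)])
        peaks["name"] = [f"p{i}" for i in range(4)]
        counts = np.array([[10, 20], [20, 40], [30, 60], [40, 80]])
        lib = np.array([1000, 1000])
        cm = pm.CountMatrix(peaks, ["a", "b"], counts, lib)
        f = pm.tmm_factors(cm)
        # all M = 1 against either reference -> raw factor 2, rescaled to sqrt2
        np.testing.assert_allclose(sorted(f), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-9)

    def test_brute_force_trimmed_weighted_mean(self, rng):
        # oracle: direct computation of the doubly trimmed weighted mean M
        counts = rng.poisson(50, size=(200, 2)) + 1
        lib = counts.sum(axis=0).astype(float)
        peaks = peakset([("chr1", i * 1000, i * 1000 + 300, i * 1000 + 150)
                         for i in range(200)])
        peaks["name"] = [f"p{i}" for i in range(200)]
        cm = pm.CountMatrix(peaks, ["a", "b"], counts, counts.sum(axis=0))
        f = pm.tmm_factors(cm, ref="a")
        o, r = counts[:, 1].astype(float), counts[:, 0].astype(float)
        m = np.log2((o / lib[1]) / (r / lib[0]))
        a = 0.5 * np.log2((o / lib[1]) * (r / lib[0]))
        w = (lib[1] - o) / (lib[1] * o) + (lib[0] - r) / (lib[0] * r)
        n = len(m)
        from scipy.stats import rankdata
        keep = ((rankdata(m) >= np.floor(n * 0.3) + 1) & (rankdata(m) <= n - np.floor(n * 0.3))
                & (rankdata(a) >= np.floor(n * 0.05) + 1) & (rankdata(a) <= n - np.floor(n * 0.05)))
        expected_log2 = np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])
        raw = 2.0 ** expected_log2
        expected = np.array([1.0, raw])
        expected = expected / np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f, expected, rtol=1e-9)

    def test_scaling_invariance(self, rng):
        counts = rng.poisson(40, size=(100, 3)) + 1
        peaks = peakset([("chr1", i * 1000, i * 1000 + 300, i * 1000 + 150)
                         for i in range(100)])
        peaks["name"] = [f"p{i}" for i in range(100)]
        cm = pm.CountMatrix(peaks, ["a", "b", "c"], counts, counts.sum(axis=0))
        f1 = pm.tmm_factors(cm, ref="a")
        scaled = counts.copy()
        scaled[:, 1] *= 4  # lib size scales along
        cm2 = pm.CountMatrix(peaks, ["a", "b", "c"], scaled, scaled.sum(axis=0))
        f2 = pm.tmm_factors(cm2, ref="a")
        # equal count *proportions* -> same factors up to the count-dependent
        # precision weights
        np.testing.assert_allclose(f1, f2, rtol=1e-2)

    def test_edger_oracle(self, rng, tmp_path):
        """Cross-check TMM factors against edgeR's calcNormFactors."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        counts = rng.poisson(rng.uniform(10, 200, size=(80, 1)), size=(80, 4)) + 1
        counts[:, 2] = (counts[:, 2] * 1.7).astype(int)
        peaks = peakset([("chr1", i * 1000, i * 1000 + 300, i * 1000 + 150)
                         for i in range(80)])
        peaks["name"] = [f"p{i}" for i in range(80)]
        cm = pm.CountMatrix(peaks, list("abcd"), counts, counts.sum(axis=0))
        ours = pm.tmm_factors(cm, ref="a")
        np.savetxt(tmp_path / "counts.tsv", counts, fmt="%d", delimiter="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR));'
            f'x <- as.matrix(read.table("{tmp_path}/counts.tsv"));'
            'f <- calcNormFactors(x, method="TMM", refColumn=1);'
            'cat(f, sep="\\n")')
        res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=120)
        if res.returncode != 0:
            pytest.skip(f"edgeR unavailable: {res.stderr[:200]}")
        theirs = np.array([float(x) for x in res.stdout.split()])
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)


class TestShuffleEnrichment:
    def test_uniform_fragments_ratio_near_one(self, layout):
        rng = np.random.default_rng(5)
        peaks = sg.gen_peaks(layout, 60, seed=6)
        sizes = layout.chrom_sizes()
        rows = []
        for _ in range(4000):
            chrom = "chr1"
            s = int(rng.integers(0, sizes[chrom] - 50))
            rows.append((chrom, s, s + 50))
        frags = {"s1": pd.DataFrame(rows, columns=["chrom", "start", "end"])}
        rep = pm.shuffle_enrichment(frags, peaks, layout.mappable, layout.blacklist,
                                    n_shuffles=10, seed=7)
        assert 0.6 < rep.per_sample_ratio.iloc[0] < 1.6

    def test_concentrated_fragments_ratio_near_three(self, layout):
        rng = np.random.default_rng(8)
        peaks = sg.gen_peaks(layout, 60, seed=9)
        peaks = peaks[peaks["chrom"] == "chr1"].reset_index(drop=True)
        size = layout.chrom_sizes()["chr1"]
        mappable = layout.mappable[layout.mappable["chrom"] == "chr1"]
        blacklist = layout.blacklist[layout.blacklist["chrom"] == "chr1"]
        extend, frag_len, n_bg = 300, 50, 3000
        rows = [("chr1", int(s), int(s) + frag_len)
                for s in rng.integers(0, size - frag_len, n_bg)]
        # a 300-bp peak catches extended fragments starting within ~width+extend
        eff = (peaks["end"] - peaks["start"] + extend).sum()
        n_extra = int(round(2 * n_bg * eff / size))
        for _ in range(n_extra):
            p = peaks.iloc[int(rng.integers(len(peaks)))]
            s = int(rng.integers(p["start"] - extend + frag_len, p["end"] - 1))
            rows.append(("chr1", max(s, 0), max(s, 0) + frag_len))
        frags = {"s1": pd.DataFrame(rows, columns=["chrom", "start", "end"])}
        rep = pm.shuffle_enrichment(frags, peaks, mappable, blacklist,
                                    n_shuffles=10, extend=extend, seed=10)
        assert 2.2 < rep.per_sample_ratio.iloc[0] < 4.0

    def test_empty_allowed_space_raises(self, layout):
        peaks = sg.gen_peaks(layout, 10, seed=3)
        frags = {"s1": pd.DataFrame(columns=["chrom", "start", "end"])}
        with pytest.raises(ValueError, match="allowed space|insufficient"):
            pm.shuffle_enrichment(frags, peaks, layout.mappable.iloc[:0],
                                  layout.blacklist)

    def test_seed_reproducible(self, layout):
        peaks = sg.gen_peaks(layout, 30, seed=3)
        rng = np.random.default_rng(1)
        rows = [("chr1", int(s), int(s) + 50) for s in rng.integers(0, 900_000, 500)]
        frags = {"s1": pd.DataFrame(rows, columns=["chrom", "start", "end"])}
        r1 = pm.shuffle_enrichment(frags, peaks, layout.mappable, layout.blacklist, seed=42)
        r2 = pm.shuffle_enrichment(frags, peaks, layout.mappable, layout.blacklist, seed=42)
        assert r1.per_sample_ratio.equals(r2.per_sample_ratio)


class TestReplicateConcordance:
    def test_perfect_replicates(self, rng):
        base = rng.poisson(rng.uniform(20, 200, size=(150, 1)), size=(150, 4))
        noise = rng.poisson(50, size=(150, 16))
        counts = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 1],
                                  noise])
        peaks = peakset([("chr1", i * 1000, i * 1000 + 300, i * 1000 + 150)
                         for i in range(150)])
        peaks["name"] = [f"p{i}" for i in range(150)]
        samples = ["a1", "a2", "b1", "b2"] + [f"n{i}" for i in range(16)]
        cm = pm.CountMatrix(peaks, samples, counts, counts.sum(axis=0))
        res = pm.replicate_concordance(cm, [("a1", "a2"), ("b1", "b2")],
                                       n_perm=999, seed=0)
        assert res["within_mean"] > 0.99
        assert res["p"] == pytest.approx(1 / 1000)

    def test_missing_sample_raises(self, small_cohort):
        with pytest.raises(ValueError, match="missing sample"):
            pm.replicate_concordance(small_cohort["cm"], [("S000", "nope"), ("S001", "S002")])


class TestJaccard:
    def test_identical_and_disjoint(self):
        a = pd.DataFrame([("chr1", 0, 300)], columns=["chrom", "start", "end"])
        b = pd.DataFrame([("chr2", 0, 300)], columns=["chrom", "start", "end"])
        assert pm.jaccard(a, a) == 1.0
        assert pm.jaccard(a, b) == 0.0

    def test_partial_overlap_hand_value(self):
        a = pd.DataFrame([("chr1", 0, 300)], columns=["chrom", "start", "end"])
        b = pd.DataFrame([("chr1", 150, 450)], columns=["chrom", "start", "end"])
        assert pm.jaccard(a, b) == pytest.approx(150 / 450)

    def test_empty_convention(self):
        e = pd.DataFrame(columns=["chrom", "start", "end"])
        assert pm.jaccard(e, e) == 0.0


class TestTssAnnotate:
    def tss(self):
        return pd.DataFrame({"chrom": ["chr1"], "pos": [100_000], "strand": ["+"],
                             "quartile": ["Q4"]})

    def make_peak(self, center):
        return pd.DataFrame({"chrom": ["chr1"], "start": [center - 150],
                             "end": [center + 150], "name": ["p0"],
                             "summit": [center]})

    def test_peak_on_tss(self):
        ann = pm.tss_annotate(self.make_peak(100_000), self.tss())
        assert ann["distance"].iloc[0] == 0
        assert ann["tss_class"].iloc[0] == "±5kb"

    def test_boundary_closed_at_5kb(self):
        ann = pm.tss_annotate(self.make_peak(105_000), self.tss())
        assert ann["tss_class"].iloc[0] == "±5kb"
        ann2 = pm.tss_annotate(self.make_peak(105_001), self.tss())
        assert ann2["tss_class"].iloc[0] == "5–25kb"

    def test_constructed_far_peaks_all_beyond_25kb(self):
        peaks = pd.concat([self.make_peak(130_001), self.make_peak(160_000)],
                          ignore_index=True)
        ann = pm.tss_annotate(peaks, self.tss())
        assert (ann["tss_class"] == ">25kb").all()

    def test_strand_gives_sign(self):
        tss = self.tss()
        ann = pm.tss_annotate(self.make_peak(101_000), tss)
        assert ann["distance"].iloc[0] == 1000 and ann["orientation"].iloc[0] == "downstream"
        tss_minus = tss.assign(strand="-")
        ann2 = pm.tss_annotate(self.make_peak(101_000), tss_minus)
        assert ann2["distance"].iloc[0] == -1000 and ann2["orientation"].iloc[0] == "upstream"

    def test_chromosome_without_tss(self):
        peak = self.make_peak(1000).assign(chrom="chr9")
        ann = pm.tss_annotate(peak, self.tss())
        assert ann["tss_class"].iloc[0] == ">25kb"
        assert np.isinf(ann["abs_distance"].iloc[0])
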