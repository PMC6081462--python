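"""Synthetic cohort generator with known ground truth.

Emulates a postmortem-brain ATAC-seq case--control study at desk scale: a small
genome with TSS annotation, block-LD genotypes, a peaks x samples
negative-binomial count matrix driven by diagnosis/age/PMI/batch effects and
cis-acting genotype effects, per-sample fragment placements, allele-specific
read counts at regulatory SNPs, and GWAS summary statistics whose chi-square
inflation tracks annotation-weighted LD scores.

Every generator is a pure function of its arguments and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import merge_intervals, subtract_intervals
from .peakmatrix import CountMatrix

QUARTILE_LABELS = ("Q0", "Q1", "Q2", "Q3", "Q4")


@dataclass
class GenomeLayout:
    """Chromosome sizes plus TSS, mappability and blacklist tracks."""

    chromosomes: list  # list of (name, length)
    tss: pd.DataFrame  # chrom, pos, strand, quartile
    mappable: pd.DataFrame  # chrom, start, end
    blacklist: pd.DataFrame  # chrom, start, end

    def chrom_sizes(self) -> dict:
        return dict(self.chromosomes)


@dataclass
class Genotypes:
    """Dosage matrix (SNPs x samples) with a SNP map."""

    dosages: np.ndarray
    snp_map: pd.DataFrame  # snp, chrom, pos, a1, a2
    samples: list

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]


@dataclass
class TruthSet:
    """Ground-truth effects behind a simulated cohort."""

    samples: pd.DataFrame  # sample, diagnosis, sex, age, pmi, batch
    peak_effects: pd.DataFrame  # peak, dx_log2fc, age_slope, pmi_slope, batch_shift
    cqtl_map: pd.DataFrame  # peak, snp, beta (log scale per alt allele)
    causal_tau: pd.DataFrame = field(default_factory=pd.DataFrame)  # category, tau

    def validate(self, peaks: pd.DataFrame | None = None, snp_map: pd.DataFrame | None = None) -> None:
        if not set(self.samples["diagnosis"]) <= {"case", "control"}:
            raise ValueError("diagnosis must be case/control")
        if not set(self.samples["sex"]) <= {"M", "F"}:
            raise ValueError("sex must be M/F")
        if peaks is not None:
            known = set(peaks["name"])
            for col_df in (self.peak_effects, self.cqtl_map):
                bad = set(col_df["peak"]) - known
                if bad:
                    raise ValueError(f"truth references unknown peaks: {sorted(bad)[:5]}")
        if snp_map is not None:
            bad = set(self.cqtl_map["snp"]) - set(snp_map["snp"])
            if bad:
                raise ValueError(f"truth references unknown SNPs: {sorted(bad)[:5]}")


def gen_genome(n_autosomes: int = 2, chrom_length: int = 1_000_000, n_tss: int = 100,
               blacklist_fraction: float = 0.02, seed: int = 0) -> GenomeLayout:
    """Build a toy genome: autosomes + chrX + chrY, uniform TSS, random blacklist."""
    if n_autosomes < 1 or chrom_length < 10_000 or n_tss < 1:
        raise ValueError("non-positive or too-small genome dimensions")
    if not 0 <= blacklist_fraction < 0.5:
        raise ValueError("blacklist_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_autosomes)]
    chroms += [("chrX", chrom_length), ("chrY", chrom_length // 2)]

    tss_rows = []
    per = np.full(len(chroms), n_tss // len(chroms))
    per[: n_tss % len(chroms)] += 1
    for (name, length), k in zip(chroms, per):
        pos = np.sort(rng.integers(1000, length - 1000, size=k))
        strand = rng.choice(["+", "-"], size=k)
        quart = rng.choice(QUARTILE_LABELS, size=k)
        for p, s, q in zip(pos, strand, quart):
            tss_rows.append((name, int(p), s, q))
    tss = pd.DataFrame(tss_rows, columns=["chrom", "pos", "strand", "quartile"])

    mappable = pd.DataFrame([(name, 0, length) for name, length in chroms],
                            columns=["chrom", "start", "end"])

    bl_rows = []
    if blacklist_fraction > 0:
        for name, length in chroms:
            target = int(length * blacklist_fraction)
            covered = 0
            while covered < target:
                w = min(int(rng.integers(500, 2000)), target - covered + 500)
                s = int(rng.integers(0, length - w))
                bl_rows.append((name, s, s + w))
                covered += w
    blacklist = merge_intervals(pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])) \
        if bl_rows else pd.DataFrame(columns=["chrom", "start", "end"])
    return GenomeLayout(chroms, tss, mappable, blacklist)


def gen_samples(n_samples: int = 288, case_fraction: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Cohort metadata shaped like a schizophrenia postmortem series.

    Cases skew male and have much longer postmortem intervals than controls;
    ages are ~74 y in both groups. A few technical variables (batch, GC
    content, RIN) are included so covariate selection has something to find.
    """
    rng = np.random.default_rng(seed)
    n_cases = int(round(n_samples * case_fraction))
    dx = np.array(["case"] * n_cases + ["control"] * (n_samples - n_cases))
    male_p = np.where(dx == "case", 0.68, 0.53)
    sex = np.where(rng.random(n_samples) < male_p, "M", "F")
    age = np.where(dx == "case", rng.normal(73.3, 12.6, n_samples),
                   rng.normal(73.9, 17.7, n_samples)).clip(18, 105)
    pmi = np.where(dx == "case",
                   rng.gamma(2.4, 24.3 / 2.4, n_samples),
                   rng.gamma(2.1, 10.9 / 2.1, n_samples)).clip(1, 90)
    batch = rng.choice([f"B{i}" for i in range(4)], size=n_samples)
    gc = rng.normal(41.0, 1.5, n_samples)
    rin = np.where(dx == "case", rng.normal(7.11, 0.79, n_samples),
                   rng.normal(7.57, 0.84, n_samples)).clip(2, 10)
    return pd.DataFrame({
        "sample": [f"S{i:03d}" for i in range(n_samples)],
        "diagnosis": dx, "sex": sex,
        "age": np.round(age, 1), "pmi": np.round(pmi, 1),
        "batch": batch, "gc_pct": np.round(gc, 2), "rin": np.round(rin, 2),
    })


def gen_peaks(layout: GenomeLayout, n_peaks: int = 5000, width: int = 300,
              tss_bias: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Place fixed-width peaks; a fraction lands near TSS, the rest uniform.

    Peaks avoid the blacklist and stay within chromosome bounds.
    """
    rng = np.random.default_rng(seed)
    allowed = subtract_intervals(layout.mappable, layout.blacklist)
    rows = []
    sizes = layout.chrom_sizes()
    tss = layout.tss
    half = width // 2
    i = 0
    attempts = 0
    starts_by_chrom = {c: g for c, g in allowed.groupby("chrom")}
    cum = allowed.assign(length=allowed["end"] - allowed["start"])
    total = cum["length"].sum()
    cum["cumlen"] = cum["length"].cumsum()
    while i < n_peaks and attempts < n_peaks * 50:
        attempts += 1
        if rng.random() < tss_bias and len(tss):
            t = tss.iloc[int(rng.integers(len(tss)))]
            chrom = t["chrom"]
            summit = int(t["pos"] + rng.normal(0, 1500))
        else:
            x = rng.random() * total
            row = cum[cum["cumlen"] > x].iloc[0]
            chrom = row["chrom"]
            summit = int(row["start"] + (x - (row["cumlen"] - row["length"])))
        if summit - half < 0 or summit + half > sizes[chrom]:
            continue
        rows.append((chrom, summit - half, summit - half + width, f"peak{i:05d}", summit))
        i += 1
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "summit"])
    return peaks.sort_values(["chrom", "start"]).reset_index(drop=True)


def gen_genotypes(n_samples: int, n_snps: int, block_size: int = 10,
                  maf_low: float = 0.05, maf_high: float = 0.5, seed: int = 0,
                  layout: GenomeLayout | None = None,
                  block_jitter: int = 0) -> Genotypes:
    """Block-exchangeable LD genotypes.

    SNPs come in consecutive blocks sharing a latent biallelic haplotype;
    SNP alleles are the latent allele flipped with a probability that grows
    along the block, so pairwise r^2 decays with distance within a block and
    is ~0 between blocks. Dosage = sum of two haplotypes, in [0, 2].

    ``block_jitter`` draws each block's length uniformly from
    [max(1, block_size - jitter), block_size + jitter], giving the variable
    LD-score landscape real genomes have; 0 keeps all blocks equal.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if n_snps < block_size:
        raise ValueError("n_snps must be >= block_size")
    rng = np.random.default_rng(seed)

    doses = np.empty((n_snps, n_samples), dtype=np.int8)
    eps_max = 0.05
    lo = 0
    while lo < n_snps:
        if block_jitter:
            size = int(rng.integers(max(1, block_size - block_jitter),
                                    block_size + block_jitter + 1))
        else:
            size = block_size
        hi = min(lo + size, n_snps)
        k = hi - lo
        p = rng.uniform(maf_low, maf_high)
        latent = rng.random((2, n_samples)) < p  # two haplotypes
        eps = eps_max * np.arange(k) / max(size - 1, 1)
        flips = rng.random((k, 2, n_samples)) < eps[:, None, None]
        alleles = latent[None, :, :] ^ flips
        doses[lo:hi] = alleles.sum(axis=1)
        lo = hi

    # SNP positions: evenly spread over the autosomes with jitter
    if layout is None:
        layout = gen_genome(seed=seed)
    autosomes = [(c, L) for c, L in layout.chromosomes if c not in ("chrX", "chrY")]
    per = np.full(len(autosomes), n_snps // len(autosomes))
    per[: n_snps % len(autosomes)] += 1
    chroms, pos = [], []
    for (c, L), k in zip(autosomes, per):
        step = L / (k + 1)
        base = (np.arange(1, k + 1) * step).astype(int)
        jitter = rng.integers(-int(step // 4) or 1, int(step // 4) + 1, size=k)
        pos.extend(np.clip(base + jitter, 1, L - 1).tolist())
        chroms.extend([c] * k)
    snp_map = pd.DataFrame({
        "snp": [f"rs{i:06d}" for i in range(n_snps)],
        "chrom": chroms, "pos": pos, "a1": "A", "a2": "G",
    })
    samples = [f"S{i:03d}" for i in range(n_samples)]
    return Genotypes(doses.astype(np.float64), snp_map, samples)


def gen_truth(peaks: pd.DataFrame, snp_map: pd.DataFrame, samples: pd.DataFrame,
              frac_dx: float = 0.02, dx_log2fc: float = 1.5,
              frac_age: float = 0.05, age_slope: float = 0.02,
              frac_pmi: float = 0.02, pmi_slope: float = 0.02,
              frac_cqtl: float = 0.10, cqtl_beta: float = 0.5,
              cis_window: int = 5000, batch_shift: float = 0.0,
              frac_batch: float = 0.0, seed: int = 0) -> TruthSet:
    """Assign diagnosis/age/PMI/cQTL effects to random peak subsets.

    cQTL peaks are paired with the SNP nearest their center (within the cis
    window); effect signs are random. Slopes are per-unit of the standardized
    covariate on the natural-log scale; diagnosis effects are log2 fold
    changes.
    """
    rng = np.random.default_rng(seed)
    n = len(peaks)
    eff = pd.DataFrame({"peak": peaks["name"].to_numpy(),
                        "dx_log2fc": 0.0, "age_slope": 0.0, "pmi_slope": 0.0,
                        "batch_shift": 0.0})

    def pick(frac):
        k = int(round(n * frac))
        return rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)

    eff.loc[pick(frac_dx), "dx_log2fc"] = rng.choice([-1, 1], size=int(round(n * frac_dx))) * dx_log2fc
    eff.loc[pick(frac_age), "age_slope"] = rng.choice([-1, 1], size=int(round(n * frac_age))) * age_slope
    eff.loc[pick(frac_pmi), "pmi_slope"] = rng.choice([-1, 1], size=int(round(n * frac_pmi))) * pmi_slope
    eff.loc[pick(frac_batch), "batch_shift"] = batch_shift

    # cQTLs: autosomal peaks with a SNP within the window of the peak center
    cq_rows = []
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    cand = []
    for chrom, grp in snp_map.groupby("chrom"):
        sel = peaks["chrom"] == chrom
        if not sel.any():
            continue
        spos = grp["pos"].to_numpy()
        order = np.argsort(spos)
        spos_s = spos[order]
        ids = grp["snp"].to_numpy()[order]
        for idx in np.flatnonzero(sel.to_numpy()):
            c = centers[idx]
            j = np.searchsorted(spos_s, c)
            best, bestd = None, cis_window + 1
            for jj in (j - 1, j):
                if 0 <= jj < len(spos_s):
                    d = abs(int(spos_s[jj]) - int(c))
                    if d < bestd:
                        best, bestd = jj, d
            if best is not None and bestd <= cis_window:
                cand.append((peaks["name"].iloc[idx], ids[best]))
    k = min(int(round(n * frac_cqtl)), len(cand))
    chosen = rng.choice(len(cand), size=k, replace=False) if k else []
    for ci in chosen:
        pk, sn = cand[ci]
        cq_rows.append((pk, sn, float(rng.choice([-1, 1]) * cqtl_beta)))
    cqtl = pd.DataFrame(cq_rows, columns=["peak", "snp", "beta"])
    truth = TruthSet(samples=samples.copy(), peak_effects=eff, cqtl_map=cqtl)
    truth.validate(peaks, snp_map)
    return truth


def gen_counts(layout: GenomeLayout, peaks: pd.DataFrame, genotypes: Genotypes | None,
               truth: TruthSet, dispersion: float = 0.2, mean_depth: float = 100.0,
               seed: int = 0) -> CountMatrix:
    """Draw the peaks x samples count matrix from the generative NB model.

    log mean = log(baseline_g) + log(library factor_s) + ln2 * dx_log2fc * I(case)
    + age/PMI slopes on standardized covariates + batch shift + cQTL beta x dosage.
    chrY peaks are zeroed in females. dispersion -> 0 recovers Poisson.
    """
    if dispersion < 0 or mean_depth <= 0:
        raise ValueError("dispersion must be >= 0 and mean_depth > 0")
    truth.validate(peaks, genotypes.snp_map if genotypes is not None else None)
    rng = np.random.default_rng(seed)
    meta = truth.samples
    n_g, n_s = len(peaks), len(meta)

    baseline = np.exp(rng.normal(np.log(mean_depth), 0.5, size=n_g))
    libfac = np.exp(rng.normal(0, 0.25, size=n_s))
    is_case = (meta["diagnosis"] == "case").to_numpy().astype(float)
    age_z = ((meta["age"] - meta["age"].mean()) / meta["age"].std()).to_numpy()
    pmi_z = ((meta["pmi"] - meta["pmi"].mean()) / meta["pmi"].std()).to_numpy()
    batch_ind = (meta["batch"] == meta["batch"].mode().iloc[0]).to_numpy().astype(float)

    eff = truth.peak_effects.set_index("peak").loc[peaks["name"]]
    log_mu = (np.log(baseline)[:, None] + np.log(libfac)[None, :]
              + np.log(2.0) * eff["dx_log2fc"].to_numpy()[:, None] * is_case[None, :]
              + eff["age_slope"].to_numpy()[:, None] * age_z[None, :]
              + eff["pmi_slope"].to_numpy()[:, None] * pmi_z[None, :]
              + eff["batch_shift"].to_numpy()[:, None] * batch_ind[None, :])

    if genotypes is not None and len(truth.cqtl_map):
        sample_idx = {s: i for i, s in enumerate(genotypes.samples)}
        cols = np.array([sample_idx[s] for s in meta["sample"]])
        peak_idx = {p: i for i, p in enumerate(peaks["name"])}
        snp_idx = {s: i for i, s in enumerate(genotypes.snp_map["snp"])}
        for _, row in truth.cqtl_map.iterrows():
            g = genotypes.dosages[snp_idx[row["snp"]]][cols]
            log_mu[peak_idx[row["peak"]]] += row["beta"] * (g - g.mean())

    mu = np.exp(log_mu)
    if dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    on_y = (peaks["chrom"] == "chrY").to_numpy()
    female = (meta["sex"] == "F").to_numpy()
    counts[np.ix_(on_y, female)] = 0

    lib_size = counts.sum(axis=0)
    return CountMatrix(peaks=peaks.reset_index(drop=True), samples=list(meta["sample"]),
                       counts=counts.astype(np.int64), lib_size=lib_size.astype(np.int64))


def gen_fragments(layout: GenomeLayout, cm: CountMatrix, background_per_peak_read: float = 0.5,
                  frag_len: int = 50, seed: int = 0) -> dict:
    """Per-sample fragment placements consistent with the count matrix.

    In-peak fragments follow a triangular density peaking at the summit;
    background fragments are uniform over the mappable genome. Returns
    ``{sample: BED3 DataFrame}``.
    """
    rng = np.random.default_rng(seed)
    allowed = merge_intervals(layout.mappable)
    lens = (allowed["end"] - allowed["start"]).to_numpy()
    cumlen = np.concatenate([[0], np.cumsum(lens)])
    total = cumlen[-1]
    out = {}
    peaks = cm.peaks
    summits = peaks["summit"].to_numpy()
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    for si, sample in enumerate(cm.samples):
        rows = []
        col = cm.counts[:, si]
        for gi in np.flatnonzero(col):
            k = int(col[gi])
            w = ends[gi] - starts[gi]
            off = rng.triangular(-w / 2, 0, w / 2, size=k)
            fs = (summits[gi] + off - frag_len / 2).astype(int)
            for s in fs:
                rows.append((peaks["chrom"].iloc[gi], max(s, 0), max(s, 0) + frag_len))
        n_bg = rng.poisson(background_per_peak_read * col.sum())
        xs = rng.random(n_bg) * total
        idx = np.searchsorted(cumlen, xs, side="right") - 1
        for i, x in zip(idx, xs):
            s = int(allowed["start"].iloc[i] + (x - cumlen[i]))
            rows.append((allowed["chrom"].iloc[i], s, s + frag_len))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out[sample] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def gen_gwas_sumstats(genotypes_ref: Genotypes, annotations: np.ndarray, tau: np.ndarray,
                      n_gwas: int, seed: int = 0) -> pd.DataFrame:
    """Summary statistics from an annotation-stratified polygenic model.

    Per-SNP effects are drawn with variance sum_c tau_c * a_jc; marginal
    standardized effects are computed on the reference cohort and observed
    z-scores add N(0,1) sampling noise at sample size ``n_gwas``, so
    E[chi^2_j] = 1 + N * sum_c tau_c * l(j, c).
    """
    tau = np.asarray(tau, dtype=float)
    A = np.asarray(annotations, dtype=float)
    if A.shape[0] != genotypes_ref.n_snps:
        raise ValueError("annotation rows must match SNP count")
    if A.shape[1] != len(tau):
        raise ValueError("tau length must match annotation columns")
    if np.any(tau < 0) or n_gwas <= 0:
        raise ValueError("tau must be >= 0 and n_gwas > 0")
    rng = np.random.default_rng(seed)
    X = genotypes_ref.dosages
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd  # M x n
    n = Z.shape[1]
    var = A @ tau
    beta = rng.normal(0, 1, size=len(var)) * np.sqrt(var)
    g = Z.T @ beta  # genetic value per reference individual
    alpha = (Z @ g) / n  # marginal standardized effects
    z = np.sqrt(n_gwas) * alpha + rng.normal(0, 1, size=len(alpha))
    sm = genotypes_ref.snp_map
    return pd.DataFrame({
        "SNP": sm["snp"], "CHR": sm["chrom"], "BP": sm["pos"],
        "A1": sm["a1"], "A2": sm["a2"], "Z": z, "N": n_gwas,
    })


def gen_allelic_reads(genotypes: Genotypes, peaks: pd.DataFrame, cqtl_truth: pd.DataFrame,
                      depth: int = 50, seed: int = 0):
    """Allele-specific read counts at SNPs for heterozygous individuals.

    ``cqtl_truth`` rows are (peak, snp, beta); beta = 0 marks control SNPs.
    For a heterozygote, alt reads ~ Binomial(depth, sigmoid(beta)). SNPs
    falling outside their peak are skipped and counted.

    Returns (records DataFrame, n_skipped).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    snp_idx = {s: i for i, s in enumerate(genotypes.snp_map["snp"])}
    pk = peaks.set_index("name")
    pos_by_snp = genotypes.snp_map.set_index("snp")
    rows, skipped = [], 0
    for _, t in cqtl_truth.iterrows():
        p = pk.loc[t["peak"]]
        s = pos_by_snp.loc[t["snp"]]
        if not (s["chrom"] == p["chrom"] and p["start"] <= s["pos"] < p["end"]):
            skipped += 1
            continue
        dos = genotypes.dosages[snp_idx[t["snp"]]]
        gclass = np.rint(dos).astype(int)
        p_alt = 1.0 / (1.0 + np.exp(-t["beta"]))
        for si in np.flatnonzero(gclass == 1):
            alt = int(rng.binomial(depth, p_alt))
            rows.append((t["snp"], genotypes.samples[si], depth - alt, alt, gclass[si]))
    rec = pd.DataFrame(rows, columns=["snp", "sample", "ref_reads", "alt_reads", "genotype"])
    if len(rec):
        rec["alt_fraction"] = rec["alt_reads"] / (rec["ref_reads"] + rec["alt_reads"])
    else:
        rec["alt_fraction"] = pd.Series(dtype=float)
    return rec, skipped
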