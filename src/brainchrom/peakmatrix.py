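"""Peak merging, quantification, TMM normalization, and peak-set QC.

Peaks are fixed-width intervals centered on a consensus summit. Counting
extends each fragment to a fixed length from its start and counts >=1 bp
overlaps. Normalization is the trimmed mean of M-values with inverse
asymptotic-variance weights and geometric-mean-1 rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (intersect_intervals, merge_intervals, subtract_intervals,
                        total_length)

PEAK_COLS = ["chrom", "start", "end", "name", "summit"]


@dataclass
class CountMatrix:
    """Peaks x samples fragment counts with library sizes and TMM factors."""

    peaks: pd.DataFrame
    samples: list
    counts: np.ndarray
    lib_size: np.ndarray
    tmm_factor: np.ndarray | None = None

    def validate(self) -> None:
        if self.counts.shape != (len(self.peaks), len(self.samples)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.lib_size < self.counts.sum(axis=0)).any():
            raise ValueError("lib_size below column sums")
        if self.tmm_factor is not None:
            gm = np.exp(np.mean(np.log(self.tmm_factor)))
            if abs(gm - 1.0) > 1e-9:
                raise ValueError("TMM factors must have geometric mean 1")

    def cpm_log2(self, prior: float = 0.5) -> np.ndarray:
        """log2 counts per million on effective library sizes."""
        f = self.tmm_factor if self.tmm_factor is not None else np.ones(len(self.samples))
        eff = self.lib_size * f
        return np.log2(self.counts / eff[None, :] * 1e6 + prior)


@dataclass
class EnrichmentReport:
    """Observed/shuffled read-count enrichment per sample and per peak."""

    per_sample_ratio: pd.Series
    per_peak: pd.DataFrame  # peaks x samples enrichment scores

    def n_enriched_ge(self, threshold: float) -> pd.Series:
        """Per peak: number of samples with enrichment >= threshold."""
        return (self.per_peak >= threshold).sum(axis=1)


def merge_peaks(per_sample_peak_sets: list, min_support: int = 2, width: int = 300) -> pd.DataFrame:
    """Merge per-sample peak calls into consensus fixed-width peaks.

    Overlapping intervals across samples are unioned; union regions supported
    by fewer than ``min_support`` distinct samples are dropped. Each retained
    region becomes one ``width``-bp peak centered on the median of the
    contributing summits (lower coordinate on half-integer medians).
    """
    rows = []
    for si, df in enumerate(per_sample_peak_sets):
        if df is None or len(df) == 0:
            continue
        for c in ("chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"peak set {si}: missing column {c}")
        summit = df["summit"] if "summit" in df.columns else (df["start"] + df["end"]) // 2
        for chrom, s, e, sm in zip(df["chrom"], df["start"], df["end"], summit):
            if e <= s:
                raise ValueError(f"peak set {si}: malformed interval {chrom}:{s}-{e}")
            rows.append((chrom, int(s), int(e), int(sm), si))
    if not rows:
        return pd.DataFrame(columns=PEAK_COLS)
    pooled = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "sample"])
    pooled = pooled.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    out = []
    for chrom, grp in pooled.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur = [0]
        cur_end = ends[0]
        for i in range(1, len(grp)):
            if starts[i] < cur_end:  # strict: bookended intervals do not overlap
                cur.append(i)
                cur_end = max(cur_end, ends[i])
            else:
                out.append((chrom, grp.iloc[cur]))
                cur = [i]
                cur_end = ends[i]
        out.append((chrom, grp.iloc[cur]))

    peaks = []
    for chrom, members in out:
        support = members["sample"].nunique()
        if support < min_support:
            continue
        med = np.median(members["summit"].to_numpy())
        summit = int(np.floor(med))
        start = summit - width // 2
        peaks.append((chrom, start, start + width, summit, support))
    res = pd.DataFrame(peaks, columns=["chrom", "start", "end", "summit", "support"])
    res = res.drop_duplicates(["chrom", "start", "end"]).sort_values(["chrom", "start"]).reset_index(drop=True)
    res["name"] = [f"peak{i:05d}" for i in range(len(res))]
    return res[["chrom", "start", "end", "name", "summit", "support"]]


def quantify(fragments_per_sample: dict, peaks: pd.DataFrame, extend: int = 300) -> CountMatrix:
    """Count extended fragments overlapping each peak by >=1 bp.

    Each fragment is extended to ``extend`` bp from its start; a fragment is
    counted once per peak it overlaps. Fragments on chromosomes absent from
    the peak set contribute only to library size.
    """
    samples = list(fragments_per_sample)
    n_g = len(peaks)
    counts = np.zeros((n_g, len(samples)), dtype=np.int64)
    lib = np.zeros(len(samples), dtype=np.int64)
    pk_by_chrom = {c: g for c, g in peaks.reset_index().groupby("chrom")}
    for si, sample in enumerate(samples):
        frags = fragments_per_sample[sample]
        lib[si] = len(frags)
        for chrom, g in frags.groupby("chrom"):
            if chrom not in pk_by_chrom:
                continue
            pk = pk_by_chrom[chrom]
            fs = np.sort(g["start"].to_numpy())
            ps = pk["start"].to_numpy()
            pe = pk["end"].to_numpy()
            # fragment [f, f+extend) overlaps peak [s, e) iff s - extend < f < e
            hi = np.searchsorted(fs, pe, side="left")
            lo = np.searchsorted(fs, ps - extend, side="right")
            counts[pk["index"].to_numpy(), si] += hi - lo
    return CountMatrix(peaks=peaks.reset_index(drop=True), samples=samples,
                       counts=counts, lib_size=np.maximum(lib, counts.sum(axis=0)))


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """edgeR-style TMM factor of one sample against the reference (log2)."""
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        raise ValueError("no peak with positive counts in both sample and reference")
    o, r = obs[ok].astype(float), ref[ok].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)  # asymptotic var of M
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    lo_a = np.floor(n * trim_a) + 1
    keep = ((stats.rankdata(m) >= lo_m) & (stats.rankdata(m) <= n + 1 - lo_m)
            & (stats.rankdata(a) >= lo_a) & (stats.rankdata(a) <= n + 1 - lo_a))
    if not keep.any():
        keep = np.ones(n, dtype=bool)
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                ref: str = "auto") -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples (overridable by sample id).
    """
    if len(cm.samples) < 2:
        raise ValueError("TMM needs >= 2 samples")
    counts = cm.counts.astype(float)
    lib = cm.lib_size.astype(float)
    q75 = np.array([np.quantile(counts[:, k][counts[:, k] >= 0], 0.75) / lib[k]
                    for k in range(len(cm.samples))])
    if ref == "auto":
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        if ref not in cm.samples:
            raise ValueError(f"unknown reference sample {ref!r}")
        ref_idx = cm.samples.index(ref)
    log2f = np.zeros(len(cm.samples))
    for k in range(len(cm.samples)):
        if k == ref_idx:
            continue
        try:
            log2f[k] = _tmm_pair(counts[:, k], counts[:, ref_idx], lib[k], lib[ref_idx],
                                 trim_m, trim_a)
        except ValueError as exc:
            raise ValueError(f"sample {cm.samples[k]!r}: {exc}") from exc
    f = 2.0 ** log2f
    f = f / np.exp(np.mean(np.log(f)))
    return f


def shuffle_peaks(peaks: pd.DataFrame, allowed: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Place each peak uniformly in the allowed space, non-overlapping."""
    allowed = merge_intervals(allowed)
    lens = (allowed["end"] - allowed["start"]).to_numpy()
    total = int(lens.sum())
    widths = (peaks["end"] - peaks["start"]).to_numpy()
    if total < int(widths.sum()):
        raise ValueError("allowed space smaller than total peak length")
    cum = np.concatenate([[0], np.cumsum(lens)])
    placed = []
    occupied = []  # (chrom, start, end) to reject overlaps
    for w in sorted(widths, reverse=True):
        for _ in range(10_000):
            x = rng.random() * total
            i = int(np.searchsorted(cum, x, side="right") - 1)
            start = int(allowed["start"].iloc[i] + (x - cum[i]))
            chrom = allowed["chrom"].iloc[i]
            end = start + int(w)
            if end > allowed["end"].iloc[i]:
                continue
            if any(c == chrom and s < end and e > start for c, s, e in occupied):
                continue
            occupied.append((chrom, start, end))
            placed.append((chrom, start, end))
            break
        else:
            raise ValueError("could not place shuffled peak without overlap")
    return pd.DataFrame(placed, columns=["chrom", "start", "end"])


def shuffle_enrichment(fragments_per_sample: dict, peaks: pd.DataFrame, mappable: pd.DataFrame,
                       blacklist: pd.DataFrame, excluded_regions: pd.DataFrame | None = None,
                       n_shuffles: int = 1, extend: int = 300, seed: int = 0,
                       pseudo_floor: float = 0.5) -> EnrichmentReport:
    """Reads-in-peaks over reads-in-shuffled-peaks enrichment QC.

    Peaks are re-placed uniformly over mappable minus blacklist minus
    excluded regions. The per-sample ratio divides total reads overlapping
    the real peaks by the mean (over shuffles) of reads overlapping shuffled
    peaks; per-peak scores divide observed reads by the median shuffled-peak
    read count, floored at ``pseudo_floor``.
    """
    allowed = subtract_intervals(mappable, blacklist)
    if excluded_regions is not None and len(excluded_regions):
        allowed = subtract_intervals(allowed, excluded_regions)
    if total_length(allowed) < int((peaks["end"] - peaks["start"]).sum()):
        raise ValueError("insufficient allowed space for shuffling")
    rng = np.random.default_rng(seed)
    obs = quantify(fragments_per_sample, peaks, extend=extend)
    shuf_totals = np.zeros((n_shuffles, len(obs.samples)))
    shuf_medians = np.zeros((n_shuffles, len(obs.samples)))
    for b in range(n_shuffles):
        sh = shuffle_peaks(peaks, allowed, rng)
        sh = sh.assign(name=[f"shuf{i}" for i in range(len(sh))],
                       summit=(sh["start"] + sh["end"]) // 2)
        qm = quantify(fragments_per_sample, sh, extend=extend)
        shuf_totals[b] = qm.counts.sum(axis=0)
        shuf_medians[b] = np.median(qm.counts, axis=0)
    denom_sample = np.maximum(shuf_totals.mean(axis=0), pseudo_floor)
    ratio = pd.Series(obs.counts.sum(axis=0) / denom_sample, index=obs.samples)
    denom_peak = np.maximum(np.median(shuf_medians, axis=0), pseudo_floor)
    per_peak = pd.DataFrame(obs.counts / denom_peak[None, :],
                            index=obs.peaks["name"], columns=obs.samples)
    return EnrichmentReport(per_sample_ratio=ratio, per_peak=per_peak)


def replicate_concordance(cm: CountMatrix, replicate_pairs: list, n_perm: int = 10000,
                          seed: int = 0) -> dict:
    """Within-pair vs between-pair Spearman correlation with a permutation p.

    The observed statistic is (mean within-pair rho) - (mean between-pair
    rho); the null re-pairs samples at random. p = (1 + #{perm >= obs}) /
    (1 + n_perm).
    """
    if len(replicate_pairs) < 2:
        raise ValueError("need >= 2 replicate pairs")
    idx = {s: i for i, s in enumerate(cm.samples)}
    for a, b in replicate_pairs:
        if a not in idx or b not in idx:
            raise ValueError(f"pair ({a}, {b}) references missing sample")
    mat = cm.cpm_log2()
    rho = stats.spearmanr(mat).statistic
    if np.isscalar(rho):
        rho = np.array([[1.0, rho], [rho, 1.0]])
    pair_idx = [(idx[a], idx[b]) for a, b in replicate_pairs]
    n = len(cm.samples)

    def statistic(pairs):
        within = np.array([rho[a, b] for a, b in pairs])
        mask = np.ones_like(rho, dtype=bool)
        np.fill_diagonal(mask, False)
        for a, b in pairs:
            mask[a, b] = mask[b, a] = False
        between = rho[np.triu(mask)]
        return within.mean() - between.mean(), within.mean(), between.mean()

    obs_stat, within_mean, between_mean = statistic(pair_idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pairs = [(perm[2 * i], perm[2 * i + 1]) for i in range(len(pair_idx))]
        if statistic(pairs)[0] >= obs_stat:
            hits += 1
    return {"within_mean": float(within_mean), "between_mean": float(between_mean),
            "statistic": float(obs_stat), "p": (1 + hits) / (1 + n_perm)}


def jaccard(peakset_a: pd.DataFrame, peakset_b: pd.DataFrame) -> float:
    """Base-pair Jaccard index of two (merged) interval sets."""
    inter = total_length(intersect_intervals(peakset_a, peakset_b))
    union = total_length(pd.concat([peakset_a[["chrom", "start", "end"]],
                                    peakset_b[["chrom", "start", "end"]]]))
    return inter / union if union else 0.0


def tss_annotate(peaks: pd.DataFrame, tss: pd.DataFrame,
                 near: int = 5000, far: int = 25000) -> pd.DataFrame:
    """Signed distance from peak center to nearest TSS with distance class.

    Distance sign follows the TSS strand: positive = the peak lies
    downstream of (inward from) the TSS. Class boundaries are closed at
    ``near`` and ``far``. Chromosomes without any TSS get +inf / ">25kb".
    """
    if len(tss) == 0:
        raise ValueError("TSS list is empty")
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    dist = np.full(len(peaks), np.inf)
    signed = np.full(len(peaks), np.inf)
    orient = np.array(["none"] * len(peaks), dtype=object)
    for chrom, g in tss.groupby("chrom"):
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tp = np.sort(g["pos"].to_numpy())
        order = np.argsort(g["pos"].to_numpy())
        strands = g["strand"].to_numpy()[order]
        c = centers[mask]
        j = np.clip(np.searchsorted(tp, c), 0, len(tp) - 1)
        jm = np.clip(j - 1, 0, len(tp) - 1)
        pick = np.where(np.abs(tp[j] - c) <= np.abs(tp[jm] - c), j, jm)
        d = c - tp[pick]
        sgn = np.where(strands[pick] == "+", 1, -1)
        signed[mask] = d * sgn
        dist[mask] = np.abs(d)
        orient[mask] = np.where(signed[mask] >= 0, "downstream", "upstream")
    cls = np.where(dist <= near, f"±{near // 1000}kb",
                   np.where(dist <= far, f"{near // 1000}–{far // 1000}kb", f">{far // 1000}kb"))
    return pd.DataFrame({"name": peaks["name"].to_numpy() if "name" in peaks else np.arange(len(peaks)),
                         "distance": signed, "abs_distance": dist,
                         "tss_class": cls, "orientation": orient})
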