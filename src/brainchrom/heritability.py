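"""Partitioned LD scores and stratified heritability regression.

LD scores sum small-sample-adjusted squared genotype correlations within a
physical window per annotation category. The regression fits chi-square
statistics on N-scaled category LD scores with heteroskedasticity weights;
per-category heritability shares, fold enrichments, and block-jackknife
standard errors follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import points_in_intervals
from .synthgen import Genotypes

DEFAULT_WIDTHS = (100, 300, 1000, 2000, 5000, 10000)


@dataclass
class AnnotationMatrix:
    """SNP x category binary indicators; first category must cover all SNPs."""

    matrix: np.ndarray
    names: list

    def __post_init__(self):
        a = np.asarray(self.matrix)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("annotation entries must be 0/1")
        if not (a[:, 0] == 1).all():
            raise ValueError("first category must be the all-SNP base")
        self.matrix = a.astype(float)

    @property
    def prop_snps(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


@dataclass
class PartitionResult:
    categories: list
    tau: np.ndarray
    tau_se: np.ndarray
    coefficient_z: np.ndarray
    prop_snps: np.ndarray
    prop_h2: np.ndarray
    enrichment: np.ndarray
    enrichment_se: np.ndarray
    enrichment_p: np.ndarray
    intercept: float
    h2_total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": self.categories, "tau": self.tau, "tau_se": self.tau_se,
            "coefficient_z": self.coefficient_z, "prop_snps": self.prop_snps,
            "prop_h2": self.prop_h2, "enrichment": self.enrichment,
            "enrichment_se": self.enrichment_se, "enrichment_p": self.enrichment_p,
        })


def ld_scores(dosages_ref: Genotypes | np.ndarray, snp_map: pd.DataFrame,
              annotations: np.ndarray, window_bp: int = 1_000_000,
              chunk: int = 2000) -> np.ndarray:
    """Per-SNP per-category LD scores l(j, c).

    l(j, c) = sum over SNPs k in the window with a_kc = 1 of
    r2_adj(j, k), where r2_adj = r2 - (1 - r2) / (n - 2) removes the
    finite-reference-panel bias. The self term (r2 = 1) is included for
    j in c.
    """
    X = dosages_ref.dosages if isinstance(dosages_ref, Genotypes) else np.asarray(dosages_ref)
    A = np.asarray(annotations, dtype=float)
    M, n = X.shape
    if A.shape[0] != M:
        raise ValueError("annotation rows must match SNPs")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((X - mu) / sd) / np.sqrt(n)  # so Z @ Z.T is the correlation matrix
    pos = snp_map["pos"].to_numpy()
    chrom = snp_map["chrom"].to_numpy()
    out = np.zeros((M, A.shape[1]))
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order = idx[np.argsort(pos[idx], kind="mergesort")]
        cpos = pos[order]
        Zc = Z[order]
        Ac = A[order]
        for lo in range(0, len(order), chunk):
            hi = min(lo + chunk, len(order))
            jlo = int(np.searchsorted(cpos, cpos[lo] - window_bp, side="left"))
            jhi = int(np.searchsorted(cpos, cpos[hi - 1] + window_bp, side="right"))
            r = Zc[lo:hi] @ Zc[jlo:jhi].T
            r2 = r ** 2
            r2_adj = r2 - (1 - r2) / (n - 2)
            mask = np.abs(cpos[lo:hi, None] - cpos[None, jlo:jhi]) <= window_bp
            out[order[lo:hi]] = (r2_adj * mask) @ Ac[jlo:jhi]
    return out


def stratified_regression(chi2: np.ndarray, ldscores: np.ndarray, annotations: np.ndarray,
                          n_gwas: float, n_blocks: int = 20) -> PartitionResult:
    """Stratified LD-score regression with block-jackknife uncertainty.

    Regresses chi2_j on {N * l(j, c)} plus an intercept with weights
    1 / max(l_base, 1). tau_c converts to per-category heritability via
    h2_c = sum_{j in c} sum_c' tau_c' a_jc'; enrichment = prop_h2 /
    prop_snps with leave-one-block-out SEs; coefficient z = tau / SE(tau).
    """
    chi2 = np.asarray(chi2, dtype=float)
    L = np.asarray(ldscores, dtype=float)
    A = np.asarray(annotations, dtype=float)
    M, C = L.shape
    if np.linalg.matrix_rank(A.T @ A) < C:
        raise ValueError("annotation categories are collinear")
    X = np.column_stack([np.ones(M), n_gwas * L])
    w = 1.0 / np.maximum(L[:, 0], 1.0)
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = chi2 * sw

    def solve(xw, yw_):
        coef, *_ = np.linalg.lstsq(xw, yw_, rcond=None)
        return coef

    def summarize(coef):
        tau = coef[1:]
        per_snp_h2 = A @ tau
        h2_tot = per_snp_h2.sum()
        h2_c = A.T @ per_snp_h2
        prop_h2 = h2_c / h2_tot if h2_tot != 0 else np.full(C, np.nan)
        enr = prop_h2 / A.mean(axis=0)
        return tau, prop_h2, enr, h2_tot

    coef_full = solve(Xw, yw)
    tau, prop_h2, enrich, h2_tot = summarize(coef_full)

    blocks = np.array_split(np.arange(M), n_blocks)
    tau_jk = np.empty((n_blocks, C))
    enr_jk = np.empty((n_blocks, C))
    for b, idx in enumerate(blocks):
        keep = np.ones(M, dtype=bool)
        keep[idx] = False
        coef_b = solve(Xw[keep], yw[keep])
        tau_b = coef_b[1:]
        per_snp = A[keep] @ tau_b
        h2b = per_snp.sum()
        h2_cb = A[keep].T @ per_snp
        prop_b = h2_cb / h2b if h2b != 0 else np.full(C, np.nan)
        enr_jk[b] = prop_b / A[keep].mean(axis=0)
        tau_jk[b] = tau_b

    def jk_se(est):
        m = est.mean(axis=0)
        return np.sqrt((n_blocks - 1) / n_blocks * ((est - m) ** 2).sum(axis=0))

    tau_se = jk_se(tau_jk)
    enr_se = jk_se(enr_jk)
    z = np.divide(tau, tau_se, out=np.zeros(C), where=tau_se > 0)
    t_enr = np.divide(enrich - 1.0, enr_se, out=np.zeros(C), where=enr_se > 0)
    p_enr = 2 * stats.t.sf(np.abs(t_enr), n_blocks - 1)
    return PartitionResult(
        categories=[f"cat{i}" for i in range(C)], tau=tau, tau_se=tau_se,
        coefficient_z=z, prop_snps=A.mean(axis=0), prop_h2=prop_h2,
        enrichment=enrich, enrichment_se=enr_se, enrichment_p=p_enr,
        intercept=float(coef_full[0]), h2_total=float(h2_tot))


def enrichment_stat(prop_h2: float, prop_snps: float) -> float:
    """Fold enrichment = share of h2 over share of SNPs."""
    if prop_snps <= 0:
        raise ValueError("prop_snps must be > 0")
    return prop_h2 / prop_snps


def resize_peaks(peaks: pd.DataFrame, width: int, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Resize peaks about their summit, clipping to chromosome bounds."""
    half = width // 2
    out = peaks.copy()
    out["start"] = peaks["summit"] - half
    out["end"] = out["start"] + width
    clipped = 0
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            m = out["chrom"] == chrom
            clipped += int(((out.loc[m, "start"] < 0) | (out.loc[m, "end"] > size)).sum())
            out.loc[m, "start"] = out.loc[m, "start"].clip(lower=0)
            out.loc[m, "end"] = out.loc[m, "end"].clip(upper=size)
    else:
        clipped = int((out["start"] < 0).sum())
        out["start"] = out["start"].clip(lower=0)
    out.attrs["n_clipped"] = clipped
    return out


def build_annotations(snp_map: pd.DataFrame, peaks: pd.DataFrame,
                      conserved: pd.DataFrame | None = None,
                      gwa_loci: pd.DataFrame | None = None,
                      widths: tuple = (300,), pad: int = 500,
                      chrom_sizes: dict | None = None) -> AnnotationMatrix:
    """SNP annotation matrix: base, per-width peak sets with padded
    companions, conserved, conserved-within-peak, and GWA-locus membership.

    The padded companion is the +-pad flank *excluding* the peak itself, so
    the two categories partition the padded interval.
    """
    chroms = snp_map["chrom"].to_numpy()
    pos = snp_map["pos"].to_numpy()
    cols = [np.ones(len(snp_map))]
    names = ["base"]
    peak300 = None
    for w in widths:
        pk = resize_peaks(peaks, w, chrom_sizes)
        inside = points_in_intervals(chroms, pos, pk)
        padded = pk.copy()
        padded["start"] = (padded["start"] - pad).clip(lower=0)
        padded["end"] = padded["end"] + pad
        in_pad = points_in_intervals(chroms, pos, padded) & ~inside
        cols += [inside.astype(float), in_pad.astype(float)]
        names += [f"peak_{w}bp", f"peak_{w}bp_pad{pad}"]
        if w == 300:
            peak300 = inside
    if conserved is not None and len(conserved):
        cons = points_in_intervals(chroms, pos, conserved)
        cols.append(cons.astype(float))
        names.append("conserved")
        if peak300 is not None:
            cols.append((cons & peak300).astype(float))
            names.append("conserved_in_peak")
    if gwa_loci is not None and len(gwa_loci):
        cols.append(points_in_intervals(chroms, pos, gwa_loci).astype(float))
        names.append("gwa_locus")
    return AnnotationMatrix(np.column_stack(cols), names)


def width_experiment(sumstats: pd.DataFrame, ref: Genotypes, peaks: pd.DataFrame,
                     widths: tuple = DEFAULT_WIDTHS, pad: int = 500,
                     window_bp: int = 1_000_000, n_blocks: int = 20,
                     chrom_sizes: dict | None = None) -> pd.DataFrame:
    """Heritability enrichment of the peak annotation at each peak width."""
    chi2 = sumstats["Z"].to_numpy() ** 2
    n_gwas = float(sumstats["N"].iloc[0])
    rows = []
    for w in widths:
        ann = build_annotations(ref.snp_map, peaks, widths=(w,), pad=pad,
                                chrom_sizes=chrom_sizes)
        L = ld_scores(ref, ref.snp_map, ann.matrix, window_bp)
        res = stratified_regression(chi2, L, ann.matrix, n_gwas, n_blocks)
        i = ann.names.index(f"peak_{w}bp")
        rows.append({"width": w, "enrichment": res.enrichment[i],
                     "enrichment_se": res.enrichment_se[i],
                     "prop_snps": res.prop_snps[i], "prop_h2": res.prop_h2[i],
                     "coefficient_z": res.coefficient_z[i]})
    return pd.DataFrame(rows)
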