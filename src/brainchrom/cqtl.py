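"""Cis-window chromatin QTL mapping with permutation-calibrated significance.

Phenotypes (normalized peak quantifications) and dosages are residualized
against covariates once; per-SNP slopes use the t distribution with the
covariate-adjusted degrees of freedom. Peak-level significance fits a
Beta(a, b) distribution to the permutation minima of the nominal p across
the cis window, and Storey q-values control FDR across peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc

from .diffaccess import bh_fdr


@dataclass
class CisResult:
    peak: str
    n_snps: int
    top_snp: str | None
    beta: float
    se: float
    p_nominal: float
    a_hat: float
    b_hat: float
    p_adjusted: float
    fallback: bool = False


def _residualize_cols(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(C)
    return y - q @ (q.T @ y)


def cis_snps(snp_map: pd.DataFrame, chrom: str, center: int, window: int) -> pd.DataFrame:
    """SNPs within ``window`` bp of the peak center, boundary inclusive."""
    g = snp_map[snp_map["chrom"] == chrom]
    d = (g["pos"] - center).abs()
    return g[d <= window]


def _scan_stats(y_r: np.ndarray, G_r: np.ndarray, dof: int) -> tuple:
    """Slopes, ses, and p-values of y on each residualized dosage column."""
    gss = (G_r ** 2).sum(axis=0)
    gss = np.where(gss <= 0, np.nan, gss)
    beta = (G_r.T @ y_r) / gss
    resid_ss = (y_r ** 2).sum() - beta ** 2 * gss
    sigma2 = np.maximum(resid_ss, 0) / dof
    se = np.sqrt(sigma2 / gss)
    t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, p


def map_cis(norm_counts: np.ndarray, peaks: pd.DataFrame, dosages: np.ndarray,
            snp_map: pd.DataFrame, covariates: np.ndarray, window: int = 5000) -> pd.DataFrame:
    """Per-peak nominal cis scan; retain the most significant SNP.

    ``norm_counts``: peaks x samples normalized phenotypes; ``dosages``:
    SNPs x samples. Ties on p go to the SNP nearest the peak center, then
    lexicographic id. Peaks without cis SNPs get NA results.
    """
    C = np.column_stack([np.ones(norm_counts.shape[1]), covariates]) \
        if covariates is not None and covariates.size else np.ones((norm_counts.shape[1], 1))
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    Y_r = _residualize_cols(norm_counts.T, C)  # samples x peaks
    G_r = _residualize_cols(dosages.T, C)  # samples x snps
    dof = norm_counts.shape[1] - C.shape[1] - 1
    snp_pos = {s: p for s, p in zip(snp_map["snp"], snp_map["pos"])}
    snp_row = {s: i for i, s in enumerate(snp_map["snp"])}

    rows = []
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    for gi in range(len(peaks)):
        chrom, center = peaks["chrom"].iloc[gi], int(centers[gi])
        cs = cis_snps(snp_map, chrom, center, window)
        if len(cs) == 0:
            rows.append((peaks["name"].iloc[gi], 0, None, np.nan, np.nan, np.nan))
            continue
        cols = np.array([snp_row[s] for s in cs["snp"]])
        beta, se, p = _scan_stats(Y_r[:, gi], G_r[:, cols], dof)
        dist = np.abs(cs["pos"].to_numpy() - center)
        order = np.lexsort((cs["snp"].to_numpy(), dist, p))
        j = order[0]
        rows.append((peaks["name"].iloc[gi], len(cs), cs["snp"].iloc[j],
                     float(beta[j]), float(se[j]), float(p[j])))
    return pd.DataFrame(rows, columns=["peak", "n_snps", "top_snp", "beta", "se", "p_nominal"])


def fit_beta_null(min_ps: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> tuple:
    """Beta(a, b) MLE for permutation minimum p-values.

    Method-of-moments start, Newton refinement on the log-likelihood (via
    scipy's constrained Beta fit); falls back to the moment estimate when
    the likelihood optimization fails.
    """
    x = np.clip(np.asarray(min_ps, dtype=float), 1e-300, 1 - 1e-16)
    m, v = x.mean(), x.var()
    if v <= 0:
        raise ValueError("degenerate permutation distribution")
    common = m * (1 - m) / v - 1
    a0, b0 = max(m * common, 1e-3), max((1 - m) * common, 1e-3)
    try:
        a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0, fscale=1)
        if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
            raise ValueError
        return float(a), float(b)
    except Exception:
        return float(a0), float(b0)


def perm_adjust(peak_phenotype: np.ndarray, cis_dosages: np.ndarray, covariates: np.ndarray,
                n_perm: int = 1000, seed: int = 0) -> dict:
    """Beta-approximated permutation p for a peak's cis scan.

    Permutes the residualized phenotype, records the per-permutation minimum
    nominal p over the cis SNPs, fits Beta(a, b), and evaluates its CDF at
    the observed minimum p. Degenerate permutation distributions fall back
    to the empirical permutation p with a flag.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if cis_dosages.ndim == 1:
        cis_dosages = cis_dosages[:, None] if cis_dosages.shape[0] == len(peak_phenotype) \
            else cis_dosages[None, :].T
    n = len(peak_phenotype)
    C = np.column_stack([np.ones(n), covariates]) \
        if covariates is not None and covariates.size else np.ones((n, 1))
    y_r = _residualize_cols(peak_phenotype[:, None], C)[:, 0]
    G_r = _residualize_cols(cis_dosages.T if cis_dosages.shape[0] != n else cis_dosages, C)
    dof = n - C.shape[1] - 1
    _, _, p_obs = _scan_stats(y_r, G_r, dof)
    p_min = float(np.nanmin(p_obs))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Yp = y_r[perms]  # n_perm x n
    gss = (G_r ** 2).sum(axis=0)
    gss = np.where(gss <= 0, np.nan, gss)
    bet = (Yp @ G_r) / gss[None, :]
    yss = (y_r ** 2).sum()
    sigma2 = np.maximum(yss - bet ** 2 * gss[None, :], 0) / dof
    se = np.sqrt(sigma2 / gss[None, :])
    t = np.divide(bet, se, out=np.zeros_like(bet), where=se > 0)
    pp = 2 * stats.t.sf(np.abs(t), dof)
    null_min = np.nanmin(pp, axis=1)

    empirical = (1 + np.sum(null_min <= p_min)) / (1 + n_perm)
    if np.std(null_min) < 1e-12:
        return {"a_hat": np.nan, "b_hat": np.nan, "p_adjusted": empirical,
                "p_nominal": p_min, "empirical_p": empirical, "fallback": True}
    a, b = fit_beta_null(null_min)
    return {"a_hat": a, "b_hat": b, "p_adjusted": float(betainc(a, b, p_min)),
            "p_nominal": p_min, "empirical_p": empirical, "fallback": False}


def storey_qvalue(p_values, lambda_grid: np.ndarray | None = None) -> tuple:
    """Storey q-values with cubic-smoother pi0 estimation.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) on a 0.05..0.95 grid,
    extrapolated to lambda = 1 with a cubic polynomial fit, clipped to
    (0, 1]. q = pi0 x BH step-up. Falls back to pi0 = 1 (pure BH) when the
    p-value set is too small to support the grid.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    if m < 4 * len(lambda_grid):
        import warnings
        warnings.warn("too few p-values for pi0 smoothing; using pi0 = 1")
        pi0 = 1.0
    else:
        pi0_l = np.array([(p[ok] > lam).mean() / (1 - lam) for lam in lambda_grid])
        coef = np.polyfit(lambda_grid, pi0_l, 3)
        pi0 = float(np.clip(np.polyval(coef, 1.0), 1e-8, 1.0))
    q = bh_fdr(p) * pi0
    return np.minimum(q, 1.0), pi0


def map_cis_permuted(norm_counts: np.ndarray, peaks: pd.DataFrame, dosages: np.ndarray,
                     snp_map: pd.DataFrame, covariates: np.ndarray, window: int = 5000,
                     n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Full cQTL scan: nominal top SNP + beta-approximated permutation p + Storey q."""
    nominal = map_cis(norm_counts, peaks, dosages, snp_map, covariates, window)
    centers = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    snp_row = {s: i for i, s in enumerate(snp_map["snp"])}
    rng = np.random.default_rng(seed)
    a_hat = np.full(len(peaks), np.nan)
    b_hat = np.full(len(peaks), np.nan)
    p_adj = np.full(len(peaks), np.nan)
    fallback = np.zeros(len(peaks), dtype=bool)
    for gi in range(len(peaks)):
        if nominal["n_snps"].iloc[gi] == 0:
            continue
        cs = cis_snps(snp_map, peaks["chrom"].iloc[gi], int(centers[gi]), window)
        cols = np.array([snp_row[s] for s in cs["snp"]])
        res = perm_adjust(norm_counts[gi], dosages[cols].T, covariates,
                          n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
        a_hat[gi], b_hat[gi] = res["a_hat"], res["b_hat"]
        p_adj[gi] = res["p_adjusted"]
        fallback[gi] = res["fallback"]
    out = nominal.assign(a_hat=a_hat, b_hat=b_hat, p_adjusted=p_adj, fallback=fallback)
    q, pi0 = storey_qvalue(out["p_adjusted"].to_numpy())
    out["q"] = q
    out.attrs["pi0"] = pi0
    return out


def interaction_scan(norm_counts: np.ndarray, peaks: pd.DataFrame, dosages_top: np.ndarray,
                     diagnosis: np.ndarray, covariates: np.ndarray,
                     n_perm: int = 10000, seed: int = 0) -> pd.DataFrame:
    """Genotype x diagnosis interaction with a label-permutation null.

    For each peak, fits phenotype ~ dosage + diagnosis + dosage:diagnosis on
    covariate-residualized data; the null permutes diagnosis labels.
    Exact p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm); Storey q across
    peaks.
    """
    dx = np.asarray(diagnosis)
    levels = np.unique(dx)
    if len(levels) != 2:
        raise ValueError("need both diagnosis levels present")
    d = (dx == levels[-1]).astype(float)
    n = norm_counts.shape[1]
    C = np.column_stack([np.ones(n), covariates]) \
        if covariates is not None and covariates.size else np.ones((n, 1))
    Y_r = _residualize_cols(norm_counts.T, C)
    G_r = _residualize_cols(dosages_top.T, C)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    def t_interaction(y, g, dvec):
        X = np.column_stack([np.ones(n), g, dvec, g * dvec])
        XtX = X.T @ X
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            return np.nan
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        dof = n - X.shape[1] - (C.shape[1] - 1)
        s2 = (resid ** 2).sum() / max(dof, 1)
        se = np.sqrt(s2 * XtX_inv[3, 3])
        return beta[3] / se if se > 0 else 0.0

    rows = []
    for gi in range(norm_counts.shape[0]):
        y, g = Y_r[:, gi], G_r[:, gi]
        t_obs = t_interaction(y, g, d)
        hits = 0
        for b in range(n_perm):
            t_b = t_interaction(y, g, d[perms[b]])
            if np.abs(t_b) >= np.abs(t_obs):
                hits += 1
        rows.append((peaks["name"].iloc[gi], float(t_obs), (1 + hits) / (1 + n_perm)))
    out = pd.DataFrame(rows, columns=["peak", "t_interaction", "p"])
    out["q"], out.attrs["pi0"] = storey_qvalue(out["p"].to_numpy())
    return out


def allele_bias_analysis(records: pd.DataFrame, cqtl_results: pd.DataFrame,
                         min_depth: int = 10, n_bins: int = 10) -> dict:
    """Allelic-imbalance validation of cQTLs.

    Concordance: fraction of cQTL SNPs whose pooled alt-read fraction
    deviates from 0.5 in the direction of the cQTL's alt-allele effect.
    The chi-square compares the binned alt-fraction histograms of cQTL vs
    non-cQTL heterozygote records (bins closed on the right).
    """
    rec = records[(records["ref_reads"] + records["alt_reads"]) >= min_depth].copy()
    betas = dict(zip(cqtl_results["snp"] if "snp" in cqtl_results else cqtl_results["top_snp"],
                     cqtl_results["beta"]))
    is_cqtl = rec["snp"].map(lambda s: s in betas and betas[s] != 0)
    per_snp = rec.groupby("snp").agg(
        mean_alt=("alt_fraction", "mean"), n_het=("alt_fraction", "size")).reset_index()
    per_snp["is_cqtl"] = per_snp["snp"].map(lambda s: s in betas and betas[s] != 0)
    skipped = 0
    agree = []
    for _, row in per_snp[per_snp["is_cqtl"]].iterrows():
        b = betas[row["snp"]]
        dev = row["mean_alt"] - 0.5
        if dev == 0:
            skipped += 1
            continue
        agree.append(np.sign(dev) == np.sign(b))
    concordance = float(np.mean(agree)) if agree else np.nan

    edges = np.linspace(0, 1, n_bins + 1)
    h_c = np.histogram(rec.loc[is_cqtl, "alt_fraction"], bins=edges)[0]
    h_n = np.histogram(rec.loc[~is_cqtl, "alt_fraction"], bins=edges)[0]
    tab = np.column_stack([h_c, h_n])
    tab = tab[tab.sum(axis=1) > 0]
    if tab.shape[0] >= 2 and (tab.sum(axis=0) > 0).all():
        from .covariates import chi2_no_correction
        chi2, p = chi2_no_correction(tab)
    else:
        chi2, p = np.nan, np.nan
    return {"concordance": concordance, "n_concordant_tested": len(agree),
            "chi2": chi2, "chi2_p": p, "per_snp": per_snp, "n_skipped": skipped}
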