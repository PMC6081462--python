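"""Per-peak negative-binomial differential accessibility with sex-aware routing.

Autosomal peaks use the full-cohort NB GLM; chrX peaks are fit separately in
males and females and combined by inverse-variance weighting; chrY peaks are
fit in males only with sex dropped from the design. Effects are reported as
log2 fold changes with Wald tests and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import _design_matrix
from .peakmatrix import CountMatrix

LN2 = np.log(2.0)


def fit_nb_glm(counts: np.ndarray, design: np.ndarray, offsets: np.ndarray,
               dispersion: np.ndarray | float, max_iter: int = 50,
               tol: float = 1e-8) -> dict:
    """Batched NB regression with log link at fixed dispersion.

    ``counts`` is peaks x samples (a single row is fine); the design is
    shared across peaks, so IRLS runs on all peaks at once via batched
    weighted least squares. Returns natural-log betas, covariances, and
    convergence flags.
    """
    y = np.atleast_2d(np.asarray(counts, dtype=float))
    G, n = y.shape
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    off = np.broadcast_to(np.asarray(offsets, dtype=float), (n,))
    if not np.all(np.isfinite(off)):
        raise ValueError("offsets must be finite")
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()

    beta = np.zeros((G, X.shape[1]))
    # init intercept from mean rate
    beta[:, 0] = np.log(np.maximum(y.mean(axis=1) / np.exp(off).mean(), 1e-8))
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = beta[active] @ X.T + off[None, :]
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[active, None] * mu)
        z = eta - off[None, :] + (y[active] - mu) / mu
        xtwx = np.einsum("nk,gn,nl->gkl", X, w, X)
        xtwz = np.einsum("nk,gn,gn->gk", X, w, z)
        try:
            new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.einsum("gkl,gl->gk", np.linalg.pinv(xtwx), xtwz)
        step = new - beta[active]
        done = np.max(np.abs(step), axis=1) < tol
        beta[active] = new
        idx = np.flatnonzero(active)
        converged[idx[done]] = True
        active[idx[done]] = False

    eta = np.clip(beta @ X.T + off[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    info = np.einsum("nk,gn,nl->gkl", X, w, X)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.einsum("gkk->gk", cov), 0))
    wald = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(wald))
    p[~converged] = np.nan
    return {"beta": beta, "se": se, "cov": cov, "wald": wald, "p": p,
            "converged": converged, "mu": mu}


def fit_nb_peak(counts_row: np.ndarray, design_matrix: np.ndarray, offsets: np.ndarray,
                dispersion: float) -> dict:
    """Single-peak NB GLM; betas and Wald p per coefficient (log2 effect scale)."""
    res = fit_nb_glm(counts_row, design_matrix, offsets, dispersion)
    return {"beta_log2": res["beta"][0] / LN2, "se_log2": res["se"][0] / LN2,
            "wald": res["wald"][0], "p": res["p"][0], "converged": bool(res["converged"][0]),
            "cov": res["cov"][0]}


def estimate_dispersion(cm: CountMatrix, design: np.ndarray, floor: float = 1e-8,
                        shrink: float = 0.5) -> np.ndarray:
    """Method-of-moments per-peak dispersion with trend shrinkage.

    Fits a Poisson GLM for the means, computes the quadratic-variance MoM
    estimate, then shrinks 50/50 toward a 1/mean trend curve fit across
    peaks. Floored at ``floor``.
    """
    y = cm.counts.astype(float)
    if y.shape[1] < 2:
        raise ValueError("dispersion needs >= 2 samples")
    n, p = y.shape[1], design.shape[1]
    df_resid = n - p
    if df_resid < 8:
        import warnings
        warnings.warn(f"only {df_resid} residual degrees of freedom")
    off = np.log(np.maximum(cm.lib_size, 1) / np.median(cm.lib_size))
    fit = fit_nb_glm(y, design, off, 1e-8)
    mu = fit["mu"]
    num = ((y - mu) ** 2 - mu).sum(axis=1)
    den = (mu ** 2).sum(axis=1)
    raw = np.maximum(num / np.maximum(den, 1e-12) * n / max(df_resid, 1), floor)
    mean_count = y.mean(axis=1)
    ok = mean_count > 0
    # trend: alpha(mean) = a0 + a1/mean, least squares on raw estimates
    A = np.column_stack([np.ones(ok.sum()), 1.0 / mean_count[ok]])
    coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
    trend = np.maximum(coef[0] + coef[1] / np.maximum(mean_count, 1e-8), floor)
    return np.maximum((1 - shrink) * raw + shrink * trend, floor)


def bh_fdr(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values; NaNs propagate."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def ivw_meta(betas: np.ndarray, ses: np.ndarray) -> tuple:
    """Inverse-variance-weighted fixed-effect meta-analysis."""
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return beta, se


def differential_scan(cm: CountMatrix, metadata: pd.DataFrame, selected_covariates: list,
                      variable: str, dispersion: np.ndarray | None = None,
                      size_factor: str = "tmm") -> pd.DataFrame:
    """Scan every peak for an effect of ``variable`` with covariate adjustment.

    Offsets are log(lib_size x TMM factor) by default. Routing: autosomes ->
    full model; chrX -> male/female strata combined by IVW; chrY -> males
    only, sex dropped. BH FDR across all peaks of the scan. Betas are log2.
    """
    meta = metadata.set_index("sample").loc[cm.samples].reset_index()
    model_covs = [v for v in selected_covariates if v != variable]
    if "sex" in meta.columns and "sex" not in model_covs and variable != "sex":
        model_covs = ["sex"] + model_covs
    if size_factor == "tmm":
        f = cm.tmm_factor if cm.tmm_factor is not None else np.ones(len(cm.samples))
        eff = cm.lib_size * f
    elif size_factor == "median-ratio":
        logs = np.log(np.maximum(cm.counts, 0.5))
        ref = logs.mean(axis=1, keepdims=True)
        eff = np.exp(np.median(logs - ref, axis=0))
        eff = eff / np.exp(np.mean(np.log(eff)))
    else:
        raise ValueError("size_factor must be 'tmm' or 'median-ratio'")
    off_all = np.log(eff / np.median(eff)) if size_factor != "tmm" else np.log(eff / np.median(eff))

    def target_column(subset: pd.DataFrame) -> np.ndarray:
        s = subset[variable]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            return (x - x.mean()) / (x.std() or 1.0)
        levels = sorted(s.unique())
        # effect of 'case' (or of the second level) relative to the reference
        target = "case" if "case" in levels else levels[-1]
        return (s == target).to_numpy(dtype=float)

    def design_for(subset: pd.DataFrame, covs_: list):
        X = np.column_stack([_design_matrix(subset, covs_), target_column(subset)])
        return X, X.shape[1] - 1

    full_X, coef_idx = design_for(meta, model_covs)
    if dispersion is None:
        dispersion = estimate_dispersion(cm, full_X)

    chroms = cm.peaks["chrom"].to_numpy()
    is_x = chroms == "chrX"
    is_y = chroms == "chrY"
    is_auto = ~(is_x | is_y)
    sex = meta["sex"].to_numpy()
    rows = pd.DataFrame(index=np.arange(len(cm.peaks)),
                        columns=["beta", "se", "stat", "p", "route"], dtype=object)

    def fit_block(mask_peaks, mask_samples, covs_, route):
        if not mask_peaks.any():
            return
        sub = meta.loc[mask_samples].reset_index(drop=True)
        X, ci = design_for(sub, covs_)
        res = fit_nb_glm(cm.counts[np.ix_(mask_peaks, mask_samples)], X,
                         off_all[mask_samples], dispersion[mask_peaks])
        idx = np.flatnonzero(mask_peaks)
        rows.loc[idx, "beta"] = res["beta"][:, ci] / LN2
        rows.loc[idx, "se"] = res["se"][:, ci] / LN2
        rows.loc[idx, "stat"] = res["wald"][:, ci]
        rows.loc[idx, "p"] = res["p"][:, ci]
        rows.loc[idx, "route"] = route

    fit_block(is_auto, np.ones(len(meta), dtype=bool), model_covs, "full")

    strata_results = {}
    if is_x.any():
        for label, sel in (("M", sex == "M"), ("F", sex == "F")):
            if sel.sum() < 3:
                continue
            sub = meta.loc[sel].reset_index(drop=True)
            covs_x = [v for v in model_covs if v != "sex" and sub[v].nunique() > 1]
            if sub[variable].nunique() < 2:
                continue
            X, ci = design_for(sub, covs_x)
            res = fit_nb_glm(cm.counts[np.ix_(is_x, sel)], X, off_all[sel], dispersion[is_x])
            strata_results[label] = (res["beta"][:, ci] / LN2, res["se"][:, ci] / LN2,
                                     res["converged"])
        idx = np.flatnonzero(is_x)
        for k, gi in enumerate(idx):
            parts = [(b[k], s[k]) for b, s, c in strata_results.values()
                     if c[k] and np.isfinite(s[k]) and s[k] > 0]
            if len(parts) == 0:
                rows.loc[gi, ["beta", "se", "stat", "p", "route"]] = \
                    [np.nan, np.nan, np.nan, np.nan, "chrX-ivw-meta"]
                continue
            b, s = ivw_meta(np.array([x[0] for x in parts]), np.array([x[1] for x in parts]))
            z = b / s
            rows.loc[gi, ["beta", "se", "stat", "p", "route"]] = \
                [b, s, z, 2 * stats.norm.sf(abs(z)),
                 "chrX-ivw-meta" if len(parts) == 2 else "chrX-single-stratum"]

    if is_y.any():
        males = sex == "M"
        sub = meta.loc[males].reset_index(drop=True)
        covs_y = [v for v in model_covs if v != "sex" and sub[v].nunique() > 1]
        fit_block(is_y, males, covs_y, "chrY-male-only")

    out = pd.DataFrame({
        "peak": cm.peaks["name"].to_numpy(), "chrom": chroms, "variable": variable,
        "beta": rows["beta"].astype(float), "se": rows["se"].astype(float),
        "stat": rows["stat"].astype(float), "p": rows["p"].astype(float),
        "route": rows["route"],
    })
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def _n_params(meta: pd.DataFrame, variable: str) -> int:
    s = meta[variable]
    if pd.api.types.is_numeric_dtype(s):
        return 1
    return max(s.nunique() - 1, 1)


def matched_subset(metadata: pd.DataFrame, match_on: list, caliper: float = 1.0,
                   n_pairs: int | None = None, dx_col: str = "diagnosis") -> dict:
    """Greedy 1:1 case-control matching within sex on standardized distance.

    Returns the matched sample list, pair table, and standardized mean
    differences of the matching variables before/after.
    """
    meta = metadata.copy()
    if meta[match_on].isna().any().any():
        raise ValueError("matching variables must be complete")
    z = {}
    for v in match_on:
        x = meta[v].to_numpy(dtype=float)
        z[v] = (x - x.mean()) / (x.std() or 1.0)
    Z = np.column_stack([z[v] for v in match_on])
    cases = np.flatnonzero((meta[dx_col] == "case").to_numpy())
    controls = np.flatnonzero((meta[dx_col] == "control").to_numpy())
    pairs = []
    used = set()
    sexes = meta["sex"].to_numpy() if "sex" in meta.columns else np.array(["*"] * len(meta))
    order = cases[np.argsort(meta.loc[cases, match_on[0]].to_numpy())]
    for ci in order:
        best, bestd = None, np.inf
        for ki in controls:
            if ki in used or sexes[ki] != sexes[ci]:
                continue
            d = float(np.sqrt(((Z[ci] - Z[ki]) ** 2).sum()))
            if d < bestd:
                best, bestd = ki, d
        if best is not None and bestd <= caliper:
            pairs.append((ci, best, bestd))
            used.add(best)
        if n_pairs is not None and len(pairs) >= n_pairs:
            break
    matched_idx = [i for p in pairs for i in p[:2]]
    sub = meta.iloc[matched_idx]
    smd = {}
    for v in match_on:
        a = sub.loc[sub[dx_col] == "case", v].to_numpy(dtype=float)
        b = sub.loc[sub[dx_col] == "control", v].to_numpy(dtype=float)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2) if len(a) > 1 else 1.0
        smd[v] = float(abs(a.mean() - b.mean()) / (pooled or 1.0)) if len(a) else np.nan
    if n_pairs is not None and len(pairs) < n_pairs:
        import warnings
        warnings.warn(f"achieved {len(pairs)} of {n_pairs} requested pairs")
    return {"samples": sub["sample"].tolist() if "sample" in sub else sub.index.tolist(),
            "pairs": pd.DataFrame([(meta.iloc[a]["sample"] if "sample" in meta else a,
                                    meta.iloc[b]["sample"] if "sample" in meta else b, d)
                                   for a, b, d in pairs],
                                  columns=["case", "control", "distance"]),
            "smd": smd}
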