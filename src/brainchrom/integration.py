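"""cQTL-eQTL sharing, effect-direction concordance, and Bayesian colocalization.

Colocalization follows the standard five-hypothesis enumeration over
single-SNP causal configurations with Wakefield approximate Bayes factors;
all probability accumulation happens in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .cqtl import storey_qvalue

# prior effect-size SDs: quantitative traits and case-control log-odds
W_QUANT = 0.15
W_CC = 0.2


@dataclass
class ColocResult:
    pp: np.ndarray  # PP0..PP4
    n_snps: int
    priors: tuple
    log_abf1: np.ndarray
    log_abf2: np.ndarray

    def __post_init__(self):
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")


def estimate_shared_fraction(eqtl_pvalues_by_gene: dict, mode: str = "random",
                             seed: int = 0) -> dict:
    """Fraction of significant cQTLs that are also eQTLs (pi1 = 1 - pi0).

    ``eqtl_pvalues_by_gene`` maps gene -> array of eQTL p-values for SNPs
    matched to significant cQTLs. One p per gene is kept by ``mode``
    (random / most-significant / least-significant); pi0 comes from the
    Storey estimator on the matched set.
    """
    if not eqtl_pvalues_by_gene:
        raise ValueError("empty matched eQTL set")
    rng = np.random.default_rng(seed)
    ps = []
    for gene, arr in eqtl_pvalues_by_gene.items():
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            raise ValueError(f"gene {gene!r} has no matched eQTL p-values")
        if mode == "random":
            ps.append(arr[int(rng.integers(arr.size))])
        elif mode == "most-significant":
            ps.append(arr.min())
        elif mode == "least-significant":
            ps.append(arr.max())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    ps = np.asarray(ps)
    _, pi0 = storey_qvalue(ps)
    return {"mode": mode, "pi0": pi0, "pi1": 1.0 - pi0, "n_pairs": len(ps)}


def direction_concordance(paired_effects: pd.DataFrame) -> dict:
    """Same-sign fraction of paired cQTL/eQTL effects with an exact binomial p.

    Rows need ``beta_cqtl`` and ``beta_eqtl`` for the same tested allele;
    zero effects are excluded and counted.
    """
    b1 = paired_effects["beta_cqtl"].to_numpy(dtype=float)
    b2 = paired_effects["beta_eqtl"].to_numpy(dtype=float)
    ok = (b1 != 0) & (b2 != 0)
    conc = np.sign(b1[ok]) == np.sign(b2[ok])
    n = int(ok.sum())
    k = int(conc.sum())
    if n == 0:
        return {"fraction": np.nan, "n": 0, "n_excluded": int((~ok).sum()), "p": np.nan}
    p = stats.binomtest(k, n, 0.5).pvalue
    return {"fraction": k / n, "n": n, "n_excluded": int((~ok).sum()), "p": float(p)}


def wakefield_log_abf(beta, se, prior_sd_W: float = W_QUANT) -> np.ndarray:
    """Wakefield log approximate Bayes factor for a single-SNP association.

    With V = se^2, r = W / (V + W), z = beta / se:
    log ABF = 0.5 log(1 - r) + 0.5 z^2 r.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("non-finite beta or se")
    if np.any(se <= 0) or prior_sd_W <= 0:
        raise ValueError("se and prior W must be > 0")
    V = se ** 2
    W = prior_sd_W ** 2
    r = W / (V + W)
    z = beta / se
    return 0.5 * np.log(1 - r) + 0.5 * z ** 2 * r


def se_from_p_maf(p, maf, n, quantitative: bool = True) -> tuple:
    """Back out (beta, se) on the standardized scale from p, MAF, and N."""
    p = np.asarray(p, dtype=float)
    maf = np.asarray(maf, dtype=float)
    z = stats.norm.isf(p / 2)
    denom = 2.0 * maf * (1 - maf)
    se = 1.0 / np.sqrt(np.maximum(denom, 1e-12) * (np.asarray(n, dtype=float) + z ** 2))
    return z * se, se


def coloc_pp(trait1_stats: pd.DataFrame, trait2_stats: pd.DataFrame,
             p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
             W1: float = W_QUANT, W2: float = W_QUANT) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Both frames need aligned ``SNP`` plus either (BETA, SE) or (P, MAF, N)
    columns. H0: neither trait associated; H1/H2: one trait only; H3: two
    distinct causal SNPs; H4: one shared causal SNP.
    """
    if len(trait1_stats) != len(trait2_stats) or len(trait1_stats) < 2:
        raise ValueError("traits need the same SNP set with >= 2 SNPs")
    if not (trait1_stats["SNP"].to_numpy() == trait2_stats["SNP"].to_numpy()).all():
        t2 = trait2_stats.set_index("SNP").reindex(trait1_stats["SNP"]).reset_index()
        if t2.isna().any().any():
            missing = trait2_stats.set_index("SNP").reindex(trait1_stats["SNP"])
            bad = missing[missing.isna().any(axis=1)].index.tolist()
            raise ValueError(f"allele/SNP alignment failed for {bad[:5]}")
        trait2_stats = t2

    def labf(df, W):
        if "BETA" in df.columns and "SE" in df.columns:
            return wakefield_log_abf(df["BETA"].to_numpy(), df["SE"].to_numpy(), W)
        beta, se = se_from_p_maf(df["P"].to_numpy(), df["MAF"].to_numpy(), df["N"].to_numpy())
        return wakefield_log_abf(beta, se, W)

    l1 = labf(trait1_stats, W1)
    l2 = labf(trait2_stats, W2)
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs of distinct SNPs: sum_i sum_{j != i} e^{l1_i + l2_j}
    if len(l1) <= 1000:
        pair = l1[:, None] + l2[None, :]
        np.fill_diagonal(pair, -np.inf)
        h3 = logsumexp(pair)
    else:
        both = s1 + s2
        h3 = both + np.log1p(-np.exp(s12 - both)) if s12 < both else -np.inf
    lh = np.array([
        0.0,
        np.log(p1) + s1,
        np.log(p2) + s2,
        np.log(p1) + np.log(p2) + h3,
        np.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_snps=len(trait1_stats), priors=(p1, p2, p12),
                       log_abf1=l1, log_abf2=l2)
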