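"""Metadata screening, diagnosis-association tests, and covariate selection.

The covariate-selection loop mirrors the iterative PC-association procedure:
regress every metadata variable on each of the leading principal components
of the log-normalized count matrix, pick one Bonferroni-significant variable
by priority rules, residualize the matrix against the selected set, and
repeat until nothing passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CovariateSelection:
    selected: list
    iterations: list  # dicts: iteration, variable, pc, p, threshold, r2
    status: str = "converged"  # converged | collinearity | max-iterations
    unresolved: list = field(default_factory=list)  # significant but collinear


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def screen_metadata(table: pd.DataFrame, max_missing: float = 0.05, max_levels: int = 30,
                    protected: tuple = ("diagnosis", "sex")) -> tuple:
    """Drop invariant, high-missingness, and many-level variables.

    Returns (reduced table, exclusion log). Dropping a protected variable is
    a hard error.
    """
    if table.empty:
        raise ValueError("empty metadata table")
    keep, log = [], []
    for col in table.columns:
        s = table[col]
        reason = None
        if s.dropna().nunique() <= 1:
            reason = "invariant"
        elif s.isna().mean() > max_missing:
            reason = f">{max_missing:.0%} missing"
        elif not _is_numeric(s) and s.dropna().nunique() > max_levels:
            reason = f">{max_levels} levels"
        if reason is None:
            keep.append(col)
        else:
            if col in protected:
                raise ValueError(f"protected variable {col!r} would be dropped: {reason}")
            log.append({"variable": col, "reason": reason})
    return table[keep].copy(), pd.DataFrame(log, columns=["variable", "reason"])


def impute_metadata(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Complete the table: numeric -> median, categorical -> frequency draw."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col in out.columns:
        s = out[col]
        if not s.isna().any():
            continue
        obs = s.dropna()
        if len(obs) == 0:
            raise ValueError(f"variable {col!r} has no observed values")
        if _is_numeric(s):
            out[col] = s.fillna(obs.median())
        else:
            freq = obs.value_counts(normalize=True)
            fill = rng.choice(freq.index.to_numpy(), size=s.isna().sum(), p=freq.to_numpy())
            out.loc[s.isna(), col] = fill
    return out


def test_dx_association(table: pd.DataFrame, dx_col: str = "diagnosis") -> pd.DataFrame:
    """Per-variable association with diagnosis.

    Numeric variables: one-way regression F test. Categorical: Pearson
    chi-square on the level x diagnosis table, no continuity correction.
    Bonferroni threshold is 0.05 / number of variables tested.
    """
    dx = table[dx_col]
    if dx.nunique() != 2:
        raise ValueError("diagnosis must have exactly two levels present")
    rows = []
    tested = [c for c in table.columns if c != dx_col]
    for col in tested:
        s = table[col]
        if _is_numeric(s):
            groups = [s[dx == lv].dropna().to_numpy() for lv in dx.unique()]
            stat, p = stats.f_oneway(*groups)
            kind, df = "F", (1, sum(len(g) for g in groups) - 2)
        else:
            tab = pd.crosstab(s, dx)
            tab = tab.loc[(tab.sum(axis=1) > 0), (tab.sum(axis=0) > 0)]
            stat, p = chi2_no_correction(tab.to_numpy())
            kind, df = "chi2", tab.shape[0] - 1
        rows.append({"variable": col, "kind": kind, "statistic": float(stat),
                     "df": df, "p": float(p)})
    res = pd.DataFrame(rows)
    res["bonferroni_threshold"] = 0.05 / len(tested)
    res["significant"] = res["p"] < res["bonferroni_threshold"]
    return res


def chi2_no_correction(observed: np.ndarray) -> tuple:
    """Pearson chi-square on a contingency table, sum (O-E)^2 / E."""
    observed = np.asarray(observed, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    return stat, float(stats.chi2.sf(stat, df))


def _design_matrix(table: pd.DataFrame, variables: list) -> np.ndarray:
    cols = [np.ones(len(table))]
    for v in variables:
        s = table[v]
        if _is_numeric(s):
            x = s.to_numpy(dtype=float)
            sd = x.std()
            cols.append((x - x.mean()) / (sd if sd else 1.0))
        else:
            dummies = pd.get_dummies(s, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def residualize(matrix: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``matrix`` (samples x features) on design."""
    q, _ = np.linalg.qr(design)
    return matrix - q @ (q.T @ matrix)


def _pc_scores(matrix: np.ndarray, n_pcs: int) -> tuple:
    """Centered-SVD principal-component scores (samples x n_pcs)."""
    x = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, len(s))
    return u[:, :k] * s[:k], s


def _variable_pc_tests(table: pd.DataFrame, variables: list, scores: np.ndarray) -> pd.DataFrame:
    rows = []
    n = len(table)
    for v in variables:
        s = table[v]
        for pc in range(scores.shape[1]):
            y = scores[:, pc]
            if _is_numeric(s):
                x = s.to_numpy(dtype=float)
                if x.std() == 0:
                    continue
                r = np.corrcoef(x, y)[0, 1]
                r2 = r ** 2
                t = r * np.sqrt(max(n - 2, 1) / max(1 - r2, 1e-300))
                p = 2 * stats.t.sf(abs(t), n - 2)
                n_par = 1
            else:
                groups = [y[(s == lv).to_numpy()] for lv in s.dropna().unique()]
                groups = [g for g in groups if len(g)]
                if len(groups) < 2:
                    continue
                f, p = stats.f_oneway(*groups)
                gm = y.mean()
                ss_tot = ((y - gm) ** 2).sum()
                ss_b = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
                r2 = ss_b / ss_tot if ss_tot else 0.0
                n_par = len(groups) - 1
            rows.append({"variable": v, "pc": pc, "p": float(p), "r2": float(r2),
                         "n_params": n_par})
    return pd.DataFrame(rows)


def select_covariates(log_norm_counts: np.ndarray, table: pd.DataFrame, n_pcs: int = 20,
                      alpha: float = 0.05, technical_tags: tuple = (),
                      max_iter: int = 25, cond_cap: float = 1e8,
                      exclude: tuple = ("sample",)) -> CovariateSelection:
    """Iterative PC-association covariate selection.

    ``log_norm_counts`` is samples x peaks (log-normalized). Priority among
    Bonferroni-significant variables: (1) technical-tagged, (2) largest
    variance explained on its best PC, (3) fewest parameters, (4) name.
    """
    if log_norm_counts.shape[0] != len(table):
        raise ValueError("matrix rows must match metadata rows")
    if log_norm_counts.shape[0] < n_pcs + 1:
        raise ValueError("need more samples than PCs")
    candidates = [c for c in table.columns if c not in exclude]
    selected: list = []
    iterations: list = []
    unresolved: list = []
    mat = np.asarray(log_norm_counts, dtype=float)
    status = "max-iterations"
    for it in range(max_iter):
        if selected:
            design = _design_matrix(table, selected)
            if np.linalg.cond(design) > cond_cap:
                status = "collinearity"
                break
            mat_r = residualize(mat, design)
        else:
            mat_r = mat
        scores, _ = _pc_scores(mat_r, n_pcs)
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            status = "converged"
            break
        tests = _variable_pc_tests(table, remaining, scores)
        threshold = alpha / (len(remaining) * scores.shape[1])
        sig = tests[tests["p"] < threshold]
        if sig.empty:
            status = "converged"
            break
        best_per_var = sig.loc[sig.groupby("variable")["r2"].idxmax()].copy()
        best_per_var["is_tech"] = best_per_var["variable"].isin(technical_tags)
        best_per_var = best_per_var.sort_values(
            by=["is_tech", "r2", "n_params", "variable"],
            ascending=[False, False, True, True])
        # pick the highest-priority significant variable that keeps the
        # selected design well conditioned
        pickrow = None
        for _, row in best_per_var.iterrows():
            trial = _design_matrix(table, selected + [row["variable"]])
            if np.linalg.cond(trial) <= cond_cap:
                pickrow = row
                break
        if pickrow is None:
            status = "collinearity"
            unresolved.extend(v for v in best_per_var["variable"] if v not in unresolved)
            break
        selected.append(pickrow["variable"])
        iterations.append({"iteration": it, "variable": pickrow["variable"],
                           "pc": int(pickrow["pc"]), "p": float(pickrow["p"]),
                           "threshold": float(threshold), "r2": float(pickrow["r2"])})
        # other variables significant this round that are collinear with the
        # updated design can never be corrected for: record them
        base = _design_matrix(table, selected)
        for v in best_per_var["variable"]:
            if v == pickrow["variable"] or v in unresolved:
                continue
            if np.linalg.cond(np.column_stack([base, _design_matrix(table, [v])[:, 1:]])) \
                    > cond_cap:
                unresolved.append(v)
    if status != "collinearity" and unresolved:
        status = "collinearity"
    return CovariateSelection(selected=selected, iterations=iterations, status=status,
                              unresolved=unresolved)


def match_sample_identity(dosages_a: pd.DataFrame, dosages_b: pd.DataFrame,
                          min_sites: int = 100, expected: dict | None = None,
                          concordance_floor: float = 0.8) -> dict:
    """Genotype-concordance identity matching between two dosage panels.

    Inputs are SNP x sample DataFrames (SNP ids as index). Concordance is
    the fraction of shared sites where rounded dosages agree. Each column of
    ``a`` is assigned its argmax-concordance column of ``b``; mismatches are
    flagged when the best match differs from ``expected`` (default: same
    name) or concordance is below the floor.
    """
    shared = dosages_a.index.intersection(dosages_b.index)
    if len(shared) < min_sites:
        raise ValueError(f"only {len(shared)} shared sites (< {min_sites})")
    a = np.rint(dosages_a.loc[shared].to_numpy())
    b = np.rint(dosages_b.loc[shared].to_numpy())
    conc = np.zeros((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        conc[i] = (a[:, [i]] == b).mean(axis=0)
    conc_df = pd.DataFrame(conc, index=dosages_a.columns, columns=dosages_b.columns)
    best = conc_df.idxmax(axis=1)
    expected = expected or {s: s for s in dosages_a.columns if s in dosages_b.columns}
    mismatches = [{"sample": s, "best_match": best[s],
                   "concordance": float(conc_df.loc[s, best[s]])}
                  for s in conc_df.index
                  if (s in expected and best[s] != expected[s])
                  or conc_df.loc[s, best[s]] < concordance_floor]
    return {"concordance": conc_df, "best_match": best, "mismatches": mismatches}
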