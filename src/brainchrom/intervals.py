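"""Half-open genomic interval arithmetic on plain DataFrames.

All coordinates are 0-based half-open (BED convention). Interval tables are
pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED3 = ["chrom", "start", "end"]


def _as_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in BED3 if c not in df.columns]
    if missing:
        raise ValueError(f"interval table missing columns {missing}")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return _as_frame(df).sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping or bookended intervals, per chromosome."""
    df = sort_intervals(df)
    if df.empty:
        return df[BED3].copy()
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED3)


def total_length(df: pd.DataFrame) -> int:
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum())


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Base-pair intersection of two (merged) interval sets."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ga = a[a["chrom"] == chrom]
        gb = b[b["chrom"] == chrom]
        ia = ib = 0
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        while ia < len(sa) and ib < len(sb):
            lo = max(sa[ia], sb[ib])
            hi = min(ea[ia], eb[ib])
            if lo < hi:
                out.append((chrom, lo, hi))
            if ea[ia] < eb[ib]:
                ia += 1
            else:
                ib += 1
    return pd.DataFrame(out, columns=BED3)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """a minus b, base-pair wise."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for chrom, ga in a.groupby("chrom", sort=True):
        gb = b[b["chrom"] == chrom]
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        for s, e in zip(ga["start"], ga["end"]):
            cur = s
            idx = np.searchsorted(eb, cur, side="right")
            while idx < len(sb) and sb[idx] < e:
                if sb[idx] > cur:
                    out.append((chrom, cur, min(sb[idx], e)))
                cur = max(cur, eb[idx])
                idx += 1
            if cur < e:
                out.append((chrom, cur, e))
    return pd.DataFrame(out, columns=BED3)


def points_in_intervals(chroms: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean membership of positions in a merged interval set."""
    merged = merge_intervals(intervals)
    res = np.zeros(len(pos), dtype=bool)
    for chrom, grp in merged.groupby("chrom", sort=False):
        mask = chroms == chrom
        if not mask.any():
            continue
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        p = pos[mask]
        idx = np.searchsorted(s, p, side="right") - 1
        ok = (idx >= 0) & (p < e[np.clip(idx, 0, len(e) - 1)])
        res[mask] = ok
    return res


def overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """For each query interval, whether it overlaps any subject interval by >=1 bp."""
    merged = merge_intervals(subject)
    res = np.zeros(len(query), dtype=bool)
    qc = query["chrom"].to_numpy()
    qs = query["start"].to_numpy()
    qe = query["end"].to_numpy()
    for chrom, grp in merged.groupby("chrom", sort=False):
        mask = qc == chrom
        if not mask.any():
            continue
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        # overlap iff some subject start < query end and subject end > query start
        lo = np.searchsorted(e, qs[mask], side="right")
        res[mask] = (lo < len(s)) & (s[np.clip(lo, 0, len(s) - 1)] < qe[mask])
    return res
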