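"""Plain-text readers/writers for the pipeline's file formats.

Peaks travel as BED6 with the summit encoded in the name field
(``<id>;summit=<pos>``); fragments as BED3; counts, dosages, metadata and
summary statistics as TSV. All coordinates written are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .peakmatrix import CountMatrix


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    df = peaks.copy()
    support = df["support"] if "support" in df.columns else 0
    name = [f"{n};summit={s}" for n, s in zip(df["name"], df["summit"])]
    bed = pd.DataFrame({"chrom": df["chrom"], "start": df["start"], "end": df["end"],
                        "name": name, "score": support, "strand": "."})
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    names, summits = [], []
    for i, n in enumerate(bed["name"]):
        if ";summit=" in str(n):
            base, s = str(n).split(";summit=")
            names.append(base)
            summits.append(int(s))
        else:
            names.append(str(n))
            summits.append(int((bed["start"].iloc[i] + bed["end"].iloc[i]) // 2))
    out = bed[["chrom", "start", "end"]].copy()
    out["name"] = names
    out["summit"] = summits
    if (bed["score"] != 0).any():
        out["support"] = bed["score"]
    return out


def write_fragments_bed(fragments: pd.DataFrame, path) -> None:
    fragments[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])


def write_counts(cm: CountMatrix, path, factors_path=None) -> None:
    df = pd.DataFrame(cm.counts, index=cm.peaks["name"], columns=cm.samples)
    df.index.name = "peak"
    df.to_csv(path, sep="\t")
    if factors_path is not None:
        side = pd.DataFrame({"sample": cm.samples, "lib_size": cm.lib_size,
                             "tmm_factor": cm.tmm_factor if cm.tmm_factor is not None
                             else np.ones(len(cm.samples))})
        side.to_csv(factors_path, sep="\t", index=False)


def read_counts(path, peaks: pd.DataFrame, factors_path=None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    pk = peaks.set_index("name").loc[df.index].reset_index()
    cm = CountMatrix(peaks=pk, samples=list(df.columns),
                     counts=df.to_numpy(dtype=np.int64),
                     lib_size=df.to_numpy(dtype=np.int64).sum(axis=0))
    if factors_path is not None and Path(factors_path).exists():
        side = pd.read_csv(factors_path, sep="\t").set_index("sample").loc[cm.samples]
        cm.lib_size = side["lib_size"].to_numpy()
        cm.tmm_factor = side["tmm_factor"].to_numpy()
    return cm


def write_dosages(dosages: np.ndarray, snp_map: pd.DataFrame, samples: list, prefix) -> None:
    prefix = Path(prefix)
    pd.DataFrame(dosages, index=snp_map["snp"], columns=samples) \
        .rename_axis("snp").to_csv(f"{prefix}.dosage.tsv", sep="\t")
    snp_map.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)


def read_dosages(prefix):
    prefix = Path(prefix)
    d = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t", index_col=0)
    snp_map = pd.read_csv(f"{prefix}.snps.tsv", sep="\t")
    return d.to_numpy(dtype=float), snp_map, list(d.columns)
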