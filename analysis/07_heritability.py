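#!/usr/bin/env python
"""Partitioned heritability of the peak annotation and the width series.

Runs stratified LD-score regression on the cohort's simulated GWAS (h2
stage of the pipeline) and then the peak-width dilution experiment with
causal variants at summits. Writes heritability.tsv under results/run/ and
width_series.tsv under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RUN_DIR, run_through  # noqa: E402

from brainchrom import experiments as ex  # noqa: E402


def main():
    run_through("h2")
    res = pd.read_csv(RUN_DIR / "heritability.tsv", sep="\t")
    print("stratified regression on the cohort GWAS:")
    print(res[["category", "prop_snps", "prop_h2", "enrichment", "enrichment_se",
               "coefficient_z"]].round(3).to_string(index=False))

    print("\npeak-width series (causal variants at summits):")
    ws = ex.width_series(seed=2)
    print(ws[["width", "enrichment", "enrichment_se"]].round(2).to_string(index=False))
    out = RUN_DIR.parent / "width_series.tsv"
    ws.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
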