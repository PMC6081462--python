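#!/usr/bin/env python
"""Quantify peaks, normalize with TMM, and run peak-set QC.

Reports the TSS-distance class composition of the peak set and the TMM
factor spread; writes counts.tsv, norm_factors.tsv, and the TSS annotation
tables under results/run/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RUN_DIR, run_through  # noqa: E402


def main():
    run_through("qc")
    factors = pd.read_csv(RUN_DIR / "norm_factors.tsv", sep="\t")
    print(f"TMM factors: median {factors['tmm_factor'].median():.3f}, "
          f"range [{factors['tmm_factor'].min():.3f}, {factors['tmm_factor'].max():.3f}]")
    tss = pd.read_csv(RUN_DIR / "tss_class_summary.tsv", sep="\t", index_col=0)
    print("TSS distance classes (fraction of peaks):")
    print(tss.to_string())


if __name__ == "__main__":
    main()
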