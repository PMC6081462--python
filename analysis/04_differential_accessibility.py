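#!/usr/bin/env python
"""Differential accessibility scan for diagnosis with sex-aware routing.

Autosomal peaks use the full-cohort NB model, chrX peaks are sex-stratified
and IVW-meta-analyzed, chrY peaks are tested in males only. Compares calls
at 5% FDR against the ground-truth injected effects and writes
differential.tsv under results/run/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RUN_DIR, run_through  # noqa: E402


def main():
    run_through("diffacc")
    res = pd.read_csv(RUN_DIR / "differential.tsv", sep="\t")
    truth = pd.read_csv(RUN_DIR / "truth_peak_effects.tsv", sep="\t")
    merged = res.merge(truth, left_on="peak", right_on="peak")
    called = merged[merged["q"] < 0.05]
    true_pos = (called["dx_log2fc"].abs() > 0).sum()
    n_true = (merged["dx_log2fc"].abs() > 0).sum()
    print(f"peaks tested: {len(res)}; routes: {res['route'].value_counts().to_dict()}")
    print(f"significant at 5% FDR: {len(called)} "
          f"({true_pos} of {n_true} injected effects recovered)")
    if len(called):
        fdr = 1 - true_pos / len(called)
        print(f"observed false discovery proportion: {fdr:.3f}")


if __name__ == "__main__":
    main()
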