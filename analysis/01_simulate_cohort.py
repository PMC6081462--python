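#!/usr/bin/env python
"""Simulate the synthetic case-control cohort all later steps analyze.

Writes peaks, per-sample metadata, genotype dosages, and the ground-truth
effect tables to results/run/. The cohort emulates a postmortem-brain
ATAC-seq study: ~50/50 cases and controls, male-skewed cases, long case
PMIs, block-LD genotypes, and NB counts with injected diagnosis and cis
genotype effects.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RUN_DIR, run_through  # noqa: E402


def main():
    manifest = run_through("simulate")
    print(f"simulated cohort in {RUN_DIR}")
    for name in ("peaks.bed", "metadata.tsv", "genotypes.dosage.tsv",
                 "truth_peak_effects.tsv", "truth_cqtl.tsv"):
        print(f"  wrote {name}")
    print(f"stage seconds: {manifest['stages']['simulate']['seconds']}")


if __name__ == "__main__":
    main()
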