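#!/usr/bin/env python
"""Screen the metadata, test diagnosis associations, select covariates.

Prints the cohort-style association table (F tests for numeric variables,
Pearson chi-square for categorical) and the variables picked by the
iterative PC-association loop; writes dx_association.tsv and
covariate_selection.tsv under results/run/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "analysis"))
from common import RUN_DIR, run_through  # noqa: E402


def main():
    run_through("covariates")
    dx = pd.read_csv(RUN_DIR / "dx_association.tsv", sep="\t")
    print("association with diagnosis:")
    print(dx[["variable", "kind", "statistic", "p", "significant"]]
          .round(4).to_string(index=False))
    sel = pd.read_csv(RUN_DIR / "covariate_selection.tsv", sep="\t")
    if len(sel):
        print("\nselected covariates, in order:")
        print(sel[["iteration", "variable", "pc", "p"]].to_string(index=False))
    else:
        print("\nno covariate passed the Bonferroni threshold")


if __name__ == "__main__":
    main()
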