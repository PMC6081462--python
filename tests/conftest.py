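import numpy as np
import pandas as pd
import pytest

from brainchrom import peakmatrix as pm
from brainchrom import synthgen as sg


@pytest.fixture(scope="session")
def layout():
    return sg.gen_genome(n_autosomes=2, chrom_length=1_000_000, n_tss=100,
                         blacklist_fraction=0.02, seed=11)


@pytest.fixture(scope="session")
def small_cohort(layout):
    """96-sample, 300-peak cohort with genotypes, truth, and counts."""
    samples = sg.gen_samples(96, seed=21)
    peaks = sg.gen_peaks(layout, 300, seed=22)
    geno = sg.gen_genotypes(96, 2000, 10, seed=23, layout=layout)
    truth = sg.gen_truth(peaks, geno.snp_map, samples, frac_dx=0.05, dx_log2fc=1.5,
                         frac_cqtl=0.15, cqtl_beta=0.6, seed=24)
    cm = sg.gen_counts(layout, peaks, geno, truth, dispersion=0.15, mean_depth=80, seed=25)
    cm.tmm_factor = pm.tmm_factors(cm)
    return {"layout": layout, "samples": samples, "peaks": peaks, "geno": geno,
            "truth": truth, "cm": cm}


def toy_peaks(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    return df[["chrom", "start", "end", "name", "summit"]]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
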