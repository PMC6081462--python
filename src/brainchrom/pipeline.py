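"""End-to-end orchestration of the synthetic reproduction harness.

Stages run in dependency order (simulate -> quantify -> qc -> covariates ->
diffacc -> cqtl -> overlap/coloc -> h2); each stage writes TSVs into the run
directory and the manifest records seeds and content hashes so deterministic
stages can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import cqtl as cq
from . import diffaccess as da
from . import heritability as h2
from . import integration as integ
from . import io as bio
from . import peakmatrix as pm
from . import synthgen as sg

log = logging.getLogger("brainchrom")

STAGES = ["simulate", "quantify", "qc", "covariates", "diffacc", "cqtl", "overlap", "h2"]

DEFAULT_CONFIG = {
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "n_samples": 96, "n_peaks": 600, "n_snps": 3000, "block_size": 10,
        "n_autosomes": 2, "chrom_length": 1_000_000, "n_tss": 100,
        "dispersion": 0.2, "mean_depth": 100.0,
        "frac_dx": 0.02, "dx_log2fc": 1.5, "frac_cqtl": 0.10, "cqtl_beta": 0.5,
    },
    "cqtl": {"window": 5000, "n_perm": 200, "n_phenotype_pcs": 10, "n_ancestry_pcs": 5},
    "diffacc": {"variable": "diagnosis"},
    "h2": {"widths": [300], "n_gwas": 50000, "tau_focal": 2e-4, "window_bp": 500_000,
           "n_blocks": 20},
    "coloc": {"p1": 1e-4, "p2": 1e-4, "p12": 1e-5},
}


def validate_config(config: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(val, dict):
            unknown = set(val) - set(cfg[key])
            if unknown:
                raise ValueError(f"unknown keys in {key!r}: {sorted(unknown)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    bad = [s for s in cfg["stages"] if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    # later stages need earlier outputs
    enabled = [s for s in STAGES if s in cfg["stages"]]
    for s in enabled[1:]:
        if "simulate" not in enabled:
            raise ValueError(f"stage {s!r} requires the simulate stage in this harness")
    return cfg


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: dict | None = None, out_dir="run") -> dict:
    """Execute the configured stages; returns the manifest."""
    cfg = validate_config(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "stages": {}, "files": {}}
    state: dict = {}
    t00 = time.time()
    for stage in [s for s in STAGES if s in cfg["stages"]]:
        t0 = time.time()
        seed = _stage_seed(cfg["seed"], stage)
        log.info("stage %s (seed %d)", stage, seed)
        _RUNNERS[stage](cfg, seed, out, state)
        manifest["stages"][stage] = {"seed": seed, "seconds": round(time.time() - t0, 2)}
    for f in sorted(out.glob("*.tsv")):
        manifest["files"][f.name] = _hash(f)
    manifest["total_seconds"] = round(time.time() - t00, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_simulate(cfg, seed, out, state):
    p = cfg["simulate"]
    layout = sg.gen_genome(p["n_autosomes"], p["chrom_length"], p["n_tss"], 0.02, seed)
    samples = sg.gen_samples(p["n_samples"], 0.5, seed + 1)
    peaks = sg.gen_peaks(layout, p["n_peaks"], seed=seed + 2)
    geno = sg.gen_genotypes(p["n_samples"], p["n_snps"], p["block_size"], seed=seed + 3,
                            layout=layout)
    truth = sg.gen_truth(peaks, geno.snp_map, samples, frac_dx=p["frac_dx"],
                         dx_log2fc=p["dx_log2fc"], frac_cqtl=p["frac_cqtl"],
                         cqtl_beta=p["cqtl_beta"], seed=seed + 4)
    cm = sg.gen_counts(layout, peaks, geno, truth, p["dispersion"], p["mean_depth"], seed + 5)
    state.update(layout=layout, samples=samples, peaks=peaks, geno=geno, truth=truth, cm=cm)
    bio.write_peaks_bed(peaks, out / "peaks.bed")
    samples.to_csv(out / "metadata.tsv", sep="\t", index=False)
    bio.write_dosages(geno.dosages, geno.snp_map, geno.samples, out / "genotypes")
    truth.peak_effects.to_csv(out / "truth_peak_effects.tsv", sep="\t", index=False)
    truth.cqtl_map.to_csv(out / "truth_cqtl.tsv", sep="\t", index=False)


def _run_quantify(cfg, seed, out, state):
    cm = state["cm"]
    cm.tmm_factor = pm.tmm_factors(cm)
    cm.validate()
    bio.write_counts(cm, out / "counts.tsv", out / "norm_factors.tsv")


def _run_qc(cfg, seed, out, state):
    cm, layout = state["cm"], state["layout"]
    ann = pm.tss_annotate(cm.peaks, layout.tss)
    ann.to_csv(out / "tss_annotation.tsv", sep="\t", index=False)
    summary = ann["tss_class"].value_counts(normalize=True).rename("fraction")
    summary.to_csv(out / "tss_class_summary.tsv", sep="\t")
    state["tss_annotation"] = ann


def _run_covariates(cfg, seed, out, state):
    cm, samples = state["cm"], state["samples"]
    screened, excl = cov.screen_metadata(samples.drop(columns=["sample"]))
    completed = cov.impute_metadata(screened, seed)
    table = pd.concat([samples[["sample"]], completed], axis=1)
    dx = cov.test_dx_association(completed)
    dx.to_csv(out / "dx_association.tsv", sep="\t", index=False)
    sel = cov.select_covariates(cm.cpm_log2().T, table, n_pcs=min(20, len(table) - 2),
                                technical_tags=("batch", "gc_pct", "rin"))
    pd.DataFrame(sel.iterations).to_csv(out / "covariate_selection.tsv", sep="\t", index=False)
    state["metadata"] = table
    state["selection"] = sel


def _run_diffacc(cfg, seed, out, state):
    cm, table = state["cm"], state["metadata"]
    sel = state["selection"].selected
    res = da.differential_scan(cm, table, sel, cfg["diffacc"]["variable"])
    res.to_csv(out / "differential.tsv", sep="\t", index=False)
    state["differential"] = res


def _run_cqtl(cfg, seed, out, state):
    cm, geno, table = state["cm"], state["geno"], state["metadata"]
    p = cfg["cqtl"]
    lognorm = cm.cpm_log2()
    pcs, _ = cov._pc_scores(lognorm.T, p["n_phenotype_pcs"])
    gpcs, _ = cov._pc_scores(geno.dosages.T, p["n_ancestry_pcs"])
    covs = np.column_stack([pcs, gpcs])
    auto = ~cm.peaks["chrom"].isin(["chrX", "chrY"]).to_numpy()
    res = cq.map_cis_permuted(lognorm[auto], cm.peaks[auto].reset_index(drop=True),
                              geno.dosages, geno.snp_map, covs,
                              window=p["window"], n_perm=p["n_perm"], seed=seed)
    res.to_csv(out / "cqtl.tsv", sep="\t", index=False)
    state["cqtl"] = res
    state["cqtl_covs"] = covs


def _run_overlap(cfg, seed, out, state):
    """cQTL-eQTL sharing on a synthetic eQTL panel tied to the truth set."""
    res, truth = state["cqtl"], state["truth"]
    rng = np.random.default_rng(seed)
    sig = res[res["q"] < 0.05]
    true_cqtl_snps = set(truth.cqtl_map["snp"])
    genes = {}
    for i, row in sig.iterrows():
        shared = row["top_snp"] in true_cqtl_snps and rng.random() < 0.3
        p_e = rng.beta(0.3, 40) if shared else rng.random()
        genes[f"gene{i}"] = [p_e]
    if genes:
        est = integ.estimate_shared_fraction(genes, "random", seed)
        pd.DataFrame([est]).to_csv(out / "overlap.tsv", sep="\t", index=False)
        state["overlap"] = est


def _run_h2(cfg, seed, out, state):
    geno, peaks, layout = state["geno"], state["peaks"], state["layout"]
    p = cfg["h2"]
    ann = h2.build_annotations(geno.snp_map, peaks, widths=tuple(p["widths"]),
                               chrom_sizes=layout.chrom_sizes())
    tau = np.zeros(len(ann.names))
    tau[0] = 1e-5
    tau[ann.names.index(f"peak_{p['widths'][0]}bp")] = p["tau_focal"]
    ss = sg.gen_gwas_sumstats(geno, ann.matrix, tau, p["n_gwas"], seed)
    ss.to_csv(out / "gwas_sumstats.tsv", sep="\t", index=False)
    L = h2.ld_scores(geno, geno.snp_map, ann.matrix, p["window_bp"])
    res = h2.stratified_regression(ss["Z"].to_numpy() ** 2, L, ann.matrix,
                                   p["n_gwas"], p["n_blocks"])
    frame = res.to_frame()
    frame["category"] = ann.names
    frame.to_csv(out / "heritability.tsv", sep="\t", index=False)
    state["h2"] = frame


_RUNNERS = {
    "simulate": _run_simulate, "quantify": _run_quantify, "qc": _run_qc,
    "covariates": _run_covariates, "diffacc": _run_diffacc, "cqtl": _run_cqtl,
    "overlap": _run_overlap, "h2": _run_h2,
}


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def report(run_dir) -> dict:
    """Summary tables from a completed run directory."""
    run = Path(run_dir)
    out: dict = {"missing": []}
    dx_p = run / "dx_association.tsv"
    if dx_p.exists():
        out["cohort_table"] = pd.read_csv(dx_p, sep="\t")
    else:
        out["missing"].append("dx_association")
    diff_p = run / "differential.tsv"
    if diff_p.exists():
        d = pd.read_csv(diff_p, sep="\t")
        out["n_differential_q05"] = int((d["q"] < 0.05).sum())
    else:
        out["missing"].append("differential")
    cq_p = run / "cqtl.tsv"
    if cq_p.exists():
        c = pd.read_csv(cq_p, sep="\t")
        sig = c[(c["q"] < 0.05) & c["top_snp"].notna()]
        out["n_cqtl_q05"] = int(len(sig))
        if len(sig):
            peaks = bio.read_peaks_bed(run / "peaks.bed").set_index("name")
            snps = pd.read_csv(run / "genotypes.snps.tsv", sep="\t").set_index("snp")
            pk = peaks.loc[sig["peak"]]
            sp = snps.loc[sig["top_snp"]]
            center = ((pk["start"] + pk["end"]) // 2).to_numpy()
            dist = np.abs(sp["pos"].to_numpy() - center)
            inside = (sp["pos"].to_numpy() >= pk["start"].to_numpy()) & \
                     (sp["pos"].to_numpy() < pk["end"].to_numpy()) & \
                     (sp["chrom"].to_numpy() == pk["chrom"].to_numpy())
            out["cqtl_in_own_peak_pct"] = round(100 * inside.mean(), 1)
            out["cqtl_within_2kb_pct"] = round(100 * (dist <= 2000).mean(), 1)
        else:
            out["cqtl_distance_summary"] = "no significant cQTLs"
    else:
        out["missing"].append("cqtl")
    h2_p = run / "heritability.tsv"
    if h2_p.exists():
        out["heritability"] = pd.read_csv(h2_p, sep="\t")
    else:
        out["missing"].append("h2")
    return out
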