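"""Shared configuration for the numbered analysis drivers.

All drivers analyze the same deterministic synthetic cohort (seed 1); each
re-runs the pipeline through its stage, which is cheap at this scale and
keeps every script independently executable.
"""

from pathlib import Path

from brainchrom import pipeline as pl

RUN_DIR = Path(__file__).resolve().parents[1] / "results" / "run"

CONFIG = {
    "seed": 1,
    "simulate": {"n_samples": 96, "n_peaks": 600, "n_snps": 3000},
    "cqtl": {"n_perm": 200},
    "h2": {"n_gwas": 50_000, "window_bp": 500_000},
}

STAGE_ORDER = pl.STAGES


def run_through(stage: str) -> dict:
    """Run the pipeline from simulate through the requested stage."""
    cfg = dict(CONFIG)
    cfg["stages"] = STAGE_ORDER[: STAGE_ORDER.index(stage) + 1]
    return pl.run_pipeline(cfg, RUN_DIR)
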