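"""Shared cohort handling for the numbered analysis drivers.

The study cohort is a synthetic 268-accession population (91 wild + 177
under artificial selection) with 1000 genes, 77.23% of them core, generated
from a fixed seed so every driver sees the same data. Heavyweight
per-sample depth tracks live under scratch/; results/ holds the small
summary tables the drivers report.
"""

from __future__ import annotations

from pathlib import Path

from pavpan.synthetic_data import (
    SimConfig,
    make_sample_sheet,
    simulate_annotation,
    simulate_depth,
    simulate_pav_truth,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

COHORT_SEED = 20240901
STUDY_CONFIG = SimConfig(seed=COHORT_SEED)


def load_cohort():
    """(truth, annotations, tracks, sheet) for the fixed study cohort."""
    truth = simulate_pav_truth(STUDY_CONFIG)
    anns = simulate_annotation(STUDY_CONFIG)
    tracks = simulate_depth(truth, anns, STUDY_CONFIG)
    sheet = make_sample_sheet(STUDY_CONFIG)
    return truth, anns, tracks, sheet


def called_matrix_path() -> Path:
    return SCRATCH / "pav_matrix.tsv"


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
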