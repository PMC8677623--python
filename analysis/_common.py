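"""Shared plumbing for the analysis drivers: one study-condition cohort,
cached across scripts so each driver stays fast and deterministic."""

from __future__ import annotations

import pickle
from pathlib import Path

from tmepat import synthetic
from tmepat.core_io import RunConfig
from tmepat.pipeline import PipelineResult, recover_patterns

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 1
N_PATIENTS = 10
CELLS_PER_PATIENT = 500
QC_ARTIFACT_FRAC = 0.1


def get_cohort(seed: int = STUDY_SEED):
    """The study-condition single-cell cohort (10 patients, 5 per archetype)."""
    cache = SCRATCH / "cache" / f"cohort_{seed}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    out = synthetic.simulate_sc_cohort(
        n_patients=N_PATIENTS,
        cells_per_patient=CELLS_PER_PATIENT,
        qc_artifact_frac=QC_ARTIFACT_FRAC,
        seed=seed,
    )
    cache.parent.mkdir(parents=True, exist_ok=True)
    with open(cache, "wb") as fh:
        pickle.dump(out, fh)
    return out


def get_pipeline_result(seed: int = STUDY_SEED) -> tuple[PipelineResult, object]:
    """QC -> clustering -> annotation -> composition -> pattern assignment."""
    cache = SCRATCH / "cache" / f"pipeline_{seed}.pkl"
    cm, meta, truth = get_cohort(seed)
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh), truth
    res = recover_patterns(cm, meta, truth.reference_signatures(), RunConfig(seed=seed))
    with open(cache, "wb") as fh:
        pickle.dump(res, fh)
    return res, truth


def ensure_results() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
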