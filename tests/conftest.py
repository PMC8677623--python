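import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tmepat import synthetic
from tmepat.core_io import NormMatrix
from tmepat.preprocess import normalize_log, qc_filter


@pytest.fixture(scope="session")
def small_cohort():
    """4-patient cohort with QC artifacts; shared across module tests."""
    cm, meta, truth = synthetic.simulate_sc_cohort(
        n_patients=4, cells_per_patient=300, qc_artifact_frac=0.1, seed=11
    )
    return cm, meta, truth


@pytest.fixture(scope="session")
def small_cohort_clean(small_cohort):
    """QC-filtered and normalized version of the shared cohort."""
    cm, meta, truth = small_cohort
    cmf, metaf, _ = qc_filter(cm, meta)
    nm = normalize_log(cmf)
    return nm, metaf, truth


def dense_norm(matrix: np.ndarray, genes=None, cells=None) -> NormMatrix:
    """Helper: wrap a dense genes x cells array as a NormMatrix."""
    matrix = np.asarray(matrix, dtype=float)
    g = genes or [f"G{i}" for i in range(matrix.shape[0])]
    c = cells or [f"C{j}" for j in range(matrix.shape[1])]
    return NormMatrix(genes=list(g), cells=list(c), X=sp.csr_matrix(matrix))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
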