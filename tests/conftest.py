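import numpy as np
import pandas as pd
import pytest

from csfctc import datasets, normalize, synthdata
from csfctc.classify import assign_cell_type
from csfctc.io import CountMatrix
from csfctc.qc import run_qc


def small_count_matrix(counts, gene_ids=None, cell_ids=None, patients=None):
    """Helper: build a validated CountMatrix from a dense array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    patients = patients or ["p0"] * n_cells
    meta = pd.DataFrame(
        {"sample_id": patients, "patient_id": patients, "population_label": pd.NA},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CountMatrix(counts.astype(np.int64), gene_ids, cell_ids, meta).validate()


@pytest.fixture(scope="session")
def default_run():
    """One-patient study-scale cohort, QC'd and normalized, with truth."""
    cm, truth = synthdata.make_fixture("default")
    cm_qc, qc = run_qc(cm)
    em = normalize(cm_qc)
    return {"cm": cm, "cm_qc": cm_qc, "qc": qc, "em": em, "truth": truth}


@pytest.fixture(scope="session")
def cohort_run():
    """Five-patient cohort (3000 cells), QC'd and normalized, with truth."""
    cm, truth = synthdata.make_fixture("cohort")
    cm_qc, qc = run_qc(cm)
    em = normalize(cm_qc)
    return {"cm": cm, "cm_qc": cm_qc, "qc": qc, "em": em, "truth": truth}


@pytest.fixture(scope="session")
def default_annotations(default_run):
    ann = assign_cell_type(default_run["em"], datasets.marker_panels(), seed=0)
    return ann


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
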