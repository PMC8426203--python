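import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import settings

from lrprog.io import SingleCellDataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20210904)


def make_sc(counts, cell_types, genes=None, patient_id="P0", grade=3) -> SingleCellDataset:
    """Build a SingleCellDataset from a dense array (cells x genes)."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = pd.Index(genes if genes is not None else [f"G{i}" for i in range(n_genes)])
    barcodes = pd.Index([f"{patient_id}_B{i}" for i in range(n_cells)])
    return SingleCellDataset(
        patient_id=patient_id,
        counts=sp.csr_matrix(counts.astype(np.int64)),
        genes=genes,
        barcodes=barcodes,
        cell_type=pd.Series(list(cell_types), index=barcodes),
        grade=grade,
    )


@pytest.fixture
def cohort_files(tmp_path):
    """3-gene x 4-patient expression TSV plus matching clinical CSV."""
    expr = pd.DataFrame(
        [[10, 0, 5, 5], [5, 5, 10, 0], [1, 1, 1, 1]],
        index=["GA", "GB", "GC"],
        columns=["p1", "p2", "p3", "p4"],
    )
    expr_path = tmp_path / "expr.tsv"
    expr.to_csv(expr_path, sep="\t", index_label="gene")
    clin = pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4"],
            "time": [100.0, 200.0, 300.0, 400.0],
            "event": [1, 0, 1, 1],
            "grade": [2, 3, 4, 3],
            "stage": ["I", "II", "III", "II"],
        }
    )
    clin_path = tmp_path / "clinical.csv"
    clin.to_csv(clin_path, index=False)
    return expr_path, clin_path, expr, clin
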