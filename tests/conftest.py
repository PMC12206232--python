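import numpy as np
import pandas as pd
import pytest

from mloykit import sc_loy, synthdata


@pytest.fixture
def small_sc_dataset():
    """Small two-condition single-cell cohort with known LOY fractions."""
    ds, truth = synthdata.gen_sc_cohort(
        n_donors_per_condition={"IPF": 2, "control": 2},
        cells_per_donor=250,
        celltype_props={"macrophage": 0.5, "T_cell": 0.5},
        loy_frac_by_condition_and_type={
            "IPF": {"macrophage": 0.2, "T_cell": 0.2},
            "control": {"macrophage": 0.1, "T_cell": 0.1},
        },
        seed=42,
    )
    return ds, truth


@pytest.fixture
def permissive_qc():
    """QC arguments that keep every synthetic cell (tiny gene panels)."""
    return dict(mito_max=1.0, genes_min=0, genes_max=10**9)


def make_dense_dataset(matrix: np.ndarray, genes, cells=None, msy=()):
    """Dense genes x cells matrix -> CellDataset with explicit MSY set."""
    frame = pd.DataFrame(matrix, index=list(genes))
    ds = sc_loy.CellDataset.from_dense(frame, cells=cells, msy_genes=list(msy))
    return ds
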