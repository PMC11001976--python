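import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from amp_reposition.simulate import PerturbagenSet


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """The fixture contrasts nest patients in condition, which triggers the
    documented covariate-drop warning on every hurdle call."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="patient level .* occurs in only one group")
        yield


@pytest.fixture
def tiny_adata():
    """3 genes x 4 cells with known counts for hand-arithmetic checks."""
    X = np.array(
        [
            [1, 1, 2],  # cell c1: totals 4
            [2, 2, 4],  # c2: doubled c1
            [5, 0, 5],
            [0, 3, 7],
        ]
    )
    obs = pd.DataFrame(
        {
            "condition": ["malignant", "malignant", "normal", "normal"],
            "subtype": ["TNBC", "TNBC", "none", "none"],
            "patient": ["PM01", "PM01", "PN01", "PN01"],
        },
        index=["c1", "c2", "c3", "c4"],
    )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=["gA", "gB", "gC"]))
    adata.layers["counts"] = X.copy()
    return adata


def make_pset(values: dict, meta_rows: list[dict]) -> PerturbagenSet:
    """Build a PerturbagenSet from a {sample: {gene: value}} dict."""
    vals = pd.DataFrame(values)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return PerturbagenSet(values=vals[list(meta.index)], meta=meta)


@pytest.fixture
def toy_pset():
    """Two control and two treatment replicates for one drug, two genes."""
    meta = [
        {"sample_id": "DMSO_r1", "drug_id": "DMSO", "dose": "10 uM", "time": "24 h",
         "replicate": 1, "is_control": True},
        {"sample_id": "DMSO_r2", "drug_id": "DMSO", "dose": "10 uM", "time": "24 h",
         "replicate": 2, "is_control": True},
        {"sample_id": "DX_r1", "drug_id": "DX", "dose": "10 uM", "time": "24 h",
         "replicate": 1, "is_control": False},
        {"sample_id": "DX_r2", "drug_id": "DX", "dose": "10 uM", "time": "24 h",
         "replicate": 2, "is_control": False},
    ]
    values = {
        "DMSO_r1": {"g1": 4.0, "g2": 2.0},
        "DMSO_r2": {"g1": 4.0, "g2": 6.0},
        "DX_r1": {"g1": 8.0, "g2": 1.0},
        "DX_r2": {"g1": 8.0, "g2": 3.0},
    }
    return make_pset(values, meta)
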