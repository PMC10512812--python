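import numpy as np
import pandas as pd
import pytest

import crpcpanel as cp
from crpcpanel.normalize import NormMatrix


@pytest.fixture
def lr_toy():
    """4-cell ligand/receptor toy: two A cells express the ligand (2, 4),
    two B cells the receptor (1, 3); observed intensity 3*2 = 6 is the
    unique maximum over the 6 label arrangements."""
    norm = NormMatrix(
        ["L", "R"], ["c1", "c2", "c3", "c4"],
        np.array([[2.0, 4.0, 0.0, 0.0], [0.0, 0.0, 1.0, 3.0]]),
    )
    ann = cp.CellAnnotation(pd.DataFrame(
        {"dataset_id": "D", "lineage": "epithelial",
         "subgroup": ["A", "A", "B", "B"]},
        index=pd.Index(["c1", "c2", "c3", "c4"], name="cell_id"),
    ))
    model = cp.LRModel(secreted={"L"}, membrane={"R"}, pairs={frozenset(("L", "R"))})
    return norm, ann, model


@pytest.fixture(scope="session")
def sc_sim():
    cfg = cp.SCSimConfig(seed=11)
    return cp.simulate_sc(cfg)


@pytest.fixture(scope="session")
def bulk_sim():
    cfg = cp.BulkSimConfig(seed=7)
    return cp.simulate_bulk(cfg)


def make_annotation(subgroups: dict[str, int], dataset="D", lineage="epithelial"):
    """Annotation with the given subgroup -> n_cells mapping."""
    labels, ids = [], []
    for sg, n in subgroups.items():
        for i in range(n):
            labels.append(sg)
            ids.append(f"{sg}{i}")
    return cp.CellAnnotation(pd.DataFrame(
        {"dataset_id": dataset, "lineage": lineage, "subgroup": labels},
        index=pd.Index(ids, name="cell_id"),
    ))
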