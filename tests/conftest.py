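import numpy as np
import pandas as pd
import pytest

from germclock.io_formats import CategoryMap, ExpressionMatrix


def build_matrix(values, stage_of_sample, stage_order, gene_ids=None):
    """Assemble an ExpressionMatrix from a dict sample_id -> column values."""
    df = pd.DataFrame(values)
    if gene_ids is not None:
        df.index = gene_ids
    else:
        df.index = [f"g{i:03d}" for i in range(len(df))]
    df.index.name = "gene_id"
    rep_counter: dict[str, int] = {}
    rows = []
    for sid in df.columns:
        stage = stage_of_sample[sid]
        rep_counter[stage] = rep_counter.get(stage, 0) + 1
        rows.append({"sample_id": sid, "stage": stage, "replicate": rep_counter[stage]})
    meta = pd.DataFrame(rows).set_index("sample_id")
    meta["stage"] = pd.Categorical(meta["stage"], categories=stage_order, ordered=True)
    return ExpressionMatrix(values=df.astype(float), sample_meta=meta, stage_order=list(stage_order))


@pytest.fixture
def two_stage_matrix():
    """3 genes, 2 stages x 3 replicates, hand-set values."""
    values = {
        "a1": [10.0, 5.0, 0.0],
        "a2": [20.0, 5.0, 0.0],
        "a3": [30.0, 5.0, 0.0],
        "b1": [40.0, 20.0, 0.0],
        "b2": [40.0, 20.0, 0.0],
        "b3": [40.0, 20.0, 0.0],
    }
    stage_of = {s: ("0" if s.startswith("a") else "24") for s in values}
    return build_matrix(values, stage_of, ["0", "24"])


@pytest.fixture
def toy_category_map():
    return CategoryMap(
        bins={"2": "major CHO metabolism", "2.1": "major CHO metabolism.synthesis"},
        assignments={("2.1", "g000"), ("2", "g001")},
    )
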