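import numpy as np
import pandas as pd
import pytest

from ppescreen.io import INJECTIONS, TREATMENTS, ExpressionMatrix


def make_matrix(values: dict[str, list[float]], genes: list[str],
                n_replicates: int = 2) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a full-design column dict.

    ``values`` maps sample ids of the form ``{injection}_{treatment}_r{i}``
    to FPKM lists; missing design cells are simply absent.
    """
    rows = []
    for sid in values:
        injection, treatment, rep = sid.rsplit("_", 2)[0], None, None
        for inj in INJECTIONS:
            for treat in TREATMENTS:
                for i in range(1, n_replicates + 1):
                    if sid == f"{inj}_{treat}_r{i}":
                        rows.append({"sample_id": sid, "injection": inj,
                                     "treatment": treat, "replicate": i})
    samples = pd.DataFrame(rows).set_index("sample_id")
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))
    return ExpressionMatrix(values=frame, samples=samples)


@pytest.fixture
def full_design_matrix() -> ExpressionMatrix:
    """3 genes x full 4-group, 2-treatment, 2-replicate design (16 samples),
    constant FPKM 10 everywhere."""
    values = {}
    for inj in INJECTIONS:
        for treat in TREATMENTS:
            for rep in (1, 2):
                values[f"{inj}_{treat}_r{rep}"] = [10.0, 10.0, 10.0]
    return make_matrix(values, ["gA", "gB", "gC"])
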