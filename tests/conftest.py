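import numpy as np
import pandas as pd
import pytest

from chardir.expr_io import CASE, CONTROL, ExpressionMatrix, SampleAnnotation
from chardir.synthetic import toy_core_model


def make_matrix(values, genes=None, samples=None, scale_tag="log"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale_tag)


def make_annotation(case_ids, ctrl_ids):
    tab = pd.DataFrame(
        {
            "class_label": [CASE] * len(case_ids) + [CONTROL] * len(ctrl_ids),
            "cell_type": "",
            "origin": "",
        },
        index=list(case_ids) + list(ctrl_ids),
    )
    tab.index.name = "sample_id"
    return SampleAnnotation(tab)


@pytest.fixture(scope="session")
def toy_model():
    return toy_core_model()


@pytest.fixture
def two_class_8():
    """3 genes × (4 case + 4 control), gene 0 shifted up in cases."""
    rng = np.random.default_rng(42)
    vals = rng.normal(5.0, 1.0, (3, 8))
    vals[0, :4] += 2.0
    em = make_matrix(vals, samples=[f"c{i}" for i in range(4)] + [f"k{i}" for i in range(4)])
    ann = make_annotation([f"c{i}" for i in range(4)], [f"k{i}" for i in range(4)])
    return em, ann
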