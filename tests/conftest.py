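import numpy as np
import pandas as pd
import pytest

from musclenet import ExpressionMatrix, SampleAnnotation


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"S{i+1}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_annotation(samples, groups) -> SampleAnnotation:
    return SampleAnnotation(
        pd.DataFrame({"group": list(groups)}, index=pd.Index(samples, name="sample_id"))
    )


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    return make_matrix(rng.normal(7, 1, size=(20, 6)))


@pytest.fixture
def toy_annotation(toy_matrix) -> SampleAnnotation:
    return make_annotation(toy_matrix.sample_ids, ["control"] * 3 + ["case"] * 3)
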