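import numpy as np
import pandas as pd
import pytest

from ecselect.cq import CqMatrix, SampleSheet


def random_matrix(rng, n_assays, n_samples, low=15.0, high=30.0):
    """Dense random CqMatrix for oracle comparisons."""
    cq = pd.DataFrame(
        rng.uniform(low, high, size=(n_assays, n_samples)),
        index=[f"assay{i}" for i in range(n_assays)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return CqMatrix(cq)


def two_group_sheet(n_case, n_control, case="cancer", control="control"):
    samples = [f"{case}_{i}" for i in range(n_case)] + [
        f"{control}_{i}" for i in range(n_control)
    ]
    groups = [case] * n_case + [control] * n_control
    return SampleSheet(
        pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample"))
    )


def matrix_from_rows(rows: dict, samples=None) -> CqMatrix:
    cq = pd.DataFrame(rows).T
    if samples is not None:
        cq.columns = samples
    cq.index.name = "assay"
    return CqMatrix(cq)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
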