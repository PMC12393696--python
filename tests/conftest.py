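import numpy as np
import pandas as pd
import pytest

from mgmtperf import (
    ContextMatrix,
    GeneratorConfig,
    PracticeMatrix,
    adjust_scores,
    compute_scores,
    generate_cbo_panel,
)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_cbo_panel(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def practice_matrix(default_bundle):
    return PracticeMatrix.from_frame(default_bundle.practices, default_bundle.domain_map)


@pytest.fixture(scope="session")
def scores(practice_matrix):
    return compute_scores(practice_matrix)


@pytest.fixture(scope="session")
def context(default_bundle):
    return ContextMatrix.from_frame(default_bundle.context)


@pytest.fixture(scope="session")
def adjusted(scores, context):
    return adjust_scores(scores, context, mode="fitted", restandardize=True)


@pytest.fixture(scope="session")
def adjusted_frame(adjusted):
    return adjusted.to_frame()


@pytest.fixture(scope="session")
def panel(default_bundle):
    return default_bundle.panel


def toy_practice_matrix(values: np.ndarray, domains: list[str] | None = None, **kwargs):
    """Build a PracticeMatrix from a raw value array, one domain per prefix."""
    n, j = values.shape
    if domains is None:
        domains = ["d"] * j
    cols = [f"{domains[k]}_item{k:02d}" for k in range(j)]
    frame = pd.DataFrame(values, columns=cols)
    frame.insert(0, "cbo_id", [f"C{i:03d}" for i in range(n)])
    domain_map = dict(zip(cols, domains))
    return PracticeMatrix(
        cbo_ids=list(frame["cbo_id"]),
        items=frame.drop(columns=["cbo_id"]),
        domain_map=domain_map,
        **kwargs,
    )
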