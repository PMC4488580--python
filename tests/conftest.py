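import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gliomanet import synthetic
from gliomanet.expression import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_two_condition():
    """Two-condition expression with 7 A-coupled and 7 B-coupled hubs.

    300 genes, 150 samples per condition, target correlation 0.8 —
    shared by the MI-network recovery tests.
    """
    graph, truth = synthetic.make_interactome(300, 3, 25, seed=2)
    synthetic.plant_regulators(truth, 14, 10, seed=3)
    expr = synthetic.make_two_condition_expression(
        truth, 150, 150, target_corr=0.8, noise_sd=1.0, seed=4
    )
    return graph, truth, expr


@pytest.fixture()
def small_expr():
    """Tiny two-condition matrix with one strongly shifted gene."""
    rng = np.random.default_rng(0)
    data = rng.normal(size=(20, 12))
    data[0, 6:] += 4.0  # clear DE gene
    genes = [f"g{i}" for i in range(20)]
    samples = [f"s{i}" for i in range(12)]
    conditions = {s: ("A" if i < 6 else "B") for i, s in enumerate(samples)}
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples), conditions)
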