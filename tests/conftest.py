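import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from marasvd import mara_core, synthetic_data
from marasvd.data_io import ExpressionMatrix, SampleDesign, SiteCountMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_expression():
    return ExpressionMatrix(
        ["pA", "pB", "pC"], ["s1", "s2"],
        np.array([[1.0, 2.0], [3.0, 4.5], [5.25, 6.0]]),
    )


@pytest.fixture
def tiny_counts():
    return SiteCountMatrix(
        ["pA", "pB", "pC"], ["m1", "m2"],
        np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 1.0]]),
    )


@pytest.fixture
def kinetic_design():
    rows = []
    for t in (1, 3, 7, 14, 28, 57, 91):
        for cond in ("treated", "control"):
            rows.append({"sample_id": f"{cond}_d{t}", "dataset": "kinetic",
                         "condition": cond, "time": float(t), "replicate": 1})
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic kinetic study (500 promoters, 20 motifs, 14 samples)."""
    return synthetic_data.generate_study(synthetic_data.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def noisefree_study():
    config = synthetic_data.GeneratorConfig(
        seed=5, noise_sd=0.0, noise_mode="absolute")
    return synthetic_data.generate_study(config)


@pytest.fixture(scope="session")
def fitted_default(default_study):
    table = mara_core.fit_activities(
        default_study.expression, default_study.counts,
        mara_core.FitConfig(ridge_penalty=1e-3, seed=1))
    return default_study, table
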