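import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ordmi import MaskedTable, Schema, VariableSpec

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_schema() -> Schema:
    """Three predictors (binary, nominal, continuous) and a 3-level outcome."""
    return Schema([
        VariableSpec("smoke", "binary", ("no", "yes"), "no"),
        VariableSpec("income", "nominal", ("low", "mid", "high"), "low"),
        VariableSpec("age", "continuous"),
        VariableSpec("severity", "ordinal", ("none", "mild", "severe"),
                     role="outcome"),
    ])


@pytest.fixture
def tiny_table(tiny_schema) -> MaskedTable:
    data = pd.DataFrame({
        "smoke": ["yes", "no", np.nan, "yes", "no", "no"],
        "income": ["low", np.nan, "high", "mid", "low", "high"],
        "age": [10.0, 11.5, 9.0, np.nan, 10.5, 12.0],
        "severity": ["none", "mild", "severe", "none", "mild", "none"],
    })
    return MaskedTable(tiny_schema, data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
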