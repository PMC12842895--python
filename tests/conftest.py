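import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def ecv_series():
    """A three-bin endocranial-volume-style series, ages in years BP."""
    from qgtempo import TraitSeries

    bins = pd.DataFrame(
        {
            "age": [2_000_000.0, 1_000_000.0, 10_000.0],
            "mean": [400.0, 900.0, 1350.0],
            "sd": [45.0, 90.0, 130.0],
            "n": [8, 12, 30],
        }
    )
    return TraitSeries(lineage_label="ecv", bins=bins, age_unit="years",
                       generation_time=29.0)


@pytest.fixture
def specimen_table():
    """Two groups of six individuals each, both sexes plus one unknown."""
    from qgtempo import SpecimenTable

    rows = []
    values_a = [950, 1000, 1050, 1100, 1150, 1200]
    values_b = [1250, 1300, 1350, 1400, 1450, 1500]
    sexes = ["female", "female", "female", "male", "male", "unknown"]
    for i, (v, s) in enumerate(zip(values_a, sexes)):
        rows.append((f"a{i}", "group_a", s, v))
    for i, (v, s) in enumerate(zip(values_b, sexes)):
        rows.append((f"b{i}", "group_b", s, v))
    return SpecimenTable(
        records=pd.DataFrame(rows, columns=["specimen_id", "group", "sex", "value"])
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
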