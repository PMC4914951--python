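import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sigwrap import BinaryLabels, FeatureTable, PlantedSpec, generate_planted

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_table():
    """4 samples x 3 features, finite, balanced labels."""
    values = np.array(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0], [1.5, 2.5, 3.5]]
    )
    table = FeatureTable(values, ("s1", "s2", "s3", "s4"), ("f1", "f2", "f3"))
    labels = BinaryLabels(("a", "a", "b", "b"))
    return table, labels


@pytest.fixture(scope="session")
def planted_separable():
    """One strong feature among noise; small enough for fast fits."""
    spec = PlantedSpec(n_per_class=15, p=20, n_informative=1, effect=3.0, seed=42)
    return generate_planted(spec)
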