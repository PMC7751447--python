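import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from realmkit.bank import ItemBank, ItemRecord
from realmkit.responses import ResponseMatrix
from realmkit.simulate import (
    LanguageSpec,
    SimulationConfig,
    generate_item_bank,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def simulate_2pl(a, b, theta, rng):
    """Direct Bernoulli draws from the 2PL — independent of the package IRF."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    eta = a[None, :] * (theta[:, None] - b[None, :])
    P = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(P.shape) < P).astype(float)


@pytest.fixture(scope="session")
def small_bank() -> ItemBank:
    items = []
    for s, n in (("low", 4), ("medium", 3), ("high", 3)):
        for k in range(n):
            items.append(
                ItemRecord(f"{s[0]}{k + 1}", {"en": f"word_{s}_{k + 1}"}, s)
            )
    return ItemBank(tuple(items), ("en",))


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Scaled-down three-language study used by fast integration tests."""
    return SimulationConfig(
        seed=17,
        items_per_stratum={"low": 6, "medium": 5, "high": 5},
        languages={
            "en": LanguageSpec(n=150, mode="separated"),
            "ko": LanguageSpec(n=140, mode="compressed"),
        },
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    from realmkit.simulate import generate_study

    return generate_study(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250930)


def random_response_matrix(rng, n=12, items=("i1", "i2", "i3"), missing=0.0):
    vals = (rng.random((n, len(items))) < 0.5).astype(float)
    if missing:
        vals[rng.random(vals.shape) < missing] = np.nan
    meta = pd.DataFrame(
        {
            "person_id": [f"p{k}" for k in range(n)],
            "language": "en",
            "arm": "none",
            "timepoint": "none",
        }
    )
    return ResponseMatrix(pd.DataFrame(vals, columns=list(items)), meta)
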