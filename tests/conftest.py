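import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pepmine as pm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return pm.load_registry()


@pytest.fixture(scope="session")
def prep(registry):
    return registry["prep"]


@pytest.fixture(scope="session")
def trypsin(registry):
    return registry["trypsin"]


@pytest.fixture(scope="session")
def gi_enzymes(registry):
    from pepmine.cascade import default_gi_enzymes

    return default_gi_enzymes()


@pytest.fixture
def toy_after_k():
    """Toy enzyme cleaving C-terminal to every Lys."""
    return pm.EnzymeSpec(name="after_k", rules=(pm.pattern(p1="K"),))


@pytest.fixture(scope="session")
def final_survivors():
    """The packaged 30-peptide survivor fixture -> list of (sequence, status)."""
    from importlib import resources

    import pandas as pd

    with resources.as_file(
        resources.files("pepmine").joinpath(
            "data/reference/final_screened_peptides.tsv"
        )
    ) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return list(zip(df["sequence"], df["status"]))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
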