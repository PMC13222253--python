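import numpy as np
import pytest

from remarkov.basecase import base_case_bundle
from remarkov.parameters import LifeTable, ModelConfig, TransitionParams


@pytest.fixture(scope="session")
def base_bundle():
    return base_case_bundle()


@pytest.fixture()
def bundle(base_bundle):
    """Fresh mutable copy of the base case for each test."""
    return base_bundle.copy()


def constant_life_table(q: float, lo: int = 40, hi: int = 99) -> LifeTable:
    ages = np.arange(lo, hi + 1)
    return LifeTable(ages=ages, qx=np.full(ages.size, q))


@pytest.fixture()
def immortal_life_table():
    return constant_life_table(0.0)


@pytest.fixture()
def default_config():
    return ModelConfig()


def simple_params(p_remission=0.0, p_relapse=0.0, **kw) -> TransitionParams:
    return TransitionParams(p_remission=p_remission, p_relapse=p_relapse, **kw)
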