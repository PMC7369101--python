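import numpy as np
import pandas as pd
import pytest

from admarkov import (
    GeneratorParams,
    reference_inputs,
    reference_intervention,
    run_cohort,
    run_treated_cohort,
)
from admarkov.synthetic_registry import generate_registry


@pytest.fixture(scope="session")
def ref_inputs():
    return reference_inputs()


@pytest.fixture(scope="session")
def base_trajectory(ref_inputs):
    return run_cohort(ref_inputs)


@pytest.fixture(scope="session")
def treated_trajectory(ref_inputs):
    return run_treated_cohort(ref_inputs, reference_intervention())


@pytest.fixture(scope="session")
def small_registry():
    """A modest synthetic registry with informative drop-out (n=400)."""
    params = GeneratorParams(n_individuals=400, seed=11)
    return generate_registry(params), params


def zero_life_table(max_age: int = 110) -> pd.DataFrame:
    ages = np.arange(60, max_age + 1)
    return pd.DataFrame({"age": ages, "q": np.zeros(len(ages))})


def flat_life_table(q: float, max_age: int = 110) -> pd.DataFrame:
    ages = np.arange(60, max_age + 1)
    return pd.DataFrame({"age": ages, "q": np.full(len(ages), q)})
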