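import numpy as np
import pytest

from depcat import (ItemBank, PopulationSpec, QuadratureGrid, fit_mml_em,
                    load_cat_depression_bank, simulate_responses,
                    simulate_thetas)
from depcat.bank import ItemParameters


@pytest.fixture(scope="session")
def table4_bank() -> ItemBank:
    return load_cat_depression_bank()


@pytest.fixture(scope="session")
def grid() -> QuadratureGrid:
    return QuadratureGrid.standard_normal()


def make_grm_bank(J: int, seed: int, a_range=(0.8, 2.5)) -> ItemBank:
    """Random-but-seeded GRM bank with well-spread ordered thresholds."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(*a_range, J)
    b = np.sort(rng.normal(0.0, 1.0, (J, 3)) + np.array([-1.0, 0.0, 1.0]),
                axis=1)
    items = [ItemParameters(f"i{j + 1}", "GRM", 4, a=float(a[j]),
                            b=tuple(b[j])) for j in range(J)]
    return ItemBank(items, name=f"sim_grm_{J}")


@pytest.fixture(scope="session")
def grm_sim():
    """A J=20, N=1000 GRM-simulated dataset with its generating bank."""
    bank = make_grm_bank(20, seed=3)
    thetas, _ = simulate_thetas(PopulationSpec(1000, seed=5))
    responses = simulate_responses(bank, thetas, seed=6)
    return bank, thetas, responses


@pytest.fixture(scope="session")
def grm_fit(grm_sim):
    """One calibrated GRM fit of the shared simulated dataset."""
    _, _, responses = grm_sim
    return fit_mml_em(responses, "grm")
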