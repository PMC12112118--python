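import numpy as np
import pytest

import ohfate as of


@pytest.fixture(scope="session")
def bpa() -> of.Scenario:
    """Bisphenol A scenario: 15 mA/cm2, 5 h, printed constants."""
    return of.builtin_scenario("bpa15")


@pytest.fixture(scope="session")
def rhodamine() -> of.Scenario:
    """Rhodamine B scenario: 20 mA/cm2, 3 h."""
    return of.builtin_scenario("rhodamine20")


@pytest.fixture(scope="session")
def bpa_trajectory(bpa):
    grid = np.linspace(0.0, bpa.duration_s, 61)
    return of.simulate_chain(bpa.system, bpa.constants, bpa.profile, grid)


@pytest.fixture(scope="session")
def lc50_table():
    return of.load_lc50_table()


@pytest.fixture(scope="session")
def bpa_reference():
    return of.ToxRecord("Bisphenol A", 228.29, 3.24)


def random_scenario(rng: np.random.Generator) -> of.Scenario:
    """A random but physically plausible chain scenario for property tests."""
    n_pools = int(rng.integers(3, 6))
    rates = 10 ** rng.uniform(9.0, 10.7, size=n_pools - 1)
    # occasionally force a repeated step to exercise the confluent branch
    if n_pools >= 4 and rng.random() < 0.3:
        rates[-1] = rates[-2]
    c0 = 10 ** rng.uniform(-4.5, -3.5)
    coeffs = (rng.uniform(0.01, 0.1), rng.uniform(1e-4, 5e-4),
              rng.uniform(-5e-8, 0.0), rng.uniform(0.0, 2e-12))
    poly = of.H2O2Poly(coeffs, (0.0, 18000.0))
    return of.Scenario(
        name="random",
        system=of.ChainSystem(tuple(f"S{i}" for i in range(n_pools)), c0),
        constants=of.KineticConstants(tuple(rates)),
        poly=poly,
        k_prop=10 ** rng.uniform(-11.0, -9.5),
        duration_s=18000.0,
    )
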