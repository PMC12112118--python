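"""Scenario definitions and synthetic measurement generation.

A :class:`Scenario` bundles everything needed to run the model end to end:
the lumped chain, its rate constants, the fitted H2O2 polynomial, and the
radical proportionality factor (given directly or resolved from a current
density through the linear law).  Two scenarios ship with the package:

``bpa15``
    Bisphenol A at 15 mA/cm2 over 5 h: C0 = 1.31e-4 M, cubic H2O2
    coefficients B = (3.09e-2, 3.39e-4, -3.10e-8, 8.81e-13), k = 1e-10,
    chain constants (1.002e10, 3.92e10, 1.387e10) 1/(M*s) for the
    BPA -> two-ring -> one-ring -> CO2 chain.
``rhodamine20``
    Rhodamine B at 20 mA/cm2 over 3 h: C0 = 1.04e-4 M, constants
    (9e9, 1.2e10, 1.2e10) 1/(M*s), k from the current-density law.

Synthetic measurement tables emulate hourly aliquot sampling: the H2O2
column from the polynomial and the pool columns from the simulated chain,
optionally corrupted with seeded Gaussian noise (multiplicative by default —
concentration measurement errors scale with the level).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_model import ChainSystem, KineticConstants
from .errors import ContractViolation
from .radical_profile import CurrentDensityLaw, H2O2Poly, OhProfile, k_of_j
from .simulate import simulate_chain

__all__ = [
    "Scenario",
    "NoiseModel",
    "builtin_scenario",
    "BUILTIN_SCENARIOS",
    "generate_measurements",
    "perturb_truth",
]

BUILTIN_SCENARIOS = ("bpa15", "rhodamine20")

#: Default relative noise level, mirroring the ~4% RMSE of the calibration fit.
DEFAULT_NOISE_SIGMA = 0.04


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation/estimation setting."""

    name: str
    system: ChainSystem
    constants: KineticConstants
    poly: H2O2Poly
    k_prop: float
    duration_s: float
    sample_interval_s: float = 3600.0
    current_density_mA_cm2: float | None = None
    current_law: CurrentDensityLaw | None = None

    def __post_init__(self):
        if not self.duration_s > 0:
            raise ContractViolation("duration must be > 0")
        if not self.sample_interval_s > 0:
            raise ContractViolation("sampling interval must be > 0")
        lo, hi = self.poly.valid_domain
        if self.duration_s > hi + 1e-9 * hi:
            raise ContractViolation(
                f"duration {self.duration_s}s exceeds polynomial domain [{lo},{hi}]s"
            )
        if not self.k_prop > 0:
            raise ContractViolation("k_prop must be > 0")

    @property
    def profile(self) -> OhProfile:
        return OhProfile(self.poly, self.k_prop,
                         self.system.initial_molar_conc)

    @property
    def sample_grid(self) -> np.ndarray:
        """Default hourly-style grid: 0, dt, 2dt, ..., duration."""
        n = int(round(self.duration_s / self.sample_interval_s))
        return np.linspace(0.0, n * self.sample_interval_s, n + 1)


@dataclass(frozen=True)
class NoiseModel:
    """Seeded Gaussian measurement noise, additive or multiplicative."""

    kind: str = "multiplicative"
    sigma: float = DEFAULT_NOISE_SIGMA
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("additive", "multiplicative"):
            raise ContractViolation("noise kind must be additive|multiplicative")
        if self.sigma < 0:
            raise ContractViolation("sigma must be >= 0")
        if self.sigma > 0 and self.seed is None:
            raise ContractViolation("a seed is mandatory when sigma > 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.asarray(values, dtype=float)
        eps = rng.standard_normal(np.shape(values))
        if self.kind == "multiplicative":
            noisy = values * (1.0 + self.sigma * eps)
        else:
            noisy = values + self.sigma * eps
        return np.clip(noisy, 0.0, None)


def builtin_scenario(name: str) -> Scenario:
    """Load one of the packaged scenarios by name."""
    from importlib import resources

    from .io import load_scenario_config

    if name not in BUILTIN_SCENARIOS:
        raise ContractViolation(
            f"unknown scenario {name!r}; available: {', '.join(BUILTIN_SCENARIOS)}"
        )
    ref = resources.files("ohfate.data") / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_scenario_config(path)


def generate_measurements(scenario: Scenario,
                          noise: NoiseModel | None = None,
                          grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Synthetic measurement table: time_s, one column per pool, h2o2_star.

    With ``noise=None`` (or sigma 0) the table holds exact model values;
    otherwise the noise model is applied reproducibly from its seed.  Values
    are clipped at zero like any real concentration reading.
    """
    t = scenario.sample_grid if grid is None else np.asarray(grid, dtype=float)
    traj = simulate_chain(scenario.system, scenario.constants,
                          scenario.profile, t)
    h2o2 = scenario.poly(t)
    data = {"time_s": t}
    states = traj.states
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        states = noise.apply(states, rng)
        h2o2 = noise.apply(h2o2, rng)
    for i, label in enumerate(scenario.system.species_names):
        data[label] = states[:, i]
    data["h2o2_star"] = h2o2
    return pd.DataFrame(data)


def perturb_truth(scenario: Scenario, factors: Sequence[float]) -> Scenario:
    """Scenario with chain constants multiplied componentwise (for recovery
    and identifiability experiments)."""
    f = np.asarray(factors, dtype=float)
    if f.size != len(scenario.constants):
        raise ContractViolation(
            f"need {len(scenario.constants)} factors, got {f.size}"
        )
    if np.any(f <= 0):
        raise ContractViolation("perturbation factors must be > 0")
    new_rates = KineticConstants(tuple(scenario.constants.as_array() * f))
    return replace(scenario, constants=new_rates)
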