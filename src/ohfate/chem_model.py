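"""Lumped sequential oxidation-chain kinetics.

A pollutant attacked by hydroxyl radicals is modelled as an ordered chain of
pools:  parent -> intermediate pool(s) -> CO2.  Every step is an elementary
second-order reaction with *the same* oxidant, so for a prescribed radical
level the chain is linear in the pool concentrations:

    d[X_0]/dt = -k_0 [OH] [X_0]
    d[X_i]/dt =  k_{i-1} [OH] [X_{i-1}] - k_i [OH] [X_i]
    d[X_N]/dt =  k_{N-1} [OH] [X_{N-1}]          (terminal pool, CO2)

The chain conserves total (normalised) mass exactly.  In the transformed
variable u(t) = INT_0^t [OH] ds (the radical *exposure*, M*s) the system
becomes a constant-coefficient sequential decay chain whose closed-form
solution is the classical Bateman formula; :func:`bateman_chain` implements
it with a confluent branch for repeated rate constants and serves as the
exact oracle against which numerical trajectories are verified.

Normalisation convention: concentrations are divided by the parent's initial
molar concentration C0, time by a fixed scaling factor (default 1e-6 s).
A dimensionless rate constant k* maps back to an absolute second-order
constant as  k = k* / (scaling_factor * C0)  with units 1/(M*s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractViolation

__all__ = [
    "ChainSystem",
    "KineticConstants",
    "NormalizationScheme",
    "chain_rhs",
    "rescale_constants",
    "inverse_rescale_constants",
    "bateman_chain",
    "DEFAULT_SCALING_FACTOR_S",
]

#: Time scaling factor used to form dimensionless time t* = t / scaling.
DEFAULT_SCALING_FACTOR_S = 1e-6

#: Relative rate difference below which two chain steps are treated as equal
#: and the confluent (repeated-eigenvalue) Bateman branch is used.
REPEATED_RATE_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSystem:
    """An ordered lumped reaction chain.

    Parameters
    ----------
    species_names
        Ordered pool labels; first is the parent pollutant, last the mineral
        end-product (CO2).
    initial_molar_conc
        Parent initial concentration C0 in mol/L.
    initial_state
        Normalised pool concentrations at t=0 (default: all mass in the
        parent).  Must be non-negative and sum to 1.
    lump_members
        Optional mapping pool-label -> list of (name, molar_mass_g_mol,
        lc50_mg_L) tuples describing the identified compounds lumped into a
        pseudo-component; consumed by the toxicity layer.
    """

    species_names: tuple[str, ...]
    initial_molar_conc: float
    initial_state: tuple[float, ...] = ()
    lump_members: dict = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.species_names)
        object.__setattr__(self, "species_names", names)
        if len(names) < 3:
            raise ContractViolation(
                f"chain needs >=3 pools (parent, >=1 intermediate, CO2); got {len(names)}"
            )
        if len(set(names)) != len(names):
            raise ContractViolation("species names must be unique")
        if not self.initial_molar_conc > 0:
            raise ContractViolation("initial molar concentration C0 must be > 0")
        state = tuple(self.initial_state) or (1.0,) + (0.0,) * (len(names) - 1)
        object.__setattr__(self, "initial_state", state)
        if len(state) != len(names):
            raise ContractViolation("initial_state length must match species count")
        if any(x < 0 for x in state):
            raise ContractViolation("initial_state entries must be >= 0")
        if abs(sum(state) - 1.0) > 1e-12:
            raise ContractViolation("initial_state must sum to 1 within 1e-12")

    @property
    def n_pools(self) -> int:
        return len(self.species_names)

    @property
    def parent(self) -> str:
        return self.species_names[0]

    @property
    def terminal(self) -> str:
        return self.species_names[-1]

    def index(self, label: str) -> int:
        try:
            return self.species_names.index(label)
        except ValueError:
            raise ContractViolation(
                f"unknown pool {label!r}; chain has {self.species_names}"
            ) from None


@dataclass(frozen=True)
class KineticConstants:
    """Second-order rate constants of the chain, one per step, in 1/(M*s)."""

    rates: tuple[float, ...]

    def __post_init__(self):
        rates = tuple(float(r) for r in self.rates)
        object.__setattr__(self, "rates", rates)
        if len(rates) < 1:
            raise ContractViolation("at least one chain step is required")
        if any(not r > 0 for r in rates):
            raise ContractViolation(f"all rate constants must be > 0; got {rates}")

    def __len__(self) -> int:
        return len(self.rates)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)


@dataclass(frozen=True)
class NormalizationScheme:
    """Time/concentration scaling linking dimensionless and absolute constants."""

    scaling_factor: float = DEFAULT_SCALING_FACTOR_S  # s
    reference_conc: float = 1.0                        # mol/L (C0)

    def __post_init__(self):
        if not self.scaling_factor > 0:
            raise ContractViolation("scaling_factor must be > 0")
        if not self.reference_conc > 0:
            raise ContractViolation("reference_conc must be > 0")


# ---------------------------------------------------------------------------
# Rate equations
# ---------------------------------------------------------------------------

def chain_rhs(state: Sequence[float], oh_level: float,
              rates: Sequence[float]) -> np.ndarray:
    """Time derivative of the pool vector for a given radical level.

    Works identically in the dimensionless frame (``state`` and ``oh_level``
    normalised, ``rates`` dimensionless) and in absolute time (``oh_level``
    in mol/L, ``rates`` in 1/(M*s)) because the right-hand side is bilinear.

    The derivatives telescope, so their sum is exactly zero (mass balance).
    """
    x = np.asarray(state, dtype=float)
    k = np.asarray(rates, dtype=float)
    if x.ndim != 1 or k.ndim != 1 or x.size != k.size + 1:
        raise ContractViolation(
            f"state length ({x.size}) must equal rates length + 1 ({k.size + 1})"
        )
    if oh_level < 0:
        raise ContractViolation("radical level must be >= 0")
    flux = k * x[:-1] * oh_level          # flux through each chain step
    dx = np.empty_like(x)
    dx[0] = -flux[0]
    dx[1:-1] = flux[:-1] - flux[1:]
    dx[-1] = flux[-1]
    return dx


def rescale_constants(rates_star: Sequence[float],
                      scheme: NormalizationScheme) -> KineticConstants:
    """Convert dimensionless chain constants to absolute 1/(M*s) units.

    k = k* / (scaling_factor * C0).  Zero maps to zero; the result for a
    positive input round-trips through :func:`inverse_rescale_constants`
    to floating precision.
    """
    denom = scheme.scaling_factor * scheme.reference_conc
    rates = tuple(float(ks) / denom for ks in rates_star)
    if any(r == 0 for r in rates):
        # KineticConstants forbids zero; callers needing the raw numbers
        # (e.g. printing a zero optimiser bound) can do the division inline.
        raise ContractViolation("dimensionless constants must be > 0 to rescale")
    return KineticConstants(rates)


def inverse_rescale_constants(constants: KineticConstants,
                              scheme: NormalizationScheme) -> tuple[float, ...]:
    """Absolute 1/(M*s) constants -> dimensionless k* = k * scaling * C0."""
    factor = scheme.scaling_factor * scheme.reference_conc
    return tuple(r * factor for r in constants.rates)


# ---------------------------------------------------------------------------
# Closed-form (Bateman) oracle
# ---------------------------------------------------------------------------

def _merge_term(groups: list, lam: float, degree: int, coeff: float) -> None:
    """Accumulate coeff*u^degree*exp(-lam*u) into the term list."""
    for entry in groups:
        ref = entry[0]
        scale = max(abs(ref), abs(lam))
        if abs(ref - lam) <= REPEATED_RATE_RTOL * scale or (ref == 0.0 and lam == 0.0):
            poly = entry[1]
            while len(poly) <= degree:
                poly.append(0.0)
            poly[degree] += coeff
            return
    groups.append([lam, [0.0] * degree + [coeff]])


def _propagate(groups_prev: list, lam_next: float, rate_in: float,
               init_next: float) -> list:
    """Closed-form solution of pool j given the polynomial-exponential
    representation of pool j-1.

    Pool j obeys  N_j' = rate_in * N_{j-1} - lam_next * N_j  (in exposure
    time), whose integrating-factor solution only needs integrals of
    u^m * exp(-a u).  When a vanishes (repeated rates) the integral is the
    confluent power  u^{m+1}/(m+1) — no division by the rate gap occurs.
    """
    out: list = []
    if init_next != 0.0:
        _merge_term(out, lam_next, 0, init_next)
    for lam_t, poly in groups_prev:
        a = lam_t - lam_next
        scale = max(abs(lam_t), abs(lam_next))
        confluent = abs(a) <= REPEATED_RATE_RTOL * scale or scale == 0.0
        for m, c in enumerate(poly):
            if c == 0.0:
                continue
            amp = rate_in * c
            if confluent:
                _merge_term(out, lam_next, m + 1, amp / (m + 1))
            else:
                fact_m = math.factorial(m)
                _merge_term(out, lam_next, 0, amp * fact_m / a ** (m + 1))
                for r in range(m + 1):
                    _merge_term(
                        out, lam_t, r,
                        -amp * (fact_m / math.factorial(r)) / a ** (m - r + 1),
                    )
    return out


def _bateman_terms(decay: np.ndarray, initial_state: Sequence[float]) -> list:
    """Per-pool polynomial-exponential terms of the chain solution."""
    terms = []
    first: list = []
    if initial_state[0] != 0.0:
        _merge_term(first, decay[0], 0, float(initial_state[0]))
    terms.append(first)
    for j in range(1, decay.size):
        terms.append(
            _propagate(terms[j - 1], decay[j], decay[j - 1], float(initial_state[j]))
        )
    return terms


def _eval_terms(groups: list, u: np.ndarray) -> np.ndarray:
    total = np.zeros_like(u, dtype=float)
    for lam, poly in groups:
        pw = np.zeros_like(u, dtype=float)
        for m, c in enumerate(poly):
            if c != 0.0:
                pw += c * u ** m
        with np.errstate(over="ignore", under="ignore"):
            total += pw * np.exp(-lam * u)
    return total


def bateman_chain(exposure, rates: KineticConstants | Sequence[float],
                  initial_state: Sequence[float]) -> np.ndarray:
    """Exact chain solution as a function of radical exposure u = INT [OH] dt.

    Parameters
    ----------
    exposure
        Scalar or array of exposures in M*s; must be >= 0.
    rates
        Absolute second-order constants (1/(M*s)), one per chain step.
    initial_state
        Normalised pool vector at u = 0.

    Returns
    -------
    ndarray
        Pool vector (last axis indexes pools).  Pools sum to the initial sum
        to ~1e-10; rate constants equal to within a relative 1e-9 are handled
        by the confluent-limit branch.
    """
    k = rates.as_array() if isinstance(rates, KineticConstants) else np.asarray(rates, float)
    x0 = np.asarray(initial_state, dtype=float)
    if x0.size != k.size + 1:
        raise ContractViolation(
            f"initial_state length ({x0.size}) must equal rates length + 1 ({k.size + 1})"
        )
    u = np.asarray(exposure, dtype=float)
    if np.any(u < 0):
        raise ContractViolation("exposure must be >= 0")
    decay = np.append(k, 0.0)             # terminal pool does not decay
    terms = _bateman_terms(decay, x0)
    flat = np.atleast_1d(u).astype(float)
    out = np.stack([_eval_terms(g, flat) for g in terms], axis=-1)
    if u.ndim == 0:
        return out[0]
    return out
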