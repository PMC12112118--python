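"""Time-dependent mixture toxicity from simulated pool profiles.

Acute toxicity of the treated solution is expressed as an additive toxic-unit
sum.  Each compound contributes (mass concentration)/LC50; with normalised
molar pools x_i* this becomes x_i* * M_i / LC50_i up to the common factor C0.
Normalising by the parent's own potency anchors the scale:

    Toxicity%(t) = 100 * (LC50_ref / M_ref) * sum_i x_i*(t) * M_i / LC50_i

so a solution of pure parent reads exactly 100% and full mineralisation reads
0% (CO2 carries zero potency).  Lumped pseudo-components (e.g. the two-ring
and one-ring intermediate pools) get an aggregate potency of their identified
members — arithmetic mean by default, min/max selectable.

LC50 values are 96-h Fathead Minnow endpoints (mg/L) taken from a QSAR
consensus estimate; they are consumed as plain inputs here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolation
from .simulate import Trajectory

__all__ = [
    "ToxRecord",
    "LumpedPotency",
    "lump_potency",
    "potencies_from_table",
    "load_lc50_table",
    "toxicity_profile",
    "toxicity_summary",
]

_LUMP_METHODS = ("mean", "min", "max")


@dataclass(frozen=True)
class ToxRecord:
    """One compound: molar mass (g/mol) and 96-h Fathead Minnow LC50 (mg/L)."""

    name: str
    molar_mass: float
    lc50: float

    def __post_init__(self):
        if not self.molar_mass > 0:
            raise ContractViolation(f"{self.name}: molar mass must be > 0")
        if not self.lc50 > 0:
            raise ContractViolation(f"{self.name}: LC50 must be > 0")

    @property
    def potency(self) -> float:
        """Mass potency M/LC50 — toxic units contributed per mole per litre."""
        return self.molar_mass / self.lc50


@dataclass(frozen=True)
class LumpedPotency:
    """Per-pool aggregate potencies, aligned with a chain's species order.

    The terminal (CO2) pool has potency 0 by construction.
    """

    potencies: tuple[float, ...]
    pools: tuple[str, ...]
    method: str = "mean"

    def __post_init__(self):
        if len(self.potencies) != len(self.pools):
            raise ContractViolation("potencies and pools must align")
        if any(p < 0 for p in self.potencies):
            raise ContractViolation("potencies must be >= 0")
        if self.potencies[-1] != 0.0:
            raise ContractViolation("terminal pool potency must be 0 (mineral products)")


def lump_potency(members: Sequence[ToxRecord], method: str = "mean") -> float:
    """Aggregate potency of a lumped pseudo-component."""
    if not members:
        raise ContractViolation("a lumped pool needs at least one member compound")
    if method not in _LUMP_METHODS:
        raise ContractViolation(f"method must be one of {_LUMP_METHODS}")
    p = np.array([m.potency for m in members])
    return float({"mean": np.mean, "min": np.min, "max": np.max}[method](p))


def load_lc50_table(path=None) -> pd.DataFrame:
    """Read a compound toxicity table (columns: name, pool, molar_mass_g_mol,
    lc50_mg_L).  Without a path, the packaged BPA-intermediate table is used."""
    if path is None:
        ref = resources.files("ohfate.data") / "table1_lc50.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "pool", "molar_mass_g_mol", "lc50_mg_L"}
    missing = required - set(df.columns)
    if missing:
        raise ContractViolation(f"LC50 table missing columns: {sorted(missing)}")
    return df


def potencies_from_table(table: pd.DataFrame, pools: Sequence[str],
                         method: str = "mean") -> LumpedPotency:
    """Build aligned pool potencies from a toxicity table.

    Every non-terminal pool must have at least one member row; the terminal
    pool gets potency 0 regardless of the table.
    """
    pools = tuple(pools)
    values = []
    for pool in pools[:-1]:
        rows = table[table["pool"] == pool]
        members = [ToxRecord(r["name"], r["molar_mass_g_mol"], r["lc50_mg_L"])
                   for _, r in rows.iterrows()]
        values.append(lump_potency(members, method=method))
    values.append(0.0)
    return LumpedPotency(tuple(values), pools, method=method)


def toxicity_profile(traj: Trajectory, potencies: LumpedPotency,
                     reference: ToxRecord) -> np.ndarray:
    """Toxic-unit mixture toxicity (%) along a trajectory."""
    if potencies.pools != traj.species_names:
        raise ContractViolation(
            f"potency pools {potencies.pools} do not match trajectory pools "
            f"{traj.species_names}"
        )
    p = np.asarray(potencies.potencies)
    return 100.0 * (traj.states @ p) / reference.potency


def toxicity_summary(times: Sequence[float],
                     profile: Sequence[float]) -> tuple[float, float, float]:
    """(peak toxicity %, peak time s, reduction % at the final time).

    Peak is the discrete argmax with the earlier time winning ties; reduction
    is 100 minus the final value.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(profile, dtype=float)
    if t.size != y.size or t.size < 3:
        raise ContractViolation("need >= 3 aligned (time, toxicity) points")
    i = int(np.argmax(y))          # argmax returns the first maximum
    return float(y[i]), float(t[i]), float(100.0 - y[-1])
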