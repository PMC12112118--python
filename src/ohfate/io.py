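"""File formats: the time-series CSV and the scenario configuration.

All files use seconds for time (rate constants are 1/(M*s), so mixing hours
in would invite unit bugs) and normalised (dimensionless) concentrations,
with C0 carried in the scenario config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .chem_model import ChainSystem, KineticConstants
from .errors import ConfigError, ParseError
from .radical_profile import CurrentDensityLaw, H2O2Poly, k_of_j

__all__ = ["read_timeseries", "write_timeseries", "load_scenario_config"]

TIME_COLUMN = "time_s"


def read_timeseries(path) -> pd.DataFrame:
    """Read a time-series CSV (column ``time_s`` + one column per species).

    Validates the contract rather than repairing data: a missing time column,
    non-numeric cells, negative or non-monotone times all raise
    :class:`ParseError` naming the offending location.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.columns.str.startswith("Unnamed").any() or TIME_COLUMN not in df.columns:
        raise ParseError(f"{path}: header row with a '{TIME_COLUMN}' column is required")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row + 2}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ParseError(f"{path}: missing value in column {col!r}, row {row + 2}")
        df[col] = converted.astype(float)
    t = df[TIME_COLUMN].to_numpy()
    if t[0] != 0.0:
        raise ParseError(f"{path}: time axis must start at 0 s (got {t[0]})")
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ParseError(
            f"{path}: times must be strictly increasing "
            f"(violation between rows {row + 2} and {row + 3})"
        )
    value_cols = [c for c in df.columns if c != TIME_COLUMN]
    if (df[value_cols] < 0).any().any():
        raise ParseError(f"{path}: negative concentration values present")
    return df


def write_timeseries(table: pd.DataFrame, path) -> None:
    """Write a time-series table; round-trips through read_timeseries to
    better than 12 significant digits."""
    if TIME_COLUMN not in table.columns:
        raise ParseError(f"table lacks the mandatory '{TIME_COLUMN}' column")
    table.to_csv(path, index=False, float_format="%.15g")


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "name", "species", "c0_mol_per_L", "rate_constants_per_M_s", "h2o2_poly",
    "k_prop", "current_density_mA_cm2", "current_law", "duration_s",
    "sample_interval_s",
}
_POLY_KEYS = {"b_coeffs", "t_max_s", "fit_r2"}
_LAW_KEYS = {"slope_cm2_per_mA", "intercept", "fit_r2"}


def _require(cfg: Mapping, key: str, path):
    if key not in cfg:
        raise ConfigError(f"{path}: missing mandatory key {key!r}")
    return cfg[key]


def load_scenario_config(path) -> "Scenario":
    """Parse and validate a YAML scenario file into a :class:`Scenario`.

    Unknown keys are rejected (a typo must not silently drop a parameter).
    The radical proportionality factor is given either directly (``k_prop``)
    or resolved as ``current_law`` applied at ``current_density_mA_cm2``.
    """
    from .synthetic_data import Scenario

    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")

    name = str(_require(cfg, "name", path))
    species = _require(cfg, "species", path)
    c0 = float(_require(cfg, "c0_mol_per_L", path))
    rates = _require(cfg, "rate_constants_per_M_s", path)
    poly_cfg = _require(cfg, "h2o2_poly", path)
    duration = float(_require(cfg, "duration_s", path))

    unknown = set(poly_cfg) - _POLY_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown h2o2_poly keys {sorted(unknown)}")
    poly = H2O2Poly(
        tuple(float(b) for b in _require(poly_cfg, "b_coeffs", path)),
        (0.0, float(_require(poly_cfg, "t_max_s", path))),
        fit_r2=poly_cfg.get("fit_r2"),
    )

    law = None
    j = cfg.get("current_density_mA_cm2")
    if "current_law" in cfg:
        law_cfg = cfg["current_law"]
        unknown = set(law_cfg) - _LAW_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown current_law keys {sorted(unknown)}")
        law = CurrentDensityLaw(
            float(_require(law_cfg, "slope_cm2_per_mA", path)),
            float(_require(law_cfg, "intercept", path)),
            fit_r2=law_cfg.get("fit_r2"),
        )

    if "k_prop" in cfg and law is not None:
        raise ConfigError(
            f"{path}: give either k_prop or current_law (+ current density), not both"
        )
    if "k_prop" in cfg:
        k_prop = float(cfg["k_prop"])
    elif law is not None:
        if j is None:
            raise ConfigError(
                f"{path}: current_law requires current_density_mA_cm2"
            )
        k_prop = k_of_j(law, float(j))
    else:
        raise ConfigError(f"{path}: one of k_prop or current_law is required")

    try:
        system = ChainSystem(tuple(str(s) for s in species), c0)
        constants = KineticConstants(tuple(float(r) for r in rates))
        return Scenario(
            name=name,
            system=system,
            constants=constants,
            poly=poly,
            k_prop=k_prop,
            duration_s=duration,
            sample_interval_s=float(cfg.get("sample_interval_s", 3600.0)),
            current_density_mA_cm2=None if j is None else float(j),
            current_law=law,
        )
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
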