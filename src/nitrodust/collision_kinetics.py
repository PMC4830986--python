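"""Collision-theory quantities: reaction probability, coverage, lifetime.

The apparent reaction probability (uptake coefficient) gamma converts an
observed pseudo-first-order loss rate of a surface-bound molecule into the
fraction of gas-surface collisions that remove it:

    gamma = 4 k_obs / (sigma * omega * n_gas)

i.e. k_obs divided by the per-molecule collision frequency (1/4) omega n
sigma, with sigma the adsorbate's effective cross-section, omega the gas
collider's thermal speed and n its number density. Initial fractional
surface coverage follows the monolayer-packing estimate
theta = loading * N_A * sigma / BET area, and the e-folding lifetime is
tau = 1 / k_obs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .constants import N_A
from .core_units import GasConditions, SpeciesProperties

__all__ = [
    "SubstrateRecord",
    "reaction_probability",
    "surface_coverage",
    "lifetime",
    "lifetime_hours",
    "write_substrate_table",
    "read_substrate_table",
    "format_substrate_table",
]


def reaction_probability(
    k_obs: float,
    species: SpeciesProperties,
    gas: GasConditions,
    convention: str = "mean",
) -> float:
    """Apparent reaction probability gamma = 4 k_obs / (sigma omega n).

    gamma is linear in k_obs and inversely proportional to the gas number
    density. Values above 1 are unphysical for a true uptake coefficient but
    can arise for an effective (apparent) probability; they warn and are
    returned as-is.
    """
    if not (math.isfinite(k_obs) and k_obs >= 0):
        raise ValueError(f"k_obs must be >= 0 s^-1, got {k_obs}")
    if gas.number_density <= 0:
        raise ValueError("gas number density must be > 0 (zero mixing ratio?)")
    omega = species.thermal_speed(gas.temperature, convention)
    gamma = 4.0 * k_obs / (species.cross_section * omega * gas.number_density)
    if gamma > 1.0:
        warnings.warn(
            f"gamma = {gamma:.3g} exceeds 1: apparent probability is unphysical "
            "as a true uptake coefficient",
            stacklevel=2,
        )
    return gamma


def surface_coverage(loading: float, sigma: float, bet_area: float) -> float:
    """Initial fractional monolayer coverage theta = loading * N_A * sigma / A_BET.

    Parameters
    ----------
    loading : float
        Adsorbate loading in mol per gram of substrate.
    sigma : float
        Effective molecular cross-section, m^2.
    bet_area : float
        Specific (BET) surface area, m^2 per gram. Must be > 0.
    """
    if loading < 0:
        raise ValueError(f"loading must be >= 0 mol g^-1, got {loading}")
    if sigma <= 0:
        raise ValueError(f"cross-section must be > 0 m^2, got {sigma}")
    if bet_area <= 0:
        raise ValueError(f"BET area must be > 0 m^2 g^-1, got {bet_area}")
    theta = loading * N_A * sigma / bet_area
    if theta >= 1.0:
        warnings.warn(
            f"theta = {theta:.3g} >= 1: above monolayer coverage, "
            "pseudo-first-order surface kinetics may not apply",
            stacklevel=2,
        )
    return theta


def lifetime(k_obs: float) -> float:
    """e-folding lifetime tau = 1 / k_obs, in seconds."""
    if not (math.isfinite(k_obs) and k_obs > 0):
        raise ValueError(f"lifetime requires k_obs > 0 s^-1, got {k_obs}")
    return 1.0 / k_obs


def lifetime_hours(k_obs: float) -> float:
    """e-folding lifetime in hours."""
    return lifetime(k_obs) / 3600.0


@dataclass
class SubstrateRecord:
    """Per-substrate kinetic summary row (the bench-top survey shape).

    All quantities are stored unscaled: k_obs in s^-1, gamma and theta0
    dimensionless, d_py / y_1np in percent. The customary presentation scale
    factors (1e5, 1e8, 1e2) are applied only by :func:`format_substrate_table`.
    """

    name: str
    k_obs: float
    k_obs_se: float = 0.0
    gamma: float = float("nan")
    gamma_se: float = float("nan")
    d_py: float = float("nan")
    y_1np: float = float("nan")
    dnp_formed: str = "-"
    theta0: float = float("nan")
    py_loading: Optional[float] = None  # mol g^-1
    bet_area: Optional[float] = None  # m^2 g^-1

    def __post_init__(self) -> None:
        if self.k_obs < 0 or self.k_obs_se < 0:
            raise ValueError("k_obs and its SE must be >= 0")
        if not math.isnan(self.theta0) and self.theta0 < 0:
            raise ValueError("theta0 must be >= 0")
        if not math.isnan(self.gamma) and not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


_TABLE_COLUMNS = [
    "name", "k_obs", "k_obs_se", "gamma", "gamma_se",
    "d_py", "y_1np", "dnp_formed", "theta0",
]


def write_substrate_table(records: Iterable[SubstrateRecord], path) -> None:
    """Write substrate records to CSV (unscaled values, survey column order)."""
    rows = [{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_substrate_table(path) -> list[SubstrateRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"substrate table {path} missing columns: {sorted(missing)}")
    return [
        SubstrateRecord(**{c: row[c] for c in _TABLE_COLUMNS})
        for _, row in df.iterrows()
    ]


def format_substrate_table(records: Iterable[SubstrateRecord]) -> pd.DataFrame:
    """Presentation view with the customary scale factors applied:
    k_obs x 1e5 (s^-1), gamma x 1e8, theta0 x 1e2."""
    rows = []
    for r in records:
        rows.append(
            {
                "Substrate": r.name,
                "k_obs x 1e5 (s^-1)": r.k_obs * 1e5,
                "se x 1e5": r.k_obs_se * 1e5,
                "gamma x 1e8": r.gamma * 1e8,
                "D_Py (%)": r.d_py,
                "Y_1NP (%)": r.y_1np,
                "DNP": r.dnp_formed,
                "theta0 x 1e2": r.theta0 * 1e2,
            }
        )
    return pd.DataFrame(rows)
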