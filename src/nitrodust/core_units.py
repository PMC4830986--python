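"""Unit-safe gas-phase conversions and gas-kinetic quantities.

Everything downstream works in molecules m^-3 and SI units; ppmv/ppbv mixing
ratios are converted here, once, at the interface. The two public helpers are
:func:`mixing_ratio_to_number_density` (ideal-gas number density) and
:func:`mean_thermal_speed` (Maxwell-Boltzmann mean or root-mean-square speed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import K_B, M_NO2, P_STD, R, SIGMA_PY, T_STD

__all__ = [
    "GasConditions",
    "SpeciesProperties",
    "PY_NO2",
    "mixing_ratio_to_number_density",
    "mean_thermal_speed",
]

_SPEED_CONVENTIONS = ("mean", "rms")


def _require_finite(name: str, value: float, unit: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be a finite number in {unit}, got {value!r}")
    return value


def mixing_ratio_to_number_density(
    mixing_ratio: float, temperature: float = T_STD, pressure: float = P_STD
) -> float:
    """Convert a mole-fraction mixing ratio to an ideal-gas number density.

    Parameters
    ----------
    mixing_ratio : float
        Dimensionless mole fraction (e.g. 3 ppmv is ``3e-6``). Must be >= 0.
    temperature : float
        Gas temperature in kelvin, > 0. Default 298.15 K.
    pressure : float
        Total pressure in pascal, > 0. Default 101325 Pa.

    Returns
    -------
    float
        Number density in molecules m^-3, ``x * P / (k_B * T)``.
    """
    x = _require_finite("mixing_ratio", mixing_ratio, "mole fraction (dimensionless)")
    T = _require_finite("temperature", temperature, "kelvin")
    P = _require_finite("pressure", pressure, "pascal")
    if x < 0:
        raise ValueError(
            f"mixing_ratio must be >= 0 (mole fraction, e.g. 3 ppmv = 3e-6); got {x}"
        )
    if T <= 0:
        raise ValueError(f"temperature must be > 0 kelvin; got {T}")
    if P <= 0:
        raise ValueError(f"pressure must be > 0 pascal; got {P}")
    return x * P / (K_B * T)


def mean_thermal_speed(
    molar_mass: float, temperature: float = T_STD, convention: str = "mean"
) -> float:
    """Thermal speed of a gas molecule in m s^-1.

    ``convention="mean"`` (default) returns the Maxwell-Boltzmann mean speed
    sqrt(8RT / (pi M)); ``convention="rms"`` returns the root-mean-square
    speed sqrt(3RT / M). The collision-frequency expression for uptake
    coefficients conventionally uses the mean speed; both are provided
    because published uptake tables are not always explicit about which
    constant entered the collision frequency.
    """
    M = _require_finite("molar_mass", molar_mass, "kg mol^-1")
    T = _require_finite("temperature", temperature, "kelvin")
    if M <= 0:
        raise ValueError(f"molar_mass must be > 0 kg mol^-1; got {M}")
    if T <= 0:
        raise ValueError(f"temperature must be > 0 kelvin; got {T}")
    if convention == "mean":
        return math.sqrt(8.0 * R * T / (math.pi * M))
    if convention == "rms":
        return math.sqrt(3.0 * R * T / M)
    raise ValueError(
        f"unknown speed convention {convention!r}; expected one of {_SPEED_CONVENTIONS}"
    )


@dataclass(frozen=True)
class GasConditions:
    """Reactor or ambient gas-phase conditions for the reactive trace gas.

    ``mixing_ratio`` is a plain mole fraction; use :meth:`from_ppmv` /
    :meth:`from_ppbv` for the usual field units. ``number_density`` (molecules
    m^-3) is derived and kept consistent with the other fields.
    """

    temperature: float = T_STD
    pressure: float = P_STD
    mixing_ratio: float = 0.0
    number_density: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mixing_ratio <= 1.0):
            raise ValueError(
                "mixing_ratio must be a mole fraction in [0, 1]; "
                f"got {self.mixing_ratio} (did you forget to scale ppmv by 1e-6?)"
            )
        n = mixing_ratio_to_number_density(
            self.mixing_ratio, self.temperature, self.pressure
        )
        object.__setattr__(self, "number_density", n)

    @classmethod
    def from_ppmv(
        cls, ppmv: float, temperature: float = T_STD, pressure: float = P_STD
    ) -> "GasConditions":
        return cls(temperature=temperature, pressure=pressure, mixing_ratio=ppmv * 1e-6)

    @classmethod
    def from_ppbv(
        cls, ppbv: float, temperature: float = T_STD, pressure: float = P_STD
    ) -> "GasConditions":
        return cls(temperature=temperature, pressure=pressure, mixing_ratio=ppbv * 1e-9)

    @property
    def ppmv(self) -> float:
        return self.mixing_ratio * 1e6

    @property
    def ppbv(self) -> float:
        return self.mixing_ratio * 1e9


@dataclass(frozen=True)
class SpeciesProperties:
    """Collision-pair properties entering the uptake-coefficient formula.

    ``molar_mass`` is the molar mass of the gas-phase collider (kg mol^-1),
    setting its thermal speed; ``cross_section`` is the effective area of one
    surface-adsorbed target molecule (m^2), setting the collision target size.
    """

    molar_mass: float
    cross_section: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.molar_mass) and self.molar_mass > 0):
            raise ValueError(
                f"molar_mass must be > 0 kg mol^-1; got {self.molar_mass}"
            )
        if not (math.isfinite(self.cross_section) and self.cross_section > 0):
            raise ValueError(
                f"cross_section must be > 0 m^2 per molecule; got {self.cross_section}"
            )

    def thermal_speed(self, temperature: float, convention: str = "mean") -> float:
        return mean_thermal_speed(self.molar_mass, temperature, convention)


#: NO2 gas colliding with surface-adsorbed pyrene (the system studied here).
PY_NO2 = SpeciesProperties(molar_mass=M_NO2, cross_section=SIGMA_PY)
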