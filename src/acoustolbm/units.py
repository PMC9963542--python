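"""Mapping between physical units and reduced lattice units.

The lattice Boltzmann solver works in a reduced system where the lattice
spacing and the time step are both 1.  A simulation is tied to the laboratory
frame through three *base* conversion factors chosen by the user — length,
density and kinematic viscosity — from which every derived factor follows by
dimensional analysis:

    cf_time     = cf_length**2 / cf_viscosity
    cf_velocity = cf_length / cf_time
    cf_force    = cf_velocity**2 * cf_length**2 * cf_density

Dynamic similarity between the two frames is guaranteed by matching the
Reynolds number, which is invariant under this construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["UnitSystem", "build_unit_system", "convert", "reynolds"]


@dataclass(frozen=True)
class UnitSystem:
    """Ledger of conversion factors, each in physical units per lattice unit."""

    cf_length: float      # m per lattice spacing
    cf_density: float     # kg/m^3 per lattice density unit
    cf_viscosity: float   # m^2/s per lattice viscosity unit
    cf_time: float = field(init=False)      # s per lattice step
    cf_velocity: float = field(init=False)  # m/s per lattice velocity unit
    cf_force: float = field(init=False)     # N per lattice force unit

    def __post_init__(self):
        for name in ("cf_length", "cf_density", "cf_viscosity"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        object.__setattr__(self, "cf_time", self.cf_length**2 / self.cf_viscosity)
        object.__setattr__(self, "cf_velocity", self.cf_length / self.cf_time)
        object.__setattr__(
            self, "cf_force", self.cf_velocity**2 * self.cf_length**2 * self.cf_density
        )

    def factor(self, quantity: str) -> float:
        """Physical-per-lattice factor for a supported quantity kind."""
        try:
            return _FACTORS[quantity](self)
        except KeyError:
            raise InvalidParameterError(
                f"unknown quantity kind {quantity!r}; supported kinds: "
                + ", ".join(sorted(_FACTORS))
            ) from None

    def as_dict(self) -> dict:
        """Serializable echo of the ledger for run provenance."""
        return {
            "cf_length_m": self.cf_length,
            "cf_density_kg_m3": self.cf_density,
            "cf_viscosity_m2_s": self.cf_viscosity,
            "cf_time_s": self.cf_time,
            "cf_velocity_m_s": self.cf_velocity,
            "cf_force_N": self.cf_force,
        }


_FACTORS = {
    "length": lambda u: u.cf_length,
    "time": lambda u: u.cf_time,
    "density": lambda u: u.cf_density,
    "viscosity": lambda u: u.cf_viscosity,
    "velocity": lambda u: u.cf_velocity,
    "force": lambda u: u.cf_force,
    # Acoustic energy density is energy per volume = force per area.
    "energy_density": lambda u: u.cf_force / u.cf_length**2,
}


def build_unit_system(
    channel_width_phys: float,
    lattice_width: float,
    rho_phys: float,
    rho_lbm: float,
    nu_phys: float,
    nu_lbm: float,
) -> UnitSystem:
    """Build the conversion-factor ledger from matched (physical, lattice) pairs.

    Parameters
    ----------
    channel_width_phys : channel width in metres.
    lattice_width : channel width in lattice nodes.
    rho_phys, rho_lbm : fluid (or particle) density in kg/m^3 and lattice units.
    nu_phys, nu_lbm : kinematic viscosity in m^2/s and lattice units.
    """
    pairs = {
        "channel_width_phys": channel_width_phys,
        "lattice_width": lattice_width,
        "rho_phys": rho_phys,
        "rho_lbm": rho_lbm,
        "nu_phys": nu_phys,
        "nu_lbm": nu_lbm,
    }
    for name, value in pairs.items():
        if not value > 0:
            raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
    return UnitSystem(
        cf_length=channel_width_phys / lattice_width,
        cf_density=rho_phys / rho_lbm,
        cf_viscosity=nu_phys / nu_lbm,
    )


def convert(value, quantity: str, direction: str, units: UnitSystem):
    """Convert a scalar or array between physical and lattice units.

    ``direction`` is ``"to_lattice"`` (divide by the factor) or
    ``"to_physical"`` (multiply by it); the operation is elementwise on fields.
    """
    factor = units.factor(quantity)
    arr = np.asarray(value, dtype=float)
    if direction == "to_lattice":
        out = arr / factor
    elif direction == "to_physical":
        out = arr * factor
    else:
        raise InvalidParameterError(
            f"direction must be 'to_lattice' or 'to_physical', got {direction!r}"
        )
    return out.item() if np.isscalar(value) or arr.ndim == 0 else out


def reynolds(u_char: float, length_char: float, nu: float) -> float:
    """Reynolds number Re = U L / nu; frame-invariant for a consistent ledger."""
    if not length_char > 0:
        raise InvalidParameterError("length_char must be strictly positive")
    if nu == 0:
        raise ZeroDivisionError("kinematic viscosity must be nonzero")
    if nu < 0:
        raise InvalidParameterError("nu must be strictly positive")
    return u_char * length_char / nu
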