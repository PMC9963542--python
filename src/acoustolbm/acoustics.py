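"""Primary acoustic radiation force of a standing surface acoustic wave.

A one-dimensional standing wave of wavelength lambda across the channel exerts
a time-averaged radiation force on a small particle (r << lambda):

    F_A(y) = -(2 pi V_p E_ac / lambda) Phi(beta, rho) sin(4 pi (y - phi0) / lambda)

with V_p the particle volume, E_ac the acoustic energy density and Phi the
acoustic contrast factor

    Phi = (5 rho_p - 2 rho_f) / (2 rho_p + rho_f) - beta_p / beta_f.

``phi0`` (the ``phase_offset``, metres) shifts the node pattern along the
channel: with the sign convention above, positions y = phi0 + k lambda/2 are
stable pressure nodes for Phi > 0 (restoring force), and the antinodes midway
between them attract particles with Phi < 0.  The energy density may be given
directly or through the transducer voltage as E_ac = a V^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, InvalidParameterError
from .immersed_boundary import ParticleSpec

__all__ = ["AcousticConfig", "contrast_factor", "acoustic_force",
           "energy_density", "node_positions"]

WATER_COMPRESSIBILITY = 4.5e-10  # 1/Pa, standard value for water


@dataclass(frozen=True)
class AcousticConfig:
    """SSAW field parameters (physical units)."""

    wavelength: float                 # m
    energy_density: float | None = None  # J/m^3 (exclusive with voltage+a)
    voltage: float | None = None      # V
    a: float | None = None            # J/m^3/V^2 proportionality
    phase_offset: float = 0.0         # m; shifts the node pattern
    active: bool = True
    fluid_density: float = 1027.0     # kg/m^3
    fluid_compressibility: float = WATER_COMPRESSIBILITY  # 1/Pa

    def __post_init__(self):
        if not self.wavelength > 0:
            raise InvalidParameterError("wavelength must be positive")
        has_e = self.energy_density is not None
        has_va = self.voltage is not None and self.a is not None
        if has_e == has_va:
            raise ConfigurationError(
                "supply exactly one of energy_density or (voltage, a)"
            )
        if has_e and self.energy_density < 0:
            raise InvalidParameterError("energy_density must be non-negative")

    @property
    def eac(self) -> float:
        """Acoustic energy density in J/m^3, from whichever input was given."""
        if self.energy_density is not None:
            return self.energy_density
        return energy_density(self.voltage, self.a)

    @classmethod
    def centered_node(cls, channel_width: float, **kw) -> "AcousticConfig":
        """Half-wavelength channel with a single stable node at mid-width."""
        return cls(wavelength=2.0 * channel_width,
                   phase_offset=channel_width / 2.0, **kw)

    @classmethod
    def two_nodes(cls, channel_width: float, **kw) -> "AcousticConfig":
        """Full-wavelength channel: two stable nodes at W/4 and 3W/4 with the
        antinode at mid-width."""
        return cls(wavelength=channel_width,
                   phase_offset=channel_width / 4.0, **kw)

    def as_dict(self) -> dict:
        return {
            "wavelength_m": self.wavelength,
            "energy_density_J_m3": self.eac if self.active else 0.0,
            "phase_offset_m": self.phase_offset,
            "active": self.active,
            "fluid_density_kg_m3": self.fluid_density,
            "fluid_compressibility_per_Pa": self.fluid_compressibility,
        }


def contrast_factor(beta_p: float, beta_f: float, rho_p: float, rho_f: float) -> float:
    """Acoustic contrast factor Phi; positive Phi attracts to pressure nodes."""
    for name, v in (("beta_p", beta_p), ("beta_f", beta_f),
                    ("rho_p", rho_p), ("rho_f", rho_f)):
        if not v > 0:
            raise InvalidParameterError(f"{name} must be positive")
    return (5.0 * rho_p - 2.0 * rho_f) / (2.0 * rho_p + rho_f) - beta_p / beta_f


def energy_density(voltage: float, a: float) -> float:
    """E_ac = a V^2 for transducer voltage V and proportionality a."""
    if a < 0:
        raise InvalidParameterError("proportionality a must be non-negative")
    return a * voltage**2


def acoustic_force(y_p: float, particle: ParticleSpec, cfg: AcousticConfig) -> float:
    """Lateral radiation force (N) on a particle centred at y_p (m).

    Returns 0 when the field is inactive.  Valid for r << wavelength.
    """
    if not cfg.active:
        return 0.0
    if particle.radius > 0.1 * cfg.wavelength:
        raise ConfigurationError(
            f"radiation-force law requires r << wavelength "
            f"(r={particle.radius:.2e}, lambda={cfg.wavelength:.2e})"
        )
    phi = contrast_factor(particle.compressibility, cfg.fluid_compressibility,
                          particle.density, cfg.fluid_density)
    amplitude = 2.0 * math.pi * particle.volume * cfg.eac / cfg.wavelength
    return -amplitude * phi * math.sin(
        4.0 * math.pi * (y_p - cfg.phase_offset) / cfg.wavelength
    )


def node_positions(cfg: AcousticConfig, channel_width: float,
                   contrast_sign: float = 1.0) -> list[float]:
    """Stable equilibrium lateral positions inside (0, channel_width).

    For ``contrast_sign > 0`` these are the pressure nodes
    y = phase_offset + k lambda/2; for negative contrast, the antinodes
    shifted by lambda/4.  Raises if no stable position lies strictly inside
    the channel.
    """
    if not channel_width > 0:
        raise InvalidParameterError("channel_width must be positive")
    offset = cfg.phase_offset + (0.0 if contrast_sign > 0 else cfg.wavelength / 4.0)
    half = cfg.wavelength / 2.0
    k_min = math.ceil((0.0 - offset) / half)
    k_max = math.floor((channel_width - offset) / half)
    eps = 1e-12 * max(channel_width, cfg.wavelength)
    out = [offset + k * half for k in range(k_min, k_max + 1)
           if eps < offset + k * half < channel_width - eps]
    if not out:
        raise ConfigurationError(
            "no stable equilibrium position inside the channel for this "
            "wavelength / phase_offset / contrast sign"
        )
    return out
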