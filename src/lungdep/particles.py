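"""Aerosol particle properties.

Derived quantities follow standard aerosol mechanics: Cunningham slip
correction, Stokes settling velocity and Stokes-Einstein molecular
diffusivity, all evaluated at body temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

from . import units


@dataclass(frozen=True)
class ParticleProperties:
    """An aerosol particle species.

    Parameters
    ----------
    diameter : float
        Geometric particle diameter, metres. Default 4 um, a typical mass
        median aerodynamic diameter for nebulized therapeutics.
    density : float
        Particle density, kg m^-3 (default 1000, unit-density spheres).
    viscosity : float
        Dynamic viscosity of the carrier air, Pa s.
    temperature : float
        Absolute temperature, K.
    """

    diameter: float = 4e-6
    density: float = 1000.0
    viscosity: float = units.AIR_VISCOSITY
    temperature: float = units.BODY_TEMPERATURE
    mean_free_path: float = units.AIR_MEAN_FREE_PATH

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("particle diameter must be positive")
        if self.density <= 0:
            raise ValueError("particle density must be positive")

    @property
    def slip_correction(self) -> float:
        """Cunningham slip correction factor (>= 1)."""
        kn = 2.0 * self.mean_free_path / self.diameter
        return 1.0 + kn * (1.257 + 0.4 * math.exp(-1.1 / kn))

    @property
    def settling_velocity(self) -> float:
        """Terminal gravitational settling velocity v_s, m s^-1."""
        return (
            self.density
            * self.diameter**2
            * units.GRAVITY
            * self.slip_correction
            / (18.0 * self.viscosity)
        )

    @property
    def relaxation_time(self) -> float:
        """Inertial relaxation time tau = rho d^2 Cc / (18 mu), s."""
        return (
            self.density
            * self.diameter**2
            * self.slip_correction
            / (18.0 * self.viscosity)
        )

    @property
    def diffusivity(self) -> float:
        """Stokes-Einstein Brownian diffusivity, m2 s^-1."""
        return (
            units.K_BOLTZMANN
            * self.temperature
            * self.slip_correction
            / (3.0 * math.pi * self.viscosity * self.diameter)
        )


@dataclass(frozen=True)
class GasProperties:
    """A tracer gas, used in washout mode (no deposition, high diffusivity)."""

    diffusivity: float = units.D_N2_IN_O2
    name: str = "N2-in-O2"

    def __post_init__(self):
        if self.diffusivity <= 0:
            raise ValueError("gas diffusivity must be positive")
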