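"""Fluid, particle and run-level parameters, plus flow-regime diagnostics.

The default parameter set reproduces a gas-liquid dual-microchannel
lung-on-a-chip: air (37 degC) flowing over a cell-culture medium with
water-like properties, separated by a perforated membrane.  All quantities
are SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

KB = 1.380649e-23  # Boltzmann constant, J/K
G_STANDARD = 9.81  # m/s^2

__all__ = [
    "KB",
    "G_STANDARD",
    "FluidProperties",
    "ParticleProperties",
    "SimulationConfig",
    "RegimeReport",
    "air_properties",
    "media_properties",
    "knudsen_number",
    "validate_regime",
]


class ConfigurationError(ValueError):
    """A parameter is missing, out of range, or inconsistent."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian incompressible fluid.

    Parameters
    ----------
    rho : float
        Density, kg/m^3.
    mu : float
        Dynamic viscosity, Pa*s.
    T : float
        Temperature, K.  Both phases are held at 37 degC (310.15 K) by default.
    R : float, optional
        Specific gas constant, J/(kg*K).  Air only; needed for the Knudsen check.
    sigma : float, optional
        Molecular collision diameter, m.  Air only; hard-sphere mean-free-path model.
    """

    rho: float
    mu: float
    T: float = 310.15
    R: float | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        for name in ("rho", "mu", "T"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"FluidProperties.{name} must be > 0")
        for name in ("R", "sigma"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ConfigurationError(f"FluidProperties.{name} must be > 0 when set")


def air_properties() -> FluidProperties:
    """Air at 37 degC: rho=1.123 kg/m^3, mu=0.019 mPa*s, sigma=346 pm, R=290 J/(kg K)."""
    return FluidProperties(rho=1.123, mu=0.019e-3, T=310.15, R=290.0, sigma=346e-12)


def media_properties() -> FluidProperties:
    """Cell-culture medium modeled as water at 37 degC: rho=1000, mu=0.718 mPa*s."""
    return FluidProperties(rho=1000.0, mu=0.718e-3, T=310.15)


@dataclass(frozen=True)
class ParticleProperties:
    """Rigid spherical particle.

    dp is the diameter (m) and rho_p the material density (kg/m^3); the mass
    follows from the sphere volume, mp = rho_p * pi * dp^3 / 6.
    """

    dp: float
    rho_p: float

    def __post_init__(self) -> None:
        if self.dp <= 0:
            raise ConfigurationError("ParticleProperties.dp must be > 0")
        if self.rho_p <= 0:
            raise ConfigurationError("ParticleProperties.rho_p must be > 0")

    @property
    def mp(self) -> float:
        """Particle mass, kg."""
        return self.rho_p * math.pi * self.dp**3 / 6.0

    def relaxation_time(self, fluid: FluidProperties) -> float:
        """Stokes momentum relaxation time tau = rho_p dp^2 / (18 mu), s."""
        return self.rho_p * self.dp**2 / (18.0 * fluid.mu)

    def diffusivity(self, fluid: FluidProperties) -> float:
        """Stokes-Einstein diffusion coefficient kB T / (3 pi mu dp), m^2/s."""
        return KB * fluid.T / (3.0 * math.pi * fluid.mu * self.dp)


@dataclass(frozen=True)
class SimulationConfig:
    """Run settings for one particle-tracing case.

    Attributes
    ----------
    u_air_inlet, u_media_inlet : float
        Uniform inlet velocities of the top (air) and bottom (media) channels, m/s.
    n_particles : int
        Number of particles released at the top-channel inlet.
    dt : float or None
        Base time step, s.  ``None`` picks a step so that neither the advective
        displacement nor the r.m.s. Brownian step exceeds a quarter pore width.
    seed : int
        Master seed; every particle owns a counter-based substream derived from it.
    g : float
        Gravitational acceleration magnitude, m/s^2, directed -y (air -> media).
    integrator_mode : str
        'overdamped' (position Langevin) or 'inertial' (exact exponential update
        of the linear-drag momentum equation).
    brownian, drag, gravity : bool
        Force switches.  Disabling drag is only meaningful in inertial mode.
    max_time : float
        Simulated-time budget, s; particles still active then are flagged incomplete.
    inlet_profile : str
        'uniform' (plug) or 'parabolic' (fully developed) inlet velocity profile.
    membrane_flow : str
        Hydraulic treatment of the membrane in the flow solve: 'sealed'
        (default; pores closed to the fluid, open to particles) or 'open'
        (pore slots resolved as fluid, channels exchange flow).
    initial_velocity : str
        'fluid' starts particles at the local fluid velocity, 'zero' starts them inert.
    release_x : float or None
        Streamwise release position, m (default: the inlet, x=0).
    """

    u_air_inlet: float = 0.3e-3
    u_media_inlet: float = 0.3e-3
    n_particles: int = 1000
    dt: float | None = None
    seed: int = 0
    g: float = G_STANDARD
    integrator_mode: str = "overdamped"
    brownian: bool = True
    drag: bool = True
    gravity: bool = True
    max_time: float = 300.0
    inlet_profile: str = "uniform"
    membrane_flow: str = "sealed"
    initial_velocity: str = "fluid"
    release_x: float | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        if self.dt is not None and self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.g < 0:
            raise ConfigurationError("g must be >= 0")
        if self.u_air_inlet < 0 or self.u_media_inlet < 0:
            raise ConfigurationError("inlet velocities must be >= 0")
        if self.integrator_mode not in ("overdamped", "inertial"):
            raise ConfigurationError("integrator_mode must be 'overdamped' or 'inertial'")
        if self.inlet_profile not in ("uniform", "parabolic"):
            raise ConfigurationError("inlet_profile must be 'uniform' or 'parabolic'")
        if self.membrane_flow not in ("sealed", "open"):
            raise ConfigurationError("membrane_flow must be 'sealed' or 'open'")
        if self.initial_velocity not in ("fluid", "zero"):
            raise ConfigurationError("initial_velocity must be 'fluid' or 'zero'")
        if self.max_time <= 0:
            raise ConfigurationError("max_time must be > 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def knudsen_number(air: FluidProperties, h: float) -> float:
    """Channel Knudsen number Kn = lambda / (2h) for a hard-sphere gas.

    Kn = kB / (sqrt(2) * pi * sigma^2 * rho_a * R * 2h).  Kn < 0.01 justifies
    the continuum, no-slip treatment of the air channel.

    Parameters
    ----------
    air : FluidProperties
        Must carry ``sigma`` (collision diameter) and ``R`` (specific gas constant).
    h : float
        Channel height, m.
    """
    if air.sigma is None:
        raise ConfigurationError("knudsen_number requires FluidProperties.sigma")
    if air.R is None:
        raise ConfigurationError("knudsen_number requires FluidProperties.R")
    if h <= 0:
        raise ConfigurationError("channel height h must be > 0")
    return KB / (math.sqrt(2.0) * math.pi * air.sigma**2 * air.rho * air.R * 2.0 * h)


@dataclass(frozen=True)
class RegimeReport:
    """Dimensionless-group diagnostics for one fluid/particle/flow combination."""

    re_particle: float
    relaxation_time: float
    stokes_number: float
    knudsen: float | None
    warnings: tuple[str, ...] = field(default=())

    @property
    def ok(self) -> bool:
        return not self.warnings


def validate_regime(
    fluid: FluidProperties,
    particle: ParticleProperties,
    u_ref: float,
    geom,
) -> RegimeReport:
    """Report-only check that the assumed creeping-flow, continuum regime holds.

    Computes the particle Reynolds number Re_p = rho u dp / mu, the Stokes
    relaxation time tau = rho_p dp^2 / (18 mu), the Stokes number tau u / h,
    and (for a gas with sigma and R set) the Knudsen number.  Flags are raised
    when Re_p >= 1 or Kn >= 0.01; nothing is rejected.
    """
    re_p = fluid.rho * abs(u_ref) * particle.dp / fluid.mu
    tau = particle.relaxation_time(fluid)
    h = min(geom.h_air, geom.h_media)
    stk = tau * abs(u_ref) / h
    kn = None
    if fluid.sigma is not None and fluid.R is not None:
        kn = knudsen_number(fluid, h)
    warnings = []
    if re_p >= 1.0:
        warnings.append(f"particle Reynolds number {re_p:.3g} >= 1: Stokes drag dubious")
    if kn is not None and kn >= 0.01:
        warnings.append(f"Knudsen number {kn:.3g} >= 0.01: continuum/no-slip dubious")
    return RegimeReport(
        re_particle=re_p,
        relaxation_time=tau,
        stokes_number=stk,
        knudsen=kn,
        warnings=tuple(warnings),
    )
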