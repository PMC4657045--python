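"""Closed-form mechanics of a filament on an elastic foundation.

A microtubule (MT) lying on a 2D substrate, tethered by kinesin motors that
act as passive linear springs, behaves under axial compression like a beam
on an elastic (Winkler) foundation.  The continuum theory predicts a
selected buckling wavelength

    lambda = 2*pi * (EI / E_c)**(1/4)

and a critical buckling force

    F_c = 2 * sqrt(E_c * EI)

where ``EI`` is the flexural rigidity of the filament and ``E_c`` the
foundation modulus, i.e. the lateral spring stiffness per unit length.
For a discrete array of springs of stiffness ``k_spring`` spaced ``L_d``
apart, ``E_c = k_spring / L_d``.

This module also carries the measurement geometry (wave number, minimum
radius of curvature of a sinusoidal buckle, bending energy) and the
substrate-calibration arithmetic (Sauerbrey mass loading, fluorescence
calibration, areal density -> spacing).

All functions take and return SI quantities; see :mod:`mtbuckle.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units

__all__ = [
    "DomainError",
    "StraightFilamentError",
    "FilamentMechanics",
    "FoundationSpec",
    "BuckleMetrics",
    "wave_number",
    "radius_of_curvature",
    "bending_energy_per_length",
    "bending_energy",
    "foundation_modulus",
    "buckling_wavelength",
    "foundation_modulus_from_wavelength",
    "critical_force",
    "combined_wavelength",
    "combined_critical_force",
    "spacing_from_density",
    "density_from_fluorescence",
    "sauerbrey_mass_density",
    "MT_SECOND_MOMENT",
    "FLUORESCENCE_DENSITY_FACTOR",
]

# Second moment of inertia of the MT cross-section used throughout the
# study conditions, m^4.
MT_SECOND_MOMENT = 32.82e-32

# Calibration slope between kinesin areal density and GFP fluorescence
# intensity, molecules per μm² per arbitrary unit.
FLUORESCENCE_DENSITY_FACTOR = 27.4


class DomainError(ValueError):
    """An input lies outside the physical domain of an operation."""


class StraightFilamentError(DomainError):
    """Curvature is undefined for a filament with zero buckling amplitude."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise DomainError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class FilamentMechanics:
    """Elastic constants of a filament.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus E, Pa.
    second_moment : float
        Second moment of inertia I of the cross-section, m^4.
    """

    youngs_modulus: float
    second_moment: float = MT_SECOND_MOMENT

    def __post_init__(self) -> None:
        _require_positive(
            youngs_modulus=self.youngs_modulus, second_moment=self.second_moment
        )

    @property
    def flexural_rigidity(self) -> float:
        """Flexural rigidity EI, N·m²."""
        return self.youngs_modulus * self.second_moment

    @classmethod
    def from_mpa(cls, youngs_modulus_mpa: float,
                 second_moment: float = MT_SECOND_MOMENT) -> "FilamentMechanics":
        return cls(youngs_modulus_mpa * units.MPA, second_moment)


@dataclass(frozen=True)
class FoundationSpec:
    """A discrete spring foundation: stiffness ``k_spring`` every ``L_d``.

    ``foundation_modulus`` is the continuum-equivalent lateral stiffness per
    unit length, E_c = k_spring / L_d (N/m²).
    """

    spring_stiffness: float  # N/m
    spacing: float  # m

    def __post_init__(self) -> None:
        _require_positive(spring_stiffness=self.spring_stiffness,
                          spacing=self.spacing)

    @property
    def foundation_modulus(self) -> float:
        return self.spring_stiffness / self.spacing

    @classmethod
    def from_modulus(cls, foundation_modulus: float,
                     spacing: float) -> "FoundationSpec":
        _require_positive(foundation_modulus=foundation_modulus)
        return cls(foundation_modulus * spacing, spacing)


@dataclass(frozen=True)
class BuckleMetrics:
    """Per-crest buckling geometry, in μm (measurement-facing units).

    ``wavelength_um`` is the crest-to-crest wavelength λ, ``amplitude_um``
    the transverse amplitude A of the sinusoidal approximation
    y = A sin(q x), and ``radius_um`` the minimum radius of curvature
    1/(A q²) of that sinusoid.  ``crest_contour_length_um`` is the contour
    length of the filament along a single buckling crest.
    """

    wavelength_um: float
    amplitude_um: float
    radius_um: float | None = None
    crest_contour_length_um: float | None = None

    def __post_init__(self) -> None:
        _require_positive(wavelength_um=self.wavelength_um)
        if self.amplitude_um < 0:
            raise DomainError("amplitude_um must be >= 0")

    @property
    def wavenumber_um(self) -> float:
        """Wave number q = 2π/λ, μm^-1."""
        return units.TWO_PI / self.wavelength_um


# ---------------------------------------------------------------------------
# measurement geometry


def wave_number(wavelength: float) -> float:
    """Wave number q = 2π/λ of a buckle of wavelength ``wavelength``."""
    _require_positive(wavelength=wavelength)
    return units.TWO_PI / wavelength


def radius_of_curvature(wavelength: float, amplitude: float) -> float:
    """Minimum radius of curvature of the sinusoid y = A sin(qx).

    R = 1/(A q²) with q = 2π/λ, attained at the crest.
    """
    _require_positive(wavelength=wavelength)
    if amplitude == 0:
        raise StraightFilamentError(
            "straight filament: amplitude is zero, curvature undefined")
    _require_positive(amplitude=amplitude)
    q = wave_number(wavelength)
    return 1.0 / (amplitude * q * q)


def bending_energy_per_length(mech: FilamentMechanics, radius: float) -> float:
    """Bending energy stored per unit contour length, EI/(2R²).

    Has units of force (N); multiplying by a contour length gives energy.
    """
    _require_positive(radius=radius)
    return mech.flexural_rigidity / (2.0 * radius * radius)


def bending_energy(mech: FilamentMechanics, radius: float,
                   contour_length: float) -> float:
    """Total bending energy EI·L/(2R²) of a uniformly curved filament, J."""
    if contour_length < 0:
        raise DomainError("contour_length must be >= 0")
    return bending_energy_per_length(mech, radius) * contour_length


# ---------------------------------------------------------------------------
# elastic-foundation model


def foundation_modulus(spring_stiffness: float, spacing: float) -> float:
    """Continuum foundation modulus E_c = k_spring / L_d, N/m²."""
    _require_positive(spring_stiffness=spring_stiffness, spacing=spacing)
    return spring_stiffness / spacing


def buckling_wavelength(mech: FilamentMechanics, ec: float) -> float:
    """Selected buckling wavelength λ = 2π (EI/E_c)^(1/4), m."""
    _require_positive(ec=ec)
    return units.TWO_PI * (mech.flexural_rigidity / ec) ** 0.25


def foundation_modulus_from_wavelength(mech: FilamentMechanics,
                                       wavelength: float) -> float:
    """Inverse of :func:`buckling_wavelength`: E_c = EI (2π/λ)^4."""
    _require_positive(wavelength=wavelength)
    return mech.flexural_rigidity * (units.TWO_PI / wavelength) ** 4


def critical_force(mech: FilamentMechanics, ec: float,
                   prefactor: float = 2.0) -> float:
    """Critical buckling force of an infinite beam on a foundation.

    Default ``prefactor = 2`` gives the continuum minimum
    F_c = 2 sqrt(E_c·EI) = min over q of (EI q² + E_c/q²).  The prefactor
    is exposed because reported experimental values in this system are
    consistent in ratio but not in absolute constant with any single
    standard choice.
    """
    _require_positive(ec=ec, prefactor=prefactor)
    return prefactor * math.sqrt(ec * mech.flexural_rigidity)


def combined_wavelength(mech: FilamentMechanics, k_spring: float,
                        L_d: float) -> float:
    """λ = 2π (EI·L_d / k_spring)^(1/4): Winkler wavelength with the
    foundation modulus written in terms of discrete-spring parameters."""
    return buckling_wavelength(mech, foundation_modulus(k_spring, L_d))


def combined_critical_force(mech: FilamentMechanics, k_spring: float,
                            L_d: float, prefactor: float = 2.0) -> float:
    """F_c = 2 sqrt(k_spring·EI / L_d)."""
    return critical_force(mech, foundation_modulus(k_spring, L_d), prefactor)


# ---------------------------------------------------------------------------
# substrate calibration


def spacing_from_density(density: float) -> float:
    """Mean spacing between springs from their areal density, m.

    Assumes a square arrangement: L_d = density^(-1/2).  Densities in
    molecules/m² give spacings in m; use :data:`mtbuckle.units.PER_UM2`
    and :data:`mtbuckle.units.NM` at boundaries.
    """
    _require_positive(density=density)
    return density ** -0.5


def density_from_fluorescence(intensity: float,
                              factor: float = FLUORESCENCE_DENSITY_FACTOR
                              ) -> float:
    """Kinesin areal density from GFP fluorescence intensity, molecules/m².

    ``factor`` is the calibration slope in molecules·μm^-2·au^-1 from the
    quartz-crystal-microbalance / fluorescence standard curve.
    """
    if intensity < 0:
        raise DomainError("fluorescence intensity must be >= 0")
    _require_positive(factor=factor)
    return intensity * factor * units.PER_UM2


def sauerbrey_mass_density(freq_shift: float, mass_sensitivity: float,
                           molar_mass: float) -> float:
    """Molecules per unit area deposited on a QCM crystal.

    The Sauerbrey relation is linear: areal mass = C·|Δf| with
    ``mass_sensitivity`` C in kg·m^-2·Hz^-1; dividing by the molar mass
    (kg/mol) and multiplying by Avogadro's number gives molecules/m².
    """
    _require_positive(mass_sensitivity=mass_sensitivity,
                      molar_mass=molar_mass)
    areal_mass = mass_sensitivity * abs(freq_shift)
    return areal_mass * units.AVOGADRO / molar_mass
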