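"""Kinesin-spacing-dependent softening of the microtubule.

Dense kinesin decoration lowers the apparent Young's modulus of a
microtubule.  The dependence on kinesin spacing L_d is captured by a
saturating function

    E(L_d) = E0 * s(L_d / L_star)

with s increasing from 0 to 1, bare modulus ``E0`` and critical spacing
``L_star`` below which the filament is drastically softened.  Three
families are provided:

``hill`` (default, exponent n)
    E(L) = E0 * L^n / (L^n + L_star^n); E(L_star) = E0/2.
``exp_saturation``
    E(L) = E0 * (1 - exp(-L/L_star)).
``gaussian_saturation`` (exponent n)
    E(L) = E0 * (1 - exp(-(L/L_star)^n)).

Substituting E(L_d) into the Winkler wavelength gives the modified
elastic-foundation model

    lambda(L_d) = 2*pi * (E(L_d) * I * L_d / k_spring)**(1/4),

whose inversion yields a pointwise spring-constant estimate

    k_i = (2*pi)**4 * E(L_d_i) * I * L_d_i / lambda_i**4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from . import units
from .mechanics import DomainError, _require_positive

__all__ = [
    "CalibrationError",
    "SofteningModel",
    "calibrate_softening",
    "modified_wavelength",
    "SpringConstantEstimate",
    "spring_constant_from_fit",
]

FAMILIES = ("hill", "exp_saturation", "gaussian_saturation")


class CalibrationError(ValueError):
    """The requested anchors are unattainable for the chosen family."""


@dataclass(frozen=True)
class SofteningModel:
    """Spacing-dependent Young's modulus E(L_d).

    Parameters
    ----------
    bare_modulus : float
        Modulus of an undecorated filament E0, Pa.
    critical_spacing : float
        Spacing scale L_star below which softening is drastic, m.
    family : str
        One of ``hill``, ``exp_saturation``, ``gaussian_saturation``.
    shape_exponent : float
        Exponent n used by the hill and gaussian families.
    """

    bare_modulus: float
    critical_spacing: float
    family: str = "hill"
    shape_exponent: float = 2.0
    calibration_residuals: tuple[float, ...] | None = field(
        default=None, compare=False)

    def __post_init__(self) -> None:
        _require_positive(bare_modulus=self.bare_modulus,
                          critical_spacing=self.critical_spacing,
                          shape_exponent=self.shape_exponent)
        if self.family not in FAMILIES:
            raise ValueError(f"unknown softening family {self.family!r}; "
                             f"choose from {FAMILIES}")

    def saturation(self, spacing) -> np.ndarray | float:
        """Dimensionless factor E(L_d)/E0 in (0, 1)."""
        u = np.asarray(spacing, dtype=float) / self.critical_spacing
        if np.any(u <= 0):
            raise DomainError("spacing must be > 0")
        n = self.shape_exponent
        if self.family == "hill":
            s = u ** n / (u ** n + 1.0)
        elif self.family == "exp_saturation":
            s = 1.0 - np.exp(-u)
        else:  # gaussian_saturation
            s = 1.0 - np.exp(-(u ** n))
        return s if s.ndim else float(s)

    def __call__(self, spacing):
        """Softened Young's modulus at spacing ``L_d`` (m), Pa."""
        return self.bare_modulus * self.saturation(spacing)


def softened_modulus(model: SofteningModel, spacing: float) -> float:
    """Functional alias for ``model(spacing)``."""
    return model(spacing)


def _max_ratio(family: str, n: float, L1: float, L2: float) -> float:
    # supremum of E(L1)/E(L2) over the family's scale parameter (L1 > L2),
    # reached in the small-argument limit where the saturation is a power law
    if family == "exp_saturation":
        return L1 / L2
    return (L1 / L2) ** n


def calibrate_softening(anchors: Sequence[tuple[float, float]],
                        family: str = "hill",
                        shape_exponent: float = 2.0) -> SofteningModel:
    """Fit (E0, L_star) so that E(L_d) passes through the anchor points.

    Parameters
    ----------
    anchors : sequence of (spacing, modulus)
        Spacings in m, moduli in Pa.  Two anchors are solved exactly;
        more are fit by least squares in log-modulus, with residuals
        stored on the returned model.

    Raises
    ------
    CalibrationError
        If the required modulus ratio exceeds what the family can attain
        (e.g. exponential saturation is capped at E(L1)/E(L2) <= L1/L2).
    """
    anchors = sorted(anchors, key=lambda p: p[0])
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    if len({a[0] for a in anchors}) < len(anchors):
        raise ValueError("anchor spacings must be distinct")
    for L, E in anchors:
        _require_positive(spacing=L, modulus=E)

    if len(anchors) == 2:
        (L2, E2), (L1, E1) = anchors  # L1 > L2
        ratio = E1 / E2
        if ratio <= 1.0:
            raise CalibrationError(
                "modulus must increase with spacing for a saturating family")
        ceiling = _max_ratio(family, shape_exponent, L1, L2)
        if ratio >= ceiling:
            raise CalibrationError(
                f"family {family!r} (n={shape_exponent:g}) can reach a "
                f"modulus ratio of at most {ceiling:.4g} between spacings "
                f"{L1:.4g} and {L2:.4g} m, but {ratio:.4g} is required")
        if family == "hill":
            n = shape_exponent
            x1, x2 = L1 ** n, L2 ** n
            c = x1 * x2 * (E2 - E1) / (E1 * x2 - E2 * x1)  # c = L_star^n
            L_star = c ** (1.0 / n)
            E0 = E1 * (x1 + c) / x1
        else:
            # solve g(L1/a)/g(L2/a) = ratio for the scale a by bisection;
            # the ratio is monotone in a between 1 (a->0) and the ceiling.
            if family == "exp_saturation":
                g = lambda u: -math.expm1(-u)
            else:
                g = lambda u: -math.expm1(-(u ** shape_exponent))

            def f(log_a: float) -> float:
                a = math.exp(log_a)
                return math.log(g(L1 / a) / g(L2 / a)) - math.log(ratio)

            lo, hi = math.log(L2) - 8, math.log(L1) + 12
            sol = optimize.brentq(f, lo, hi, xtol=1e-14)
            L_star = math.exp(sol)
            E0 = E1 / g(L1 / L_star)
        model = SofteningModel(E0, L_star, family, shape_exponent,
                               calibration_residuals=(0.0, 0.0))
        return model

    # >2 anchors: least squares on log E
    Ls = np.array([a[0] for a in anchors])
    Es = np.array([a[1] for a in anchors])

    def resid(theta):
        m = SofteningModel(math.exp(theta[0]), math.exp(theta[1]),
                           family, shape_exponent)
        return np.log(m(Ls)) - np.log(Es)

    theta0 = np.array([math.log(Es.max() * 1.5), math.log(np.median(Ls))])
    sol = optimize.least_squares(resid, theta0, xtol=1e-14, ftol=1e-14)
    model = SofteningModel(math.exp(sol.x[0]), math.exp(sol.x[1]),
                           family, shape_exponent,
                           calibration_residuals=tuple(sol.fun))
    return model


def modified_wavelength(model: SofteningModel, second_moment: float,
                        k_spring: float, spacing) -> np.ndarray | float:
    """Buckling wavelength with the spacing-dependent modulus, m.

    lambda(L_d) = 2*pi * (E(L_d) * I * L_d / k_spring)**0.25
    """
    _require_positive(second_moment=second_moment, k_spring=k_spring)
    E = model(spacing)
    L = np.asarray(spacing, dtype=float)
    lam = units.TWO_PI * (E * second_moment * L / k_spring) ** 0.25
    return lam if np.ndim(lam) else float(lam)


@dataclass(frozen=True)
class SpringConstantEstimate:
    """Spring constant extracted by inverting the modified model.

    ``k_spring`` is the geometric mean of the per-observation estimates
    (k enters the wavelength at the fourth root, so errors are
    multiplicative); ``pointwise`` retains them for diagnostics.
    """

    k_spring: float  # N/m
    pointwise: tuple[float, ...]
    log_sd: float  # sd of ln(k_i)

    @property
    def n(self) -> int:
        return len(self.pointwise)


def spring_constant_from_fit(model: SofteningModel, second_moment: float,
                             observations: Sequence[tuple[float, float]]
                             ) -> SpringConstantEstimate:
    """Extract k_spring from (spacing, wavelength) observations, both m.

    Pointwise inversion of the modified model,
    k_i = (2*pi)**4 * E(L_d_i) * I * L_d_i / lambda_i**4,
    aggregated by geometric mean.
    """
    if len(observations) == 0:
        raise ValueError("need at least one (spacing, wavelength) observation")
    _require_positive(second_moment=second_moment)
    ks = []
    for L_d, lam in observations:
        _require_positive(spacing=L_d, wavelength=lam)
        ks.append(units.TWO_PI ** 4 * model(L_d) * second_moment * L_d
                  / lam ** 4)
    logs = np.log(ks)
    return SpringConstantEstimate(
        k_spring=float(np.exp(logs.mean())),
        pointwise=tuple(ks),
        log_sd=float(logs.std(ddof=1)) if len(ks) > 1 else 0.0,
    )
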