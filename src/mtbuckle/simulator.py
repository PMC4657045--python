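"""Quasi-static simulation of a discrete elastic rod on a spring foundation.

The filament is a chain of nodes joined by stiff axial segments with a
discrete bending energy at each interior node; kinesin tethers are linear
springs acting purely transverse to the substrate, anchored every ``L_d``
along the rod to an affinely compressed substrate.  Compressing the
substrate shortens the imposed end-to-end distance; at each strain step
the total energy

    E = sum_i  EI/(2 ds) * theta_i^2                  (bending)
      + sum_j  k_a/(2 ds) * (l_j - ds)^2              (axial stretching)
      + sum_a  k_spring/2 * y_a^2                     (foundation)

is minimised over node positions (L-BFGS with analytic gradients),
warm-started from the previous step with a small seeded transverse
perturbation to break the straight-state symmetry.  There are no dynamics:
the observed insensitivity of buckling to strain rate justifies the
quasi-static treatment, and "strain rate" enters only as the number of
ramp steps.

Internally everything is nondimensionalised (lengths in node spacings,
energies in EI/ds) so conditioning is scale-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import units
from .mechanics import (DomainError, FilamentMechanics, FoundationSpec,
                        _require_positive)

__all__ = [
    "ConvergenceError",
    "RodModel",
    "SimulationResult",
    "total_energy",
    "relax",
    "simulate_ramp",
    "dominant_wavelength",
    "finite_length_critical_force",
]


class ConvergenceError(RuntimeError):
    """Energy minimisation failed to reach the gradient tolerance."""


@dataclass(frozen=True)
class RodModel:
    """A discrete rod on a discrete transverse-spring foundation.

    Parameters
    ----------
    n_nodes : int
        Number of nodes (>= 10); rod length is (n_nodes - 1) * node_spacing.
    node_spacing : float
        Rest length of each segment, m.
    mech : FilamentMechanics
        Young's modulus and second moment; sets the bending stiffness EI.
    k_spring : float
        Stiffness of each kinesin spring, N/m.
    anchor_spacing : float
        Spacing L_d between spring anchor points along the rod, m.  May be
        smaller than the node spacing, in which case several springs pool
        on one node (continuum-foundation regime).
    axial_stiffness : float or None
        Axial force per unit strain (an EA surrogate), N.  Default
        1e3 * EI / node_spacing², stiff enough that the rod is nearly
        inextensible relative to bending.
    boundary : str
        ``clamped`` (default) or ``pinned``.
    """

    n_nodes: int
    node_spacing: float
    mech: FilamentMechanics
    k_spring: float
    anchor_spacing: float
    axial_stiffness: float | None = None
    boundary: str = "clamped"

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        _require_positive(node_spacing=self.node_spacing,
                          k_spring=self.k_spring,
                          anchor_spacing=self.anchor_spacing)
        if self.boundary not in ("clamped", "pinned"):
            raise ValueError("boundary must be 'clamped' or 'pinned'")
        if self.n_anchors < 2:
            raise ValueError("need at least 2 spring anchors on the rod")

    @property
    def length(self) -> float:
        return (self.n_nodes - 1) * self.node_spacing

    @property
    def n_anchors(self) -> int:
        return int(math.floor(self.length / self.anchor_spacing)) + 1

    @property
    def ka(self) -> float:
        if self.axial_stiffness is not None:
            return self.axial_stiffness
        return 1e3 * self.mech.flexural_rigidity / self.node_spacing ** 2

    def node_foundation_stiffness(self) -> np.ndarray:
        """Per-node pooled spring stiffness (N/m), springs every L_d."""
        k = np.zeros(self.n_nodes)
        pos = np.arange(self.n_anchors) * self.anchor_spacing
        idx = np.clip(np.round(pos / self.node_spacing).astype(int),
                      0, self.n_nodes - 1)
        np.add.at(k, idx, self.k_spring)
        return k

    def rest_shape(self) -> np.ndarray:
        """Straight unstrained shape, (n_nodes, 2) in m."""
        shape = np.zeros((self.n_nodes, 2))
        shape[:, 0] = np.arange(self.n_nodes) * self.node_spacing
        return shape

    @classmethod
    def from_foundation(cls, mech: FilamentMechanics,
                        foundation: FoundationSpec, length: float,
                        node_spacing: float, **kwargs) -> "RodModel":
        n = int(round(length / node_spacing)) + 1
        return cls(n_nodes=n, node_spacing=node_spacing, mech=mech,
                   k_spring=foundation.spring_stiffness,
                   anchor_spacing=foundation.spacing, **kwargs)

    def analytic_wavelength(self) -> float:
        """Continuum Winkler wavelength 2π(EI·L_d/k)^(1/4), m."""
        ec = self.k_spring / self.anchor_spacing
        return units.TWO_PI * (self.mech.flexural_rigidity / ec) ** 0.25


# ---------------------------------------------------------------------------
# energy and gradient (dimensionless internals)


def _energy_grad(p: np.ndarray, ka_hat: float,
                 kf_hat: np.ndarray) -> tuple[float, np.ndarray]:
    """Dimensionless energy and gradient for node positions ``p`` (N, 2)."""
    v = np.diff(p, axis=0)  # segments
    l = np.hypot(v[:, 0], v[:, 1])
    grad = np.zeros_like(p)

    # axial stretching
    e_ax = 0.5 * ka_hat * np.sum((l - 1.0) ** 2)
    f_ax = (ka_hat * (l - 1.0) / l)[:, None] * v
    grad[1:] += f_ax
    grad[:-1] -= f_ax

    # bending: turning angle between consecutive segments
    u, w = v[:-1], v[1:]
    c = u[:, 0] * w[:, 1] - u[:, 1] * w[:, 0]
    d = np.sum(u * w, axis=1)
    theta = np.arctan2(c, d)
    e_bend = 0.5 * np.sum(theta ** 2)
    denom = c * c + d * d
    s = theta / denom
    # d(theta)/du = (d * dc/du - c * dd/du)/denom, dc/du=(w_y,-w_x), dd/du=w
    dtheta_du = np.empty_like(u)
    dtheta_du[:, 0] = s * (d * w[:, 1] - c * w[:, 0])
    dtheta_du[:, 1] = s * (-d * w[:, 0] - c * w[:, 1])
    dtheta_dw = np.empty_like(w)
    dtheta_dw[:, 0] = s * (-d * u[:, 1] - c * u[:, 0])
    dtheta_dw[:, 1] = s * (d * u[:, 0] - c * u[:, 1])
    grad[:-2] -= dtheta_du
    grad[1:-1] += dtheta_du - dtheta_dw
    grad[2:] += dtheta_dw

    # transverse foundation
    e_f = 0.5 * np.sum(kf_hat * p[:, 1] ** 2)
    grad[:, 1] += kf_hat * p[:, 1]

    return e_ax + e_bend + e_f, grad


def total_energy(model: RodModel, shape: np.ndarray) -> float:
    """Total elastic energy of a shape ((n_nodes, 2) array in m), J."""
    shape = np.asarray(shape, dtype=float)
    if shape.shape != (model.n_nodes, 2):
        raise ValueError(
            f"shape must be ({model.n_nodes}, 2), got {shape.shape}")
    ds = model.node_spacing
    ei = model.mech.flexural_rigidity
    ka_hat = model.ka * ds ** 2 / ei
    kf_hat = model.node_foundation_stiffness() * ds ** 3 / ei
    e_hat, _ = _energy_grad(shape / ds, ka_hat, kf_hat)
    return e_hat * ei / ds


def _free_masks(model: RodModel) -> tuple[np.ndarray, np.ndarray]:
    n = model.n_nodes
    free_x = np.ones(n, dtype=bool)
    free_x[[0, n - 1]] = False
    free_y = np.ones(n, dtype=bool)
    if model.boundary == "clamped":
        free_y[[0, 1, n - 2, n - 1]] = False
    else:
        free_y[[0, n - 1]] = False
    return free_x, free_y


def relax(model: RodModel, shape: np.ndarray, strain: float,
          seed: int | None = 0, perturb: bool = True,
          gtol: float = 1e-6, maxiter: int = 100_000) -> np.ndarray:
    """Minimise the energy at fixed substrate strain; returns the shape (m).

    The imposed end-to-end distance is (1 - strain) times the rest
    length; the starting shape is the supplied one with its x axis
    rescaled to match, plus a seeded transverse perturbation of amplitude
    node_spacing/100 on the free nodes.  ``gtol`` is the gradient
    tolerance in units of the natural scale EI/node_spacing.
    """
    if not 0 <= strain <= 0.5:
        raise DomainError("strain must be in [0, 0.5]")
    ds = model.node_spacing
    ei = model.mech.flexural_rigidity
    ka_hat = model.ka * ds ** 2 / ei
    kf_hat = model.node_foundation_stiffness() * ds ** 3 / ei

    p = np.asarray(shape, dtype=float) / ds
    if p.shape != (model.n_nodes, 2):
        raise ValueError("shape size mismatch")
    # rescale axial coordinate so the ends sit at the strained positions
    span_target = (model.n_nodes - 1) * (1.0 - strain)
    span_now = p[-1, 0] - p[0, 0]
    p = p.copy()
    p[:, 0] = (p[:, 0] - p[0, 0]) * (span_target / span_now)

    free_x, free_y = _free_masks(model)
    p[~free_y, 1] = 0.0
    if perturb:
        rng = np.random.default_rng(seed)
        p[free_y, 1] += rng.standard_normal(free_y.sum()) / 100.0

    nfx, nfy = int(free_x.sum()), int(free_y.sum())
    # diagonal preconditioning: the axial direction is ~ka_hat times
    # stiffer than bending/foundation; rescaling x by sqrt(ka_hat) keeps
    # the optimizer's effective curvature O(1) in every variable
    sx = math.sqrt(ka_hat)

    def pack(q: np.ndarray) -> np.ndarray:
        return np.concatenate([q[free_x, 0] * sx, q[free_y, 1]])

    def unpack(z: np.ndarray) -> np.ndarray:
        q = p.copy()
        q[free_x, 0] = z[:nfx] / sx
        q[free_y, 1] = z[nfx:]
        return q

    def fun(z: np.ndarray):
        q = unpack(z)
        e, g = _energy_grad(q, ka_hat, kf_hat)
        return e, np.concatenate([g[free_x, 0] / sx, g[free_y, 1]])

    res = optimize.minimize(fun, pack(p), jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                                     "gtol": gtol, "ftol": 1e-16})
    q = unpack(res.x)
    _, g = _energy_grad(q, ka_hat, kf_hat)
    gnorm = max(np.abs(g[free_x, 0]).max(initial=0.0),
                np.abs(g[free_y, 1]).max(initial=0.0))
    if gnorm > 100 * gtol:
        raise ConvergenceError(
            f"relaxation stalled: |grad|={gnorm:.3e} (tol {gtol:.1e}), "
            f"nit={res.nit}, message={res.message!r}")
    return q * ds


@dataclass
class SimulationResult:
    """Per-step record of a strain ramp.

    ``axial_force`` is the compressive force carried by the rod (N,
    positive in compression); ``dominant_wavelength`` holds ``None``
    until the transverse amplitude exceeds the onset threshold.
    """

    model: RodModel
    strain_history: np.ndarray
    shapes: list[np.ndarray]
    axial_force: np.ndarray
    dominant_wavelength_m: list[float | None]
    max_amplitude_m: np.ndarray
    onset_strain: float | None

    @property
    def final_shape(self) -> np.ndarray:
        return self.shapes[-1]

    def post_onset_wavelength(self) -> float | None:
        """Dominant wavelength at the final strain step, m."""
        return self.dominant_wavelength_m[-1]

    def to_trace(self, step: int = -1, filament_id: str = "sim"):
        """Export one step as a μm-unit trace for the measurement pipeline."""
        from .traces import FilamentTrace
        return FilamentTrace(
            points=self.shapes[step] / units.UM,
            strain=float(self.strain_history[step]),
            filament_id=filament_id)


def _axial_force(model: RodModel, shape: np.ndarray) -> float:
    v = np.diff(shape / model.node_spacing, axis=0)
    l = np.hypot(v[:, 0], v[:, 1])
    return float(-model.ka * np.mean(l - 1.0))


def simulate_ramp(model: RodModel, max_strain: float, n_steps: int,
                  seed: int | None = 0, onset_amplitude: float | None = None,
                  gtol: float = 1e-6) -> SimulationResult:
    """Quasi-statically ramp the substrate strain from 0 to ``max_strain``.

    Each step relaxes the rod warm-started from the previous shape.
    ``onset_amplitude`` (m; default node_spacing/10) defines buckling
    onset: the first step whose maximum transverse amplitude exceeds it
    sets ``onset_strain``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if onset_amplitude is None:
        onset_amplitude = model.node_spacing / 10.0
    strains = np.linspace(0.0, max_strain, n_steps + 1)[1:]
    shape = model.rest_shape()
    shapes, forces, lams, amps = [], [], [], []
    onset = None
    for i, eps in enumerate(strains):
        shape = relax(model, shape, eps, seed=None if seed is None
                      else seed + i, gtol=gtol)
        y = shape[:, 1]
        amp = float(np.abs(y).max())
        shapes.append(shape)
        forces.append(_axial_force(model, shape))
        amps.append(amp)
        lam = (dominant_wavelength(shape, min_amplitude=onset_amplitude)
               if amp > onset_amplitude else None)
        lams.append(lam)
        if onset is None and amp > onset_amplitude:
            onset = float(eps)
    return SimulationResult(model=model, strain_history=strains,
                            shapes=shapes, axial_force=np.array(forces),
                            dominant_wavelength_m=lams,
                            max_amplitude_m=np.array(amps),
                            onset_strain=onset)


def dominant_wavelength(shape: np.ndarray, min_amplitude: float = 0.0,
                        pad_factor: int = 8) -> float | None:
    """Dominant buckling wavelength of a shape by periodogram peak, m.

    The transverse profile is detrended against the chord, resampled on a
    uniform axial grid and Fourier transformed (zero-padded); the peak is
    refined by parabolic interpolation.  Returns ``None`` when the
    profile's amplitude is below ``min_amplitude``.
    """
    shape = np.asarray(shape, dtype=float)
    x, y = shape[:, 0], shape[:, 1]
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    d = y - chord
    if np.abs(d).max() <= min_amplitude:
        return None
    n = len(x)
    xg = np.linspace(x[0], x[-1], n)
    dg = np.interp(xg, x, d)
    dg = dg - dg.mean()
    nfft = pad_factor * n
    power = np.abs(np.fft.rfft(dg, nfft)) ** 2
    k = int(np.argmax(power[1:])) + 1
    if 1 <= k < len(power) - 1:
        pm, p0, pp = power[k - 1], power[k], power[k + 1]
        denom = pm - 2 * p0 + pp
        delta = 0.5 * (pm - pp) / denom if denom != 0 else 0.0
        k = k + float(np.clip(delta, -0.5, 0.5))
    df = 1.0 / (nfft * (xg[1] - xg[0]))
    return 1.0 / (k * df)


def finite_length_critical_force(mech: FilamentMechanics, ec: float,
                                 length: float, boundary: str = "clamped"
                                 ) -> tuple[float, int]:
    """Critical force of a finite rod on a foundation, with its mode number.

    Minimises F(m) = EI q_m² + E_c / q_m² over integer mode m >= 1 with
    q_m = m·π_eff/L (π_eff = 2π for clamped ends, π for pinned — the
    clamped value reproduces the classical clamped Euler load at E_c = 0).
    Ties break toward the smaller mode.  As L -> ∞ the force approaches
    the continuum value 2√(EI·E_c).
    """
    _require_positive(length=length)
    if ec < 0:
        raise DomainError("ec must be >= 0")
    p_eff = 2 * math.pi if boundary == "clamped" else math.pi
    ei = mech.flexural_rigidity
    if ec == 0:
        return ei * (p_eff / length) ** 2, 1

    def force(m: int) -> float:
        q = m * p_eff / length
        return ei * q * q + ec / (q * q)

    q_star = (ec / ei) ** 0.25
    m_max = max(2, int(math.ceil(q_star * length / p_eff)) + 3)
    best_m, best_f = 1, force(1)
    for m in range(2, m_max + 1):
        f = force(m)
        if f < best_f * (1 - 1e-12):
            best_m, best_f = m, f
    return best_f, best_m
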