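"""Statistical fits connecting buckling measurements to the models.

Two model classes follow the fit-object convention of statistical
packages: construct from data, call ``fit()``, get a results object with
estimates, uncertainties, diagnostics and a ``summary()`` table.

``TransitionalStrainModel``
    Two-segment ("broken-stick") regression of wavelength on strain.  The
    wavelength of buckled filaments drops steeply with strain up to a
    transitional strain (~15%) and shallowly beyond; the breakpoint and
    the wavelength at the intersection of the two lines are the
    quantities of interest.

``ElasticFoundationModel``
    Fit of the (modified) elastic-foundation model to per-condition
    (kinesin spacing, buckling wavelength) summaries.  The single free
    parameter is the kinesin spring constant; the results object compares
    observed wavelengths against the unmodified (constant-modulus) and
    modified (spacing-softened) predictions.

Functional helpers (``loglog_slope``, ``powerlaw_exponent_fc``,
``transitional_strain_fit``, ``fit_modified_model``) expose the same
computations without the object ceremony.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import units
from .mechanics import DomainError, FilamentMechanics, combined_wavelength
from .softening import (SofteningModel, SpringConstantEstimate,
                        modified_wavelength, spring_constant_from_fit)

__all__ = [
    "SlopeFit",
    "loglog_slope",
    "powerlaw_exponent_fc",
    "BreakpointFit",
    "transitional_strain_fit",
    "TransitionalStrainModel",
    "BreakpointResults",
    "ElasticFoundationModel",
    "ElasticFoundationResults",
    "fit_modified_model",
]


# ---------------------------------------------------------------------------
# log-log slopes


@dataclass(frozen=True)
class SlopeFit:
    slope: float
    intercept: float
    stderr: float
    n: int


def loglog_slope(points: Sequence[tuple[float, float]]) -> SlopeFit:
    """OLS slope of log y on log x.

    The slope of a straight line on a log-log plot is the power-law
    exponent; an exact power law is recovered to floating precision.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if np.any(pts <= 0):
        raise DomainError("log-log fit requires strictly positive values")
    res = stats.linregress(np.log(pts[:, 0]), np.log(pts[:, 1]))
    return SlopeFit(float(res.slope), float(res.intercept),
                    float(res.stderr), pts.shape[0])


def powerlaw_exponent_fc(observations: Sequence[tuple[float, float]]) -> float:
    """|exponent| of critical force vs spacing, F_c ~ L_d^(-p).

    For two observations the exponent is computed directly from the pair;
    for three or more it is the absolute log-log OLS slope.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.any(obs <= 0):
        raise DomainError("power-law fit requires strictly positive values")
    if obs.shape[0] == 2:
        (x1, y1), (x2, y2) = obs
        return abs(math.log(y2 / y1) / math.log(x2 / x1))
    return abs(loglog_slope(obs).slope)


# ---------------------------------------------------------------------------
# transitional-strain (breakpoint) regression


@dataclass(frozen=True)
class BreakpointFit:
    """Two-segment least-squares fit of wavelength vs strain.

    ``breakpoint_strain`` is the knee (the transitional strain),
    ``intersection_wavelength_um`` the wavelength where the two fitted
    lines cross.  ``distinct`` is False when a single line fits as well
    (no transition), ``parallel`` when the segments never intersect and
    the breakpoint wavelength falls back to the fitted value at the
    breakpoint strain.
    """

    breakpoint_strain: float
    below_slope: float  # μm per unit strain fraction
    above_slope: float
    intersection_wavelength_um: float
    sse: float
    single_line_sse: float
    distinct: bool
    parallel: bool


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def transitional_strain_fit(points: Sequence[tuple[float, float]]
                            ) -> BreakpointFit:
    """Locate the transitional strain by exhaustive breakpoint search.

    Candidate breakpoints are the midpoints between consecutive observed
    strains, restricted so each segment keeps at least two points; each
    side gets its own OLS line and the breakpoint minimising total SSE
    wins (ties toward the smallest breakpoint).
    """
    pts = np.asarray(sorted(points), dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 (strain, wavelength) points")
    x, y = pts[:, 0], pts[:, 1]
    _, _, sse1 = _ols_line(x, y)

    best = None
    for i in range(2, len(x) - 1):  # split so both sides have >= 2 points
        if x[i] == x[i - 1]:
            continue
        bp = 0.5 * (x[i - 1] + x[i])
        s_lo, b_lo, sse_lo = _ols_line(x[:i], y[:i])
        s_hi, b_hi, sse_hi = _ols_line(x[i:], y[i:])
        sse = sse_lo + sse_hi
        if best is None or sse < best[0] - 1e-12 * max(1.0, best[0]):
            best = (sse, bp, s_lo, b_lo, s_hi, b_hi)
    if best is None:
        raise ValueError("no admissible breakpoint (degenerate strains)")
    sse, bp, s_lo, b_lo, s_hi, b_hi = best

    parallel = math.isclose(s_lo, s_hi, rel_tol=1e-9, abs_tol=1e-12)
    if parallel:
        lam_star = s_lo * bp + b_lo
    else:
        x_star = (b_hi - b_lo) / (s_lo - s_hi)
        lam_star = s_lo * x_star + b_lo
    distinct = sse < sse1 * (1.0 - 1e-9) - 1e-12
    return BreakpointFit(
        breakpoint_strain=float(bp), below_slope=s_lo, above_slope=s_hi,
        intersection_wavelength_um=float(lam_star), sse=float(sse),
        single_line_sse=float(sse1), distinct=distinct, parallel=parallel)


class TransitionalStrainModel:
    """Broken-stick model of buckling wavelength against applied strain.

    Parameters
    ----------
    strain : array-like
        Applied compression strains (fractions).
    wavelength_um : array-like
        Buckling wavelengths, μm.
    """

    def __init__(self, strain, wavelength_um):
        self.strain = np.asarray(strain, dtype=float)
        self.wavelength_um = np.asarray(wavelength_um, dtype=float)
        if self.strain.shape != self.wavelength_um.shape:
            raise ValueError("strain and wavelength lengths differ")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, strain_col: str = "strain",
                       wavelength_col: str = "wavelength_mean_um"):
        return cls(df[strain_col].to_numpy(),
                   df[wavelength_col].to_numpy())

    def fit(self) -> "BreakpointResults":
        bf = transitional_strain_fit(
            list(zip(self.strain, self.wavelength_um)))
        return BreakpointResults(self, bf)


class BreakpointResults:
    """Results of :class:`TransitionalStrainModel`."""

    def __init__(self, model: TransitionalStrainModel, fit: BreakpointFit):
        self.model = model
        self.breakpoint = fit
        self.params = {
            "transitional_strain": fit.breakpoint_strain,
            "below_slope_um_per_strain": fit.below_slope,
            "above_slope_um_per_strain": fit.above_slope,
            "transitional_wavelength_um": fit.intersection_wavelength_um,
        }

    def predict(self, strain) -> np.ndarray:
        """Fitted wavelength at ``strain``: each segment's own OLS line."""
        f = self.breakpoint
        s = np.asarray(strain, dtype=float)
        lo = f.below_slope * s + self._intercept(below=True)
        hi = f.above_slope * s + self._intercept(below=False)
        return np.where(s <= f.breakpoint_strain, lo, hi)

    def _intercept(self, below: bool) -> float:
        f = self.breakpoint
        mask = (self.model.strain <= f.breakpoint_strain if below
                else self.model.strain > f.breakpoint_strain)
        x, y = self.model.strain[mask], self.model.wavelength_um[mask]
        slope = f.below_slope if below else f.above_slope
        return float(np.mean(y) - slope * np.mean(x))

    def summary(self) -> str:
        f = self.breakpoint
        lines = [
            "Transitional-strain (two-segment) fit",
            "=" * 44,
            f"n points                 {len(self.model.strain):>10d}",
            f"transitional strain      {f.breakpoint_strain:>10.4f}"
            f"   ({100 * f.breakpoint_strain:.1f}%)",
            f"wavelength at knee (μm)  {f.intersection_wavelength_um:>10.3f}",
            f"slope below (μm/strain)  {f.below_slope:>10.3f}",
            f"slope above (μm/strain)  {f.above_slope:>10.3f}",
            f"SSE two-segment (μm²)    {f.sse:>10.4g}",
            f"SSE single line (μm²)    {f.single_line_sse:>10.4g}",
        ]
        if not f.distinct:
            lines.append("note: no distinct transition (single line fits "
                         "as well)")
        if f.parallel:
            lines.append("note: segments parallel; knee wavelength taken "
                         "at the breakpoint strain")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# elastic-foundation model fit


class ElasticFoundationModel:
    """Elastic-foundation model of wavelength vs kinesin spacing.

    The observed per-condition buckling wavelength λ_i at kinesin
    spacing L_d,i is modelled as

        λ_i = 2π (E(L_d,i) · I · L_d,i / k)^(1/4)

    where E(L_d) is a (possibly constant) softening model and the
    kinesin spring constant k is the free parameter, estimated by
    geometric-mean inversion.

    Parameters
    ----------
    spacing : array-like
        Kinesin spacings L_d, m.
    wavelength : array-like
        Buckling wavelengths λ, m.
    softening : SofteningModel
        Spacing-dependent Young's modulus.  Calibrate one with
        :func:`mtbuckle.softening.calibrate_softening`.
    second_moment : float
        Cross-section second moment I, m^4.
    """

    def __init__(self, spacing, wavelength, softening: SofteningModel,
                 second_moment: float):
        self.spacing = np.asarray(spacing, dtype=float)
        self.wavelength = np.asarray(wavelength, dtype=float)
        if self.spacing.shape != self.wavelength.shape:
            raise ValueError("spacing and wavelength lengths differ")
        if self.spacing.size < 1:
            raise ValueError("need at least one observation")
        self.softening = softening
        self.second_moment = second_moment

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, softening: SofteningModel,
                       second_moment: float,
                       spacing_col: str = "spacing_nm",
                       wavelength_col: str = "wavelength_mean_um"):
        """Build from a summary table with spacing in nm, wavelength in μm."""
        return cls(df[spacing_col].to_numpy() * units.NM,
                   df[wavelength_col].to_numpy() * units.UM,
                   softening, second_moment)

    def fit(self) -> "ElasticFoundationResults":
        est = spring_constant_from_fit(
            self.softening, self.second_moment,
            list(zip(self.spacing, self.wavelength)))
        return ElasticFoundationResults(self, est)


class ElasticFoundationResults:
    """Results of :class:`ElasticFoundationModel`.

    ``params['k_spring']`` is the estimated kinesin spring constant in
    N/m; ``k_spring_se`` its (multiplicative, delta-method) standard
    error from the scatter of pointwise estimates.
    """

    def __init__(self, model: ElasticFoundationModel,
                 estimate: SpringConstantEstimate):
        self.model = model
        self.estimate = estimate
        self.params = {"k_spring": estimate.k_spring}
        n = estimate.n
        self.k_spring_se = (estimate.k_spring * estimate.log_sd
                            / math.sqrt(n) if n > 1 else float("nan"))

    def predict(self, spacing=None, modified: bool = True) -> np.ndarray:
        """Predicted wavelength (m) at ``spacing`` (m; model data default)."""
        L = self.model.spacing if spacing is None else np.asarray(spacing)
        k = self.estimate.k_spring
        if modified:
            return modified_wavelength(self.model.softening,
                                       self.model.second_moment, k, L)
        bare = FilamentMechanics(self.model.softening.bare_modulus,
                                 self.model.second_moment)
        return np.array([combined_wavelength(bare, k, l) for l in
                         np.atleast_1d(L)])

    @property
    def resid_log(self) -> np.ndarray:
        """Residuals in log wavelength, observed minus modified model."""
        return np.log(self.model.wavelength) - np.log(self.predict())

    def comparison(self) -> pd.DataFrame:
        """Observed vs unmodified vs modified predicted wavelengths."""
        return pd.DataFrame({
            "spacing_nm": self.model.spacing / units.NM,
            "observed_um": self.model.wavelength / units.UM,
            "unmodified_um": np.atleast_1d(
                self.predict(modified=False)) / units.UM,
            "modified_um": np.atleast_1d(self.predict()) / units.UM,
            "resid_log": self.resid_log,
        })

    def summary(self) -> str:
        k = self.estimate.k_spring
        lines = [
            "Elastic-foundation model fit (modified: spacing-dependent E)",
            "=" * 62,
            f"n observations          {self.estimate.n:>12d}",
            f"softening family        {self.model.softening.family:>12s}",
            f"bare modulus (MPa)      "
            f"{self.model.softening.bare_modulus / units.MPA:>12.3f}",
            f"critical spacing (nm)   "
            f"{self.model.softening.critical_spacing / units.NM:>12.2f}",
            f"k_spring (N/m)          {k:>12.4e}",
            f"k_spring SE (N/m)       {self.k_spring_se:>12.4e}",
        ]
        comp = self.comparison()
        lines.append("")
        lines.append(comp.to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Log-log plot of observed wavelengths and both model curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        L = np.geomspace(self.model.spacing.min() * 0.8,
                         self.model.spacing.max() * 1.2, 100)
        ax.loglog(self.model.spacing / units.NM,
                  self.model.wavelength / units.UM, "o", label="observed")
        ax.loglog(L / units.NM, self.predict(L, modified=False) / units.UM,
                  "-", label="elastic foundation (slope 1/4)")
        ax.loglog(L / units.NM, np.atleast_1d(self.predict(L)) / units.UM,
                  "--", label="modified (softened E)")
        ax.set_xlabel("kinesin spacing $L_d$ (nm)")
        ax.set_ylabel("buckling wavelength $\\lambda$ (μm)")
        ax.legend()
        return ax


def fit_modified_model(summaries: Sequence[tuple[float, float]],
                       softening: SofteningModel,
                       second_moment: float) -> ElasticFoundationResults:
    """Functional wrapper: fit k_spring from (spacing, wavelength) in m."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 (spacing, wavelength) summaries")
    arr = np.asarray(summaries, dtype=float)
    model = ElasticFoundationModel(arr[:, 0], arr[:, 1], softening,
                                   second_moment)
    return model.fit()
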