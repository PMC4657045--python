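"""Measurement of buckling metrics from filament centerline traces.

The experimental observable is a traced filament centerline: an ordered
polyline of (x, y) coordinates in μm, with x along the compression axis,
tagged with the applied substrate strain and the kinesin concentration of
the condition.  This module replaces manual image measurement with a
reproducible convention:

1.  detrend the transverse profile against the end-to-end chord,
2.  smooth (Savitzky-Golay) and locate alternating-sign extrema whose
    deviation clears both an absolute floor and a multiple of the
    coordinate-noise scale — these are the buckling crests,
3.  per pair of adjacent opposite-sign extrema: wavelength = 2 x axial
    separation, amplitude = half the transverse peak-to-valley distance,
    radius of curvature from the sinusoidal approximation,
4.  aggregate per condition (mean ± SD over filaments), keeping only
    filaments aligned with the compression axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .mechanics import BuckleMetrics, DomainError, radius_of_curvature

__all__ = [
    "FilamentTrace",
    "StrainSeries",
    "ExperimentDataset",
    "Crest",
    "CrestParams",
    "TraceMeasurement",
    "ConditionSummary",
    "applied_strain",
    "detect_crests",
    "measure_buckle",
    "critical_strain",
    "aggregate_condition",
    "measure_dataset",
    "DEFAULT_SUBSTRATE_LENGTH_MM",
]

# Length of the pre-elongated PDMS substrate taken as the initial length
# for all strain bookkeeping, mm.
DEFAULT_SUBSTRATE_LENGTH_MM = 8.0


@dataclass(frozen=True)
class FilamentTrace:
    """An ordered centerline trace of one filament at one strain.

    ``points`` is an (N, 2) array of (x, y) in μm with x along the
    compression axis.  ``strain`` is the applied substrate compression as
    a fraction, ``strain_rate`` in fraction/s, ``kinesin_nM`` the kinesin
    concentration of the condition.
    """

    points: np.ndarray
    strain: float = 0.0
    strain_rate: float = 0.0
    kinesin_nM: float = 0.0
    filament_id: str = "f0"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("points must be an (N>=2, 2) array")
        object.__setattr__(self, "points", pts)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def contour_length_um(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def end_to_end_um(self) -> float:
        return float(np.hypot(*(self.points[-1] - self.points[0])))

    @property
    def orientation_deg(self) -> float:
        """Angle of the end-to-end vector to the compression (x) axis."""
        dx, dy = self.points[-1] - self.points[0]
        return math.degrees(math.atan2(abs(dy), abs(dx)))

    def oriented(self) -> "FilamentTrace":
        """Return the trace ordered with increasing x."""
        if self.points[0, 0] > self.points[-1, 0]:
            return replace(self, points=self.points[::-1].copy())
        return self


@dataclass(frozen=True)
class StrainSeries:
    """Traces of one filament followed over increasing strain."""

    traces: tuple[FilamentTrace, ...]
    substrate_initial_length_mm: float = DEFAULT_SUBSTRATE_LENGTH_MM

    def __post_init__(self) -> None:
        if len(self.traces) == 0:
            raise ValueError("empty strain series")
        object.__setattr__(self, "traces", tuple(self.traces))
        strains = [t.strain for t in self.traces]
        if any(b <= a for a, b in zip(strains, strains[1:])):
            raise ValueError("strains must be strictly increasing")
        ids = {t.filament_id for t in self.traces}
        if len(ids) > 1:
            raise ValueError(f"series mixes filaments: {sorted(ids)}")


@dataclass
class ExperimentDataset:
    """Traces grouped by condition, with optional per-filament ground truth.

    ``ground_truth`` (for synthetic data) is a DataFrame keyed by
    (filament_id, strain) holding the programmed wavelength/amplitude.
    """

    traces: list[FilamentTrace]
    ground_truth: pd.DataFrame | None = None

    def select(self, kinesin_nM: float | None = None,
               strain: float | None = None) -> list[FilamentTrace]:
        out = self.traces
        if kinesin_nM is not None:
            out = [t for t in out if math.isclose(t.kinesin_nM, kinesin_nM)]
        if strain is not None:
            out = [t for t in out if math.isclose(t.strain, strain,
                                                  abs_tol=1e-12)]
        return out

    @property
    def conditions(self) -> list[float]:
        return sorted({t.kinesin_nM for t in self.traces})

    @property
    def strains(self) -> list[float]:
        return sorted({t.strain for t in self.traces})

    def series_for(self, filament_id: str) -> StrainSeries:
        ts = sorted((t for t in self.traces if t.filament_id == filament_id),
                    key=lambda t: t.strain)
        return StrainSeries(tuple(ts))


def applied_strain(initial_length: float, current_length: float) -> float:
    """Compression strain (L0 - L)/L0 of the substrate (any length unit)."""
    if initial_length <= 0:
        raise DomainError("initial_length must be > 0")
    if current_length <= 0:
        raise DomainError("current_length must be > 0")
    if current_length > initial_length:
        raise DomainError("current_length exceeds initial_length: that is "
                          "extension, not compression")
    return (initial_length - current_length) / initial_length


@dataclass(frozen=True)
class Crest:
    """A detected buckling crest: a local extremum of the detrended profile."""

    position_um: float
    sign: int  # +1 peak, -1 valley
    deviation_um: float  # signed extremal deviation from the chord
    index: int  # sample index in the (oriented) trace


@dataclass(frozen=True)
class CrestParams:
    """Crest-detection settings.

    The smoothing window must sit well below the wavelength being
    measured.  ``smooth_window_um`` (default 1 μm, suited to the long
    crests of sparse-kinesin conditions) acts as a cap: with
    ``adaptive_window`` on, each trace whose transverse profile shows a
    clear spectral peak gets a window of an eighth of that dominant
    wavelength, so short-wavelength buckles are not smoothed away.
    Traces without a clear peak (straight filaments) keep the cap, which
    is what suppresses coordinate noise.
    """

    smooth_window_um: float = 1.0
    polyorder: int = 2
    amplitude_floor_um: float = 0.15
    prominence_factor: float = 3.0
    adaptive_window: bool = True


DEFAULT_CREST_PARAMS = CrestParams()


def _spectral_guess(x: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """Rough (wavelength, amplitude) of the dominant periodic component."""
    n = len(x)
    xg = np.linspace(x[0], x[-1], n)
    dg = np.interp(xg, x, d)
    dg = dg - dg.mean()
    nfft = 4 * n
    spec = np.abs(np.fft.rfft(dg, nfft))
    k = int(np.argmax(spec[1:])) + 1
    df = 1.0 / (nfft * (xg[1] - xg[0]))
    return 1.0 / (k * df), 2.0 * spec[k] / n


def _detrended(trace: FilamentTrace, params: CrestParams,
               noise_sigma: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """x and chord-detrended, smoothed transverse profile of a trace."""
    t = trace.oriented()
    x, y = t.x, t.y
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    d = y - chord
    dx = float(np.median(np.diff(x)))
    if dx <= 0:
        raise ValueError("trace x coordinates must be increasing")
    window_um = params.smooth_window_um
    if params.adaptive_window:
        lam_est, amp_est = _spectral_guess(x, d)
        thr = max(params.amplitude_floor_um,
                  params.prominence_factor * noise_sigma)
        if amp_est > thr:  # a real buckle dominates the profile
            window_um = min(window_um, lam_est / 8.0)
    win = int(round(window_um / dx))
    win = max(win, params.polyorder + 2, 5)
    if win % 2 == 0:
        win += 1
    if win < len(d):
        d = savgol_filter(d, win, params.polyorder)
    return x, d


def detect_crests(trace: FilamentTrace, noise_sigma: float = 0.05,
                  params: CrestParams = DEFAULT_CREST_PARAMS) -> list[Crest]:
    """Locate buckling crests along a trace.

    Returns alternating-sign local extrema of the chord-detrended,
    smoothed transverse profile whose prominence exceeds
    ``max(amplitude_floor, prominence_factor * noise_sigma)``.  A straight
    filament yields an empty list.
    """
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    x, d = _detrended(trace, params, noise_sigma)
    thr = max(params.amplitude_floor_um,
              params.prominence_factor * noise_sigma)
    # prominence, not absolute height: the chord detrend can leave a DC
    # offset of up to one amplitude when both trace ends sit near the same
    # phase, which would hide every valley from a height threshold
    pos, _ = find_peaks(d, prominence=thr)
    neg, _ = find_peaks(-d, prominence=thr)
    raw = sorted([(i, +1) for i in pos] + [(i, -1) for i in neg])
    crests: list[Crest] = []
    for i, sign in raw:
        c = Crest(position_um=float(x[i]), sign=sign,
                  deviation_um=float(d[i]), index=int(i))
        if crests and crests[-1].sign == sign:
            # enforce alternation: keep the larger of same-sign neighbours
            if abs(c.deviation_um) > abs(crests[-1].deviation_um):
                crests[-1] = c
        else:
            crests.append(c)
    return crests


@dataclass(frozen=True)
class TraceMeasurement:
    """Buckling metrics of one trace: per-crest values and trace means."""

    crests: tuple[Crest, ...]
    per_crest: tuple[BuckleMetrics, ...]
    mean_wavelength_um: float | None
    mean_amplitude_um: float | None
    mean_radius_um: float | None

    @property
    def n_crests(self) -> int:
        return len(self.crests)


def _crest_contour_length(trace: FilamentTrace, x: np.ndarray,
                          d: np.ndarray, i_left: int, i_right: int) -> float:
    """Arc length of the raw polyline spanning a crest pair.

    The span runs between alternate zero crossings of the detrended
    profile around the pair (one full wave); where crossings are missing
    the trace ends bound the span, so a single-crest filament contributes
    its whole contour.
    """
    sign_change = np.nonzero(np.diff(np.signbit(d)))[0]
    left_cross = sign_change[sign_change < i_left]
    right_cross = sign_change[sign_change >= i_right]
    lo = int(left_cross[-2]) if len(left_cross) >= 2 else 0
    hi = int(right_cross[0]) + 1 if len(right_cross) >= 1 else len(x) - 1
    pts = trace.oriented().points[lo:hi + 1]
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def measure_buckle(trace: FilamentTrace, noise_sigma: float = 0.05,
                   params: CrestParams = DEFAULT_CREST_PARAMS
                   ) -> TraceMeasurement:
    """Measure per-crest wavelength, amplitude and radius of curvature.

    Wavelength is twice the axial separation of adjacent opposite-sign
    extrema; amplitude is half their transverse peak-to-valley distance.
    With fewer than two crests the wavelength is reported as absent
    (``None``), not zero.
    """
    crests = detect_crests(trace, noise_sigma, params)
    x, d = _detrended(trace, params, noise_sigma)
    per_crest: list[BuckleMetrics] = []
    for a, b in zip(crests, crests[1:]):
        lam = 2.0 * abs(b.position_um - a.position_um)
        amp = 0.5 * abs(b.deviation_um - a.deviation_um)
        rad = radius_of_curvature(lam, amp) if amp > 0 else None
        contour = _crest_contour_length(trace, x, d, a.index, b.index)
        per_crest.append(BuckleMetrics(
            wavelength_um=lam, amplitude_um=amp, radius_um=rad,
            crest_contour_length_um=contour))

    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    mean_amp = (_mean([m.amplitude_um for m in per_crest])
                if per_crest else
                (abs(crests[0].deviation_um) if crests else None))
    return TraceMeasurement(
        crests=tuple(crests),
        per_crest=tuple(per_crest),
        mean_wavelength_um=_mean([m.wavelength_um for m in per_crest]),
        mean_amplitude_um=mean_amp,
        mean_radius_um=_mean([m.radius_um for m in per_crest]),
    )


def critical_strain(series: StrainSeries, noise_sigma: float = 0.05,
                    params: CrestParams = DEFAULT_CREST_PARAMS
                    ) -> float | None:
    """Smallest strain at which the filament first shows a buckling crest.

    Returns ``None`` if no trace in the series buckles (short filaments
    may stay straight through the full strain range).
    """
    for t in series.traces:
        if detect_crests(t, noise_sigma, params):
            return t.strain
    return None


@dataclass(frozen=True)
class ConditionSummary:
    """Mean ± SD of buckling metrics over filaments of one condition."""

    kinesin_nM: float
    strain: float
    n: int
    wavelength_mean_um: float | None
    wavelength_sd_um: float | None
    amplitude_mean_um: float | None
    amplitude_sd_um: float | None
    radius_mean_um: float | None
    radius_sd_um: float | None

    def to_dict(self) -> dict:
        return {
            "kinesin_nM": self.kinesin_nM, "strain": self.strain,
            "strain_pct": 100.0 * self.strain, "n": self.n,
            "wavelength_mean_um": self.wavelength_mean_um,
            "wavelength_sd_um": self.wavelength_sd_um,
            "amplitude_mean_um": self.amplitude_mean_um,
            "amplitude_sd_um": self.amplitude_sd_um,
            "radius_mean_um": self.radius_mean_um,
            "radius_sd_um": self.radius_sd_um,
        }


def _mean_sd(vals: list[float]) -> tuple[float | None, float | None]:
    if not vals:
        return None, None
    m = float(np.mean(vals))
    s = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return m, s


def aggregate_condition(dataset: ExperimentDataset, kinesin_nM: float,
                        strain: float, noise_sigma: float = 0.05,
                        params: CrestParams = DEFAULT_CREST_PARAMS,
                        orientation_tol_deg: float = 15.0
                        ) -> ConditionSummary:
    """Aggregate buckling metrics for one kinesin concentration x strain.

    Filaments whose end-to-end vector deviates from the compression axis
    by more than ``orientation_tol_deg`` are excluded, mirroring the
    restriction to filaments aligned parallel to the compression axis.
    """
    traces = [t for t in dataset.select(kinesin_nM, strain)
              if t.orientation_deg <= orientation_tol_deg]
    if not traces:
        raise ValueError(
            f"no traces for kinesin={kinesin_nM} nM, strain={strain}")
    lams, amps, rads = [], [], []
    for t in traces:
        m = measure_buckle(t, noise_sigma, params)
        if m.mean_wavelength_um is not None:
            lams.append(m.mean_wavelength_um)
        if m.mean_amplitude_um is not None:
            amps.append(m.mean_amplitude_um)
        if m.mean_radius_um is not None:
            rads.append(m.mean_radius_um)
    lm, ls = _mean_sd(lams)
    am, asd = _mean_sd(amps)
    rm, rs = _mean_sd(rads)
    return ConditionSummary(kinesin_nM, strain, len(traces),
                            lm, ls, am, asd, rm, rs)


def measure_dataset(dataset: ExperimentDataset, noise_sigma: float = 0.05,
                    params: CrestParams = DEFAULT_CREST_PARAMS,
                    orientation_tol_deg: float = 15.0) -> pd.DataFrame:
    """Condition summaries for every (kinesin, strain) cell with traces."""
    rows = []
    for c in dataset.conditions:
        for s in sorted({t.strain for t in dataset.select(kinesin_nM=c)}):
            try:
                summ = aggregate_condition(dataset, c, s, noise_sigma,
                                           params, orientation_tol_deg)
            except ValueError:
                continue
            rows.append(summ.to_dict())
    return pd.DataFrame(rows)
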