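# Methods

## System and scope

A microtubule (MT) lies on a compressible elastomer substrate, tethered
by kinesin motors that, in the absence of ATP, behave as passive linear
springs fixed perpendicular to the filament. Compressing the substrate
imposes end-shortening on the filament; the filament responds by
buckling. The package models this as a slender elastic rod on a Winkler
(elastic) foundation and covers four stages: closed-form mechanics,
trace measurement, statistical fitting, and a discrete quasi-static
simulator. Wet-lab steps, raw image segmentation, ATP-driven gliding and
filament fracture are out of scope.

## Closed-form mechanics

For flexural rigidity `EI` and foundation modulus `E_c` (N/m²), the
buckling load of mode wave number `q` is `F(q) = EI q² + E_c/q²`.
Minimising over `q` gives the selected wavelength `λ = 2π (EI/E_c)^¼`
and critical force `F_c = 2√(E_c·EI)`. With discrete springs of
stiffness `k` every `L_d`, `E_c = k/L_d`, so `λ ∝ L_d^¼` and
`F_c ∝ L_d^(−1/2)` at fixed `EI` and `k` — the two analytic exponents
the fits are compared against. The prefactor of `F_c` is configurable
(default 2, the continuum minimum) because absolute experimental force
values in this system are consistent in ratio but not in prefactor with
any single standard constant; only the ratio `(λ₁/λ₂)²` is treated as a
checkable prediction.

Measurement geometry assumes a locally sinusoidal buckle
`y = A sin(qx)`: wave number `q = 2π/λ`, minimum radius of curvature
`R = 1/(Aq²)` at the crest, bending energy per unit contour length
`EI/(2R²)`. With the study constants `E = 49.75 MPa`,
`I = 32.82×10⁻³² m⁴` this reproduces 0.47 pN and 28.0 pN at
`R = 4.18 μm` and `0.54 μm` respectively.

Substrate calibration: kinesin areal density from fluorescence intensity
via a linear factor (default 27.4 molecules·μm⁻²·au⁻¹) or from a QCM
frequency shift via the Sauerbrey relation; spacing from density by
`L_d = ρ^(−1/2)` (square-lattice convention), reported in nm, rounded at
the presentation layer.

## Kinesin softening

Dense kinesin decoration lowers the filament's effective Young's
modulus. `E(L_d) = E⁰ s(L_d/L*)` with a saturating `s`; the default is a
hill law with exponent 2, `s(u) = u²/(u²+1)`, the simplest form able to
pass through both calibration anchors (49.75 MPa at 95 nm, 7.15 MPa at
18 nm). Exponential saturation provably cannot: its attainable modulus
ratio is capped at `L₁/L₂ = 95/18 ≈ 5.28`, below the required 6.96, and
the calibrator raises an explicit error naming that bound. Two anchors
are solved exactly (closed form for hill, 1-D bracketing otherwise);
more anchors are fit by least squares in log-modulus. The calibrated
hill-2 parameters are `E⁰ ≈ 63.9 MPa`, `L* ≈ 50.7 nm`.

The modified foundation model replaces `E` by `E(L_d)`:
`λ(L_d) = 2π (E(L_d)·I·L_d/k)^¼`. Its local log-log slope exceeds ¼
wherever `E` is rising, matching the steeper experimental trend at short
spacing. Inverting per observation gives
`k_i = (2π)⁴ E(L_d,i)·I·L_d,i/λ_i⁴`; the reported estimate is the
geometric mean (errors in λ enter at the fourth power and are
multiplicative), with the scatter of `ln k_i` as the uncertainty scale.
No literature value is asserted for `k`: the package validates the
estimator by parameter recovery on synthetic data (median within 30% of
truth at 10% wavelength noise).

## Trace measurement

Input is a filament centerline polyline (μm) with x along the
compression axis. Conventions:

- **Strain** is substrate compression relative to the 8.0 mm elongated
  substrate length, stored as a fraction, displayed as percent.
- **Detrending**: the transverse profile is referenced to the chord
  through the trace endpoints (which preserves single-crest Euler
  shapes), then smoothed with a Savitzky–Golay filter (order 2).
- **Smoothing window**: capped at 1 μm; when the raw profile shows a
  clear spectral peak (estimated amplitude above the detection
  threshold), the window narrows to an eighth of the dominant
  periodogram wavelength. A fixed window suited to 20 μm crests would
  smooth away 3 μm crests entirely.
- **Crests** are local extrema with peak prominence above
  `max(0.15 μm, 3×σ_noise)`. Prominence, not absolute deviation: chord
  detrending can leave a DC offset of up to one amplitude when both
  trace ends sit near the same phase, which would hide valleys from an
  absolute threshold. Same-sign neighbours are merged (larger kept) so
  crests alternate.
- **Per-crest metrics**: wavelength = 2× the axial separation of
  adjacent opposite-sign extrema; amplitude = half their peak-to-valley
  transverse distance; radius from `R = 1/(Aq²)`; crest contour length
  is the polyline arc length between alternate zero crossings (falling
  back to the trace ends, so a single-crest filament contributes its
  whole contour). Fewer than two crests → wavelength reported as
  absent, never zero.
- **Critical strain** of a strain series is the smallest strain whose
  trace yields at least one crest; absent if none does (short filaments
  may never buckle).
- **Aggregation** is mean ± sample SD over filaments, restricted to
  filaments whose end-to-end direction lies within 15° of the
  compression axis.

With default settings, straight traces carrying 0.05 μm coordinate noise
produce no false crests, and amplitude estimates are unbiased to <2% at
SNR ≥ 10.

## Fitting

- **Transitional strain**: two-segment ("broken-stick") least squares of
  wavelength on strain. Candidate breakpoints are midpoints between
  consecutive observed strains with ≥2 points per side; the SSE-minimal
  split wins, ties toward the smallest breakpoint. Collinear data are
  flagged "no distinct transition"; parallel segments fall back to the
  fitted wavelength at the breakpoint. The wavelength entering
  spacing fits can be either the critical-strain wavelength (default) or
  the two-line-intersection wavelength, selectable because both
  conventions are in use.
- **Power laws** are OLS slopes in log-log space (matching
  straight-line-on-log-log presentation); two-point inputs use the
  direct ratio of logs.
- **Foundation-model fit** (`ElasticFoundationModel.fit()`) wraps the
  spring-constant inversion and reports per-point residuals in log λ
  plus a comparison table of observed vs constant-modulus vs
  softened-modulus predictions.

## Simulator

A discrete rod of `n` nodes (spacing `ds`): bending energy
`EI/(2ds)·θ²` per interior turning angle θ, axial energy
`k_a/(2ds)·(l−ds)²` per segment (default `k_a = 10³·EI/ds²`, making the
rod nearly inextensible relative to bending), and transverse springs of
stiffness `k` anchored every `L_d` along the rod (springs pool onto the
nearest node when `L_d < ds`, the continuum-foundation regime).
Substrate compression imposes the end-to-end distance; ends are clamped
by default (transverse displacement of the two end node pairs fixed),
pinned available. Each strain step minimises the total energy
(L-BFGS-B, analytic gradients), warm-started from the previous shape
with a seeded transverse perturbation of `ds/100` to break the straight
state's symmetry.

Numerical choices: internal nondimensionalisation (lengths by `ds`,
energies by `EI/ds`); diagonal preconditioning of the axial coordinates
by `√(k_a ds²/EI)`; gradient tolerance 10⁻⁶ of the natural force scale
`EI/ds` (the Hessian is near-singular along buckle-phase directions, and
residual forces at 10⁻⁶ are ~10⁻⁵ of the critical load); iteration cap
10⁵ with an explicit convergence error carrying diagnostics. Buckling
onset is recorded when the transverse amplitude exceeds `ds/10`. The
dominant wavelength is the zero-padded periodogram peak of the
chord-detrended profile with parabolic interpolation.

Quasi-statics is justified by the observed insensitivity of buckling to
strain rate; "strain rate" is exposed only as the ramp step count, and
the selected wavelength changes by <5% over a 4× step-count range. The
simulator reproduces the continuum wavelength within 10% for rods ≥5λ,
the Euler single-crest mode as the foundation vanishes, a non-decreasing
crest count as kinesin density rises, onset strains non-decreasing in
foundation stiffness, and post-onset axial force within 15% of the
finite-length critical load.

`finite_length_critical_force` minimises `F(m) = EI q_m² + E_c/q_m²`
over integer modes with `q_m = m·π_eff/L` (`π_eff = 2π` clamped — giving
the classical clamped Euler load at `E_c = 0` — and `π` pinned). Short
rods pay a premium over the continuum force, vanishing by `L ≈ 50λ_c`
(within 2%, away from resonant lengths where it is exact).

## Synthetic data

The generator emulates the measured phenomenology, not the images:
below a condition's critical strain a filament is a straight noisy
centerline; above it, a sinusoid with per-filament wavelength and
amplitude drawn from truncated normal distributions (cut at 0.1× the
mean; distributional form is otherwise unconstrained by the reported
mean ± SD summaries) and uniform random phase. Coordinate noise is
Gaussian with σ = 0.05 μm, a diffraction-limited localisation surrogate.
Everything is a pure function of the seed (bit-identical regeneration).

The five default conditions use kinesin spacings 95/51/36/23/18 nm. The
endpoint conditions carry the reported critical-strain distributions
(λ = 21.14 ± 5.6 μm, A = 2.16 ± 0.89 μm at 95 nm; λ = 3.11 ± 1.21 μm,
A = 0.72 ± 0.16 μm at 18 nm) and critical strains (0.6%, 2.0%); the
36 nm condition's critical strain is 1.2% as reported. Interior
conditions are log-log interpolations between the endpoints — a package
choice, since their distributions are not reported numerically.
Filament lengths are uniform on 20–50 μm; sampling step 0.1 μm (0.05 μm
for short-wavelength conditions). The strain response is two-slope
piecewise linear with the knee at the 15% transitional strain
(wavelength falling to 55% of its critical-strain mean at the knee and
50% by 50% strain; amplitude growing 1.8× by 50% strain) — shapes
chosen once to match the qualitative trends (λ↓, A↑ with strain, with a
slope break at ~15%).

What passing tests show — and don't: recovery tests demonstrate that the
measurement pipeline is unbiased for sinusoidal buckles with Gaussian
localisation noise. Real micrographs add segmentation errors,
non-sinusoidal and localised buckles, crossing filaments and
photobleaching, none of which the generator emulates; pipeline accuracy
on real data is therefore not established here. An optional raster
renderer (Gaussian PSF line integral) produces synthetic images for any
future pixel-level tracing work.

## Problem sizes and defaults

Pipeline-recovery runs use 200 filaments per condition; Monte-Carlo
estimator checks use 100–500 replicates; simulator scenarios use rods of
3–5 wavelengths at 12–16 nodes per wavelength, strain ramps of 6–24
steps to 0.4–2% strain. These sizes put every stochastic check well
inside its tolerance while keeping the full suite fast.

## Known limitations

- The filament is a 2-D inextensible-ish elastic rod: no thermal
  fluctuations, no anisotropic/orthotropic shell corrections, no
  polymerisation forces, no fracture, no kinesin binding kinetics, no
  substrate viscoelasticity.
- Springs are strictly transverse and harmonic; there is no axial drag
  or slack, so simulated onset strains are set by the rod's own axial
  compliance and are much smaller than substrate-referenced experimental
  critical strains.
- The hill-2 softening law is a calibration device pinned by two
  anchors, not a mechanistic model; its extrapolation below 18 nm
  spacing is unvalidated.
- The spring-constant estimator amplifies wavelength noise fourfold;
  with few conditions its confidence interval is wide (see the reported
  log-scatter).
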