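# Methods

## Forward spectrum model

An interrogation frame is modelled as a constant spectral floor plus one
Gaussian peak per FBG channel,

    I(λ) = b + Σ_ch A_ch · exp(−(λ − λ_ch)² / 2σ²) + ε(λ),

sampled on a uniform grid (default 1510–1590 nm at the 2 pm hardware step).
`A_ch = reflectivity × envelope(λ_ch)` couples the grating reflectivity
(~30% for all four channels) to the interrogator's source-power envelope; a
linear gain ramp across the grid is the default envelope, reproducing the
observed amplitude discrepancy between equal-reflectivity channels (an
identity envelope is available). ε is additive white Gaussian noise with
standard deviation `sigma_rel` × (tallest peak amplitude), clipped at zero.
This is a phenomenological model: no coupled-mode FBG physics, no
polarization, no electronics.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| nominal centers | 1520/1540/1560/1580 nm | four separated C-band peaks; true device values are only shown graphically, so these are configurable stand-ins |
| peak FWHM | 60 pm | the inverse model fits Gaussians, so the forward model is Gaussian; width is a stand-in of the same order as short femtosecond-written gratings |
| grid step | 2 pm | the interrogator's printed hardware resolution |
| baseline b | 0.05 (fraction of unit amplitude) | raw interrogator output shows a non-zero floor; also keeps the noise-clipping at zero from biasing fits |
| sigma_rel | 0.01 | the interrogator's noise floor is uncharacterized; 1% of the tallest peak is the documented assumption used by every noise study here |

## Peak localization

Each frame is partitioned into per-channel windows with boundaries at the
midpoints between adjacent nominal centers (outer boundaries at the grid
ends) — symmetric headroom for peak motion. In each window a Gaussian plus
constant baseline is fitted by bounded trust-region least squares
(`scipy.optimize.curve_fit`, tolerances 1e-10, center bounded to the
window, width to [0.2×, 5×] the default). Initialization: center at the
window argmax (first maximum on ties), amplitude = max − min, baseline =
min. Flat windows, non-convergence, and center estimates pinned within one
grid step of a window bound are reported as `converged=False` with a
diagnostic, and any unconverged channel refuses the whole palpation point
(the statistic needs all four shifts). Only the fitted center feeds the
statistic; amplitude changes are recorded but unused.

### Localization accuracy and its floor

A Monte-Carlo study (`localization_error_study`) measures the center error
at the hardware grid. At the defaults (FWHM 60 pm, 2 pm step, 1% noise) the
Fisher information of the Gaussian-plus-baseline model puts the Cramér–Rao
bound for the center at σ_c ≈ 0.076 pm; the fitter empirically attains it
(measured RMS ≈ 0.076 pm), i.e. it is an efficient estimator. The 95th
percentile of |error| is therefore ≈ 1.96 σ_c ≈ 0.15 pm, and **cannot** be
below 0.1 pm in this noise world for any unbiased estimator. The
acceptance test asserting the instrument's printed sub-0.1 pm figure under
these assumptions consequently fails, and is left failing on purpose: the
printed figure must correspond to a quieter interrogator and/or a
different peak width than our stand-in defaults. Reaching 0.1 pm at the
95th percentile requires e.g. sigma_rel ≲ 0.0067 at FWHM 60 pm (σ_c scales
as sigma_rel · √FWHM).

## Stiffness statistic

S is the sum of absolute per-channel shifts in pm; min–max normalization
maps a session's extremes to exactly 0 and 1. Degenerate sessions (all S
equal) map to all-zeros with a warning — "no contrast, uniformly softest"
is safer than NaN. Normalization scope is a single session; cross-session
comparability is explicitly not claimed. Calibration fits are unweighted
ordinary least squares (linearity holds over the working range; nothing is
known about heteroscedasticity), reporting slope, intercept, R², and the
support over which interpolation is valid.

## Heat-map reconstruction

Scattered (x, y, s_norm) points are interpolated piecewise-linearly on
their Delaunay triangulation inside the convex hull, with nearest-neighbor
extrapolation outside. A linear interpolant obeys the maximum principle, so
the map never leaves the input range and normalization survives
interpolation; this is why splines were not used (no interpolant is named
by the source material). Output grid: 50×50 over the ROI by default.
Fewer than three points fall back to nearest-neighbor; three or more
collinear points refuse 2D contouring with an explicit message (a 1D line
profile is offered instead). Stiff-region detection thresholds the map at
a fraction of its maximum and labels connected components
(`scipy.ndimage.label`), reporting centroid, bounding box, and area
fraction.

## Phantom simulator

The phantom is a 40 mm × 40 mm patch of unit-stiffness tissue with an
optional rigid line-segment inclusion (a blade or needle slid underneath):
footprint half-width 1.5 mm, stiffness multiplier 30, depth-attenuation
factor 1.0, and a 1 mm continuous linear taper at the footprint edge.
A press at (x, y) produces per-channel shifts

    Δλ_B(ch) = response_slope · press_depth · stimulus(x, y) · w_ch,

a linear model matching the probe's measured linear response; the default
slope (5 pm/mm per unit relative stiffness) puts a 2 mm background press at
10 pm per channel — far above the localization floor, far below the
nm-scale large-deformation regime.

The stimulus and direction weights `w_ch` make the qualitative contact-
angle behaviour concrete:

- **direct contact** (press point within the inclusion footprint + taper):
  stimulus = local stiffness; all four gratings compress (w = −1, common
  blue-shift);
- **side contact** (offset beyond the footprint but within the 6 mm
  influence radius): the probe feels whichever dominates — the soft tissue
  under the tip or the inclusion's elevated response attenuated by
  `side_contact_attenuation = 0.1`, i.e. stimulus = max(background,
  0.1 × elevated). The grating whose dome azimuth faces the inclusion goes
  tensile (w = +1, red-shift), the others compress. Direct contact is
  therefore exactly 1/attenuation = 10× stronger than side contact at the
  defaults, and side contact still exceeds background (30 × 0.1 = 3×), as
  the needle-adjacent points in the in vivo scans do;
- **free tissue**: stimulus = background, uniform compression.

The multiplier default of 30 (rather than the minimal 10) encodes that
metal is vastly stiffer than parenchyma while keeping the 10× direct/side
ratio, which depends only on the attenuation once multiplier × attenuation
exceeds 1. Depth attenuation is a single multiplicative factor — insertion
depth was never quantified at the source. Amplitude losses under large
deformation are not simulated (no pipeline stage consumes amplitude).

Sessions are reproducible: one `SeedSequence` per session spawns a child
stream per press point, so the same seed yields byte-identical spectrum
files regardless of evaluation order.

### What the simulator does and does not establish

It emulates: four Gaussian peaks with unequal amplitudes, the linear
shift-vs-indentation response, blue/red shift signs by contact geometry,
the order-of-magnitude direct/side contrast, and a 2D stiffness field with
a rigid inclusion. It does not emulate: real dome mechanics (no contact
model, no viscoelasticity), temperature drift, hand-held press-depth
variability, amplitude losses, or the true (uncharacterized) mapping from
tissue contrast to shift magnitude. A green end-to-end test therefore
establishes that the *pipeline* recovers what the *stated forward model*
generates — not that the physical probe meets those numbers.

## Numerical choices and degenerate inputs

- Shifts are differences of fitted centers, in pm; antisymmetric by
  construction and invariant to uniform intensity scaling.
- Spectrum files are two-column UTF-8 text written at 10 significant
  digits; the reader rejects non-monotone or non-uniform grids and negative
  intensities, naming the offending line.
- Duplicate press coordinates with conflicting values are refused by name;
  exact duplicates are deduplicated.
- Ties in the map argmax resolve to the first grid cell (row-major).
- Configuration is validated by a pydantic schema before any stage runs;
  pipeline runs log a config hash and the seed sufficient to reproduce them.

## Known limitations

- The nominal Bragg wavelengths, peak widths, and noise floor are stand-ins
  for graphically-reported device characteristics; all are configurable.
- Vectorial force magnitude/direction decoding is out of scope, as is any
  absolute stiffness scale (kPa): S is relative within a session.
- The sub-0.1 pm localization figure is not reachable under the documented
  1%-noise assumption (see the Cramér–Rao analysis above).
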