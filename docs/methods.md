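# Methods

## Physical model

**Gradient formation.** The observation channel spans `width_um`
(default 1000 µm) between two reservoirs treated as infinite,
constant-concentration sources: the membrane (0.1 µm pores) passes
solutes freely and blocks cells, and the reservoirs are large compared
with the channel volume, so transport across the width reduces to 1-D
diffusion with Dirichlet boundaries. `simulate_concentration` solves the
transient problem explicitly (conservative second-order central
differences, time step at half the diffusive CFL limit); its long-time
limit, and the profile used for whole-experiment simulations, is the
linear `steady_gradient`. For a small molecule (D_c ≈ 500 µm²/s) the
formation time w²/D_c is ~30 min against a 9-h horizon, and the
device's gradient is stable over that horizon, so population runs use
the steady profile throughout.

**Population dynamics.** The bacterial density b(x, t) follows a
drift–diffusion–growth (Keller–Segel type) equation

    ∂b/∂t = D_b ∂²b/∂x² − ∂/∂x(χ b ∂c/∂x) + r(c) b

with zero-flux walls. This is the standard continuum reduction of a
run-and-reverse swimmer in a shallow gradient: D_b is the effective
motility diffusivity, χ the chemotactic sensitivity (drift velocity
χ ∂c/∂x), and r(c) a local specific growth rate. The growth law is
Monod by default, r(c) = r0·c/(K + c) with K = c_left/2 — a saturating
nutrient response that reduces to linear at low concentration; linear,
constant, and no-growth laws are available for controlled tests.

Assumptions worth stating: no flow (the device is diffusion-only), no
cell–cell interactions or consumption of the attractant, no
behavioral-state detail (run–reverse–flick statistics enter only through
the effective D_b and χ), constant reservoirs for the full 9 h.

## Numerical scheme

The population solver is an operator-split explicit finite-volume
scheme on a cell-centered grid tiling [0, width] — by default one cell
per imaging pixel column, so density cells map one-to-one onto rendered
pixels. Diffusive and advective fluxes are assembled at cell faces
(central for diffusion, first-order upwind on the face drift velocity
for advection, zero at the walls) and applied conservatively; growth
multiplies by exp(r(c) Δt) pointwise. The step satisfies both the
diffusive and advective CFL conditions with a safety factor of 0.5.
Consequences:

- with r0 = 0, ∫b dx is conserved to round-off (the mass-conservation
  tests assert < 10⁻⁶ relative drift and observe ~10⁻¹⁴);
- the upwind + CFL combination keeps b ≥ 0; a negative value beyond
  round-off raises a solver error rather than being silently clipped;
- first-order upwind is mildly diffusive: at the default 100-cell
  scenario grid the discretization error of a steep (Péclet ≈ 6)
  steady profile is ~2%, small against replicate-to-replicate imaging
  noise; grid-halving convergence is verified at 200→400 cells (< 1%
  change).

The transient concentration solver uses the same explicit machinery on
a node grid with pinned boundary values and is validated against the
Fourier-series solution of the Dirichlet problem.

## Scenarios (study conditions)

Five presets mirror the assay conditions; all share D_b = 30 µm²/s,
uniform initial density, and the default imaging model.

| scenario | c_left | units | χ (µm²/(s·conc)) | r0 (1/h) |
|---|---|---|---|---|
| control | 0 (= c_right) | — | 0 | 0 |
| algae | 1.0 | effective | 185 | 0.15 |
| conditioned_media | 1.0 | effective | 135 | 0.15 |
| oxaloacetate | 0.8 | mM | 70 | 0.06 |
| citric_acid | 0.4 | mM | 30 | 0.02 |

The organic-acid concentrations (0.8 mM oxaloacetate, 0.4 mM citric
acid) are the assay's loading concentrations. The algae and
conditioned-media sources are complex mixtures with no single measurable
attractant concentration, so they are modeled as an *effective
attractant* normalized to 1 at the left reservoir; their χ and r0 were
fixed once by the sweep in `scripts/calibrate_scenarios.py` so that the
full pipeline's 9-h endpoint asymmetry lands in the observed bands for
each condition (algae ≈ 0.6, conditioned media ≈ 0.5), and the
organic-acid sensitivities were scaled in proportion to their weaker
observed endpoints (≈ 0.28 and ≈ 0.08). These are descriptive
parameterizations of two source strengths, not a mechanistic claim
about what the mixtures contain.

D_b = 30 µm²/s is at the low end of reported effective diffusivities
for peritrichous/polar swimmers; together with the calibrated χ it
gives the observed phenomenology — asymmetry rising over the first
hours and saturating well before 9 h (steady-state A for a gradient
scenario is (1 − a)/(1 + a) with a = exp(−χ c_left/(2 D_b)), ≈ 0.6 for
the algae parameters before imaging effects).

## Fluorescence rendering

Two modes, selected per `ImagingParams`:

- **particles** (default for bacterial scenarios): each frame draws a
  Poisson number of discrete cells (expected `cells_per_unit`·∫b dx ≈
  3000 at the initial density) with positions sampled from the density
  profile, stamped as Gaussian spots (σ = 1 px). Spot amplitudes are
  normalized so the channel-mean cell signal equals `gain`·b̄, matching
  the continuum mode in expectation. Frames are re-sampled
  independently — cells rearrange completely between 5-min frames.
- **continuum**: `gain`·b broadcast along the channel length; the right
  model for dissolved dye and the exact-linearity reference.

Both then add a constant `background_level` (200 counts), a smooth
zero-mean inhomogeneity field (Gaussian-filtered white noise, std 30
counts, 300 µm length scale — out-of-focus light and illumination
falloff), Poisson shot noise and Gaussian read noise (σ = 3), and
quantize to 16-bit. All randomness flows from a single per-replicate
seed recorded in the stack metadata; rendering is bit-reproducible.

The particles mode exists because of how rolling-ball correction
interacts with image structure: grayscale opening with a ball removes
*everything* smoother and wider than the ball (planes are fixed points
of the opening), so a smooth continuum rendering of the cell layer would
be subtracted away with the background. Real frames are granular —
individual GFP cells at low magnification — and it is precisely that
granularity that lets the correction separate cell signal from smooth
background. Correcting particle-rendered frames therefore preserves a
signal proportional to local cell density (with a noise-floor residual
that slightly compresses A toward 0; the scenario calibration absorbs
this).

## Image processing

- **Rolling-ball correction**: background = grayscale morphological
  opening with a ball (spherical-cap) structuring element;
  corrected = frame − background, clipped at 0, applied to each frame
  independently. The generic default radius is 50 px; the scenario
  pipeline uses 20 px at 10 µm/px (a 200 µm ball) — larger than any
  cell spot, smaller than the background structure. The implementation
  (scipy grey_opening with an explicit cap height map) is tested for
  exact agreement with a brute-force opening oracle; note that
  scikit-image's `rolling_ball` is a different (kernel-based) variant
  that deviates from a plain ball opening on tilted backgrounds.
- **Profiles and kymographs**: the intensity profile averages the ROI
  along the channel length per column; a kymograph stacks one such
  compressed row per frame in time order. Pixel coordinates are
  0-based half-open; "left" always denotes the chemoeffector side, and
  stacks acquired mirrored are flipped on load via a sidecar flag.

## Metrics conventions

- A is computed on rolling-ball-corrected frames (A is invariant under
  intensity scaling but not under additive offsets, so the offset must
  be removed first).
- Odd ROI widths drop the single middle column so the halves are
  exactly equal.
- A frame with zero total intensity has no defined A and carries NaN,
  never 0; NaNs propagate as missing values in summaries.
- Endpoint selection takes the frame nearest the requested time, ties
  to the earlier frame; replicate summaries report mean and sample SD
  (n−1), SD undefined for a single replicate.
- The saturation value averages A over a trailing window, default
  60 min, matching the flat tail after the rise of the first 4–5 h.

## Dye calibration

A linear (affine) intensity–concentration relation is assumed —
standard for dilute fluorescein-class dyes at the 100 nM scale used to
visualize gradients. The offset comes from a dye-free (dark) profile,
the slope from a uniform-concentration control; conversion clips at
zero. Gradient linearity is assessed by ordinary least squares with R²
and edge-extrapolated endpoint concentrations. Round-trip recovery
(render a known gradient, calibrate, convert back) is accurate to a few
percent at default noise; photobleaching and the dye's pH sensitivity
are not modeled.

## HPLC arithmetic

Peak areas are taken as given. Percent area is computed over exactly
the record set supplied by the caller; single-point quantification is
linear through the origin against the 1.25 mg/ml standards; mg/ml→mM
uses bundled molecular weights (oxaloacetic 132.07, citric anhydrous
192.12, citric monohydrate 210.14, malic 134.09, succinic 118.09,
fumaric 116.07 g/mol), with supernatant conversions using the anhydrous
forms. Reports round percentages to 2 decimals and mM to 1 decimal;
full precision is kept internally. Note the plain ratio model applied
to the printed supernatant areas gives ≈ 0.066 mg/ml for oxaloacetic
acid, not the reported 0.116 — consistent with an unstated dilution or
injection factor in the original quantification; the module's contract
is the ratio model, and the mM conversions operate on reported mg/ml
values directly.

## Problem sizes

Scenario simulations use a 100-cell density grid (one cell per 10 µm
pixel column), 100×60 px frames, 109 frames over 9 h, and ball radius
20 px; at these sizes a full replicate (PDE + rendering + correction +
metrics) takes a few seconds, so multi-replicate acceptance runs
complete in minutes. The geometry, raster, and radius are configurable;
analyses of finer rasters scale linearly in pixel count times ball
area.

## What the generator does and does not emulate

It reproduces the measurable structure of the assay: gradient
formation, drift + differential-growth redistribution, granular
fluorescence with structured background and realistic noise, replicate
variability through seeds. It does not model attractant consumption,
reservoir depletion, secretion dynamics of a living algal culture,
cell–cell signaling, swimming-pattern detail, photobleaching, or focus
drift. Passing tests therefore demonstrate that the *analysis chain*
recovers known ground truth under realistic imaging conditions — not
that the biological parameters are the true ones for any particular
strain.
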