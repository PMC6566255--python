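# Methods

## The physical model

The wing-scale interior is idealized as `n_stories` (default 4) pairs of
horizontal layers.  An "A" layer of thickness `d_a` carries one air void per
lateral unit cell — a cuboid of width `v_xy = p_xy − c` and height
`v_z = d_a` — connected to its four lateral neighbors by horizontal air
channels of square cross-section `w_a × w_a`.  A "B" layer of thickness
`d_b` is solid chitin except for one vertical channel of cross-section
`w_b × w_b`.  The channel crossing each cell boundary has total length `2c`
and is halved by the boundary, so each cell contains channel segments of
length `c` at both ends of each lateral axis; where a segment reaches into
the central void the overlap is counted once (the air volume is the union
of the cuboids, computed by inclusion–exclusion over the five boxes and
cross-checked in the tests against a 1-nm voxel count).

Two parameter sets describe the two wing sides; all lengths in nm:

| quantity | dorsal | ventral |
|---|---|---|
| lateral / vertical periodicity `p_xy = p_z` | 200 | 260 |
| `d_a` / `d_b` | 150 / 50 | 195 / 65 |
| channel widths `w_a = w_b` | 100 | 130 |
| horizontal channel length `c` | 25 | 32.5 |

The ventral cell is a uniform 1.3× scaling of the dorsal one, so both share
the same perforation factors (`P_A ≈ 0.849`, `P_B = 0.25`) and differ only
in the length scale.

Each layer reduces to an effective medium,
`n_eff = P·n_void + (1−P)·n_chitin`, with `n_chitin = 1.56 + 0.033i` (the
imaginary part standing in for pigment absorption), `n_ethanol = 1.36` and
`n_air = 1`.  The stack predictor `λ_main = 2(Re n_a·d_a + Re n_b·d_b)`
gives 467.4 nm (dorsal) and 607.6 nm (ventral).  The channel width is the
one free geometric parameter; `calibrate_channel_width` solves the
monotone 1-D problem `λ_main(w) = λ_target` by bracketed root finding
(0.1 nm tolerance).

### Why a 1-D transfer-matrix solver

Normal-incidence backscattering from this architecture is insensitive, to
first order, to the lateral arrangement of the voids — lateral disorder
redistributes light in angle, not in the normal-return spectrum.  The
lateral structure therefore enters only through the volume fractions, and
the stack is solved as a 1-D effective-medium multilayer with the standard
characteristic-matrix recursion at normal incidence (substrate and ambient
are air; the wing's deeper scale layers are handled as an additive
background instead).  The recursion is written in the `n − ik` convention
internally and conjugates the package's `n + ik` inputs; it is verified in
the tests against closed-form Fresnel and Airy formulas at 1e-10 relative
accuracy.

A consequence of the shallow, four-story stack is that the reflectance
maximum sits 12–16 nm blue of `λ_main`: the finite-thickness Fabry–Perot
envelope skews the fundamental stop band.  This is physical, not a solver
artifact — the maximum converges to `λ_main` as stories are added (0.25 nm
offset at 16 stories), which is how the Bragg consistency check is run
(24 stories, agreement within one 2-nm grid step across random geometries).

### Vapor response

Capillary condensation fills the smallest air spaces first, and at ordinary
illumination the filled and unfilled regions are farther apart than the
coherence length of white light, so reflectances (not fields) add.  The
spectrum at a filling state `(c_B, c_AB, s)` is the incoherent mixture of
the three scenario spectra, each evaluated at `λ/(1+s)`:

* `c_B` — the weight of the process filling only the B channels; it raises
  the A/B index contrast and with it the peak reflectance;
* `c_AB` — the weight of the process filling both layers; it lowers the
  contrast and depresses the reflectance near the peak;
* `s` — fractional isotropic swelling of the chitin skeleton; a pure red
  shift.  (The rescale `λ/(1+s)` is used because fitted values like
  `s = 0.008` mean "0.8% enlargement".)  Rescaled wavelengths falling
  outside 200–800 nm take the boundary value; the background-fit windows
  remove any edge influence.

The filling factors of the layers follow as `f_A = c_AB`,
`f_B = c_AB + c_B`.  Only the fully-empty/fully-filled spectra are ever
solved; partial filling never enters through intermediate effective
indices, consistent with the incoherent-mixture picture.

### Whole-wing corrections

Two effects separate a whole-wing spectrum from a single-scale one: the
melanin-bearing ground scales add a smooth background, modeled as a line
`a + b·λ` fitted by least squares to the 200–250 nm and 750–800 nm flanks,
and the random angular distribution of scales smears the spectrum, modeled
as a Gaussian convolution (kernel normalized on the grid, nearest-value
edge padding).  Defaults, chosen once as plausible for a dark-backed
lycaenid wing and not revisited: background `0.10 + 5·10⁻⁵·λ[nm]` when
synthesizing (melanin absorbs more strongly toward the blue, so the
background rises to the red), broadening width `σ = 15 nm`, denominator
floor `10⁻⁴` reflectance when forming relative spectra (the deep-UV
reference can approach zero under chitin absorption).  All are
configurable.  Relative spectra are always ratios of two whole-wing
spectra on the common 200–800 nm, 2-nm grid (301 points).

### Fitting

The fit minimizes `Δ = ∫ (ρ_measured − ρ_model)² dλ` over 200–800 nm
(trapezoidal quadrature).  At fixed `s` the model relative spectrum is
affine in `(c_B, c_AB)` — broadening and background are affine maps and the
zero-vapor denominator carries no parameters — so three forward evaluations
(at states (0,0,s), (1,0,s), (0,1,s)) give the affine basis and a bounded
linear least squares (`scipy.optimize.lsq_linear`, BVLS) solves the inner
problem exactly.  The swelling enters nonlinearly through the spectral
rescale and is handled by a 26-point grid on `s ∈ [0, 0.05]` followed by
bounded golden-section refinement between the best grid point's neighbors
(`xatol = 10⁻⁹`).  The procedure is deterministic; a forward model whose
filling scenarios coincide is flagged as non-identifiable.  The fit is
performed at the largest measured concentration (`x = 0.5`) and the linear
law `parameter = slope·x` extrapolates downward; per-concentration fitting
is a one-argument change.

Peak positions are localized by a parabola through the grid maximum and its
two neighbors inside a 400–700 nm search window (the 2-nm grid is coarse
against ~4–6 nm shifts); a maximum on the window edge raises an error
rather than returning a truncated value.

### TEM direct-space averaging

For every interior void of the annotated middle "A" layer (endpoints lack a
neighbor and never contribute), the left/right-neighbor chord gives the
local distance `d` and tilt `α`; the sub-image is sampled in the void-local
frame — translate to the void center, rotate by `−α`, rescale so `d` maps
to the median chord — with bilinear interpolation, and the sub-images are
averaged pixel by pixel without per-sub-image intensity normalization.
Samples falling outside the image take the nearest edge value and are
flagged in a coverage map.  Note `d` spans two lattice spacings (left
neighbor to right neighbor), so walls between voids appear at odd multiples
of `d/4` in the averaged frame.  Detection of void centers (when no manual
annotation is supplied) smooths the band with `σ = spacing/8`, keeps local
maxima above 65% of the band's dynamic range separated by at least half the
expected spacing, and refines each to an intensity-weighted centroid; the
band is extended by 20% of its height so layer waviness does not clip the
blobs.  Linecuts are min–max rescaled to [0,1]; a constant row is returned
as zeros and flagged.  Two statistics summarize channel–void correlation in
a B row: the detrended autocorrelation at one lattice spacing, and a
wall-alignment contrast (mean intensity near wall positions minus mean near
void positions, scaled by the row's range) which is ≈0 for uncorrelated
channels.

### Synthetic data — what it does and does not emulate

The TEM generator renders three gray levels (chitin 60, projected channels
150, voids 230 on an 8-bit scale — partial-thickness air in a ~70-nm slice
projects as intermediate gray), with: jittered neighbor spacings (Gaussian,
std = `spacing_jitter`·period, resampled below the void diameter because
real voids are disjoint cavities), half-lattice stagger between adjacent A
layers, sinusoidal layer waviness, vertical channels placed either above
the walls of the middle layer (`above_wall`) or uniformly at random, and
additive Gaussian sensor noise.  It does not attempt electron-optics
simulation, defocus/astigmatism, stain gradients, curved void walls, or
ridge cross-sections; passing DSA tests therefore demonstrate correctness
of the registration/averaging machinery, not robustness to every real
imaging artifact.  The spectra generator drives the forward chain with a
linear-in-x coefficient law at `x ∈ {0.125, 0.25, 0.375, 0.5}` (the
calculated-series concentrations) and multiplies by unit-mean lognormal
noise (relative spectra are positive); every generator is a pure function
of its parameters and seed.

The packaged ethanol-response laws — dorsal `c_B = 0.08x`, `c_AB = 0.08x`,
`s = 0.016x`; ventral `c_B = 0.4x`, `c_AB = 0`, `s = 0.012x` — are the
fitted characterizations of the two wing sides and serve as ground truth
for round-trip tests: at `x = 0.5` they give `f_B = 8%`, `f_A = 4%`, 0.8%
swelling (dorsal) and `f_B = 20%`, `f_A = 0%`, 0.6% swelling (ventral).
The forward models with these laws shift the whole-wing peak by ≈4.3 nm
(dorsal) and ≈6.1 nm (ventral) at `x = 0.5`, against measured shifts of
4.5 and 6.5 nm — the ~0.2–0.4 nm deficit is the expected cost of the
effective-medium reduction, and the dorsal < ventral ordering and the
shift-to-periodicity ratios (≈0.021 and ≈0.024 per unit `x = 0.5`) are
reproduced.

## Problem sizes

All computations are desk-scale: 301-point spectra, stacks of 8–48 layers,
TEM renders of roughly 2000×350 px with 20–30 voids, fits of three
parameters.  The full test suite runs in well under a minute; the
acceptance script in about a second.

## Known limitations

* Normal incidence only; no polarization splitting, oblique or goniometric
  spectra.
* The effective-medium reduction drops all lateral interference structure;
  UV behavior (where the cuboid-void approximation and the reduction are
  both least faithful) should not be trusted.
* The melanin background is linear and fitted/assumed, not derived from
  eumelanin/pheomelanin absorption curves; broadening width and background
  defaults are package choices, so absolute whole-wing line shapes are
  illustrative.
* The shallow-stack blue offset of the reflectance maximum from `2·p_eff`
  (~13 nm at four stories) means `λ_main` is a periodicity descriptor, not
  the literal four-story peak position.
* Fit uncertainties are only available as seeded-replicate spread; no
  analytic error propagation.
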