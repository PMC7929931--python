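# Methods

This note documents the models, numerical choices and limitations behind
`rootdome`.  Units are micrometres (µm) for lengths, µm² for areas, hours for
simulated time; angles are radians unless stated.

## Outline standardization

An outline is an ordered sequence of cell-junction coordinates along the
outer surface of a root-tip median section.  The unified frame is built in
three steps: (1) duplicate the points rotated by π, (2) translate the
duplicates vertically until max y(original) = min y(duplicate), so the two
halves join into a closed curve, (3) take the mean x of all points (original
plus duplicated) and the minimum y of the originals as the new origin.  We
rotate about the centroid of the original points; with that choice the final
frame is exactly (x − mean x, y − min y), which makes the procedure invariant
to input translation and point-order reversal — properties asserted in the
tests.  Rotating about any other center would make the step-3 origin depend
on the digitization frame, which cannot be intended.

Dome width at a height cutoff interpolates linearly along each flank (the
outermost crossing is used, with a warning, if a flank is non-monotone); dome
area clips the outline polygon below the cutoff (shapely).  The coefficient
of variation uses the sample (n−1) standard deviation: the cohorts this is
designed for have K ≈ 11–12.

## Radial Fourier shape descriptors

The closed outline is expressed in polar coordinates about the centroid of
the closed junction set.  The apex-at-origin frame puts its origin *on* the
curve, where polar radius degenerates, so an interior center is required and
the centroid is the canonical choice.  The radius is treated as a periodic
function of normalized perimeter α (cumulative arc length / total perimeter
T) and expanded to N_f modes (default 200) by Riemann sums — not an FFT,
because junctions are unevenly spaced.  By default the piecewise-linear
profile r(t) is first resampled on a dense uniform perimeter grid (4096
points): raw sums on the irregular junction grid alias badly near their
Nyquist mode, producing spurious tens-of-percent "shape differences"
between identically shaped but differently sampled outlines, whereas the
resampled estimate stays faithful to the sampled profile at every retained
mode (sub-percent residual for identical shapes at cell-scale spacing; the
acceptance script reports the cohort index).  The raw
Δt_i-weighted sums on the junction points remain available
(``resample=None``; exact for uniform sampling).  Modes above half the
sample count are truncated.  Normalized profiles r̂ = r/c₀ have unit mean;
cohort means and
the reproducibility index S₂^½ are evaluated on a fixed 2048-point α grid by
the trapezoid rule, making them deterministic and refinement-testable.
S₂^½ is the plain RMS L2 deviation from the cohort mean profile; since r̂ is
dimensionless with unit mean, no further normalization is applied.

## Dome-curve fitting and model selection

The five families and their parameter counts k:

| family    | y(x)                          | k |
|-----------|-------------------------------|---|
| parabola  | a₁x²                          | 1 |
| catenary  | a₂cosh(x/a₂) − a₂             | 1 |
| ellipse   | b₃(1 − √(1 − (x/a₃)²))        | 2 |
| hyperbola | b₄(√(1 + (x/a₄)²) − 1)        | 2 |
| cosine    | −a₅cos(b₅x) + a₅              | 2 |

All are even with y(0) = 0 (apex anchored at the origin).  The ellipse is the
lower half re-anchored; outside |x| > a₃ a continuous linear penalty ramp
replaces the undefined square root so the least-squares objective stays
finite and continuous.  The hyperbola is the upward apex-at-origin branch,
chosen as the conic sharing evenness and apex anchoring with the other
candidates.  Fits use `scipy.optimize.least_squares` with a multistart grid
(catenary a ∈ {5, 10, …, 100}; log-spaced boxes scaled to the data extent for
the two-parameter families), pre-screened by raw SSE so only the best few
starts are polished; ties break toward the smaller parameter norm.  The
parabola is solved in closed form (linear least squares).

SSE is the unnormalized Σ of squared y-residuals.  AIC uses the Gaussian
profiled-likelihood form n·ln(SSE/n) + 2k; additive constants are identical
across families and cancel in ΔAIC, which is the quantity used (ΔAIC < 2
marks candidate best models).  Cross-validation repeats N random 99%/1%
splits (default N = 100, seeded; the test set rounds up to ≥ 1 point),
refitting on the training points warm-started from the full-data optimum and
averaging the held-out MSE.  With y-noise of variance σ² the expected
cv_mse ≈ σ²(1 + k/n), which the calibration test checks at σ = 1 µm.

The catenary-closest ellipse minimizes the mean squared vertical deviation
from a given catenary over |x| ≤ w (default w: the sample's fitted dome
half-width) on a 401-point grid, by a coarse log-grid search polished with
Nelder-Mead; candidates whose semi-axis fails to cover the window incur a
finite penalty.  By dimensional analysis the optimum scales linearly with the
catenary parameter when w does — the linearity of (a_ellipse, b_ellipse) in a
(R² > 0.999) is asserted rather than assumed.

The isometric collapse divides both coordinates by the fitted a and reports
the RMS deviation from Y = cosh X − 1 at the sample points.

## Synthetic outlines

The generator lays junctions along a chosen curve at arc-length steps drawn
from N(spacing, (jitter·spacing)²) (defaults 10 µm, 20% — cell-scale spacing
for root epidermis), symmetric about the apex, with both flank endpoints at
the dome height always included, then adds isotropic Gaussian positional
noise.  The symmetric placement makes the standardization an exact identity
for noiseless outlines, so exact-recovery tests are meaningful; positional
noise is what breaks bilateral symmetry in realistic cohorts.  Cohorts draw
the per-sample catenary parameter log-normally (positivity at CVs up to
~15%); class presets mirror the root classes analysed: primary roots
(mean a 45 µm, CV 14%), mature laterals (30 µm, 7.2%), emerged laterals
(30 µm, 8.5%), digitization noise 1 µm.  What the generator does *not*
emulate: root-cap sloughing artifacts, true biological asymmetries,
correlated digitization errors — so passing tests validate the pipeline's
statistics, not any claim about real tissue.

## The cell-vertex growth model

Cells are simple polygons sharing vertices and edges.  The energy is

E = Σ_cells (c/2)(Aₙ − A₀)²/A₀ + Σ_edges (β_ij/2)L_ij²,

with c = 1, β = 0.002 µm for horizontal and 0.004 µm for vertical edges
(orientation class fixed at edge creation and inherited on splits; division
interfaces get the class matching their geometry).  The area term is
normalized per cell size: the pressure ∂E/∂A = c(Aₙ−A₀)/A₀ is the relative
area strain.  We verified that the unnormalized alternative (c/2)(Aₙ−A₀)²
equilibrates every cell to the *same* absolute deficit regardless of size —
the tissue becomes a single pressure bag whose dome shape sits in neutral
soft modes, the 10,080 µm² overlay becomes effectively rigid, and growth
stalls; no dome-shape selection is possible in that regime.  With the
normalized form, wall tension and pressure share a scale, the β anisotropy
sets cell aspect ratios, and the overlay is naturally compliant in
proportion to its size.

Vertices obey overdamped dynamics dx/dt = −∂E/∂x with mobility constraints:
basal vertices slide on y = 0 (stiff parental xylem), the lateral extremes at
x = ±140 µm are fixed, everything else is free.  Equilibria are found either
by forward Euler with step-halving on energy increase (the dynamical
reference; a dt-halving regression test bounds its discretization influence
below 0.1 µm) or, by default, by L-BFGS-B on the same energy and analytic
gradient, which reaches the same equilibria (asserted in tests) orders of
magnitude faster given the stiffness ratio between area and wall terms.

Numerical limit worth knowing: the tissue has ultra-soft collective modes
(stiffness ~10⁻⁵).  Settling them to sub-nanometre needs force residuals
below what float64 energy comparisons can resolve (E ~ 10, so line searches
stagnate near ΔE ~ 10⁻¹⁵).  Snapshots taken immediately after a division
batch therefore carry a transient ~10⁻⁴ µm asymmetry even in the zero-noise
wild type; it decays below 10⁻⁶ µm within a few growth steps, and the
symmetry assertions distinguish settled states from division-adjacent ones.

### Growth program

The tissue starts as 20 cells (14 µm × 4 µm, A₀ = 56 µm²) spanning
x ∈ [−140, 140].  Wild-type roles: two central files, one flanking file per
side, the rest peripheral; an overlaying parental mass of thickness 36 µm
(A₀ = 36 × 20 × 14 = 10,080 µm²) presses from above until the apical surface
reaches 40 µm, when it is removed.  Growing cells increase A₀ linearly
(5.6 µm²/h; the provascular rate is 28 µm²/h); a cell divides when its
realized area reaches twice the target it was born with, with Gaussian
threshold noise (s.d. 5.6 µm²) drawn once at birth, through its centroid at
the program orientation plus 0.1° Gaussian plane noise.  Central files run
periclinal → anticlinal → periclinal (the four-layer stage; the alternative
two-periclinal reading of the third step is available via the
`central_program` config), then short-axis divisions until the central
lineage reaches the stage-VII count (default 32); each flanking file divides
periclinally once; peripheral files never divide.  Then the two central
basal cells switch to provascular expansion: rapid A₀ growth with their
vertical walls softening linearly from 0.002 to 0.0005 µm over the phase,
while continuing the same division cycle.  Divisions triggered in the same
growth step execute as one batch followed by a single relaxation; a cut
crossing within 10⁻⁷ µm of an existing vertex snaps to it, which is exactly
what happens when adjacent cells of a synchronous batch divide at the same
height and their interfaces meet on a shared wall.

Variants change one rule each: `shallow_gradient` / `shallower_gradient` add
2 / 3 extra single-division flanking files per side, `increasing_central_zone`
widens the central zone to 4 files, `randomized_division` draws central
division angles uniformly on [0, π), `no_overlay` omits the parental mass.

Dome outlines are the apical boundary chain (overlay excluded), trimmed to
the contiguous run around the apex rising more than 0.75 µm above the apron
plus one shoulder junction per side (mirroring how dome outlines are
delineated on micrographs, where the basal-most junctions at the dome foot
are included), flipped and passed through the standardization.  Dome height
h is the outline height; study tables bin it at {10, 30, 50} µm.

### Force decomposition

At equilibrium the load on each outline vertex (everything except its two
outline-edge tensions) is decomposed obliquely as F = W·ŷ + T·t̂ with t̂ the
local tangent: W = vertical load, T = tangential force.  For a
catenary-shaped dome under a vertical uniform load, W is uniform over the
loaded span and drops to zero outside it, while T vanishes at the apex by
symmetry and grows toward the periphery as the horizontal thrust divided by
cos θ.  The load CV is evaluated over the dividing zone (current x-extent of
central + flanking + provascular cells) intersected with the dome proper;
the inverse-cosine regression uses a 3-point running mean of the load along
the outline — a discrete-to-continuum estimate, since each interior wall
pulls at its own discrete angle and the raw per-vertex values alternate at
mesh scale.  In this concretization the inverse-cosine signature is strong
in clean, near-symmetric runs (R² > 0.95) but washes out in runs whose domes
lean, so the five-simulation aggregate typically lands at R² ≈ 0.5–0.9: the
uniform-load signature is robust, the tension signature is resolution-
limited at cell-scale outlines.

### Study configuration and problem sizes

`SimConfig()` holds the full-scale defaults above.  The analyses, tests and
the acceptance script run `SimConfig.reduced()`: stage-VII central target 24
instead of 32, provascular phase 8 h, stop height 52 µm — a full run takes
tens of seconds while exercising every stage of the program, and all
cross-variant comparisons are orderings at matched dome-height bins, which
are insensitive to this scale.  Five seeds per variant are used throughout.

## Known limitations

- No T1/T2 topological rearrangements: the tissue is purely proliferative.
- No turgor-based elasto-plastic wall extension; growth is encoded entirely
  in target-area increase.
- The wild-type and provascular growth rates are config defaults chosen for
  order-of-magnitude consistency with the division cadence; all reported
  comparisons are rate-insensitive orderings.
- Dome-shape conclusions are 2D (median section); no rotational 3D surface.
- The synthetic generator's noise model is isotropic and uncorrelated; real
  digitization noise is neither.
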