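# Methods

## Scope and input contract

The package consumes already-segmented, triangulated surfaces (STL/PLY) of
an aneurysm's outer wall and lumen, one pair per imaging session, in a
common patient frame with coordinates in centimetres, together with
acquisition times.  Image handling, segmentation and registration are out
of scope: co-registration of follow-up scans is a *precondition*.  The
loader only sanity-checks that consecutive scans' bounding boxes overlap by
more than 50% and warns otherwise.  Times are integer days since the
earliest scan; reporting helpers convert to years by dividing by 365.25.

Meshes are lightly repaired on load (degenerate faces dropped, duplicate
vertices merged, orientation fixed to positive signed volume) and must be
watertight afterwards; a failed mesh is rejected with its open-edge count.

## Geometry representation

**Centerline.**  At each of K evenly spaced axial levels the area centroid
of the constant-z cross-section (largest loop if the plane cuts several)
gives a raw station.  The transverse coordinates x(s), y(s) are smoothed by
least-squares projection onto a truncated Fourier basis (mean plus
`n_harmonics` sine/cosine pairs) in the normalised axial parameter
s ∈ [0, 1]; z is the parameter and is left untouched.  The default
`n_harmonics = 5` preserves sac-scale curvature while suppressing
slice-centroid jitter; it is a configuration knob because nothing in the
data pins it.  Smoothing is applied only to the transverse coordinates, the
same quantities the growth model later predicts.

**Station lattice.**  "Evenly spaced" is implemented as evenly spaced *in
z*: slicing planes are constant-z planes, which is the only reading
self-consistent with anchoring slice levels at the station coordinates
z_k.  Within one patient and layer the lattice is computed once over the z
range common to all of that layer's scans (shrunk by 2% of the range at
each end so every plane cuts every mesh strictly inside) and reused for
every scan, which is the minimal mechanism guaranteeing identical axes —
and hence one-to-one node correspondence — across imaging sessions.  The
grids of all scans share the same axis *objects*, making the
correspondence structural.

**Unwrapping.**  Each cross-section is chained from triangle–plane
intersection segments into closed loops (the loop whose centroid is nearest
the centerline point is kept, counter-clockwise orientation enforced),
resampled to N points uniform in arclength starting from the vertex with
smallest polar angle (reproducibility of the stored Cartesian slices), and
converted to polar samples (r, θ) about the station.  Radii are
interpolated onto the fixed angle axis θ_i = −π + 2πi/N by periodic linear
interpolation with ±2π sample augmentation — on a single slice this is what
natural-neighbour interpolation degenerates to in 1-D, and it is exactly
testable and seam-free at ±π by construction.

Two numerical choices matter here:

- *Grid radii come from the full chained contour*, not from the N
  arclength-resampled points.  The resampled points exist to give
  reproducible Cartesian slices S_k for evaluation; feeding the complete
  intersection polygon to the angular interpolation is strictly more
  information and avoids aliasing sub-lattice radial detail through the
  arclength reparameterization.
- *Star-shape handling*: each section is assumed star-shaped about its
  centerline point (r single-valued in θ).  A section whose unwrapped angle
  backtracks by more than one full turn triggers a warning and falls back
  to the outer envelope (maximum radius per lattice angle), which errs
  conservatively outward for an aneurysm wall.

The inverse map places node (k, i) at
(c_x,k + r_{k,i} cos θ_i, c_y,k + r_{k,i} sin θ_i, z_k).  Round-trip error
of forward-plus-inverse mapping is bounded by the angular chord length
2π·max r/N (≈0.15 cm at N=100 for a 4.6 cm sac) and is zero to machine
precision when slice samples coincide with grid nodes.

## Growth model

Per patient and layer, each response (centerline x, centerline y over K
stations; radius over K·N nodes) follows

    Y_tn = (α + b0_n) + (β + b1_n)·t + ε_tn,

with node-level random intercepts and slopes, diagonal random-effects
covariance, and i.i.d. Gaussian residuals.  Estimation is maximum
likelihood.  Because the lattice guarantees a balanced panel, all nodes
share one T×T marginal covariance V = σ₀²11ᵀ + σ₁²ttᵀ + σ_ε²I; the fixed
effects are profiled out by GLS against the node-mean trajectory and the
search runs over the three log-variances only (bounded L-BFGS-B, three
starts: method-of-moments from per-node OLS lines, equal split,
residual-dominated; objective tolerance 1e-10).  BLUPs follow as
b̂_n = D Xᵀ V⁻¹ (y_n − Xγ̂) with D = diag(σ̂₀², σ̂₁²).  This factorisation
fits the six models of a 100×100 patient in well under a second on one
core.

Numerical details:

- *Variance floor* 1e-12 (cm² or (cm/day)²) keeps V invertible at boundary
  solutions.  Zero-noise panels drive all components to the floor and the
  fit reproduces the observations to ~1e-8.
- *Time is raw days*, not standardised; slopes are reported per day and per
  year.  One consequence: the 2×2 BLUP shrinkage matrix is non-diagonal, so
  shrinkage holds for the node *trajectory* (‖X b̂_n‖ ≤ ‖X ĉ_n‖ for every
  node, with ĉ_n the per-node OLS deviation) rather than componentwise.
- *Two-scan patients*: with T=2 the marginal model is exactly saturated
  (three variance parameters, three empirical second moments), and
  σ̂_ε² = var(y_t0) − cov(y_t0, y_t1).  When node size and node growth are
  non-negatively correlated — which aneurysm growth data exhibit, and the
  synthetic generator reproduces — this lands on the variance floor and the
  fit interpolates both observed surfaces; forecasts from two scans are
  pure linear extrapolation and should be treated accordingly.
- Lumen and wall centerlines are fitted independently; no coherence between
  layers is enforced (a known limitation, see below).

Forecasts ŷ_n(t*) = (α̂+b̂0_n) + (β̂+b̂1_n)t* are affine in t*; forecast
radii are clamped below at 1e-9 cm before back-projection.  Forecasts more
than five years outside the training span log a warning but are not
refused.

## Evaluation

HD95 is the 95th percentile — linear interpolation between order
statistics, pinned for reproducibility — of the combined bidirectional
nearest-neighbour distance lists between forecast and ground-truth point
sets, computed in three spaces: centerline stations, the unwrapped
(r, θ, z) cloud, and the reconstructed Cartesian cloud.  The unwrapped
space deliberately mixes units (radians with cm), matching how the
representation is defined; a variant that rescales θ by the mean radius is
available behind a non-default flag.

Scalars are the maximum hydraulic diameter D_h = 4A/P over constant-z
sections (shoelace area, polyline perimeter) and the trapezoidal
integration of section area over z.  Both the forecast and the ground truth
pass through the same constant-z slice representation, so scalar errors
isolate the growth model rather than the parameterization.  Whether the
reference volume should be mesh-based or slice-based is not determined by
the problem; slice-based is used so both sides share a representation (the
test suite cross-checks slice integration against a mesh divergence-theorem
volume at the 1% level).

Cohort summaries are macro-averages: per-patient means over follow-ups
first, then the mean across patients, so scan count does not reweight
patients.  R² (1 − SS_res/SS_tot about the truth mean) and MAE of predicted
versus true scalars are computed across patient-follow-up pairs.

## Synthetic data generator

The generator emulates what the pipeline consumes from clinical imaging —
and is the package's test bed, since no clinical data can ship.  The wall
radius field on the lattice is

    r(z, θ, t) = r0 + (A0 + g·t)·exp(−(z−z0)²/2w²)·(1 + e·cos(θ−θ0))
                 + η_n + b_n·t + ε_nt,

a Gaussian axial bulge with cosine cross-sectional asymmetry: growth
concentrates near the maximum diameter and fades toward the necks.  Node
intercept deviations η_n ~ N(0, σ_node²), node slope deviations
b_n ~ N(0, σ_slope²) and observation noise ε ~ N(0, σ_obs²) mirror the
growth model's random-effects structure exactly.  The lumen is the wall
field minus a constant offset (floored at 0.3·r0; defaults keep the floor
inactive so lumen truth stays linear in time), with independent noise
draws.  The centerline drifts as x_c = δ·sin(πz/L)·t/t_last — linear in
time, hence inside the model class.

Defaults describe a surveillance-typical case: r0 = 1 cm, A0 = 1.25 cm
(≈4.5 cm baseline maximum diameter), g = 2.74e-4 cm/day (≈2 mm/yr diameter
growth at the apex), e = 0.25, δ = 0.15 cm, σ_node = 0.05 cm,
σ_slope = 2.5e-5 cm/day, σ_obs = 0.02 cm (the scale of CT segmentation
variability), four scans over 1540 days, K = N = 100.

Construction details chosen for exact oracles: meshes are swept and
triangulated with rings deliberately offset from the lattice station
levels (slicing planes never hit vertex rings), at three rings per station
interval and two vertices per lattice angle; the white-noise node fields
are extended piecewise-constant over their lattice cells, so parameterizing
a generated mesh on the generator's own lattice recovers each node's exact
draw up to sweep-triangulation chord error (≲1e-3 cm near the default
lattice resolution).  All draws are stored in the returned ground-truth
object, so downstream assertions are exact rather than statistical.

What the generator does **not** emulate: segmentation artefacts and
registration error, non-linear (e.g. staccato or exponential) growth,
axial remodeling, thrombus dynamics, branching anatomy, and irregular
scan spacing beyond what the configured times encode.  Passing tests on
synthetic data therefore demonstrate correctness of the pipeline and
estimator under the model's own assumptions — not clinical accuracy.

## Problem sizes used in checks

The automated checks run at deliberately scaled sizes chosen as the
smallest that still exercise each property: unit geometry tests use
analytic meshes; end-to-end fixtures use a 24×24 lattice; the round-trip
fidelity check runs at the default 100×100 lattice; the hold-out
forecasting experiment uses 10 patients at 50×50 (angular chord error
scales as 1/N and is accounted for in its bound); estimator recovery uses
G = 1000 nodes over 20 seeds; the throughput check fits the full
G = 10,000 lattice.

## Known limitations

- Axial (z-direction) deformation is not modelled; remodeling is assumed
  cross-sectional.
- Node random effects are spatially independent: no smoothness prior over
  (z, θ) and no lumen–wall coupling, so neighbouring nodes can disagree
  slightly where noise is large.
- Linear-in-time growth is an approximation valid over typical
  surveillance intervals; two-scan fits interpolate and extrapolate
  linearly with no curvature information.
- Sections must be star-shaped about the centerline; strongly lobulated
  sacs fall back to an outer-envelope approximation with a warning.
- Branch anatomy (beyond the iliac bifurcation) is out of scope; slices
  with multiple loops keep the loop nearest the centerline.
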