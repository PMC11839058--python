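# Methods

This note records the models, conventions and design choices behind
`myelindev`, in the package's own terms. All quantitative claims made here
are recomputed by the test suite and `scripts/acceptance.py`; none are
imported from elsewhere.

## T1w/T2w ratio and calibration

The myelin-sensitive map is the voxelwise quotient of a T1-weighted by a
co-registered T2-weighted volume. The division cancels the receive-coil
sensitivity profile and adds the two images' (mutually inverted)
myelin-related contrasts. Units are arbitrary and scanner-dependent, so
`calibrate_ratio` applies a two-point affine map anchored on a
low-intensity reference (ventricles) and a high-intensity one (corpus
callosum for humans, pons for macaques): the subject's reference means are
mapped exactly onto the group means. The affine form is the minimal
assumption that removes per-subject scale and offset; the ROI summary is
the mean. Division guards: any in-mask T2w voxel at or below `1e-6`
(native units) is an error naming the offending voxel count — silently
producing huge ratios would be worse than failing.

Absolute ratio levels are never compared across species; cross-species
analyses use baseline-adjusted trajectories (below).

## Equivolumetric depth

Cortical depth is divided into K compartments of equal tissue volume
(bin 1 = deepest, adjacent to white matter, everywhere in this package).
For a column whose cross-sectional area varies linearly from the white
surface area `A_w` to the pial area `A_p`, the geometric depth fraction at
cumulative volume fraction α has the closed form

    ρ(α) = (−A_w + sqrt((1−α) A_w² + α A_p²)) / (A_p − A_w),  ρ(α) = α when A_w = A_p.

`equivolume_rho` implements this; the tests check it against brute-force
numerical inversion of the cumulative volume integral (tolerance 1e−9).
Voxels are assigned bin k iff α ∈ [(k−1)/K, k/K), with α = 1 closed into
bin K. For phantom ribbons the exact per-voxel α is analytic (linear, r²,
or r³ interpolation for slab, annulus, shell). For general ribbons a
geometric depth coordinate is consumed as input and converted through the
column's area profile; recomputing a full Laplacian depth field is out of
scope. A 7-bin segmentation with the first and last bins removed (the
standard guard against white-matter and CSF partial-volume contamination)
leaves 5 analysis bins, which keep their original labels 2..6.

## Geodesic sensorimotor–association axis

The S-A axis is proxied by the minimum geodesic distance from seed
vertices in association (default-mode) parcels. Seed subsampling follows
the k-means recipe: seed-parcel vertices are clustered on 3-D coordinates
and 10% of the clusters are drawn at random, all member vertices becoming
sources. The cluster count is unstated in the underlying protocol; the
default `max(10, n_seed_vertices / 100)` keeps granularity
resolution-independent and is configurable. Distances are multi-source
Dijkstra over the mesh edge graph with Euclidean weights — an
approximation to exact polyhedral geodesics whose grid-mesh directional
bias is bounded in tests (edge-graph distance ≥ Euclidean; refinement
never increases it) rather than corrected. Parcels are ranked by mean
vertex distance (ties broken lexicographically by parcel label for
determinism) and split into equal thirds: nearest = association,
farthest = sensorimotor, remainders into the middle group.

## Trajectory model

Per unit (parcel, or parcel × depth bin):

    ratio = β₀ + β_sex · sex + f(age) + b_subject + ε,

with sex coded ±0.5, `f` a thin-plate regression spline of rank k = 3 and
`b_subject` optional random intercepts for longitudinal designs. The
basis follows the standard construction: radial kernel η(r) = r³/12 at
the unique observed ages, eigen-restricted to the three leading terms,
with the polynomial constraint absorbed so exactly one penalized
curvature coefficient remains beside the unpenalized {1, age} null space.
Constants and lines are therefore reproduced exactly at every smoothing
parameter — the conformance test for any admissible basis at this rank.
λ (and the subject ridge) are selected by restricted maximum likelihood,
profiled over σ² and optimized over log λ (bounded Brent, tolerance 1e−8;
Nelder–Mead when the subject variance adds a second parameter). The fit
matches `mgcv`'s REML thin-plate fit to ~1e−5 on shared data (dual-route
test in the suite).

The age effect is ΔR² between the full model and the nested model without
the age smooth (R² computed on fixed-effects fitted values, so subject
intercepts do not masquerade as age effects), signed by the mean fitted
first derivative over a 200-point age grid. Significance uses the
deviance (RSS) difference divided by the full model's residual scale
RSS/(n − edf). The reference degrees of freedom are the smooth's *maximal*
dimension (k − 1 = 2), not the data-chosen effective-df difference, and
the statistic is referred to an F distribution on (df, n − edf): because
REML selects λ adaptively, the effective-df chi-squared reference is
anticonservative (measured ≈ 0.09 rejection at nominal 0.05 under the
null, 200 parcels × 100 replicates at n = 50; mgcv's model-comparison
chi-squared measures ≈ 0.075), while the maximal-dimension F reference
restores nominal calibration (measured ≈ 0.047–0.050). The maximal
dimension is the space the penalized fit actually searches, and the F
form accounts for the estimated Gaussian scale. Multiplicity across
parcels is controlled by Benjamini–Hochberg within each analysis family.

## Derivative bands and plateaus

The first derivative of the fitted smooth is analytic (basis derivatives
times coefficients; a finite-difference cross-check at step 1e−4 is in
the tests). Uncertainty is propagated by posterior simulation: 10,000
coefficient draws from N(β̂, V_β) with V_β = σ̂²(XᵀX + S_λ)⁻¹; the
simultaneous 95% band is d̂ ± m*·se with m* the 95% quantile of the
maximum standardized deviation over the grid (m* ≥ the pointwise 1.96;
Monte-Carlo error on m* is below 1% at this draw count; the seed is
mandatory).

The plateau age is a terminal-state rule: the first grid age after the
*last* age at which the band lies entirely above zero (growth
significant). Units whose band never lies above zero are flagged
`no-growth` (plateaued at or before the window start — distinct from
`no-plateau`, where growth is still significant at the range end). The
rule is one-sided in the growth direction: a band ending significantly
*below* zero still ends growth. A two-sided variant (band contains zero
through the range end) is equivalent whenever the fitted derivative does
not overshoot, but a rank-3 smooth fitted to a trajectory that saturates
within the window systematically overshoots to a significantly negative
end-derivative — a basis artifact (the generating derivative is never
negative) that would erase every real plateau; the one-sided rule is
invariant to it while keeping the same specificity on strictly monotone
trajectories.

Group summaries report plateau proportions (denominator: all units; units
with FDR q > 0.05 are excluded from timing means and the one-way ANOVA
but kept in proportion denominators, with both counts reported) and
unweighted one-way ANOVAs of plateau timing. Degenerate ANOVAs (zero
within-group variance with a real between-group difference) return a
large finite F (1e12) with a warning instead of infinity.

## Cross-species comparison

Macaque development runs ≈ 4× faster than human; trajectories are
overlaid after multiplying macaque ages by the factor. Comparisons are
made on baseline-adjusted fitted trajectories — shifted to zero at a
species-specific reference age (defaults 1 y macaque / 4 y human; when
the nominal baseline precedes a fit's observed range the pipeline clips
it to the range start) — never on absolute levels.

`estimate_scaling` is a recovery harness for the compression factor. The
two observed windows overlap only partially (human 5.5–36 y vs macaque
1 mo–3 y ≈ 0.3–12 rescaled human years), which makes s only weakly
identifiable from rank-3 fits: the objective combines (i) a *windowed*
term — both species refit on the shared window so the smoothing bias is
common and cancels in the comparison — and (ii) a weighted (0.4)
*full-window* term that retains each species' global curvature and
suppresses a degenerate large-s alignment in which both windowed refits
collapse to near-linear curves. Both terms are mean-centered within the
window (the level-free analogue of baseline adjustment) and normalized by
pooled window signal variance; candidates leaving less than 5% of the
human range as overlap are rejected. The pipeline feeds group-averaged
trajectories (three S-A groups plus deepest/most superficial bins):
averaging ~20 parcels shrinks noise while the compression identity is
exact under averaging. The weight 0.4 was fixed from an insensitivity
scan (0.25–0.6 give the same median recovery) on ground-truth
simulations. Even so, a single cohort pair identifies s only coarsely;
the recovery study therefore reports the median over 20 replicates (the
acceptance quantity) together with the per-replicate in-band fraction.

## Synthetic cortex

The generator emulates exactly what the pipeline consumes: phantom
ribbons with analytically known equivolume boundaries, labeled grid
meshes, and cohort tables following saturating growth

    μ(age) = baseline + amplitude · (1 − exp(−rate · (age − t₀)₊)),

a fixture choice (the simplest monotone curve with a well-defined
plateau), not a biological claim. Ground-truth plateau onset is the age
where the derivative falls below 1% of its initial value, i.e.
t₀ + ln(100)/rate. Defaults: baseline 1.2, amplitude 0.6, noise SD 0.06
(10% of amplitude), sex contrast +0.05 (coded ±0.5), subject-intercept
SD 0.05; human arm 150 cross-sectional subjects uniform on 5.5–36 y;
macaque arm 34 subjects × 5 longitudinal sessions on 1/12–3 y with a 4×
time compression (the macaque mean curve at age a equals the human curve
at 4a, exactly, including the origin t₀/4). Axis structure: per-parcel
plateau onsets increase linearly from 10 to 30 y along the synthetic S-A
axis; depth structure: rate multipliers 1.1→0.9 and amplitude multipliers
1.5→0.65 from the deepest to the most superficial of 5 bins, plus a
baseline gradient +0.15→−0.15 (deep cortex brighter).

The growth origin t₀ matters more than it looks. `growth_curve` itself
uses t₀ = 0 (growth from birth), and the generator's default follows it.
But with growth from birth, a faster-growing unit has largely finished
*before* the observed window opens, so its observed mean slope is
*smaller* — inverting the joint structure the pipeline is meant to
recover (fast units both steeper in-window and earlier to plateau, deep
bins steeper and faster). The pipeline's default study conditions
therefore set t₀ = 5.5 y (the human window start; curves are flat at
baseline before it), under which the depth ordering (amplitude-driven,
large contrasts) and the plateau ordering along the axis are both
recovered essentially perfectly. The parcel-level slope-vs-axis relation
is the exception: once every parcel saturates within the window, true
mean-slope differences along the axis are tiny, and the estimated
relation is dominated by the stiff fit's boundary bias (sharply-rising
parcels are under-estimated); its R² is reported but its sign should not
be read as generative structure. One consequence is deliberately
asymmetric realism: the
macaque arm (origin 1.375 y) is flat over its first ~1.3 observed years,
whereas real macaque ratios grow steeply from birth; the harness
prioritizes an exact cross-species identity over early-infancy realism.

What the generator does *not* emulate: realistic MRI intensities, bias
fields, motion, scanner noise spectra, folded (gyrified) surfaces,
non-Gaussian noise, spatially correlated noise across parcels, or
sigmoidal/multiphase growth. Passing tests therefore demonstrate that the
pipeline recovers known structure under its own model family and honest
noise — not that the same accuracy holds on real MRI data.

## Numerical choices and degenerate inputs

- REML: log λ bounded in [−15, 25]; Brent tolerance 1e−8; two-parameter
  case Nelder–Mead (xatol 1e−6, fatol 1e−9, 400 iterations, error on
  non-convergence). Knots: unique ages, quantile-thinned above 200.
- Perfect (noise-free) fits have zero residual scale; the age-effect test
  then returns p = 0 for any positive deviance difference and p = 1 for
  none, instead of dividing by zero.
- Rank ties in the axis break lexicographically by parcel label; group
  remainders go to the middle group (133/134/133 at 400 parcels).
- Empty (parcel, bin) cells appear as rows with `n_voxels = 0` and NaN
  mean, never silently dropped; downstream fits skip them.
- Problem sizes in the validation studies (200 parcels × 100 replicates
  for calibration, 100 replicates for plateau recovery, 20 for scaling,
  60-parcel cortex end-to-end) were chosen to give stable Monte-Carlo
  estimates of each rate while keeping the full suite comfortably
  rerunnable on a laptop.

## Known limitations

- The edge-graph geodesic overestimates off-axis distances on regular
  meshes (bounded by the tests, not corrected); parcel means inherit a
  small bias that cancels in rank-based analyses.
- At k = 3 the smooth cannot localize a mid-window plateau sharply; the
  detected plateau age is a band-crossing point whose bias grows with
  noise. Recovery is validated as a rate (±15% of the range width), not
  as an unbiased estimator.
- The species-scaling factor is weakly identified from a single cohort
  pair under the realistic window overlap; only the replicate median is
  a stable estimate.
- Real-data mode ingests a prepared subject × parcel × depth profile
  table plus a labeled mesh; volume-level extraction for whole cohorts
  (per-subject NIfTI pairs) is exposed as library functions but not
  orchestrated by the pipeline.
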