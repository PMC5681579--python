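# Methods

## The inverse problem

An electroantennogram (EAG) is an extracellular field potential summing the
transmembrane currents of olfactory receptor neurons (ORNs) near the
recording electrode. Because a field potential spreads, an EAG recorded at
one position mixes contributions from the whole antenna; recording at
several positions and inverting a volume-conductor model disentangles them.

`olfactomap` treats the funiculus (the third antennal segment) as an
elliptic cylinder whose lateral surface is virtually unfolded into a plane.
This rests on the observation that the EAG amplitude collapses once the
electrode breaks through the cuticle, so conduction through the interior is
neglected and all current flows on the surface. A point source I_c in a
medium of conductivity σ produces φ = I_c/(4πσr) at distance r. Current
sources are assumed piecewise-constant over N rectangular compartments
(one per electrode), each spanning the full unfolded circumference
(half-extent q = half the cross-section circumference) and a proximo-distal
slab around its electrode. The potential at electrode x_j (on the lateral
midline, y = 0) due to unit source density in compartment i is

    F_ij = 1/(4πσ) ∫_{−q}^{q} ∫_{x_lo,i}^{x_hi,i} dx dy / √((x−x_j)² + y²)

Interior compartments span [x_i − h/2, x_i + h/2] with h the electrode
spacing; the two end compartments are half-width ([x_1, x_1 + h/2] and
[x_N − h/2, x_N]) because no ORNs lie proximal to the arista electrode or
distal to the tip electrode. The cross-section circumference uses
Ramanujan's first ellipse-perimeter approximation
π(3(a+b) − √((3a+b)(a+3b))) with a, b the half-width and half-thickness;
its relative error is < 2.2 × 10⁻⁴ for aspect ratios down to 1:5, far
below measurement precision. With N electrodes and N compartments the
system φ = F·C is square and solved exactly at every time sample:
C = F⁻¹·φ. No regularization is applied; condition numbers for realistic
geometries are ~5, and the solver refuses systems with condition number
≥ 10⁸.

The double integral has the closed-form corner antiderivative
H(u, v) = u·asinh(v/|u|) + v·asinh(u/|v|), which is finite when the
electrode lies inside or on its source rectangle (the 1/r singularity is
integrable in 2D) and numerically stable — the asinh form avoids the
catastrophic cancellation of the log form near u + r → 0. Test code
cross-checks every entry against an independent midpoint Riemann sum with
polar integration of the singular cell.

A note on q: the half-extent is defined as the half-circumference and the
integral runs over [−q, q], i.e. the rectangle width equals the full
circumference. The choice is immaterial for every reported quantity —
barycenters and area ratios are invariant to any common rescaling of F —
but it fixes the absolute scale of source-density units.

## Signal processing

Following standard EAG practice: traces are smoothed with a zero-phase
Gaussian kernel (σ = 20 ms at 500 Hz, truncated at ±4σ, unit area, reflect
padding so the baseline windows see no edge ramps), and the solvent-control
response is subtracted (mean of the two control runs when both exist).
"Width" of the smoothing kernel is interpreted as its standard deviation;
the parameter is exposed for users who read it as FWHM. Smoothing and
control subtraction are linear and commute, so their order is immaterial.

The signed response amplitude is min over (onset, onset + 0.5 s] minus the
mean over [onset − 0.5 s, onset); it is negative for canonical odor-evoked
deflections and invariant to DC offsets. The antenna-level absolute
response amplitude is the largest magnitude across electrode positions,
which avoids biasing single-position EAGs toward the nearest ORNs. For
between-individual comparisons of response patterns, per-odorant amplitudes
are normalized by their sum over the odor panel.

CSD response areas integrate each compartment's source over
(onset, onset + 1.5 s] by the trapezoidal rule on the recording's own time
base, sign-flipped once so activation is positive. The spatial barycenter
is the activation-weighted mean electrode position, with weights
max(area, 0): compartments showing net suppression do not pull the
barycenter (an all-non-positive pattern raises "no detectable activation"
rather than returning a meaningless position). Whether to rectify or
positive-part the areas was an open choice; positive-part weighting was
selected because suppression carries no localization information under
this model. The CSD inversion runs on smoothed, control-subtracted traces
for consistency with the amplitude pipeline.

## Sensilla maps

Sensilla annotated on the lateral funiculus face live in normalized
coordinates (x proximo-distal, y ventro-dorsal, both [0, 1]). Density maps
place a unit-mass 2D Gaussian on each sensillum (σx = 0.02 of the length,
σy = 0.05 of the width, truncated at ±4σ and clipped at the map boundary
without renormalization, so border sensilla lose mass — a deliberate match
to how such maps are usually drawn). The default lattice is 200 × 100
cells; dominance profiles shift by < 1% between 200 and 400 x-bins.

The sensilla dominance index (D_b + D_c − D_t)/(D_b + D_c + D_t) uses the
y-averaged density of basiconic (b), clavate (c) and trichoid (t) sensilla
at each x bin: +1 where only food-odor sensilla (basiconic + clavate)
occur, −1 where only trichoid. Bins with no sensilla of the three types
are NaN (undefined), never 0. Averaging vs summing over y does not change
the index (it is scale-invariant at fixed x) and only affects exported
density values.

Count summaries report, per individual and aggregated (mean ± SD), counts
per morphotype, the basiconic+clavate sum, the total, per-mm² densities
when a face area is supplied (counts never require one), and the
(b+c)/t ratio in both conventions — mean of per-individual ratios (the
convention used in published per-species tables) and ratio of means —
explicitly labelled, because the two differ.

## Between-species statistics

The distance ratio is the mean Euclidean distance between all cross-group
pairs of individuals divided by the mean over all within-group pairs,
pooled from both groups (pooling weights each pair equally; a per-group
average is a one-line variant). Features are either per-odorant CSD
barycenters or per-odorant normalized absolute amplitudes. The ratio is
invariant under rigid motions of feature space and increases monotonically
with group separation.

The test against ratio = 1 is a bootstrap. Two schemes are implemented:

- **pooled-null (default).** Following the standard prescription for
  bootstrap hypothesis tests — resample in a way that imposes the null —
  both pseudo-groups are drawn with replacement from the pooled
  individuals and the ratio recomputed; p = (1 + #{r* ≥ r_obs})/(B + 1),
  one-sided for ratio > 1. Measured on same-distribution groups
  (10 individuals each, 7 features): rejection at α = 0.05 of
  0.04–0.06, tail probabilities calibrated to the third decimal, residual
  mid-range deviation of the p-value distribution from uniform ≈ 0.04 (KS,
  10 000 simulations).
- **percentile.** Resample with replacement within each group and invert
  the percentile interval: p = (1 + #{r* ≤ 1})/(B + 1). Retained for
  comparison; it is markedly conservative at small n (the bootstrap spread
  of the ratio exceeds its sampling spread by ~1.5× at n = 10), so it is
  not the default.

In both schemes, resampled pairs consisting of two copies of the same
original individual are excluded from the pair means: their distance is
identically zero and would deflate the within mean (the naive plug-in
variant, available as `count_duplicate_pairs=True`, rejects a true null
~97% of the time — a trap worth documenting). Default B = 10 000.
p-values are reported raw; no correction across species pairs is applied.

LDA (eigen solver; a small ridge engages when the within-class scatter is
singular) and PCA of dominance profiles are thin wrappers over
scikit-learn; bespoke validation is limited to contract tests (separation
of well-separated clouds, rank-1 recovery, explained-variance algebra).

## Synthetic data

The generator emulates the study conditions end to end so that every
pipeline stage is testable without external recordings:

- **Geometry** default 0.6 × 0.3 × 0.25 mm (length × width × thickness), a
  plausible mid-sized tephritid funiculus; these are synthetic values, as
  are all generator defaults below.
- **Sources.** A Gaussian activation bump (center on [0, 1], σ = 0.08
  normalized) integrated per compartment, normalized so Σ|C_i| equals the
  amplitude, negative by the activation convention.
- **Transient.** Difference of exponentials, τ_rise = 50 ms,
  τ_decay = 400 ms, normalized to unit continuous-time peak — the response
  decays substantially within the 1.5-s integration window, as real EAG
  transients do.
- **Recording.** φ(t) = F·C·k(t) scaled to a 1 mV peak deflection, plus
  white Gaussian noise (default SD 0.05 mV, i.e. SNR 20; the noise model
  is a simplification — real EAGs carry drift and pink components, and a
  pink-noise option exists but is off by default). A noise-only control
  recording and the ground truth (scaled C, barycenter) always accompany
  the data. 3 s at 500 Hz, onset at 1 s, 200-ms stimulus.
- **Cohorts.** 10 individuals per species over a 7-odorant panel with
  activation centers spread over [0.15, 0.9]; inter-individual jitter:
  center shift SD 0.03 normalized units, amplitude SD 10% relative.
- **Sensilla.** Inhomogeneous Poisson patterns by thinning; defaults
  encode the qualitative gradients of real funiculi — trichoid absent
  proximally (intensity ∝ max(0, x − 0.15)) with a ventral tilt, clavate
  clustered ventro-proximally, basiconic broad with depressed borders,
  coeloconic uniform. Expected counts 450/300/150/180 (t/b/c/co) on the
  scale of a mid-sized tephritid.

Everything is driven by a single seed through `numpy.random.Generator` and
`SeedSequence.spawn`, making all outputs byte-identical across runs.

What passing tests on these data do **not** show: robustness to real-world
violations of the model — non-elliptic cross-sections, conductivity
inhomogeneity, electrode placement error, correlated noise, or ORN
adaptation across the stimulus sequence. The synthetic cohorts share the
forward model with the analysis, so recovery tests validate the inverse
algebra and the pipeline plumbing, not the biophysical adequacy of the
surface-conduction model itself.

## Numerical choices and degenerate inputs

- Forward solve: `numpy.linalg.solve` per time block; refusal above
  condition number 10⁸.
- Electrode layouts must be evenly spaced with endpoints 0 and 1 (the
  compartment construction assumes one spacing h); N ≥ 2.
- Trapezoidal integration for areas; the 1.5-s window must fit in the
  recording.
- Barycenter of an all-suppressed response, dominance index of an empty
  bin, (b+c)/t with zero trichoids, and the distance ratio of coincident
  point sets are all *undefined* (error or NaN), never silently 0.
- Bootstrap replicates with no usable pair (all draws identical) are
  dropped from the p-value denominator.
- Problem sizes used in the shipped checks — 1000 round-trip vectors, 20
  random geometries for the quadrature cross-check, 100 individuals for
  noisy-recovery RMSE, 1000 null pairs × 2000 replicates for calibration —
  keep the full suite in the low minutes on one core while leaving the
  statistical assertions sharp.

## Known limitations

- The planar unfolded model ignores circumferential wrap-around; distances
  are Euclidean in the unfolded plane, consistent with the forward
  integral above.
- σ is an opaque positive scalar (default 10). Absolute source units
  depend on it (and on the q convention); all barycenters, ratios and
  projections are σ-invariant.
- The square N×N system cannot resolve structure finer than the electrode
  spacing; non-square layouts and regularized inverses are out of scope.
- Geometry is user-supplied per species; no estimation from images.
- Coeloconic sensilla counts in real annotations are typically
  underestimated (small sensilla hide); no correction is attempted.
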