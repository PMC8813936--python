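# Methods

`cyclim` models the computational chain of a cyclic immunofluorescence
(stain–image–erase) experiment: a simulator that renders raw multi-exposure
camera frames from a known ground truth, the corrections that turn raw
frames into artifact-free intensity-rate images, the mask/background/
quantification recipes of image cytometry, and the statistics used to
compare populations across instruments. This note records the models, the
parameter choices, and the places where the design was genuinely open.

## Camera and acquisition model

A frame acquired at exposure `t` (ms) records, per pixel,

    counts = offset + gain · t · flatfield · rate + N(0, σ_read),

rounded, clipped to `[0, saturation_level]`. `rate` is the true
photon-equivalent intensity rate. Defaults are `offset = 100` counts,
`σ_read = 2` counts, `gain = 1`, 16-bit saturation at 65535 — invented but
typical sCMOS-scale numbers, all user-configurable (`NoiseModel`). Noise is
additive Gaussian read noise only; a shot-noise (signal-dependent variance)
term is deliberately out of the default model, since the correction
pipeline's weighting is derived under the read-noise model. Hot pixels
render at saturation and cold pixels at zero, at fixed sensor positions
drawn once from `sensor_seed`, mimicking real defective-pixel maps.

Spectral crosstalk is linear: observed channel rates are `M ·` true
fluorophore rates for a square calibrated matrix `M` with positive
diagonal. Autofluorescence and scene background add per observation
channel, *after* mixing — they are channel-intrinsic light, not fluorophore
signals. Consequence: unmixing alone leaves a residue `M⁻¹·af` in every
channel; it is the pre-stain subtraction (both images unmixed with the same
matrix) that removes autofluorescence exactly. Whether to subtract before
or after unmixing is not forced by the model; subtraction after unmixing is
the default and the order is a config choice.

Erasure between cycles leaves a residual fraction (default 0.10, i.e. the
guaranteed ≥ 90% reduction boundary) of each prior stain, compounding
multiplicatively over cycles. Inter-cycle stage drift is a per-cycle
subpixel shift applied to the truth field by linear interpolation before
noise.

## Synthetic scenes

Two benchmark preparations are generated:

- **Bead fields** (`make_bead_scene`): disks of radius 40 px (area
  ≈ 5000 px², matching the mask recipe's area window) whose labeled-epitope
  count is `Binomial(saturating_sites, labeled_fraction)` — the
  stoichiometric titration of fluorescent vs. dark antibody. Beads emit a
  weak uniform autofluorescence (rate 0.05) in the nuclear-reference
  channel, from which masks are built independently of the measured stain.
- **PBMC-like fields** (`make_cell_scene`): every cell carries a
  pan-leukocyte marker for masking; a configurable fraction are positive
  for a titrated marker with 57,000 copies per positive cell, the measured
  average CD3 abundance per T cell, so 10% labeling yields an expected
  5,700 labeled epitopes.

An object with count `N` emits a uniform rate density `N·r_e/area` inside
its disk (`r_e = rate_per_epitope`), so a perfectly corrected,
background-subtracted integral equals `N·r_e` — the linearity that
quantification must recover. Objects are placed by rejection sampling with
a minimum edge-to-edge separation (default 40 px) and a 20 px border
margin: the local-threshold window (radius 15) of one object's edge band
must not see a neighbour or a reflected frame border. This emulates a
well-dispersed preparation; densely clumped fields are *not* what the
generator's defaults produce, and segmentation counts on clumped data
would depend on the watershed in ways these defaults do not probe.

What the simulator does not model: optical PSF blur, photobleaching during
acquisition (< 5% in practice), 3-D structure, non-disk morphologies, and
spatially structured autofluorescence. Tests passing on these scenes
validate the *chain's arithmetic and recipes*, not robustness to every
real-tissue artifact.

## HDR exposure fusion

Each unsaturated frame gives the rate estimate `(counts − offset)/t` with
read-noise variance `σ_read²/t²`. Frames at or above
`0.98 · saturation_level` (margin for clipping nonlinearity near full
well) are excluded per pixel; the rest combine by inverse-variance
weighting — the minimum-variance unbiased combination under the Gaussian
model, equivalent to weights ∝ t². Output variance is `1/Σ(1/varᵢ)`.
Pixels saturated in every frame are flagged, assigned the
shortest-exposure estimate, and carry an infinite-variance sentinel. The
fusion is invariant to appending a fully saturated frame.

## Correction pipeline

Flatfield division, median-window outlier repair (repair iff
`|value − window median| > k·σ`, default 3×3 window and k = 5),
cross-correlation registration with subpixel refinement (nuclear-channel
shift applied to all channels of a cycle; the returned shift is what
`ndimage.shift` needs to map moving onto reference), feathered-overlap
stitching, anti-aliased decimation (block mean for integer factors —
exactly mean-preserving — Gaussian low-pass plus resampling otherwise),
matrix-inverse unmixing (negatives preserved; condition-number guard,
default bound 1e6), and pre-stain subtraction (negatives preserved).
Nothing in quantification or subtraction clips at zero: the width of the
blank distribution downstream must remain an unbiased noise-floor
estimate. An optional radial-polynomial distortion correction (identity by
default) runs before registration; no default coefficients are shipped.

## Mask recipe

The exact order: readout subtraction → Gaussian blur (σ = 3 px) → local
median threshold (disk radius 15 px) → disk dilation (radius 2 px) → hole
filling → optional distance-transform watershed → connected-component
labeling → filter to area strictly between 4000 and 12,000 px² and
circularity strictly above 0.1. Cell mode omits the watershed and allows
areas up to 15,000 px².

Numerical choices worth knowing:

- The threshold is *strictly greater*: foreground iff
  `value > local median + C`. With `≥`, any constant region (e.g. a
  noiseless background, where the median equals the value) would become
  foreground wholesale. `C` is the classic local-threshold offset, default
  0; on noiseless synthetic fields a small positive `C` (~10% of the
  object level) plays the role the camera noise floor plays on real data.
  Note the window median tracks a locally linear edge ramp, so the
  detectable band contrast peaks at only ~16% of the object level — `C`
  must stay well below that.
- On a flat-topped object the rule detects only the edge band; hole
  filling is what produces the solid mask. The final mask is therefore a
  few pixels wider than the true object (blur + dilation), which is why a
  radius-24 disk (true area 1810 px²) still stays safely under the
  4000 px² floor.
- Watershed: negated Euclidean distance transform with peak markers at
  local maxima (min separation 10 px) of a lightly smoothed (σ = 2)
  distance map — raster plateaus of near-circular objects otherwise spawn
  several spurious peaks per object.
- Circularity is `4πA/P²` capped at 1.0, with `P` a marching-squares
  contour length (diagonal steps weighted √2). Crossing-count perimeter
  estimators halve the perimeter of 1-px-wide structures and would let
  thin debris through the 0.1 gate.

## Background estimation and quantification

The filled pre-filter mask (before the area gate) is dilated by a disk of
radius 17 px and inverted; the image is tiled into non-overlapping
400 × 400 px quadrants (`⌈H/400⌉ × ⌈W/400⌉`; edge quadrants are smaller
and contribute nodes at their true centers); each quadrant with at least
20 usable pixels contributes the median of its non-excluded pixels as a
node; the full-frame surface is piecewise-cubic (Clough–Tocher) through
the nodes, nearest-node outside their convex hull. Clough–Tocher
reproduces affine surfaces exactly, so constant and ramp backgrounds come
back to raster tolerance. The 20-pixel floor guards nearly-fully-masked
quadrants and is our addition. Per-object integrals are
`Σ (image − background)` over the label; MFI is the integral over the
area; negatives everywhere preserved.

## Cytometry statistics

- **Stoichiometric expectation**: `(percentage/100) · copy_number`, with an
  optional 2-significant-figure rounding that reproduces printed titration
  tables (33% of 57,000 → 19,000).
- **Arcsinh scale**: `y = arcsinh(aI − b)/ln 10`, log₁₀-asymptotic, defined
  for negative intensities. `(a, b)` solve `mean(y_blank) = 0`,
  `mean(y_top) = 2` by a damped Newton iteration (numerical Jacobian,
  step-halving line search, residuals < 1e−9; the initial guess uses the
  linear limit for the blank and the logarithmic limit for the top
  population). Fitted independently per dataset.
- **Two-Gaussian fit**: 1-D EM initialized at the 25th/75th percentiles
  with equal weights, convergence at ΔlogL < 1e−8 or 500 iterations,
  up to 5 jittered restarts on component collapse, components ordered by
  mean. A histogram least-squares mode (`fit_two_gaussians_hist`) is
  provided for parity with fitting published histograms. The separation is
  `s = |μ₂−μ₁|/√(σ₁²+σ₂²)`.
- **Resolvability floor**: for an equal-weight mixture the component width
  below `s ≈ 1` is identified only through the fourth moment, whose
  sampling noise at n = 10⁴ exceeds the mixture's excess kurtosis
  (≈ −0.03 at s = 0.5). The intrinsic median relative error of *any*
  two-Gaussian fit at s = 0.5, n = 10⁴ is ~20% — this is a property of
  the estimation problem, consistent with published fits reporting no
  separation below s ≈ 1.3. Recovery assertions therefore hold tightly in
  the resolvable regime and only in aggregate when sub-floor separations
  are included.
- **Blank width**: standard deviation by default; Gaussian-consistent MAD
  (`width="mad"`) as the robust option. The ratio of two instruments'
  blank widths is their relative sensitivity to weak signals.
- **Linearity**: least squares of log₁₀(mean intensity) on log₁₀(labeled
  fraction); levels with nonpositive means are excluded with a warning,
  at least three usable levels required.

## Single-cell analysis

Features are per-cell background-subtracted MFIs, min–max scaled to [0, 1]
per marker before clustering (constant markers map to 0; optional
percentile clipping first). k-means (default k = 40, k-means++ with 10
restarts, seeded) and Ward agglomerative clustering on Euclidean distances
(default k = 20; linkage configurable — Ward is the conventional choice
for expression heatmaps) both emit per-cluster mean profiles. Cluster
group labels (B / T / non-B-non-T / unassigned) come from an *ordered*
rule list on cluster means — first match wins; thresholds are user
configuration since published per-marker cutoffs are not available.
Sequential gating intersects interval predicates in order and reports
per-step survivor counts; Pearson co-expression uses the exact
t-distribution p-value with n − 2 df and is affine-invariant, so raw vs.
scaled MFIs give identical r.

## Problem sizes used in the tests

Scenes of 384–896 px square with 2–16 objects, titration series of six
levels across five decades (10⁷ saturable sites per bead keep binomial
noise ≪ the 0.02 slope tolerance), mixture fits at n = 10⁴ with 20
replicates per separation, correlation samples at n = 5000. These sizes
make every statistical tolerance comfortably resolvable while keeping the
full suite around a minute of compute.

## Known limitations

The HDR weighting is exact only under pure read noise; with strong shot
noise the weights are no longer optimal (still unbiased). The stitcher
refines offsets against the first tile only, which is adequate for strips
but not for large grids with loop-closure error. The watershed marker
heuristic can under-split elongated fused clumps. The background
estimator assumes the background varies smoothly on the quadrant scale;
structured background below that scale is absorbed into object integrals.
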