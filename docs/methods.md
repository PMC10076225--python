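# Methods

This note documents the models, parameter choices and numerical conventions
behind `axotrace`, and what the synthetic benchmarks do and do not
demonstrate about real recordings.

## Coordinate and data conventions

Image arrays are indexed `[row, col]` with the origin at the top-left; the
*y* (height) component of a position is its row index, increasing downward
(matching the top-to-bottom scan of the microscope).  The geometry code in
`axotrace.separation` works in `(x, y) = (col, row)` vectors; conversion
happens at that module's boundary.  A recording is a pair of `(T, H, W)`
non-negative float arrays (green = GCaMP, red = tdTomato) plus a frame rate
in frames/s.  The two channels are assumed acquired on a common intensity
scale, as for gain-balanced detector channels.

## Synthetic recordings

The generator emulates coronal-section two-photon data of an axon bundle:

* **Geometry** — each axon cross-section is an elliptical 2-D Gaussian
  density, unit peak, rendered by midpoint integration on a 2×-oversampled
  pixel grid.  Default semi-axes are drawn uniformly from 1.8–3.2 px,
  giving mask areas of roughly 30–80 px at the 20 %-of-peak ground-truth
  cutoff — a scale consistent with a detector whose minimum meaningful
  region is 11 px.  Axons are placed with a minimum separation of five
  maximal semi-axes so that "well-separated" test conditions hold.
* **Red channel** — a static per-axon tdTomato level drawn uniformly from
  0.5–1.0 (the marker is expressed brightly).
* **Green channel** — per axon, Poisson spikes (default 1.0 events/s, drawn
  by inverse CDF so that raising the rate at a fixed seed never removes a
  spike) are convolved with a calcium response kernel and scaled by
  `gcamp_amplitude` (default 0.05 per unit trace).  With these defaults
  typical GCaMP transients stay below the tdTomato level on the common
  intensity scale, so segmentation geometry is anatomy-driven — the
  realistic regime for a bright structural marker with detector gain set to
  avoid clipping.  Trace recovery is measured by correlation and is
  amplitude-independent.
* **Calcium kernel** — difference of exponentials `exp(−λ_d t) − exp(−λ_r t)`
  normalized to unit peak, with decay rate λ_d = ln 2 / half-life
  (default 0.95 s) and λ_r solved numerically so the peak occurs at the
  rise time (default 0.1415 s).  Interpreting "rise time" as time-to-peak
  makes the tail a clean half-life decay within a few samples of the peak.
* **Movement artifacts** — each frame receives an independent random affine:
  translation within ±10 % of the frame, rotation within ±5°, scaling
  within ±5 %, all multiplied by `artifact_magnitude`.  Because an affine
  image of a Gaussian is exactly a Gaussian, the deformation is applied to
  the (center, covariance) parameters and the frame re-rendered — no
  interpolation artifacts, and the ground-truth masks stay exact.  An
  optional coarse elastic warp (3rd-order spline of a 4×4 random control
  grid) is off by default.
* **Noise** — per-pixel Poisson shot noise at 200 photons per unit
  intensity followed by additive Gaussian read noise (σ = 0.02), clipped
  at zero, applied last.

All randomness flows from one seed through four independent child streams
(geometry, spikes, deformation, noise), so conditions can be varied one at
a time while the rest stays bit-identical.

**What the generator does not emulate:** photobleaching, z-drift,
occlusion, episodic (bout-structured) movement, scan-line artifacts, or a
realistic optical PSF.  Passing the synthetic benchmarks therefore shows
the pipeline's algorithmic correctness and its robustness to frame-wise
affine deformation and Poisson/Gaussian noise — not performance on every
failure mode of real microscopy.

## Detection

The classical per-frame segmentation: non-local-means denoising of each
channel as a 3-D (T, H, W) volume with temporal search radius 2 frames
(a 5-frame window) and filter strength 11 on a 0–255 intensity scale;
grayscale as the per-pixel channel maximum; per-frame min–max normalization
to [0, 1]; Gaussian smoothing σ = 2 px; per-frame Otsu threshold; one
binary erosion with the 3×3 cross; removal of components below 11 px.
Components use 8-connectivity throughout (diagonal neighbors connect).
An all-constant frame leaves Otsu undefined: the frame yields an empty mask
with a warning.

Two known behaviors of this pipeline, measured on noiseless synthetic data:

* it *under-segments* relative to the 20 %-of-peak truth convention
  (a single global threshold sits at a larger fraction of a dim axon's
  peak), giving Dice ≈ 0.85–0.90 rather than 1;
* the pixel-count **area** of a detected ROI fluctuates by ±1–2 px under
  sub-pixel geometric deformation — an irreducible quantization effect of
  counting threshold-contour pixels (about 0.25·√perimeter for these blob
  sizes).  This matters for tracking; see below.

The fine-tune branch clusters self-similar frames with OPTICS
(min_samples = 20) on the negative cross-correlation of mean/sd-normalized
red frames.  OPTICS needs non-negative distances, so the matrix is shifted
by its smallest off-diagonal entry (rank order unchanged); the maximum
neighborhood distance is half the largest shifted pairwise distance.  The
cluster with the highest mean pairwise cross-correlation wins.  Its
temporal average (smoothed with a σ = 1 px Gaussian and a 3×3 median per
channel only when the cluster holds < 50 frames) is thresholded locally —
foreground where a pixel exceeds the Gaussian-weighted mean of its 25×25
neighborhood by 0.05 on the [0, 1] grayscale — and min-size-filtered,
giving both the tracker-initialization segmentation and the parent mask
for ROI separation.

## Tracking

Costs are exactly the nested form described in the README.  Numerical
conventions that the equations leave open:

* angles of displacement vectors come from the two-argument arctangent and
  angular differences are wrapped to [0, π];
* the height attenuation is H/(H + row(k′)) by default (the printed form,
  using the absolute height of the template axon); the variant
  H/(H + |row(k′) − row(k)|) (distance from the matched axon in the scan
  direction, matching the stated motivation) is available as
  `height_term="relative"`;
* when x_k′ = x_k the angular normalization η_θ takes its limit π/2;
* one dummy axon per ROI is added, so any subset of ROIs can go unmatched;
  dummies inside the inner problem are priced by the same
  max(0.3, 1.1·min) rule applied to the inner cost matrix;
* rectangular assignments are solved by `scipy.optimize.linear_sum_assignment`
  (deterministic; ties resolve to the lowest indices);
* areas enter the cost as raw pixel counts.

**Interaction with area quantization.**  With w_area = 0.1 per pixel and
the 0.3 dummy floor, a correct match is rejected once the frame's area
deviations sum to about 3 px.  Under frame-wise sub-pixel deformation the
±1–2 px quantization jitter of pixel-count areas therefore sends a
substantial fraction of true matches to dummies.  This is the designed
behavior of the matcher — an unmatched axon becomes a missing value in the
fluorescence table, not a wrong identity — so the evaluation reports two
numbers:

* **identity accuracy**: the fraction of *assigned* (ROI → axon) identities
  that are correct — an identity-switch-free rate;
* **coverage**: the fraction of visible true axon-slots recovered with the
  right identity.

On the mild-artifact benchmark identity accuracy is ≈ 100 % while coverage
is ≈ 60–70 %: the tracker rarely mislabels, but abstains often.  Raising
coverage under deformation would need either sub-pixel-stable areas (the
role the original detector's learned segmentation plays) or a different
area normalization in the cost; both are out of scope here.  Known residual
failure modes, each observed in roughly one synthetic recording in ten:
persistent swaps between two axons of nearly equal area, and detection
drop-out of a small, dim axon whose threshold area falls below the 11-px
floor.  This is why benchmark summaries use the median over several
independently generated recordings.

## ROI separation

Watershed of the inverted cluster-average grayscale, seeded at local maxima
with intensity ≥ 0.05 (maxima are detected globally, then assigned to
ROIs; adjacent seed pixels — intensity plateaus — merge into one seed).
Sub-regions under 11 px are fused into the adjacent sub-region sharing the
longest boundary; a 1-px border is inserted between the final sub-regions;
an ROI retaining fewer than two sub-regions is left uncut.  Each border is
fitted by total least squares (the normal is the direction of least
variance of the border pixels).

Cut lines are stored normalized to the parent ROI's least-squares ellipse
(fitted to the outer contour, i.e. the pixels one erosion removes; the
canonical form has the major semi-axis as `w` and rotation in
(−π/2, π/2]).  The normalization divides the rotated normal's components
by the ellipse half-axes (x by h, y by w) and the offset distance by w·h,
then renormalizes — the exact line image under the map taking the ellipse
to a centered axis-aligned unit circle, and the unique reading that is
well-defined for centered ellipses, preserves tangency (a tangent line maps
to distance 1), and makes normalization and re-fitting exact mutual
inverses (verified to 1e−9 over random pairs).  A variant dividing by the
ellipse *center* coordinates is kept behind `variant="printed"` for
comparison; it divides by zero for centered ellipses.  In the inverse
transform the final center offset uses the already-rotated normal — this is
what makes the round trip exact.

Applying cuts to a frame: fit the ellipse to that frame's parent ROI, map
each stored cut back through it, and give the pixels on the far side of the
line (the side opposite the ellipse center) to the child axon.  Multiple
cuts apply in order of increasing distance from the ellipse center; border
pixels stay with the near side, so the children and the remaining parent
always partition the original ROI exactly.  A frame where the ellipse fit
fails (degenerate contour) skips the cut and marks the child missing there.

## Fluorescence

F_t is the mean of non-zero green pixels of the axon's ROI (zeros are
treated as outside the effective region); tdTom_t likewise; R_t is their
ratio, which cancels any global intensity factor because tdTomato is
static.  Baselines are the minimum over *sliding* (stride-1) 10-s windows
of the within-window mean — sliding rather than disjoint windows give a
deterministic, slightly tighter minimum.  Window means skip missing frames;
windows more than half missing are excluded; a trace shorter than one
window falls back to its global mean.  ΔF/F = (F_t − F)/F is scale-free.
Missing values are NaN in memory and empty fields in CSV.

## Pipeline variants

The extraction pipeline runs over the raw stack, the cross-correlation
registered stack (single-step DFT phase correlation on the red channel
against the *second* frame, wrap-around translation applied to both
channels; integer shifts by default for bit-exactness, sub-pixel by Fourier
phase shift at `upsample > 1`), and an optic-flow-registered stack if a
registrar callable is plugged in (none ships with the package; without one
the flow variant is skipped with a warning).  The raw variant skips frame
clustering, the fine-tune target and hence automatic ROI separation —
those are built on cross-correlation similarity and would duplicate the cc
variant.  A failing variant is logged and skipped; at least one must
succeed.

## Benchmark conditions

The package's standard synthetic benchmarks, chosen once as realistic
study conditions:

* **Artifact-free**: 3 axons, 200 frames, 64×64 px, 4 frames/s, noiseless,
  `artifact_magnitude = 0`.  Expected: identity accuracy and coverage both
  100 %, trace correlation 1 (exact, since ROIs are static).
* **Mild artifact**: same geometry with `artifact_magnitude = 0.3`
  (translation within ±3 % of the frame, rotation within ±1.5°, scale
  within ±1.5 %) and the default noise model.  Expected: identity accuracy
  ≥ 95 %, per-axon ΔF/F correlation ≥ 0.8, coverage ≈ 60–70 % (reported,
  see the tracking section).
* **Separation**: two overlapping axons (centers 8.5 px apart) that
  segment as one ROI, 120 frames, static with noise; the cut-line
  machinery must recover both identities with trace correlation ≥ 0.8.

`scripts/acceptance.py` reports the median over 5 (mild) or 3
(artifact-free) independently generated recordings to damp the one-in-ten
single-recording failure modes listed above.
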