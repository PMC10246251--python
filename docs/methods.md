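# Methods

## Detection model

A head NCCT is reduced to 5 mm axial slices before any measurement: when
the acquisition is thinner, consecutive slices are merged by a
thickness-weighted mean (fractional edge slices get fractional weights),
which conserves total HU mass for integer thickness ratios and never
interpolates thick data to a finer grid. Gantry tilt is recorded but not
corrected, and in-plane resolution is left untouched.

Detection is relative, not absolute: a voxel is a hyperdensity candidate
when its HU strictly exceeds the *brain-tissue median* by more than
`hu_offset` (default 15 HU). The median is taken over the intracranial
mask — skull thresholded at `bone_hu` (default 300 HU), the enclosed
cavity filled slice-wise, the largest 3D cavity component kept, and
voxels restricted to `[brain_hu_window.low, bone_hu)` so hematoma voxels
are never carved out of the reference region. The median is a single
pass and deliberately *includes* lesion voxels: for a very large bleed
(≈100 cc in an ≈830 cc cavity) this raises the reference median by well
under 1 HU, a negligible bias against the 15 HU margin, and avoids
inventing an iterative re-estimation. The median is global; a slice-wise
variant would be a straightforward extension but is not implemented.

Candidates are labeled as 3D connected components (26-connectivity by
default; 6/18 available) and screened twice:

* **size floor** — components under `min_component_cc` (default 1 cc,
  the stated detection limit) are rejected;
* **anatomical exclusion** — components with more than
  `dural_overlap_fraction` (default 50 %) of their voxels inside the
  exclusion zone are rejected as dural/falcine.

The exclusion zone is a geometric surrogate for the structures that are
physiologically hyperdense on NCCT (dural venous sinuses, falx cerebri):
the union of a peripheral shell — the intracranial mask minus its 3D
erosion by `dural_margin_mm` (default 3 mm) — and a posterior midline
band of half-width `midline_band_mm` (default 2 mm) around the per-slice
mid-sagittal column, posterior to the per-slice in-plane centroid. The
through-plane erosion reach is expanded to at least one slice thickness:
at 5 mm analysis slices a purely metric 3 mm erosion would never erode in
z, and the cavity's top and bottom faces — where partial-volume mixing of
brain and bone produces spurious hyperdensity — would escape the shell.
Both margins at zero give an empty zone. Axial range is restricted to
[lowest slice whose cavity cross-section reaches 25 % of the maximum,
highest slice with any cavity voxel]; the 25 % rule is a reproducible
proxy for "below the brain stem", which has no crisp geometric
definition. The mid-sagittal plane is the per-slice cavity centroid
column, with no symmetry registration — adequate for phantoms and
roughly upright heads; strongly rotated scans are a known limitation.

Volume is voxel count × (row_mm × col_mm × slice_mm) / 1000, summed over
kept components only. The whole pipeline is deterministic for a fixed
input.

## Expansion rule

For a baseline/follow-up pair, `abs_diff = followup − baseline` (growth
positive) and `pct_diff = 100 · abs_diff / baseline`. HE is positive iff
`abs_diff ≥ 6 cc` **and** `pct_diff ≥ 33 %` — the conjunction, rather
than either/or, trades sensitivity for specificity. Both thresholds are
inclusive (the literature does not fix strict vs non-strict; ≥ is the
conventional reading) and configurable. Baselines under 1 cc are outside
the rule's domain (percent change degenerates below the detection
floor) and raise an error. Negative differences — follow-up smaller than
baseline, usually measurement/partial-volume effect — are reported
unmodified.

## Diagnostic statistics

Automated calls against a reference standard (taken as ground truth; no
inter-rater machinery) form a 2×2 table. Proportion metrics (sensitivity,
specificity, PPV, NPV, accuracy) are Clopper–Pearson exact binomial
intervals from beta quantiles, with the conventional closures at k = 0
and k = n; exact intervals are conservative (coverage ≥ nominal).
Likelihood ratios use the log method: `exp(ln LR ± z·SE)` with
`SE(ln LR+) = sqrt(1/tp − 1/(tp+fn) + 1/fp − 1/(fp+tn))` and the
analogous expression for LR−. A zero cell that makes an LR undefined
raises an error naming the cell — no silent continuity correction.
Rounding to two decimals happens only at report formatting. These two
method choices reproduce the published metric block from its 2×2 counts
(16/3/1/107 → 94.12 % [71.31, 99.85], 97.27 % [92.24, 99.43], 34.51
[11.23, 106.02], 0.06 [0.01, 0.41]), which the test suite asserts.

## Phantom

The generator emulates exactly the features the pipeline consumes:

| element | default | note |
|---|---|---|
| grid | 192×192×40 at 1×1×2.5 mm | sub-analysis thickness, exercises resampling |
| skull | ellipsoidal shell, semi-axes 45/85/70 mm, 6 mm thick, 1200 HU | closed vault |
| brain | inner ellipsoid, 35 HU + N(0, σ²), σ = 4 HU | i.i.d. Gaussian noise |
| hemorrhage | ellipsoids, 70 HU, analytic volume 4/3·π·abc | must sit fully inside the brain |
| falx plate | 1.5 mm mid-sagittal posterior plate, 60 HU | optional distractor |
| sinus blob | 3.5 mm-radius blob at the posterior pole, 60 HU | optional distractor |
| neck | 4 sub-skull soft-tissue slices, 40 HU | exercises the range filter |

The HU palette is chosen inside clinically typical ranges so that the
15 HU offset separates lesion (70) from brain (35) but **not** distractor
(60) from lesion by HU alone — the distractors can only be removed by the
anatomical rejection path, which is exactly what they exist to test.

Voxelization is partial-volume: every structure contributes its
fractional occupancy of each voxel (2×2×2 supersampling; boxes are
exact), so boundary voxels carry intermediate HU the way slab-averaged
CT does. A structure's truth mask is the set of voxels it majority-fills
(occupancy ≥ ½). With eighth-quantized occupancies the 15 HU cut on a
noiseless phantom falls strictly between occupancy 3/8 and 4/8, so the
detected mask equals the truth mask voxel-for-voxel when truth and
analysis grids coincide — the exact-recovery check therefore uses a
phantom generated natively at 5 mm slices; across resampling, voxelwise
comparison between grids is ill-defined and only volumes are compared.
Partial-volume mixing of brain and bone also produces a realistic
hyperdense rim along the inner table, which the peripheral-shell
rejection removes — on noisy default phantoms the detector recovers a
25 cc bleed to within ~1 % and reports exactly 0.0 cc on lesion-free
distractor phantoms.

Serial pairs share geometry and noise process (independent draws seeded
from one parent seed); the follow-up lesion is scaled isotropically to
the requested analytic volume, so truth volume scales as the cube of the
axis scale. Simulated cohorts draw baselines log-uniform on [2, 60] cc;
true expanders clear both criteria with margin (Δ ≥ 8 cc and ≥ 55 %),
non-expanders change by at most ±2 cc — "well-separated" labels so that
cohort-level checks probe pipeline integrity rather than behaviour at the
decision boundary. The default end-to-end cohort size is 40 pairs (25 %
expanders), a problem size that keeps a full simulation-plus-detection
run under a minute on one core.

What the phantom does **not** model: CT streak/beam-hardening artifacts,
anatomical asymmetry and gyral texture, ventricles and CSF spaces,
intraventricular/subarachnoid blood, gantry-tilted acquisitions, and
scanner-specific noise correlation. Passing phantom tests therefore
demonstrates correctness of the measurement pipeline under its stated
model, not clinical performance on patient scans.

## Numerical choices

* HU stored as float64 after DICOM rescale; medians and slab averages are
  fractional.
* Strict inequality at the detection threshold; ties excluded (measure
  zero under noise).
* Even-count medians take the midpoint of the two central order
  statistics.
* Resampling requires source ≤ target thickness; equal thickness returns
  the input unchanged; a trailing partial slab is averaged over its
  actual coverage.
* DICOM series must share one orientation and have uniform slice spacing
  within 5 %; duplicate or missing positions are errors naming the gap.
* Erosion structuring elements are metric ellipsoids in mm, with the
  through-plane radius floored at one slice (see above); monotonicity of
  zone volume in `dural_margin_mm` is preserved.
* Lesion containment in the phantom is validated by dense sampling of the
  lesion surface against the inner-ellipsoid equation (512 Fibonacci
  points, 0.5 % safety factor).
* Seeds: `numpy.random.default_rng` throughout; derived child seeds stay
  below 2³¹.
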