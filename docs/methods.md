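# Methods

This note documents the models, conventions and numerical choices behind
`acltunnel`, and what its synthetic validation does and does not establish
about real CT data.

## Coordinate and measurement conventions

All geometry is computed in world millimetres.  Voxel index `(i, j, k)` maps
to the world position of the voxel *centre*, `origin + index · spacing`, so
anisotropic grids (fine in-plane, coarse slice direction) are handled once.
The joint line is a plane whose unit normal points into the bone; *depth* is
the signed distance to this plane.

A tunnel is summarised by a best-fit cylinder and two cross-sectional
circles:

* **Cylinder.** Minimises Σ(dist(pᵢ, axis) − r)² over the boundary point
  cloud.  The axis is initialised from the principal direction of the cloud
  and refined together with the radius by Levenberg–Marquardt least squares
  (parameter tolerances 1e-12, at most 2000 function evaluations).  The axis
  direction is canonicalised to point away from the joint into the bone.
  Degenerate inputs error out: fewer than 50 points, coplanar clouds, and
  sphere-like clouds whose RMS residual exceeds a quarter of the fitted
  radius (clean voxelized tunnels stay below a tenth).
* **Axial origin.** The aperture (axial coordinate 0) is the intersection of
  the *fitted* axis with the joint plane.  No anatomical definition of the
  aperture is attempted.
* **Circles.** Points whose axial coordinate lies within ± 1.0 mm (the
  `slab_halfwidth` default, of the order of the slice thickness) of the
  target position are projected onto the plane through that position
  perpendicular to the cylinder axis and fitted with an algebraic (Kåsa)
  circle refined by geometric Gauss–Newton.  Fewer than 8 slab points is an
  error, never a silent fallback.  Cross-sections are therefore taken
  *perpendicular to the tunnel axis*, not parallel to the joint surface; the
  two conventions coincide for tunnels perpendicular to the joint and differ
  by a cos-factor obliquity ellipse otherwise.  The perpendicular convention
  keeps the aperture and 10-mm measures directly comparable and is flagged
  here as an interpretation.
* **End caps.** A binary mask's surface includes flat caps at the aperture
  and the drilled end; their points lie *inside* the cylinder and would bias
  all radius estimates low.  Boundary points carry surface normals
  (marching-cubes gradients, or face directions for the voxel-face method),
  and points whose normal is within ~45° of the tunnel axis (|cos| ≥ 0.7)
  are discarded before fitting.

### Screw filtering

A tibial interference screw can protrude from the tunnel wall.  Instead of a
hand-drawn cut line, the filter iterates: fit cylinder → radial residuals →
drop points with residual > median + k·MAD (k = 3.5, one-sided outward, at
most 5 iterations) → refit.  Only outward outliers are dropped because the
physical artifact is a bulge; dropping more than 40 % of points aborts with
an error, since the input is then unlikely to be a tunnel at all.  On exact
noise-free cylinders the filter removes nothing (all residuals are zero).

### Tunnel communication

Two tunnels communicate when no cortical bone separates their masks at the
joint line.  Surface voxels of both masks are binned along the joint-plane
normal at the slice thickness; within each bin the bone gap is the minimum
pairwise surface-voxel distance minus one *transverse* (in-plane) voxel
diagonal — two surface voxels closer than that have no bone voxel between
them.  The full 3D diagonal would be dominated by the 1.5 mm slice thickness
and declare contact through intact bone.  The ridge distance is the depth of
the deepest voxel-level contact, i.e. the smallest depth beyond which the
masks are never again in contact; on constructed converging pairs with true
ridges of 2.7–15.2 mm the estimate is accurate to ~0.5 mm, well inside one
slice thickness.

## Phantom model

Phantoms are solid bone blocks with drilled voids: intensity is a bone value
everywhere except inside tunnels (background value), plus seeded Gaussian
noise.  Noise affects intensities only — masks and ground truth are
bit-identical across seeds.  The default grid is 96 × 96 × 40 voxels at
(0.4, 0.4, 1.5) mm: the slice thickness and in-plane/slice anisotropy of the
emulated 16-row CT protocol, at a desk-scale field of view (a full 512 × 512
grid is available through configuration).  A tunnel is the set of voxel
centres inside the radius profile around an entry-point/axis line, cut by
the joint plane above and the drilled length below; for oblique axes the
aperture is a complete ellipse in the joint plane, as a real drill leaves
it.

* **Widening profiles.**  `uniform` adds the diameter increment everywhere.
  `aperture_weighted` applies the full increment at the aperture, decaying
  linearly to half of it at 10 mm depth and constant beyond — a minimal
  analyzable form of the aperture-dominant widening attributed to the
  windshield-wiper effect; the decay depth (10 mm) and far fraction (1/2)
  are module constants.  The true spatial shape of widening (scalloping,
  cavitation) is unknown; only these two idealisations are modelled.
* **Screw artifacts.**  A sphere of configurable radius unioned onto the
  mask near the distal end, displaced laterally; it must protrude from and
  stay connected to the wall.
* **Rater perturbation.**  Manual segmentation edits are emulated as a mean
  outward boundary shift (`rater_bias_mm`) plus voxel-wise Gaussian jitter.
  A continuous signed distance is estimated from the Gaussian-smoothed mask
  indicator (σ = 0.5 mm), x = −σ·Φ⁻¹(u), and near-boundary voxels are
  re-classified by `x ≤ bias + jitter`.  The smoothed estimate is what makes
  a 0.2 mm bias move the average boundary by 0.2 mm on a 0.4 mm grid — any
  voxel-quantised distance responds in half-voxel steps.  The smoothing
  carries a small curvature bias (≈ −0.08 mm diameter when dilating an 8 mm
  tunnel by 0.4 mm), below the voxelization noise of downstream fits.
* **Cohorts.**  Per subject and tunnel type, Year-0 diameter ~
  Normal(μ₀, σ₀) truncated above 4 mm and subject-level widening ~
  Normal(μΔ, σΔ) truncated above −0.5 mm (redrawn on violation).  Defaults
  are the published per-tunnel means and SDs (e.g. SB femur 8.3 ± 0.6 mm at
  Year 0 with 1.4 ± 0.9 mm widening; DB femoral AM 7.1 ± 0.7 with
  0.5 ± 0.6), with 22 SB and 20 DB subjects.  The diameter floor is
  essentially never hit under these defaults (worst case ≈ 3·10⁻⁶ per
  draw); the widening floor trims the lower tail of the wider-SD tunnel
  types and shifts their realised means up by ≤ 0.2 mm.  Year-0 size and
  widening are drawn independently (no published correlation to emulate);
  the fast (analytic) cohort mode applies one widening draw uniformly, so
  all three measurement levels carry the same value, while the voxel mode
  drills paired phantoms per subject.  The truncation bounds are physical
  guards, motivated by the ≥ 5 mm graft-size inclusion criteria.

### What the phantoms do not emulate

No trabecular texture, cortical/cancellous contrast, metal streaking, beam
hardening, or DICOM semantics.  Segmentation on phantoms is therefore much
easier than on clinical CT: passing tests demonstrate that the *measurement
and statistics* layers are correct and robust to the modelled artifacts
(voxelization, obliquity, screw lobes, rater edits), not that the threshold
segmentation would succeed on real scans.  Real data additionally require
per-case trim ranges (the graft region cannot be inferred automatically)
and a joint-plane definition from anatomy.

## Statistics

* **Widening.**  Computed per subject as Δ = d₁ − d₀ and Δ% = 100·Δ/d₀, then
  averaged; confidence intervals on percentages therefore reflect
  subject-level ratios.  The ratio-of-means variant 100·mean(Δ)/mean(d₀) is
  reported alongside; both round to the same integers at the default study
  conditions.
* **Tests.**  Paired t within technique (one-sample t on differences,
  two-sided, 95 % CI = mean ± t₀.₉₇₅,ₙ₋₁·SE); Welch t between techniques
  with Welch–Satterthwaite degrees of freedom (it reduces exactly to
  Student's t for equal variances and group sizes).  Raw p-values at
  α = 0.05, no multiplicity correction, matching the emulated analysis; an
  optional Holm adjustment can be applied downstream.  Reports print
  p ≥ 0.05 as "ns" while machine outputs retain exact values.
* **ICC(2,1).**  Two-way random-effects ANOVA decomposition (see README for
  the formula), subjects × raters with no missing cells and no imputation.
  The bootstrap CI resamples *subjects* with replacement (B = 2000 default,
  percentile 2.5/97.5, seeded); when a tunnel-level matrix is analysed the
  sampling unit is configurable, defaulting to subject so tunnels from one
  knee stay together.  Percentile intervals under-cover slightly for ICCs
  near 1, and subject resampling cannot absorb large rater effects drawn
  only k times per study; coverage is verified at ≥ 90 % for
  subject-dominated variance components.
* **Power.**  The a-priori computation assumes a two-sided one-sample t on
  paired differences (the emulated analysis does not name its test; this is
  the natural choice for a paired widening design, and a normal
  approximation is available as an option).  Power at a given n uses the
  noncentral t distribution with noncentrality (δ/σ)·√n; the returned n is
  the smallest with power ≥ target, floored at n = 2.  With δ = 0.5 mm,
  σ = 0.74 mm, α = 0.05 and 80 % power this gives n = 20.  Note that for
  very large effects the exact noncentral-t answer stays at 3 until the
  effect is extreme (the df = 1 noncentral t is fat-tailed), reaching the
  n = 2 floor only around δ ≳ 25σ.
* **Enrollment bookkeeping.**  The study-flow arithmetic (56 screened − 8
  logistical − 1 radiation-declined − 2 lost − 3 technical = 42 analysed,
  20 DB + 22 SB) is encoded and checked for internal consistency.  One
  published table labels the SB group "n = 24" while the text reports 22 SB
  patients; the discrepancy is preserved as a documentation note and the
  group sizes follow the text.

## Validation scale and determinism

The test suite and the acceptance checks run on desk-scale problems chosen
as the package's own validation design: 50 voxelized phantoms for parameter
recovery (mean |diameter error| ≲ 0.01 mm observed, bounds 0.2/0.4 mm
asserted), 10,000 simulated cohorts of n = 20 for type-I/power calibration,
30 × 200-subject replicates for ICC recovery, and B = 300–1000 bootstrap
resamples in tests (B = 2000 in production defaults).  Every stochastic
component takes an explicit seed; identical seeds give bit-identical masks,
cohorts, bootstrap intervals and CLI outputs.

## Known limitations

* Threshold segmentation plus robust filtering replaces interactive
  slice-by-slice editing; rater variability is *modelled* (in the phantom
  module) rather than reproduced.
* Aperture circles are measured perpendicular to the fitted axis (see
  above) — results are not directly comparable to joint-surface-plane
  measurements for strongly oblique tunnels.
* No registration between timepoints: measurements are per-scan, so axis
  and aperture definitions may differ slightly between Year 0 and Year 1.
* The communication check assumes both tunnels lie on the same bone side of
  a single joint plane and reports contact at voxel resolution; walls
  thinner than about half an in-plane voxel count as missing.
* Percentage-widening CIs assume approximately normal subject-level ratios;
  for very small Year-0 diameters the ratio distribution is skewed.
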