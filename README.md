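# acltunnel

Semi-automated 3D-CT morphometry of drilled bone tunnels in ACL-reconstructed
knees, with a full tunnel-widening statistical analysis — built and validated
end to end on synthetic knee phantoms with analytic ground truth.

## The problem

After anterior cruciate ligament (ACL) reconstruction, the drilled femoral and
tibial graft tunnels tend to enlarge during the first post-operative year.
This *tunnel widening* matters mostly for revision surgery: bone loss near the
joint may require staged bone grafting.  Quantifying widening from CT requires
(i) segmenting each tunnel from an anisotropic CT volume, (ii) reducing the
segmented void to reproducible size measures, and (iii) comparing paired
post-op / 1-year measurements within and between surgical techniques
(single-bundle SB: one tunnel per bone; double-bundle DB: separate
anteromedial AM and posterolateral PL tunnels).

`acltunnel` implements that workflow for users of quantitative
musculoskeletal imaging:

* **Measurement core** — a least-squares *best-fit cylinder* over the tunnel
  surface (minimising Σ(dist(pᵢ, axis) − r)²), plus best-fit circles in
  planes perpendicular to the cylinder axis at the *aperture* (where the axis
  crosses the joint-line plane) and *10.0 mm* deeper.  Six numbers per tunnel
  per timepoint: diameter d and cross-sectional area CSA = πr² at the three
  levels.  Interference-screw tips protruding from the tibial tunnel wall are
  rejected by an iterative robust scheme (drop radial residuals above
  median + k·MAD, refit).
* **Communication detection** — two converging DB tunnels *communicate* when
  no cortical bone separates their masks at the joint line; the *ridge
  distance* is the depth at which a separating bridge appears.
* **Statistics** — per-subject widening Δ = d₁ − d₀ (mm and %), paired t-tests
  within technique, Welch t-tests between techniques, rater reliability via
  the single-measures absolute-agreement intraclass correlation

      ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

  with a subject-resampled percentile-bootstrap CI, and a-priori paired-design
  sample size by iterating n over the exact noncentral-t power.
* **Synthetic phantoms** — CT-like bone blocks (default 96×96×40 voxels at
  0.4×0.4×1.5 mm) with drilled tunnels, widening profiles, screw artifacts,
  stochastic rater edits, converging tunnel pairs, and two-group cohorts at
  the published study conditions (22 SB / 20 DB subjects), all with analytic
  ground truth.

## Worked example

Measure a drilled 8.3 mm femoral phantom before and after 1.4 mm of
aperture-weighted widening:

```python
import numpy as np
from acltunnel import phantom as ph, volumes as vio, geometry as geo

spec = ph.PhantomSpec()
plane = spec.joint_plane
t0 = ph.TunnelSpec.drilled(plane.point, (0, 0, 1), 8.3, 25.0, side="femur")
t1 = ph.widen_tunnel(t0, 1.4, "aperture_weighted")
for label, t in (("year0", t0), ("year1", t1)):
    _, masks, truth = ph.generate_phantom(spec, [t], seed=1, timepoint=label)
    pts = vio.mask_to_points(masks[0])
    pts = vio.trim_tunnel(pts, np.asarray(plane.normal), (0.0, 23.0), plane)
    m = geo.measure_tunnel(pts, plane)
    print(f"{label}: cylinder {m.cylinder.diameter:.2f} mm  "
          f"aperture {m.aperture.diameter:.2f} mm  "
          f"10 mm {m.at10mm.diameter:.2f} mm")
```

prints

```
year0: cylinder 8.33 mm  aperture 8.33 mm  10 mm 8.33 mm
year1: cylinder 9.18 mm  aperture 9.73 mm  10 mm 9.05 mm
```

— the Year-0 tunnel reads its drill size at all three levels (voxelization
error ≈ 0.03 mm), while the widened tunnel is widest at the aperture (9.73)
and narrower 10 mm deeper (9.05), the pattern expected from graft motion at
the joint line.

A full cohort analysis through the statsmodels-style model object:

```python
from acltunnel import phantom as ph
from acltunnel.stats import TunnelWideningModel

cohort = ph.generate_cohort(ph.CohortSpec(rng_seed=7))     # 22 SB + 20 DB
res = TunnelWideningModel.from_dataframe(cohort.table).fit()
print(res.summary())
```

whose cylinder-level rows read

```
DB femur_AM  7.0 -> 7.4 mm  widening 0.4 [0.1, 0.6] mm (5 %)   p 0.002
DB femur_PL  5.6 -> 6.6 mm  widening 1.0 [0.6, 1.3] mm (17 %)  p <0.001
DB tibia_AM  9.1 -> 9.7 mm  widening 0.6 [0.3, 0.9] mm (7 %)   p <0.001
DB tibia_PL  7.0 -> 7.4 mm  widening 0.4 [0.2, 0.6] mm (6 %)   p <0.001
SB femur     8.1 -> 9.4 mm  widening 1.3 [1.0, 1.7] mm (17 %)  p <0.001
SB tibia     9.9 -> 10.8 mm  widening 0.9 [0.5, 1.2] mm (9 %)  p <0.001
```

Every tunnel type shows significant widening, with the SB femoral tunnel
widening most — the qualitative pattern the analysis is designed to detect.
`res.n_required` is 20: the smallest paired-design sample size detecting a
0.5 mm mean widening (SD 0.74 mm) with 80 % power at α = 0.05.

## Command line

```bash
acltunnel simulate -o out/                 # fast analytic 42-subject cohort
acltunnel simulate -o out/ --voxel         # NIfTI label phantoms + manifest
acltunnel measure  -m out/manifest.csv -o measurements.csv
acltunnel analyze  measurements.csv -o report/ [--raters raters.csv]
```

All stages are seeded and embed the config hash for exact reproducibility.

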