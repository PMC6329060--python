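# pelvinc

CT-based 3D measurement of **pelvic incidence (PI)** — the angle between the
perpendicular to the superior sacral endplate at its midpoint and the line
from that midpoint to the hip axis — plus the reliability statistics used to
validate such measurements.

The pipeline mirrors a CT-to-model measurement workflow:

1. **Segmentation** — HU thresholding and seeded region growing isolate the
   pelvic bone; seeded removal deletes femora/vertebrae components.
2. **Surface** — level-0.5 marching cubes reconstruction, minimally smoothed
   (Taubin λ/μ, no simplification).
3. **Frame** — the four anterior-pelvic-plane (APP) landmarks (both ASISs and
   pubic tubercles) are refined to the locally most ventral vertices by a
   fixed-point iteration; the model is realigned with the APP perpendicular
   to the horizontal plane.
4. **Hip** — least-squares spheres (algebraic init + orthogonal-distance
   refinement) are fitted to both acetabula from user seeds; the hip axis is
   the midpoint of the two centers.
5. **Endplate** — the mid-sagittal plane is refined by mirror-and-register
   ICP; 5000–8000 upward-facing endplate surface points are extracted around
   a seed, projected into the plane, and fitted with an orthogonal
   least-squares line segment; the concavity type (type 1 = concave
   anteriorly, type 2 = concave posteriorly, flat) is classified from a
   quadratic residual fit.
6. **PI** — angle between the line's perpendicular at the segment midpoint
   (oriented toward the hip axis) and the midpoint→hip-axis direction.
7. **Reliability** — ICC(2,1) interobserver (two-way random, absolute
   agreement) and ICC(3,1) intraobserver (two-way mixed, consistency) with
   F-based 95% CIs, plus normality / variance-homogeneity / t-test / Pearson
   cohort comparisons.

A parametric pelvis **phantom** with analytically exact ground truth
(PI, hip axis, endplate line, symmetry plane, landmarks) makes every stage
testable with no external data.

## CLI

```bash
# synthetic phantom (volume + mesh + landmark/truth sidecars)
pelvinc phantom --pi 45 --concavity -3 --spacing 0.98 0.98 1.0 --seed 7 --out phantom_dir

# measure PI from a DICOM directory, a NIfTI/NRRD volume, or a PLY/STL mesh
pelvinc measure --input phantom_dir/phantom.nii.gz \
    --landmarks phantom_dir/landmarks.json --out result.json

# reliability report from a long-format ratings CSV (subject,rater,session,pi_deg)
pelvinc icc --ratings ratings.csv --out icc.json
```

The landmark JSON supplies seven named points in mm (mesh/volume frame):
`ASIS_L`, `ASIS_R`, `PT_L`, `PT_R`, `acetab_seed_L`, `acetab_seed_R`,
`endplate_seed`. Every tolerance of the pipeline lives in `PipelineConfig`
and is serialized into the versioned result JSON for provenance.

## Library sketch

```python
from pelvinc import (PhantomSpec, generate_phantom_volume, LandmarkSet,
                     measure_pi_pipeline)

vol, truth = generate_phantom_volume(PhantomSpec(pi_true=45.0))
result = measure_pi_pipeline(vol, LandmarkSet.from_truth(truth))
print(result.pi, result.endplate_type.label)
```
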