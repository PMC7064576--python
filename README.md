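# morphoqc

Error decomposition for dense 3D landmark configurations from repeated
surface imaging.

## The problem

Dense surface registration places a template mesh of *V* quasi-landmarks
(thousands of vertices in anatomical correspondence) onto every 3D scan of a
study, so that row *i* of every configuration refers to the same anatomical
location. Before such configurations are used for morphometric inference —
clinical, evolutionary or genetic — the variation they carry must be split
into its nuisance components. `morphoqc` quantifies four nested sources, each
in mm at each quasi-landmark, for the common two-camera repeatability design
(subjects imaged R times on each of two camera systems, each image
registered M times):

1. **Registration precision** — for each image, the mean Euclidean distance
   of each of its M registrations to their average, computed *without*
   superimposition (repeated registrations of one image share a coordinate
   frame):
   `prec(v) = (1/M) Σ_m ‖ x_m(v) − x̄(v) ‖`.
2. **Replicate error** — registration-averaged replicates of one subject on
   one camera are superimposed by a non-scaled, non-reflected generalized
   Procrustes analysis (GPA), and each replicate's distance to the consensus
   is averaged. On live subjects this is *participant error* (movement +
   hardware); on a motionless mannequin it isolates *technical error*.
3. **Camera error** — each subject's per-camera grand averages are aligned
   pairwise (again without scaling or reflection) and their per-landmark
   distance taken; the direction of the difference is resolved by the
   **signed normal displacement** `d(v) = (x_B(v) − x_A(v)) · n̂(v)`,
   positive where camera B images the surface outward of camera A.
4. **Relative contributions** — a repeated-measures permutation Procrustes
   ANOVA on the jointly GPA-aligned coordinates, `y ~ Camera : Individual :
   Replicate`, with camera fixed and individual/replicate random, Type III
   sums of squares (the balanced orthogonal decomposition), F ratios against
   the next-nested random term, and restricted-permutation p values.

All Procrustes steps forbid scaling (form analysis: size is data) and
reflection (det R = +1 always).

Because real repeated-capture face datasets are rarely shareable, the
package ships a first-class synthetic generator (`morphoqc.synthetic`) that
produces balanced hierarchies with known registration/technical/movement
noise, per-replicate rigid nuisance motions, and a smooth camera-bias field
applied along vertex normals — with closed-form expected errors
(`expected_errors`) for recovery testing: e.g. expected precision is
`sqrt((M−1)/M) · E(χ₃) · σ_reg` with `E(χ₃) = 2√(2/π)`.

## Worked example

```python
import numpy as np
from morphoqc import (SyntheticSpec, make_template, simulate_hierarchy,
                      registration_precision, replicate_error, camera_error,
                      expected_errors, default_movement_mask)

mesh = make_template("sphere", 642)
spec = SyntheticSpec(template=mesh, n_individuals=8,
                     sigma_reg=0.10, sigma_tech=0.25, sigma_part=0.30,
                     movement_mask=default_movement_mask(mesh),
                     bias_amplitude=0.5, bias_field=np.ones(642), seed=2)
cset, truth = simulate_hierarchy(spec)
print(registration_precision(cset).summary.mean)   # 0.130 mm
print(replicate_error(cset, "camera_a").summary.mean)  # 0.381 mm
print(camera_error(cset)[0].summary.mean)          # 0.618 mm
```

The three numbers are the landmark-averaged registration precision,
replicate error and camera error of the simulated study. They order as the
noise structure dictates — precision (0.130 mm, pure registration noise)
< replicate error (0.381 mm, capture noise plus localized movement) <
camera error (0.618 mm, systematic 0.5 mm bias plus residual noise) — and
each stage also returns the full per-landmark field and per-image /
per-subject tables. The scripts in `examples/` walk through each capability
(precision, replicate/camera error, signed displacement maps, the
dense-versus-sparse ANOVA contrast) and print the numbers shown above.

Real data enter through a manifest CSV
(`individual,camera,replicate,registration,file`) naming one x-y-z
coordinate file per configuration, plus an OBJ/PLY template mesh for
normals and heatmaps; see `morphoqc.load_manifest`. A thin CLI wraps the
same functions:

```bash
morphoqc simulate --out-dir study --seed 1
morphoqc precision --manifest study/manifest.csv --template study/template.ply --out-dir out
morphoqc anova --manifest study/manifest.csv --seed 1 --n-perm 100 --out-dir out
```

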