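# Methods

This note documents the models, numerical choices and limitations behind
`morphoqc`, in the order the pipeline runs them.

## Data model

A study is a balanced hierarchy: individuals × two cameras × R replicate
captures × M registration iterations, each cell one configuration of V
corresponded quasi-landmarks (mm). Correspondence is positional — row *i*
is template vertex *i* everywhere; no ID remapping exists anywhere in the
package. Landmark counts must agree across an analysis; the loader rejects
mixed-V manifests, duplicate hierarchy keys and missing files by name.
Vertex indices are 0-based internally and in all exported tables (stated in
a header comment of each CSV).

## Constrained Procrustes alignment

Every alignment is a rigid superimposition: scaling and reflection are
disabled throughout, because the analyses concern *form* (size retained)
and anatomical surfaces must never be mirrored. The ordinary problem is
solved in closed form (SVD of the cross-covariance; translation by centroid
matching). When reflections are forbidden and the unconstrained optimum is
improper, the smallest singular direction is negated — with exactly tied
smallest singular values the last SVD column is negated by fixed
convention, making the result deterministic (the optimum is non-unique in
that measure-zero case). Rank-deficient (e.g. collinear) configurations
produce a warning, not an error: the constrained solution is still
well-defined as one minimizer.

GPA iterates: center all configurations, take the first as the initial
consensus, superimpose each on the consensus, re-average, and stop when the
consensus RMS vertex displacement falls below `tol` or `max_iter` is hit.
Defaults are `tol = 1e-8` mm and `max_iter = 100`: far below any effect of
interest (the smallest reported in this problem domain is ~0.01 mm), and
convergence on realistic inputs takes well under ten iterations.
Non-convergence sets a flag rather than raising. The recorded objective
history (total squared deviation from the consensus) is non-increasing by
construction and asserted in tests. A two-configuration "GPA" reduces to
one ordinary superimposition plus consensus averaging and is implemented
through the same code path.

## Error stages

**Registration precision** is computed per image without superimposition:
registrations of one image share a coordinate frame, so aligning them would
absorb genuine registration scatter. The per-landmark value is the mean
distance of the M registrations to their elementwise average; the reported
field averages these over images (optionally per camera). A common rigid
motion applied to a whole cell cancels exactly (asserted numerically).

**Replicate error** represents each replicate by the average of its M
registrations, aligns the R replicate averages *within one individual and
camera only* by constrained GPA, and averages each replicate's per-landmark
distance to the consensus. Mannequin (technical-error) analyses are the
same code path with different input — there is deliberately no separate
mannequin mode.

**Camera error** reduces each camera to a grand average per individual: the
GPA *consensus* of the registration-averaged replicates. A plain elementwise
average would be wrong whenever replicates carry nuisance motions — they
always do in practice — so the consensus (which lives in the replicates'
common shape space) is the only choice that makes camera error invariant to
per-capture rigid motions; this invariance is tested to 1e-6 mm. The two
grand averages are then superimposed and their per-landmark distance taken.
The aligned pairs are retained so the **signed normal displacement** can be
computed: normals are evaluated on the reference ("from") configuration
using the template triangulation, as area-weighted sums of incident face
normals (unnormalized cross products — their magnitude is twice the face
area, so plain accumulation *is* area weighting), oriented by face winding.
The displacement is the projection of the aligned difference onto these
unit normals; it is exactly antisymmetric in its arguments and bounded by
the Euclidean distance. Stored values keep physical units (mm); a
display-only normalization (divide by max |value|) exists for unit-free
plotting and is never applied to stored results.

Summary statistics (mean, sample SD with n−1, min, max) accompany the
per-landmark field, i.e. they summarize the V landmark-wise means; the much
wider per-image and per-individual distributions are emitted as separate
tidy tables. A single value reports SD = 0 with n = 1.

## Permutation Procrustes ANOVA

The response is the jointly GPA-aligned configuration set flattened to an
n × 3V matrix (vertex-major x, y, z); sums of squares are summed over all
columns. Two formulas are supported: `dense` (Camera, Individual,
Camera:Individual = replicate-to-replicate variation, Camera:Individual:
Replicate = registration-to-registration variation, Residuals) and `sparse`
(no registration level). The design must be balanced; in that case the
orthogonal sequential decomposition equals Type III marginal SS, the
components add to the total exactly, and R² per term is SS/SS_total.

F ratios follow expected-mean-squares logic for the nested random
hierarchy: Camera and Individual are tested over the Camera:Individual mean
square, Camera:Individual over Camera:Individual:Replicate (or the residual
in the sparse formula), and the deepest term over the residual. A
numerically zero numerator yields F = 0 by convention (the fully degenerate
0/0 case of identical camera blocks).

Significance comes from permutations, with the observed statistic included
in the null set, so p ∈ {1/(n_perm+1), …, 1} and never 0. Two schemes are
provided:

* `labels` — restricted label permutation of exchangeable units within
  strata: camera blocks flipped within each individual (Camera), individual
  blocks shuffled within each camera (Individual), replicate blocks
  reassigned to cameras within each individual (Camera:Individual), rows
  reassigned to replicates within each cell (deepest term). Counts per
  stratum are preserved exactly. Its resolution for the Camera test is
  2^(n individuals) arrangements — exact but coarse for small studies.
* `residuals` (default recommendation for few individuals) — restricted
  residual randomization at each term's *denominator stratum*: e.g. for
  Camera, replicate-group residuals (group mean minus individual mean) are
  permuted within each individual across cameras, the response is rebuilt,
  and F recomputed. This respects the repeated-measures structure while
  offering C(2R, R)-per-individual resolution. Naive row-level
  Freedman–Lane randomization is *not* valid here — the Camera F ratio's
  denominator is the interaction mean square, not the residual, and
  row-permuted nulls are badly anticonservative (we measured a 0.99
  empirical type-I rate at nominal 0.05); cell-level residuals permuted
  across individuals fail the other way because the two cameras' cell
  residuals within an individual are exact negatives of each other. The
  within-individual block scheme is calibrated: its measured type-I rate at
  nominal 0.05 sits inside the binomial 95% interval in the test suite.

Both schemes are deterministic under a fixed seed.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes, per
individual: a smooth shape effect on the template (i.i.d. Gaussian vertex
offsets, smoothed by a 3-ring mesh-graph neighborhood average so anatomy is
spatially coherent); a signed camera-bias displacement along vertex normals
applied to the second camera only; per replicate, i.i.d. technical noise
plus movement noise scaled by a per-vertex mask (regions standing in for
the eyes and mouth, zero in mannequin mode), then a random rigid nuisance
motion (default 5° rotation SD, 10 mm translation SD); per registration,
i.i.d. registration noise *in the replicate's frame* — registrations do not
move the coordinate space, which is what legitimizes the
no-superimposition precision computation. Identical spec + seed is
bit-reproducible.

Closed-form expectations: a registration's deviation from the mean of M has
per-coordinate variance σ_reg²(M−1)/M, so expected precision is
√((M−1)/M)·E(χ₃)·σ_reg with E(χ₃)=2√(2/π)≈1.5958. A registration-averaged
replicate carries variance σ_tech² + w²σ_part² + σ_reg²/M at mask weight w,
giving expected replicate error √((R−1)/R)·E(χ₃)·√(σ_tech²+w²σ_part²+σ_reg²/M);
GPA absorbs only 6 of 3V degrees of freedom, a negligible bias at the
vertex counts used (V ≥ 500).

Default parameters mirror a two-camera facial study at the magnitudes such
studies report: σ_reg = 0.10 mm (implying ~0.13 mm precision), σ_tech =
0.25 mm, σ_part = 0.30 mm localized, bias amplitude 0.5 mm, individual
shape SD 2 mm, n = 35 individuals, R = M = 3. Test and acceptance runs use
smaller V (642–1024 vertices) and fewer individuals, sizes at which the
chi-form expectations hold to within the stochastic tolerances asserted.

What the generator does **not** model: point-cloud density differences
between camera systems (only their downstream noise consequence), texture,
non-rigid movement such as expressions (movement is i.i.d. within masked
regions, not coherent muscle action), registration failure modes
(correspondence slippage is i.i.d. noise here), and photorealistic facial
geometry (templates are spheres or a parametric face-like patch). Passing
recovery tests therefore validate the pipeline's *estimators* under the
assumed error structure, not the behavior of any particular camera or
registration toolbox on real faces.

## Numerical and design choices

* Orthogonality of rotations is enforced to 1e-8 on input transforms;
  no-scaling preserves centroid size to 1e-10 relative (tested).
* Coordinate files are plain delimited text (whitespace or comma), mm
  assumed; writes use 17 significant digits so read-back is bit-exact.
  Field CSVs are re-read with pandas' round-trip float parser for the same
  reason.
* Scalar-field heatmaps are written as ASCII PLY with a per-vertex
  `quality` property (plus a tidy CSV); signed fields note the diverging
  color convention in metadata.
* Template meshes must arrive triangulated; ASCII OBJ/PLY sources are
  scanned for polygon faces before loading because general mesh loaders
  silently triangulate quads. Isolated vertices are flagged on load and are
  an error where normals are required.
* Unbalanced sets are permitted by the error stages (cells weighted by
  their own M/R) but rejected by the ANOVA, which requires the full crossed
  design.
* The discussion-level "participant minus technical" subtraction is a
  scalar afterthought, not a pipeline stage, and is deliberately not
  implemented as one.

## Known limitations

* The ANOVA engine covers exactly the two balanced nested formulas above —
  it is not a general linear-model engine, has no covariates, and no
  unbalanced Type III refitting.
* The label-permutation Camera test is exact but low-resolution below ~7
  individuals; use the residual scheme there.
* Sparse-landmark analyses are modeled as vertex subsets of the dense
  correspondence; independently placed anatomical landmarks with their own
  observer error are out of scope.
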