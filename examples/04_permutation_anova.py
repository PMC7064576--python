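"""Partitioning form variation: nested permutation Procrustes ANOVA.

Simulates a study with a camera bias confined to a small surface region,
then contrasts two analyses of the same data: the full dense-configuration
ANOVA (camera fixed; individual, replicate, registration random and
nested) versus the same model on a 19-landmark sparse subset that misses
the biased region — showing why dense correspondence can detect a
localized between-camera difference that sparse landmarks cannot.
"""

from morphoqc import (
    SyntheticSpec,
    collapse_registrations,
    flatten_response,
    make_template,
    nested_anova,
    simulate_hierarchy,
    sparse_landmark_indices,
    vertex_rings_mask,
)

mesh = make_template("sphere", 642)
bias_region = vertex_rings_mask(mesh, [40], rings=1)  # ~1% of vertices
sparse_idx = sparse_landmark_indices(mesh.n_vertices, 19, exclude=bias_region)

spec = SyntheticSpec(
    template=mesh,
    n_individuals=4,
    R=3,
    M=2,
    sigma_reg=0.05,
    sigma_tech=0.1,
    sigma_part=0.0,
    bias_amplitude=0.5,
    bias_field=bias_region,
    individual_shape_sd=1.0,
    seed=4,
)
cset, _ = simulate_hierarchy(spec)

Y, factors = flatten_response(cset, aligned=False)  # joint constrained GPA first
dense = nested_anova(Y, factors, formula="dense", n_perm=100, seed=10, scheme="residuals")
print("dense configurations (all vertices):")
print(dense.to_frame().to_string(index=False))

sparse_set = collapse_registrations(cset).vertex_subset(sparse_idx)
Ys, fs = flatten_response(sparse_set, aligned=False)
sparse = nested_anova(Ys, fs, formula="sparse", n_perm=100, seed=10, scheme="residuals")
print("\n19-landmark subset avoiding the biased region:")
print(sparse.to_frame().to_string(index=False))

pd_, ps_ = dense["Camera"]["p_perm"], sparse["Camera"]["p_perm"]
print(f"\nCamera term: dense p = {pd_:.3f}, sparse p = {ps_:.3f}")
print("A localized camera bias is visible to the dense design but invisible "
      "to sparse landmarks placed outside the affected region.")
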