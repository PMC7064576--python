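"""Ordinary and generalized Procrustes alignment with scale and reflection toggles.

Form (size-and-shape) analyses of dense facial configurations keep size and
forbid improper rotations, so both toggles default to off: alignment is then
a rigid motion only. The ordinary problem is solved in closed form via the
SVD of the cross-covariance (Kabsch); the reflection constraint negates the
smallest singular direction when the unconstrained optimum is improper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DimensionError, LandmarkConfiguration, as_coords

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform x -> scale * x @ rotation + translation.

    ``rotation`` acts on row-vector coordinates from the right; with
    reflection disabled det(rotation) = +1, with scaling disabled scale = 1.
    """

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).ravel()
        if R.shape != (3, 3) or t.shape != (3,):
            raise DimensionError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def is_proper(self) -> bool:
        return float(np.linalg.det(self.rotation)) > 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(coords) @ self.rotation + self.translation


def _constrained_rotation(
    H: np.ndarray, allow_reflection: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal (or proper-rotation) maximizer of trace(R^T H) from SVD of H.

    Returns (rotation acting from the right on row vectors, adjusted singular
    values). With reflections forbidden and an improper unconstrained optimum,
    the smallest singular direction is negated (ties broken by always taking
    the last column, where numpy orders singular values descending).
    """
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if allow_reflection or d > 0:
        return U @ Vt, S
    flip = np.ones(3)
    flip[-1] = -1.0
    S_adj = S * flip
    return (U * flip) @ Vt, S_adj


def opa_align(
    moving: LandmarkConfiguration | np.ndarray,
    fixed: LandmarkConfiguration | np.ndarray,
    allow_scale: bool = False,
    allow_reflection: bool = False,
) -> tuple[RigidTransform, LandmarkConfiguration]:
    """Superimpose ``moving`` onto ``fixed`` by least squares.

    Minimizes the sum of squared distances of the transformed moving
    configuration to the fixed one over translations, rotations and — only
    when the corresponding toggle is on — scalings and reflections.
    Translation is handled by centroid matching.

    Returns the optimal transform and the transformed configuration.
    """
    X = as_coords(moving)
    Y = as_coords(fixed)
    if X.shape != Y.shape:
        raise DimensionError(
            f"configuration shapes differ: {X.shape} vs {Y.shape}"
        )
    if X.shape[0] < 3:
        raise ValueError("need at least 3 landmarks for a 3D superimposition")

    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mu_x, Y - mu_y
    H = Xc.T @ Yc
    if np.linalg.matrix_rank(H, tol=1e-12 * max(1.0, float(np.abs(H).max()))) < 2:
        warnings.warn(
            "degenerate (rank-deficient) configurations: the optimal rotation "
            "is not unique; returning one constrained solution",
            stacklevel=2,
        )
    R, S_adj = _constrained_rotation(H, allow_reflection)

    if allow_scale:
        denom = float((Xc**2).sum())
        scale = float(S_adj.sum()) / denom if denom > 0 else 1.0
        scale = max(scale, np.finfo(float).tiny)
    else:
        scale = 1.0

    translation = mu_y - scale * mu_x @ R
    transform = RigidTransform(rotation=R, translation=translation, scale=scale)
    return transform, LandmarkConfiguration(transform.apply(X))


@dataclass
class GpaResult:
    """Aligned configurations, their consensus, and per-input transforms.

    ``objective_history`` records the total sum of squared deviations from
    the consensus after each iteration; the scheme guarantees it is
    non-increasing.
    """

    aligned: list[LandmarkConfiguration]
    consensus: LandmarkConfiguration
    transforms: list[RigidTransform]
    iterations_run: int
    converged: bool
    objective_history: list[float]


def gpa(
    configs: list[LandmarkConfiguration | np.ndarray],
    allow_scale: bool = False,
    allow_reflection: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GpaResult:
    """Generalized Procrustes alignment of two or more configurations.

    Iterative scheme: center all configurations, initialize the consensus as
    the first centered configuration, then repeatedly superimpose each
    configuration on the consensus and recompute the consensus as their
    arithmetic mean, until the RMS vertex displacement of the consensus drops
    below ``tol`` (mm) or ``max_iter`` is reached. Non-convergence sets
    ``converged=False`` without raising.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    coords = [as_coords(c) for c in configs]
    V = coords[0].shape[0]
    for c in coords[1:]:
        if c.shape[0] != V:
            raise DimensionError(
                f"configurations have differing landmark counts: {V} vs {c.shape[0]}"
            )

    centered = [c - c.mean(axis=0) for c in coords]
    consensus = centered[0].copy()
    aligned = centered
    converged = False
    iterations = 0
    objective_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        aligned = []
        for c in centered:
            _, a = opa_align(
                c, consensus, allow_scale=allow_scale, allow_reflection=allow_reflection
            )
            aligned.append(a.coords)
        new_consensus = np.mean(aligned, axis=0)
        objective_history.append(
            float(sum(((a - new_consensus) ** 2).sum() for a in aligned))
        )
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break

    transforms = []
    final_aligned = []
    for orig, a in zip(coords, aligned):
        tfm, a2 = opa_align(
            orig, consensus, allow_scale=allow_scale, allow_reflection=allow_reflection
        )
        transforms.append(tfm)
        final_aligned.append(a2)
    consensus = np.mean([a.coords for a in final_aligned], axis=0)

    return GpaResult(
        aligned=final_aligned,
        consensus=LandmarkConfiguration(consensus),
        transforms=transforms,
        iterations_run=iterations,
        converged=converged,
        objective_history=objective_history,
    )
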