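"""Vertex normals and signed displacement along them.

The between-camera difference field has a direction as well as a magnitude:
projecting the difference vector onto the local surface normal separates
outward displacement (positive) from inward recession (negative). Normals
are evaluated on the reference ("from") configuration using the template
triangulation, as the area-weighted average of incident face normals, with
orientation taken from the face winding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config import DimensionError, LandmarkConfiguration, PerLandmarkField, as_coords
from .io import TemplateMesh

_DEGENERATE_AREA = 1e-12


@dataclass(frozen=True)
class VertexNormals:
    """Unit outward normals, one per template vertex."""

    normals: np.ndarray

    def __post_init__(self) -> None:
        normals = np.asarray(self.normals, dtype=float)
        if normals.ndim != 2 or normals.shape[1] != 3:
            raise DimensionError(f"normals must be V x 3, got {normals.shape}")
        norms = np.linalg.norm(normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("vertex normals are not unit length")
        object.__setattr__(self, "normals", normals)

    def __len__(self) -> int:
        return self.normals.shape[0]


def compute_vertex_normals(
    mesh: TemplateMesh, at: LandmarkConfiguration | np.ndarray | None = None
) -> VertexNormals:
    """Area-weighted vertex normals of the template triangulation.

    Normals are computed on the supplied coordinates (defaulting to the
    template's own vertices): each face contributes its unnormalized cross
    product — whose magnitude is twice the face area, so plain accumulation
    is area weighting — to its three corners. Zero-area faces are excluded
    with a warning; a vertex left with no contribution (isolated, or incident
    only to degenerate faces) is an error.
    """
    coords = mesh.vertices if at is None else as_coords(at)
    if coords.shape[0] != mesh.n_vertices:
        raise DimensionError(
            f"configuration has {coords.shape[0]} landmarks but mesh has "
            f"{mesh.n_vertices} vertices"
        )
    faces = mesh.faces
    v0, v1, v2 = coords[faces[:, 0]], coords[faces[:, 1]], coords[faces[:, 2]]
    face_cross = np.cross(v1 - v0, v2 - v0)  # |.| = 2 * area
    areas = 0.5 * np.linalg.norm(face_cross, axis=1)
    degenerate = areas < _DEGENERATE_AREA
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-area face(s) excluded from normals",
            stacklevel=2,
        )
        face_cross = face_cross[~degenerate]
        faces = faces[~degenerate]

    accum = np.zeros_like(coords)
    for k in range(3):
        np.add.at(accum, faces[:, k], face_cross)
    norms = np.linalg.norm(accum, axis=1)
    dead = np.flatnonzero(norms < _DEGENERATE_AREA)
    if dead.size:
        raise ValueError(
            f"vertices with no valid incident face (cannot orient a normal): "
            f"{dead.tolist()[:20]}{'...' if dead.size > 20 else ''}"
        )
    return VertexNormals(normals=accum / norms[:, None])


def signed_displacement(
    from_config: LandmarkConfiguration | np.ndarray,
    to_config: LandmarkConfiguration | np.ndarray,
    normals: VertexNormals,
) -> PerLandmarkField:
    """Signed projection of (to - from) onto the vertex normals, in mm.

    Positive values mean the "to" configuration sits outward of the "from"
    configuration along the local normal. The caller must supply mutually
    aligned configurations (e.g. from :func:`morphoqc.errors.camera_error`).
    """
    A = as_coords(from_config)
    B = as_coords(to_config)
    if A.shape != B.shape or A.shape[0] != len(normals):
        raise DimensionError(
            f"shape mismatch: from {A.shape}, to {B.shape}, normals {len(normals)}"
        )
    values = np.einsum("ij,ij->i", B - A, normals.normals)
    return PerLandmarkField(values=values, kind="normal_displacement", units="mm (signed)")


def average_signed_fields(fields: list[PerLandmarkField]) -> PerLandmarkField:
    """Elementwise mean of signed displacement fields (sign preserved)."""
    if not fields:
        raise ValueError("cannot average an empty list of fields")
    kinds = {f.kind for f in fields}
    if kinds != {"normal_displacement"}:
        raise ValueError(f"expected only normal_displacement fields, got kinds {kinds}")
    lengths = {len(f) for f in fields}
    if len(lengths) != 1:
        raise DimensionError(f"fields have differing lengths: {sorted(lengths)}")
    values = np.mean([f.values for f in fields], axis=0)
    return PerLandmarkField(values=values, kind="normal_displacement", units=fields[0].units)


def normalize_for_display(field: PerLandmarkField) -> PerLandmarkField:
    """Divide by max |value| for unit-free plotting; stored analyses keep mm."""
    peak = float(np.abs(field.values).max())
    if peak == 0:
        return field
    return PerLandmarkField(
        values=field.values / peak, kind=field.kind, units="relative"
    )
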