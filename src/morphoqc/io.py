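"""Reading and writing landmark configurations, manifests, meshes and fields.

File conventions
----------------
* Coordinate files: plain delimited text, one landmark per row, three columns
  (x y z) in mm, whitespace- or comma-separated, header lines starting with
  ``#`` ignored. Units are assumed to be mm.
* Manifest: CSV with header ``individual,camera,replicate,registration,file``;
  file paths are resolved relative to the manifest's directory.
* Template meshes: OBJ or PLY triangle meshes (read through trimesh).
* Scalar fields: a tidy CSV (vertex, value; 0-based vertex indices) plus an
  ASCII PLY carrying the value as a per-vertex ``quality`` property so any
  mesh viewer can color-map it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .config import (
    ConfigurationSet,
    DimensionError,
    HierarchyKey,
    LandmarkConfiguration,
    PerLandmarkField,
)

MANIFEST_COLUMNS = ["individual", "camera", "replicate", "registration", "file"]


class ManifestError(ValueError):
    """Malformed hierarchy manifest."""


@dataclass(frozen=True)
class TemplateMesh:
    """Shared triangulation over the V landmark vertices.

    Carrier of vertex normals and of heatmap geometry; ``vertices`` provide
    the reference coordinates, ``faces`` the triangle connectivity in the
    landmark vertex order used by every configuration.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        vertices = np.asarray(self.vertices, dtype=float)
        faces = np.asarray(self.faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise DimensionError(f"vertices must be V x 3, got {vertices.shape}")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError(
                f"faces must be F x 3 triangles, got shape {faces.shape}; "
                "triangulate the mesh before loading"
            )
        if faces.min(initial=0) < 0 or faces.max(initial=-1) >= len(vertices):
            raise ValueError("face indices out of range [0, V)")
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @property
    def isolated_vertices(self) -> np.ndarray:
        """Indices of vertices referenced by no face."""
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.faces.ravel()] = True
        return np.flatnonzero(~used)

    @property
    def winding_consistent(self) -> bool:
        """True when adjacent faces agree on orientation (orientable winding)."""
        tm = trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False, validate=False
        )
        return bool(tm.is_winding_consistent)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False, validate=False
        )


def load_configuration(path: str | Path) -> LandmarkConfiguration:
    """Read one coordinate file (x y z per row, whitespace or comma separated)."""
    path = Path(path)
    try:
        coords = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError:
        coords = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
    if coords.shape[1] != 3:
        raise DimensionError(
            f"{path}: expected 3 coordinate columns, found {coords.shape[1]}"
        )
    return LandmarkConfiguration(coords)


def save_configuration(
    config: LandmarkConfiguration, path: str | Path
) -> Path:
    """Write a coordinate file; full double precision, round-trip safe."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, config.coords, fmt="%.17g")
    return path


def load_manifest(manifest_path: str | Path) -> ConfigurationSet:
    """Load the configuration hierarchy declared by a manifest CSV.

    The manifest must have columns individual, camera, replicate,
    registration, file. Every referenced file must exist and share one
    landmark count; duplicate hierarchy keys are rejected.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, dtype={"individual": str, "camera": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(
            f"{manifest_path}: manifest is missing columns {missing}; "
            f"expected header {','.join(MANIFEST_COLUMNS)}"
        )
    if len(table) == 0:
        raise ManifestError(f"{manifest_path}: manifest declares no configurations")

    base = manifest_path.parent
    cset = ConfigurationSet()
    for row_no, row in enumerate(table.itertuples(index=False), start=2):
        key = HierarchyKey(
            individual=str(row.individual),
            camera=str(row.camera),
            replicate=int(row.replicate),
            registration=int(row.registration),
        )
        file_path = Path(row.file)
        if not file_path.is_absolute():
            file_path = base / file_path
        if not file_path.exists():
            raise ManifestError(
                f"{manifest_path} line {row_no}: file not found: {file_path}"
            )
        config = load_configuration(file_path)
        try:
            cset.add(key, config)
        except DimensionError as exc:
            raise DimensionError(f"{manifest_path} line {row_no}: {exc}") from exc
        except ValueError as exc:
            raise ManifestError(f"{manifest_path} line {row_no}: {exc}") from exc
    return cset


def write_manifest(
    rows: list[tuple[HierarchyKey, str]], manifest_path: str | Path
) -> Path:
    """Write a manifest CSV from (key, relative file path) pairs."""
    manifest_path = Path(manifest_path)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        [
            {
                "individual": k.individual,
                "camera": k.camera,
                "replicate": k.replicate,
                "registration": k.registration,
                "file": f,
            }
            for k, f in rows
        ],
        columns=MANIFEST_COLUMNS,
    )
    table.to_csv(manifest_path, index=False)
    return manifest_path


def _reject_non_triangular(mesh_path: Path) -> None:
    """Scan ASCII OBJ/PLY sources for polygon faces with more than 3 vertices.

    trimesh silently triangulates quads on load; the analysis template must
    be authored triangulated so the landmark triangulation is the one the
    user intends. Binary PLY is left to the loader.
    """
    suffix = mesh_path.suffix.lower()
    if suffix == ".obj":
        with open(mesh_path) as fh:
            for line in fh:
                if line.startswith("f ") and len(line.split()) > 4:
                    raise ValueError(
                        f"{mesh_path}: mesh has non-triangular faces; "
                        "triangulate before loading"
                    )
    elif suffix == ".ply":
        with open(mesh_path, "rb") as fh:
            header = fh.read(2048).decode("ascii", errors="ignore")
        if "format ascii" not in header:
            return
        n_vert = n_face = 0
        for line in header.splitlines():
            if line.startswith("element vertex"):
                n_vert = int(line.split()[2])
            elif line.startswith("element face"):
                n_face = int(line.split()[2])
        with open(mesh_path) as fh:
            for line in fh:
                if line.strip() == "end_header":
                    break
            for _ in range(n_vert):
                fh.readline()
            for _ in range(n_face):
                tokens = fh.readline().split()
                if tokens and int(tokens[0]) != 3:
                    raise ValueError(
                        f"{mesh_path}: mesh has non-triangular faces; "
                        "triangulate before loading"
                    )


def load_template(mesh_path: str | Path) -> TemplateMesh:
    """Load a triangle mesh (OBJ or PLY) as the analysis template."""
    mesh_path = Path(mesh_path)
    _reject_non_triangular(mesh_path)
    loaded = trimesh.load(mesh_path, process=False, validate=False, force="mesh")
    faces = np.asarray(loaded.faces)
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError(
            f"{mesh_path}: mesh is not triangulated; triangulate before loading"
        )
    mesh = TemplateMesh(vertices=np.asarray(loaded.vertices), faces=faces)
    if len(mesh.isolated_vertices):
        warnings.warn(
            f"{mesh_path}: {len(mesh.isolated_vertices)} isolated vertices "
            "(referenced by no face)",
            stacklevel=2,
        )
    return mesh


def check_template_matches(mesh: TemplateMesh, n_landmarks: int) -> None:
    """The template's vertex count must equal the analysis landmark count V."""
    if mesh.n_vertices != n_landmarks:
        raise DimensionError(
            f"template has {mesh.n_vertices} vertices but configurations "
            f"have {n_landmarks} landmarks"
        )


def export_field(
    mesh: TemplateMesh, field: PerLandmarkField, out_path: str | Path
) -> tuple[Path, Path]:
    """Write a per-landmark scalar field as tidy CSV + ASCII PLY heatmap.

    ``out_path`` is the stem; ``<stem>.csv`` and ``<stem>.ply`` are written.
    The PLY stores the value in a per-vertex ``quality`` property. Signed
    fields note the diverging color convention in the CSV header.
    """
    if len(field) != mesh.n_vertices:
        raise DimensionError(
            f"field has {len(field)} values but mesh has {mesh.n_vertices} vertices"
        )
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    csv_path = out_path.with_suffix(".csv")
    with open(csv_path, "w") as fh:
        fh.write("# vertex indices are 0-based\n")
        fh.write(f"# kind={field.kind} units={field.units}\n")
        if field.signed:
            fh.write("# signed field: use a symmetric diverging color map\n")
        fh.write("vertex,value\n")
        for i, v in enumerate(field.values):
            fh.write(f"{i},{v:.17g}\n")

    ply_path = out_path.with_suffix(".ply")
    with open(ply_path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment morphoqc field kind={field.kind} units={field.units}\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), q in zip(mesh.vertices, field.values):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {q:.9g}\n")
        for a, b, c in mesh.faces:
            fh.write(f"3 {a} {b} {c}\n")
    return csv_path, ply_path


def read_field_csv(csv_path: str | Path) -> PerLandmarkField:
    """Read back a tidy field CSV written by :func:`export_field`."""
    kind, units = "precision", "mm"
    with open(csv_path) as fh:
        for line in fh:
            if line.startswith("# kind="):
                parts = line[2:].split()
                kind = parts[0].split("=", 1)[1]
                units = parts[1].split("=", 1)[1]
            if not line.startswith("#"):
                break
    table = pd.read_csv(csv_path, comment="#", float_precision="round_trip")
    values = table.sort_values("vertex")["value"].to_numpy()
    return PerLandmarkField(values=values, kind=kind, units=units)


def read_field_ply(ply_path: str | Path) -> tuple[TemplateMesh, np.ndarray]:
    """Read an ASCII PLY heatmap; returns the mesh and the per-vertex scalars."""
    with open(ply_path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{ply_path}: not a PLY file")
        n_vert = n_face = 0
        vertex_props: list[str] = []
        element = None
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "element":
                element = tokens[1]
                if element == "vertex":
                    n_vert = int(tokens[2])
                elif element == "face":
                    n_face = int(tokens[2])
            elif tokens[0] == "property" and element == "vertex":
                vertex_props.append(tokens[-1])
            elif tokens[0] == "end_header":
                break
        if "quality" not in vertex_props:
            raise ValueError(f"{ply_path}: no per-vertex quality property")
        qi = vertex_props.index("quality")
        data = np.array(
            [[float(t) for t in fh.readline().split()] for _ in range(n_vert)]
        )
        faces = np.array(
            [[int(t) for t in fh.readline().split()[1:4]] for _ in range(n_face)],
            dtype=np.int64,
        )
    mesh = TemplateMesh(vertices=data[:, :3], faces=faces)
    return mesh, data[:, qi]
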