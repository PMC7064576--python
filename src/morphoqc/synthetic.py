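"""Synthetic configuration hierarchies with known error structure.

Real dense facial datasets with repeated captures on two camera systems are
rarely shareable, so every pipeline stage here is exercised against
generated hierarchies whose ground truth is known in closed form. The
generative model mirrors the nested study design — individuals, two
cameras, R replicate captures per camera, M registration iterations per
capture — with:

* a smooth per-individual shape effect on a shared template;
* a smooth signed camera-bias displacement applied along vertex normals to
  the second camera only (systematic between-camera difference);
* i.i.d. technical noise per replicate, plus spatially localized
  "participant movement" noise concentrated in designated regions standing
  in for the eyes and mouth (zero in mannequin mode);
* a random rigid nuisance motion per replicate (captures land in arbitrary
  coordinate frames);
* i.i.d. registration noise per registration iteration, *sharing the
  replicate's frame* — repeated registrations of one image do not move the
  coordinate space, which is what makes the no-superimposition precision
  computation valid.

Closed-form expectations (derived in :func:`expected_errors`) let recovery
tests compare pipeline estimates against analytic truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy import sparse

from .config import ConfigurationSet, HierarchyKey, LandmarkConfiguration
from .io import TemplateMesh, save_configuration, write_manifest
from .normals import compute_vertex_normals

#: mean of a chi distribution with 3 degrees of freedom: the expected length
#: of a standard trivariate Gaussian vector, E|N(0, I_3)| = 2 sqrt(2/pi).
CHI3_MEAN = 2.0 * np.sqrt(2.0 / np.pi)

DEFAULT_CAMERAS = ("camera_a", "camera_b")


def make_template(kind: str = "sphere", n_vertices: int = 642) -> TemplateMesh:
    """Deterministic test template: an icosphere or an open face-like patch.

    ``sphere`` picks the icosphere subdivision whose vertex count is nearest
    the request (12, 42, 162, 642, 2562, ...), at radius 90 mm (head-like
    scale). ``face_like`` builds an open paraboloid patch with a raised nose
    bump and two eye depressions on a triangulated grid, choosing the grid
    nearest the requested vertex count. If the exact count is unreachable a
    notice is issued and the nearest achievable mesh returned.
    """
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices")
    if kind == "sphere":
        # icosphere counts: 10 * 4**s + 2
        subdiv = int(round(np.log(max((n_vertices - 2) / 10.0, 1.0)) / np.log(4.0)))
        subdiv = max(subdiv, 0)
        mesh = trimesh.creation.icosphere(subdivisions=subdiv, radius=90.0)
        if mesh.vertices.shape[0] != n_vertices:
            warnings.warn(
                f"icosphere cannot hit {n_vertices} vertices exactly; "
                f"returning nearest ({mesh.vertices.shape[0]})",
                stacklevel=2,
            )
        return TemplateMesh(vertices=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))
    if kind == "face_like":
        m = int(round(np.sqrt(n_vertices)))
        if m * m != n_vertices:
            warnings.warn(
                f"face_like grid cannot hit {n_vertices} vertices exactly; "
                f"returning nearest ({m * m})",
                stacklevel=2,
            )
        xs = np.linspace(-60.0, 60.0, m)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        # convex facial shell + nose bump - two eye sockets (mm)
        z = 40.0 - (gx**2 + gy**2) / 180.0
        z += 18.0 * np.exp(-((gx / 12.0) ** 2 + (gy / 16.0) ** 2))
        for ex in (-22.0, 22.0):
            z -= 6.0 * np.exp(-(((gx - ex) / 9.0) ** 2 + ((gy - 18.0) / 7.0) ** 2))
        vertices = np.column_stack([gx.ravel(), gy.ravel(), z.ravel()])
        faces = []
        for i in range(m - 1):
            for j in range(m - 1):
                a, b, c, d = (
                    i * m + j,
                    i * m + j + 1,
                    (i + 1) * m + j,
                    (i + 1) * m + j + 1,
                )
                faces.append([a, b, d])
                faces.append([a, d, c])
        return TemplateMesh(vertices=vertices, faces=np.asarray(faces, dtype=np.int64))
    raise ValueError(f"unknown template kind {kind!r}")


def _adjacency_matrix(mesh: TemplateMesh) -> sparse.csr_matrix:
    """Symmetric vertex adjacency (edges of the triangulation)."""
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    data = np.ones(len(i))
    A = sparse.coo_matrix((data, (i, j)), shape=(mesh.n_vertices, mesh.n_vertices))
    A = A.tocsr()
    A.data[:] = 1.0
    return A


def vertex_rings_mask(
    mesh: TemplateMesh, seed_vertices: list[int], rings: int = 3
) -> np.ndarray:
    """Binary mask marking vertices within ``rings`` edge hops of any seed."""
    A = _adjacency_matrix(mesh)
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[list(seed_vertices)] = True
    for _ in range(rings):
        mask = mask | (A @ mask.astype(float) > 0)
    return mask.astype(float)


def default_movement_mask(mesh: TemplateMesh, rings: int = 4) -> np.ndarray:
    """Movement-prone regions standing in for the eyes and mouth.

    Three seed vertices are picked deterministically in the upper-left,
    upper-right ("eyes") and lower-middle ("mouth") of the template's
    bounding box; the mask is 1 within a few rings of each and 0 elsewhere.
    """
    v = mesh.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    span = hi - lo
    targets = [
        lo + span * np.array([0.3, 0.75, 0.8]),
        lo + span * np.array([0.7, 0.75, 0.8]),
        lo + span * np.array([0.5, 0.22, 0.8]),
    ]
    seeds = [int(np.argmin(((v - t) ** 2).sum(axis=1))) for t in targets]
    return vertex_rings_mask(mesh, seeds, rings=rings)


def sparse_landmark_indices(
    n_vertices: int, n_landmarks: int = 19, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Deterministic evenly spread vertex indices for a sparse-landmark subset.

    ``exclude`` is an optional boolean/weight mask of vertices to avoid
    (e.g. a localized bias region the sparse landmarks should miss).
    """
    candidates = np.arange(n_vertices)
    if exclude is not None:
        candidates = candidates[np.asarray(exclude, dtype=float) <= 0]
    if len(candidates) < n_landmarks:
        raise ValueError(
            f"only {len(candidates)} candidate vertices for {n_landmarks} landmarks"
        )
    picks = np.linspace(0, len(candidates) - 1, n_landmarks).round().astype(np.int64)
    return candidates[picks]


def smooth_field(mesh: TemplateMesh, values: np.ndarray, rings: int = 3) -> np.ndarray:
    """Neighborhood average over the mesh graph, applied ``rings`` times.

    Turns i.i.d. vertex noise into a spatially coherent field, the way real
    anatomical variation and camera artifacts are coherent.
    """
    A = _adjacency_matrix(mesh) + sparse.eye(mesh.n_vertices, format="csr")
    P = sparse.diags(1.0 / np.asarray(A.sum(axis=1)).ravel()) @ A
    out = np.asarray(values, dtype=float)
    for _ in range(rings):
        out = P @ out
    return out


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study (all lengths in mm).

    Defaults mirror the magnitudes of a two-camera facial repeatability
    study: registration noise well below capture noise, movement noise
    localized, and a sub-millimetre systematic camera bias.
    """

    template: TemplateMesh
    n_individuals: int = 35
    R: int = 3  # replicate captures per camera
    M: int = 3  # registration iterations per capture
    sigma_reg: float = 0.10  # registration noise SD per coordinate
    sigma_tech: float = 0.25  # technical (capture) noise SD per coordinate
    sigma_part: float = 0.30  # participant-movement noise SD (masked)
    movement_mask: np.ndarray | None = None  # length-V weights in [0, 1]
    bias_amplitude: float = 0.5  # camera-bias displacement scale
    bias_field: np.ndarray | None = None  # length-V signed weights in [-1, 1]
    individual_shape_sd: float = 2.0  # smoothed per-individual shape effect
    rotation_sd_deg: float = 5.0  # nuisance rigid motion per replicate
    translation_sd: float = 10.0
    cameras: tuple[str, str] = DEFAULT_CAMERAS
    seed: int = 0

    def __post_init__(self) -> None:
        V = self.template.n_vertices
        for name in ("sigma_reg", "sigma_tech", "sigma_part", "bias_amplitude",
                     "individual_shape_sd", "rotation_sd_deg", "translation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_individuals < 1 or self.R < 1 or self.M < 1:
            raise ValueError("n_individuals, R and M must be >= 1")
        if self.movement_mask is None:
            self.movement_mask = np.zeros(V)
        self.movement_mask = np.asarray(self.movement_mask, dtype=float)
        if self.movement_mask.shape != (V,) or (
            self.movement_mask.min() < 0 or self.movement_mask.max() > 1
        ):
            raise ValueError("movement_mask must be length V with weights in [0, 1]")
        if self.bias_field is None:
            self.bias_field = np.zeros(V)
        self.bias_field = np.asarray(self.bias_field, dtype=float)
        if self.bias_field.shape != (V,) or np.abs(self.bias_field).max() > 1 + 1e-12:
            raise ValueError("bias_field must be length V with weights in [-1, 1]")


@dataclass
class ExpectedErrors:
    """Closed-form expectations for the pipeline's headline estimates (mm)."""

    precision: float
    replicate_error_unmasked: float
    replicate_error_masked: float
    mean_signed_displacement: float


@dataclass
class SyntheticTruth:
    """Realized generator state: what the estimates should recover."""

    spec: SyntheticSpec
    base_shapes: dict[str, np.ndarray] = field(default_factory=dict)
    bias_displacement: np.ndarray | None = None  # signed mm along normals, camera 2
    expected: ExpectedErrors | None = None


def expected_errors(spec: SyntheticSpec) -> ExpectedErrors:
    """Analytic expectations under the generative model.

    *Precision.* Within one image, registration m is the replicate surface
    plus e_m ~ N(0, sigma_reg^2 I_3) per vertex. The deviation of e_m from
    the mean of M such draws is Gaussian with per-coordinate variance
    sigma_reg^2 (M-1)/M, so its expected length is
    sqrt((M-1)/M) * E(chi_3) * sigma_reg with E(chi_3) = 2 sqrt(2/pi).

    *Replicate error.* A registration-averaged replicate carries capture
    noise of per-coordinate variance sigma_tech^2 + w^2 sigma_part^2 (w the
    movement-mask weight at the vertex) plus averaged registration noise
    sigma_reg^2 / M; rigid nuisance motions are removed by GPA (6 degrees of
    freedom against 3V, a negligible absorption at the vertex counts used),
    leaving the same chi-form with R in place of M.
    """
    prec = np.sqrt((spec.M - 1) / spec.M) * CHI3_MEAN * spec.sigma_reg

    def rep_err(w: float) -> float:
        var = spec.sigma_tech**2 + (w * spec.sigma_part) ** 2 + spec.sigma_reg**2 / spec.M
        return float(np.sqrt((spec.R - 1) / spec.R) * CHI3_MEAN * np.sqrt(var))

    mean_disp = float(spec.bias_amplitude * np.mean(spec.bias_field))
    return ExpectedErrors(
        precision=float(prec),
        replicate_error_unmasked=rep_err(0.0),
        replicate_error_masked=rep_err(1.0),
        mean_signed_displacement=mean_disp,
    )


def _random_rigid(rng: np.random.Generator, rot_sd_deg: float, trans_sd: float):
    angle = np.deg2rad(rng.normal(0.0, rot_sd_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.normal(0.0, trans_sd, size=3)
    return R, t


def simulate_hierarchy(spec: SyntheticSpec) -> tuple[ConfigurationSet, SyntheticTruth]:
    """Generate a balanced configuration hierarchy under the generative model.

    Identical (spec, seed) pairs produce identical sets.
    """
    rng = np.random.default_rng(spec.seed)
    mesh = spec.template
    V = mesh.n_vertices
    cam_a, cam_b = spec.cameras

    truth = SyntheticTruth(spec=spec)
    cset = ConfigurationSet()
    part_sd = spec.sigma_part * spec.movement_mask  # per-vertex movement SD

    for i in range(spec.n_individuals):
        ind = f"ind{i + 1:03d}"
        base = mesh.vertices.copy()
        if spec.individual_shape_sd > 0:
            effect = rng.normal(0.0, spec.individual_shape_sd, size=(V, 3))
            base = base + smooth_field(mesh, effect, rings=3)
        truth.base_shapes[ind] = base

        normals = compute_vertex_normals(mesh, base).normals
        bias_disp = spec.bias_amplitude * spec.bias_field
        camera_surface = {
            cam_a: base,
            cam_b: base + bias_disp[:, None] * normals,
        }
        if truth.bias_displacement is None:
            truth.bias_displacement = bias_disp.copy()

        for cam in (cam_a, cam_b):
            for r in range(1, spec.R + 1):
                surf = camera_surface[cam] + rng.normal(0.0, spec.sigma_tech, size=(V, 3))
                if spec.sigma_part > 0:
                    surf = surf + rng.normal(size=(V, 3)) * part_sd[:, None]
                R_mat, t = _random_rigid(rng, spec.rotation_sd_deg, spec.translation_sd)
                surf = surf @ R_mat.T + t
                for m in range(1, spec.M + 1):
                    reg = surf + rng.normal(0.0, spec.sigma_reg, size=(V, 3))
                    cset.add(
                        HierarchyKey(ind, cam, r, m), LandmarkConfiguration(reg)
                    )

    truth.expected = expected_errors(spec)
    return cset, truth


def write_dataset(
    cset: ConfigurationSet, truth: SyntheticTruth, out_dir: str | Path
) -> Path:
    """Serialize a simulated set: coordinate files, manifest CSV, truth JSON."""
    out_dir = Path(out_dir)
    (out_dir / "configs").mkdir(parents=True, exist_ok=True)
    rows = []
    for key in cset:
        rel = (
            f"configs/{key.individual}_{key.camera}_r{key.replicate}"
            f"_m{key.registration}.txt"
        )
        save_configuration(cset[key], out_dir / rel)
        rows.append((key, rel))
    write_manifest(rows, out_dir / "manifest.csv")
    exp = truth.expected
    payload = {
        "n_individuals": truth.spec.n_individuals,
        "R": truth.spec.R,
        "M": truth.spec.M,
        "sigma_reg_mm": truth.spec.sigma_reg,
        "sigma_tech_mm": truth.spec.sigma_tech,
        "sigma_part_mm": truth.spec.sigma_part,
        "bias_amplitude_mm": truth.spec.bias_amplitude,
        "seed": truth.spec.seed,
        "expected_precision_mm": exp.precision if exp else None,
        "expected_replicate_error_mm": exp.replicate_error_unmasked if exp else None,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return out_dir
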