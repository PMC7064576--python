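"""Core containers for dense landmark configurations and their hierarchy.

A *quasi-landmark configuration* is one surface image expressed as V template
vertices in anatomical correspondence: row i of every configuration in an
analysis refers to the same template vertex. Correspondence is therefore
positional — there is no landmark-ID remapping anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np


class DimensionError(ValueError):
    """Configurations, meshes or fields with incompatible vertex counts."""


class HierarchyKey(NamedTuple):
    """Position of one configuration in the individual/camera/replicate/registration hierarchy."""

    individual: str
    camera: str
    replicate: int
    registration: int


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One image's dense coordinate set: V landmarks x 3, in mm."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DimensionError(
                f"expected a V x 3 coordinate matrix, got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("configuration contains non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Root sum of squared distances to the centroid (form size, mm)."""
        return float(np.linalg.norm(self.coords - self.centroid))

    def centered(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(self.coords - self.centroid)


def as_coords(config: "LandmarkConfiguration | np.ndarray") -> np.ndarray:
    """Accept either a LandmarkConfiguration or a bare V x 3 array."""
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return LandmarkConfiguration(np.asarray(config, dtype=float)).coords


@dataclass
class ConfigurationSet:
    """All configurations of one analysis, keyed by hierarchy position.

    The set enforces a single landmark count V across entries. ``balanced``
    is true when every individual has every camera x replicate x registration
    cell, the contract required by the ANOVA stage.
    """

    entries: dict[HierarchyKey, LandmarkConfiguration] = field(default_factory=dict)

    def add(self, key: HierarchyKey, config: LandmarkConfiguration) -> None:
        if key in self.entries:
            raise ValueError(f"duplicate hierarchy key {key!r}")
        if self.entries:
            v0 = self.n_landmarks
            if config.n_landmarks != v0:
                raise DimensionError(
                    f"configuration for {key!r} has {config.n_landmarks} landmarks, "
                    f"set has {v0}"
                )
        self.entries[key] = config

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[HierarchyKey]:
        return iter(sorted(self.entries))

    def __getitem__(self, key: HierarchyKey) -> LandmarkConfiguration:
        return self.entries[key]

    @property
    def n_landmarks(self) -> int:
        if not self.entries:
            raise ValueError("empty configuration set has no landmark count")
        return next(iter(self.entries.values())).n_landmarks

    @property
    def individuals(self) -> list[str]:
        return sorted({k.individual for k in self.entries})

    @property
    def cameras(self) -> list[str]:
        return sorted({k.camera for k in self.entries})

    def replicates(self, individual: str, camera: str) -> list[int]:
        return sorted(
            {
                k.replicate
                for k in self.entries
                if k.individual == individual and k.camera == camera
            }
        )

    def registrations(self, individual: str, camera: str, replicate: int) -> list[int]:
        return sorted(
            {
                k.registration
                for k in self.entries
                if k.individual == individual
                and k.camera == camera
                and k.replicate == replicate
            }
        )

    def cell(
        self, individual: str, camera: str, replicate: int
    ) -> list[LandmarkConfiguration]:
        """All registrations of one (individual, camera, replicate) image."""
        keys = [
            k
            for k in sorted(self.entries)
            if k.individual == individual
            and k.camera == camera
            and k.replicate == replicate
        ]
        return [self.entries[k] for k in keys]

    @property
    def balanced(self) -> bool:
        inds, cams = self.individuals, self.cameras
        if not inds or not cams:
            return False
        reps = self.replicates(inds[0], cams[0])
        regs = self.registrations(inds[0], cams[0], reps[0]) if reps else []
        if not reps or not regs:
            return False
        expected = {
            HierarchyKey(i, c, r, m)
            for i in inds
            for c in cams
            for r in reps
            for m in regs
        }
        return set(self.entries) == expected

    def subset(self, **where: object) -> "ConfigurationSet":
        """Subset by any of individual=, camera=, replicate=, registration=."""
        out = ConfigurationSet()
        for k in sorted(self.entries):
            if all(getattr(k, f) == v for f, v in where.items()):
                out.entries[k] = self.entries[k]
        return out

    def vertex_subset(self, indices) -> "ConfigurationSet":
        """Restrict every configuration to the given landmark indices.

        Models a sparse-landmark analysis: the selected rows keep their
        order, so positional correspondence is preserved across the set.
        """
        idx = np.asarray(indices, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("vertex subset is empty")
        if idx.min() < 0 or idx.max() >= self.n_landmarks:
            raise ValueError("vertex subset indices out of range")
        out = ConfigurationSet()
        for k in sorted(self.entries):
            out.entries[k] = LandmarkConfiguration(self.entries[k].coords[idx])
        return out


FieldKind = str  # {"precision", "replicate_error", "camera_error", "normal_displacement"}

_SIGNED_KINDS = {"normal_displacement"}


@dataclass(frozen=True)
class PerLandmarkField:
    """One scalar per template vertex: an error magnitude or a signed displacement."""

    values: np.ndarray
    kind: FieldKind
    units: str = "mm"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(values)):
            raise ValueError("field contains non-finite values")
        if self.kind not in _SIGNED_KINDS and np.any(values < 0):
            raise ValueError(f"magnitude field of kind {self.kind!r} has negative values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def signed(self) -> bool:
        return self.kind in _SIGNED_KINDS


@dataclass(frozen=True)
class SummaryStats:
    """Mean / sample SD / min / max over a set of values (mm)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("summary violates min <= mean <= max")
        if self.sd < 0:
            raise ValueError("summary SD is negative")


def summarize(values: Iterable[float]) -> SummaryStats:
    """Mean, sample SD (n-1 denominator; 0 for a single value), min, max, n."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        mean=float(arr.mean()),
        sd=sd,
        min=float(arr.min()),
        max=float(arr.max()),
        n=int(arr.size),
    )
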