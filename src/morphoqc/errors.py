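"""Hierarchical error decomposition for repeated dense landmark configurations.

Four nested sources of variation are quantified, each in mm at each
quasi-landmark:

* **registration precision** — spread of repeated dense registrations of the
  *same* image around their average; computed without any superimposition,
  because repeated registrations of one image share a coordinate frame;
* **replicate error** — spread of repeated captures of the same subject on
  one camera, after a non-scaled, non-reflected GPA within that subject and
  camera (participant error on live subjects, technical error in
  mannequin mode — same code path, only the input differs);
* **camera error** — distance between a subject's per-camera average
  configurations after pairwise non-scaled, non-reflected alignment.

Each stage yields a per-landmark mean field, per-unit (image or individual)
landmark-averaged values, and summary statistics over the field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    ConfigurationSet,
    LandmarkConfiguration,
    PerLandmarkField,
    SummaryStats,
    summarize,
    as_coords,
)
from .procrustes import gpa


@dataclass
class ErrorReport:
    """Per-landmark field, per-unit landmark means, and summary for one stage."""

    field: PerLandmarkField
    per_unit_values: pd.DataFrame
    summary: SummaryStats
    grouping: str  # "per_image" or "per_individual"


def average_configurations(
    configs: list[LandmarkConfiguration | np.ndarray],
) -> LandmarkConfiguration:
    """Elementwise arithmetic mean of configurations; no alignment performed."""
    if not configs:
        raise ValueError("cannot average an empty list of configurations")
    stack = np.stack([as_coords(c) for c in configs])
    return LandmarkConfiguration(stack.mean(axis=0))


def collapse_registrations(cset: ConfigurationSet) -> ConfigurationSet:
    """Reduce each image to the average of its registration iterations.

    Returns a set with one entry per (individual, camera, replicate), with
    registration index 1 — the replicate-level representation used by the
    replicate-error, camera-error and sparse-landmark analyses.
    """
    from .config import HierarchyKey

    out = ConfigurationSet()
    for ind in cset.individuals:
        for cam in cset.cameras:
            for rep in cset.replicates(ind, cam):
                avg = average_configurations(cset.cell(ind, cam, rep))
                out.add(HierarchyKey(ind, cam, rep, 1), avg)
    return out


def summarize_field(values, grouping: str = "landmarks") -> SummaryStats:
    """Mean, sample SD, min, max over the given values (see config.summarize)."""
    return summarize(values)


def _cell_precision(regs: list[LandmarkConfiguration]) -> np.ndarray:
    """Mean per-landmark distance of each registration to the registrations' mean."""
    stack = np.stack([r.coords for r in regs])  # M x V x 3
    avg = stack.mean(axis=0)
    dists = np.linalg.norm(stack - avg, axis=2)  # M x V
    return dists.mean(axis=0)


def registration_precision(
    cset: ConfigurationSet, camera: str | None = None
) -> ErrorReport:
    """Registration precision per quasi-landmark, without superimposition.

    For each (individual, camera, replicate) image the M registrations are
    averaged elementwise and the Euclidean distance of each registration to
    that average is taken at every landmark, then averaged over the M
    registrations. The field averages these per-image values over all images
    (optionally restricted to one camera); per-unit values are the
    landmark-averaged precision of each image.
    """
    cameras = [camera] if camera is not None else cset.cameras
    per_image_fields = []
    rows = []
    for ind in cset.individuals:
        for cam in cameras:
            for rep in cset.replicates(ind, cam):
                regs = cset.cell(ind, cam, rep)
                if len(regs) < 2:
                    raise ValueError(
                        f"cell (individual={ind!r}, camera={cam!r}, replicate={rep}) "
                        f"has {len(regs)} registration(s); precision needs >= 2"
                    )
                field = _cell_precision(regs)
                per_image_fields.append(field)
                rows.append(
                    {
                        "individual": ind,
                        "camera": cam,
                        "replicate": rep,
                        "value_mm": float(field.mean()),
                    }
                )
    if not per_image_fields:
        raise ValueError("no cells found for the requested camera(s)")
    mean_field = np.mean(per_image_fields, axis=0)
    field = PerLandmarkField(values=mean_field, kind="precision")
    return ErrorReport(
        field=field,
        per_unit_values=pd.DataFrame(rows),
        summary=summarize(field.values),
        grouping="per_image",
    )


def replicate_error(cset: ConfigurationSet, camera: str) -> ErrorReport:
    """Replicate (participant or technical) error for one camera.

    Per individual, each replicate image is represented by the average of its
    registrations; the R replicate averages are aligned by a non-scaled,
    non-reflected GPA *within that individual and camera only*, and the
    per-landmark distance of each aligned replicate to their consensus is
    averaged over replicates. The field averages these per-individual values
    over individuals.
    """
    per_ind_fields = []
    rows = []
    for ind in cset.individuals:
        reps = cset.replicates(ind, camera)
        if len(reps) < 2:
            raise ValueError(
                f"individual {ind!r} has {len(reps)} replicate(s) on camera "
                f"{camera!r}; replicate error needs >= 2"
            )
        rep_avgs = [average_configurations(cset.cell(ind, camera, r)) for r in reps]
        result = gpa(rep_avgs, allow_scale=False, allow_reflection=False)
        consensus = result.consensus.coords
        dists = np.stack(
            [np.linalg.norm(a.coords - consensus, axis=1) for a in result.aligned]
        )
        field = dists.mean(axis=0)
        per_ind_fields.append(field)
        rows.append({"individual": ind, "camera": camera, "value_mm": float(field.mean())})
    mean_field = np.mean(per_ind_fields, axis=0)
    field = PerLandmarkField(values=mean_field, kind="replicate_error")
    return ErrorReport(
        field=field,
        per_unit_values=pd.DataFrame(rows),
        summary=summarize(field.values),
        grouping="per_individual",
    )


@dataclass
class AlignedCameraPair:
    """One individual's per-camera grand averages after mutual rigid alignment."""

    individual: str
    from_camera: str
    to_camera: str
    from_config: LandmarkConfiguration
    to_config: LandmarkConfiguration  # aligned onto from_config's frame


def camera_error(
    cset: ConfigurationSet,
    from_camera: str | None = None,
    to_camera: str | None = None,
) -> tuple[ErrorReport, list[AlignedCameraPair]]:
    """Between-camera error per quasi-landmark, with aligned pairs retained.

    Per individual, each camera is reduced to one grand-average
    configuration: the consensus of a non-scaled, non-reflected GPA over the
    registration-averaged replicates (replicate captures land in arbitrary
    coordinate frames, so they are superimposed before averaging; with a
    single replicate its average is used directly). The two grand averages
    are then aligned by the same constrained superimposition and the
    per-landmark Euclidean distance between the aligned pair is taken.
    Individuals missing a camera are skipped with a warning.

    The aligned pairs are returned for downstream signed normal-displacement
    analysis (from_camera plays the reference role).
    """
    cameras = cset.cameras
    if from_camera is None or to_camera is None:
        if len(cameras) != 2:
            raise ValueError(
                f"set has cameras {cameras}; camera error needs exactly two "
                "(or pass from_camera/to_camera explicitly)"
            )
        from_camera, to_camera = cameras

    per_ind_fields = []
    rows = []
    pairs = []
    skipped = 0
    for ind in cset.individuals:
        grand = {}
        for cam in (from_camera, to_camera):
            reps = cset.replicates(ind, cam)
            if not reps:
                grand = {}
                break
            rep_avgs = [average_configurations(cset.cell(ind, cam, r)) for r in reps]
            if len(rep_avgs) == 1:
                grand[cam] = rep_avgs[0]
            else:
                grand[cam] = gpa(
                    rep_avgs, allow_scale=False, allow_reflection=False
                ).consensus
        if not grand:
            skipped += 1
            continue
        result = gpa(
            [grand[from_camera], grand[to_camera]],
            allow_scale=False,
            allow_reflection=False,
        )
        a_from, a_to = result.aligned
        field = np.linalg.norm(a_to.coords - a_from.coords, axis=1)
        per_ind_fields.append(field)
        rows.append({"individual": ind, "value_mm": float(field.mean())})
        pairs.append(
            AlignedCameraPair(
                individual=ind,
                from_camera=from_camera,
                to_camera=to_camera,
                from_config=a_from,
                to_config=a_to,
            )
        )
    if skipped:
        warnings.warn(
            f"camera error: skipped {skipped} individual(s) missing one camera",
            stacklevel=2,
        )
    if not per_ind_fields:
        raise ValueError("no individual has both cameras complete")
    mean_field = np.mean(per_ind_fields, axis=0)
    field = PerLandmarkField(values=mean_field, kind="camera_error")
    report = ErrorReport(
        field=field,
        per_unit_values=pd.DataFrame(rows),
        summary=summarize(field.values),
        grouping="per_individual",
    )
    return report, pairs
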