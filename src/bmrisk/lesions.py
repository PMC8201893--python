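"""Lesion VOIs: transformation into template space and centroid reduction.

A lesion VOI is a binary occupancy mask on a stated grid.  Resampling under an
affine is done by *pulling*: each candidate target voxel is inverse-mapped into
the source grid and takes the occupancy of its nearest source voxel.  Pull
resampling cannot create holes, which push (forward) mapping of a sparse voxel
set can.

The centroid is the unweighted mean of the world coordinates of the centers of
all occupied voxels; masks are binary so intensity weighting does not apply.
Centroids are computed *after* transformation into template space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import AffineTransform, Volume3D

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

__all__ = [
    "UNASSIGNED",
    "LesionVOI",
    "CentroidRecord",
    "DegenerateMaskError",
    "transform_voi",
    "centroid",
    "split_multilabel",
    "read_centroid_table",
    "write_centroid_table",
]


class DegenerateMaskError(RuntimeError):
    """A transform collapsed a lesion mask to zero voxels on the target grid."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (unlike banker's round)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass
class LesionVOI:
    """One lesion's binary mask as a set of occupied voxel indices on a grid.

    ``grid_shape`` and ``voxel_to_world`` state the grid the indices live on;
    the raster data itself is not stored.
    """

    patient_id: str
    lesion_id: str
    indices: np.ndarray  # (N, 3) int voxel indices
    grid_shape: tuple[int, int, int]
    voxel_to_world: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=np.int64))
        if self.indices.size == 0:
            raise ValueError(f"lesion {self.patient_id}/{self.lesion_id}: empty mask")
        if self.indices.shape[1] != 3:
            raise ValueError("indices must have shape (N, 3)")
        shape = np.asarray(self.grid_shape)
        if (self.indices < 0).any() or (self.indices >= shape).any():
            raise ValueError(
                f"lesion {self.patient_id}/{self.lesion_id}: indices outside grid {self.grid_shape}"
            )
        self.voxel_to_world = np.asarray(self.voxel_to_world, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])

    def world_coords(self) -> np.ndarray:
        """World-mm centers of the occupied voxels, shape (N, 3)."""
        return self.indices @ self.voxel_to_world[:3, :3].T + self.voxel_to_world[:3, 3]

    def volume_mm3(self) -> float:
        return self.n_voxels * float(abs(np.linalg.det(self.voxel_to_world[:3, :3])))

    def to_mask(self) -> np.ndarray:
        """Dense boolean raster of the mask on its grid."""
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.indices.T)] = True
        return mask

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        voxel_to_world: np.ndarray,
        patient_id: str,
        lesion_id: str,
    ) -> "LesionVOI":
        idx = np.argwhere(np.asarray(mask) > 0)
        return cls(
            patient_id=patient_id,
            lesion_id=lesion_id,
            indices=idx,
            grid_shape=tuple(mask.shape),
            voxel_to_world=voxel_to_world,
        )


@dataclass
class CentroidRecord:
    """A lesion reduced to its point location in template world mm."""

    patient_id: str
    lesion_id: str
    location_mm: np.ndarray  # (3,)
    assigned_label: str = UNASSIGNED

    def __post_init__(self) -> None:
        self.location_mm = np.asarray(self.location_mm, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.location_mm)):
            raise ValueError(f"non-finite centroid for {self.patient_id}/{self.lesion_id}")


def centroid(voi: LesionVOI) -> CentroidRecord:
    """Unweighted mean of the world coordinates of all occupied voxel centers."""
    loc = voi.world_coords().mean(axis=0)
    return CentroidRecord(patient_id=voi.patient_id, lesion_id=voi.lesion_id, location_mm=loc)


def transform_voi(voi: LesionVOI, t: AffineTransform, target_grid: Volume3D) -> LesionVOI:
    """Resample a lesion mask onto ``target_grid`` under world-mm affine ``t``.

    A target voxel is occupied iff the nearest source voxel of its
    inverse-mapped center lies in the source mask (pull resampling, nearest
    neighbour).  Only the bounding box of the forward-mapped source mask is
    scanned, so cost scales with lesion size rather than grid size.

    Raises
    ------
    DegenerateMaskError
        If no target voxel maps back into the source mask (e.g. the transform
        pushes the lesion off the target grid).
    """
    src_inv = np.linalg.inv(voi.voxel_to_world)
    t_inv = np.linalg.inv(t.matrix)

    # Forward-map occupied source voxel centers to find the target-voxel bbox.
    world = voi.world_coords() @ t.matrix[:3, :3].T + t.matrix[:3, 3]
    tgt_cont = world @ np.linalg.inv(target_grid.voxel_to_world)[:3, :3].T + np.linalg.inv(
        target_grid.voxel_to_world
    )[:3, 3]
    pad = 2  # covers rounding plus sub-voxel shear of the mapped lattice
    lo = np.maximum(np.floor(tgt_cont.min(axis=0)).astype(int) - pad, 0)
    hi = np.minimum(np.ceil(tgt_cont.max(axis=0)).astype(int) + pad, np.array(target_grid.shape) - 1)
    if np.any(lo > hi):
        raise DegenerateMaskError(
            f"lesion {voi.patient_id}/{voi.lesion_id}: transform maps mask entirely off the target grid"
        )

    axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
    cand = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    # Pull: target voxel center -> world -> source world -> nearest source voxel.
    cand_world = cand @ target_grid.voxel_to_world[:3, :3].T + target_grid.voxel_to_world[:3, 3]
    src_world = cand_world @ t_inv[:3, :3].T + t_inv[:3, 3]
    src_vox = round_half_away(src_world @ src_inv[:3, :3].T + src_inv[:3, 3])

    shape = np.asarray(voi.grid_shape)
    in_bounds = np.all((src_vox >= 0) & (src_vox < shape), axis=1)
    occupied = np.zeros(len(cand), dtype=bool)
    if in_bounds.any():
        src_mask = voi.to_mask()
        sv = src_vox[in_bounds]
        occupied[in_bounds] = src_mask[sv[:, 0], sv[:, 1], sv[:, 2]]
    if not occupied.any():
        raise DegenerateMaskError(
            f"lesion {voi.patient_id}/{voi.lesion_id}: transform collapsed mask to zero voxels"
        )
    return LesionVOI(
        patient_id=voi.patient_id,
        lesion_id=voi.lesion_id,
        indices=cand[occupied],
        grid_shape=target_grid.shape,
        voxel_to_world=target_grid.voxel_to_world,
    )


def split_multilabel(
    volume: Volume3D, patient_id: str, split_components: bool = False
) -> list[LesionVOI]:
    """Split an integer label volume into one VOI per positive label.

    Label identity, not spatial connectivity, defines a lesion: two
    disconnected blobs sharing a label are one VOI.  Pass
    ``split_components=True`` to additionally split each label into 26-connected
    components (lesion ids become ``<label>.<component>``).
    """
    data = volume.data
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"expected an integer label volume, got dtype {data.dtype}")
    labels = np.unique(data)
    labels = labels[labels > 0]
    if labels.size == 0:
        warnings.warn(f"patient {patient_id}: label volume is all background", stacklevel=2)
        return []
    vois: list[LesionVOI] = []
    structure = np.ones((3, 3, 3), dtype=bool)
    for lab in labels:
        mask = data == lab
        if split_components:
            comp, n_comp = ndimage.label(mask, structure=structure)
            for c in range(1, n_comp + 1):
                vois.append(
                    LesionVOI.from_mask(
                        comp == c, volume.voxel_to_world, patient_id, f"{int(lab)}.{c}"
                    )
                )
        else:
            vois.append(LesionVOI.from_mask(mask, volume.voxel_to_world, patient_id, str(int(lab))))
    total = sum(v.n_voxels for v in vois)
    assert total == int((data > 0).sum()), "voxel count not conserved by label split"
    return vois


CENTROID_COLUMNS = ["patient_id", "lesion_id", "x_mm", "y_mm", "z_mm"]


def read_centroid_table(path: str | Path) -> list[CentroidRecord]:
    """Read a precomputed centroid table (TSV: patient_id, lesion_id, x/y/z_mm)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "lesion_id": str})
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: centroid table missing columns {missing}")
    return [
        CentroidRecord(
            patient_id=row.patient_id,
            lesion_id=row.lesion_id,
            location_mm=np.array([row.x_mm, row.y_mm, row.z_mm]),
        )
        for row in df.itertuples()
    ]


def write_centroid_table(centroids, path: str | Path, include_label: bool = False) -> None:
    """Write centroids as TSV; optionally include the assigned region group."""
    rows = []
    for c in centroids:
        row = {
            "patient_id": c.patient_id,
            "lesion_id": c.lesion_id,
            "x_mm": c.location_mm[0],
            "y_mm": c.location_mm[1],
            "z_mm": c.location_mm[2],
        }
        if include_label:
            row["assigned_label"] = c.assigned_label
        rows.append(row)
    cols = CENTROID_COLUMNS + (["assigned_label"] if include_label else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6g")
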