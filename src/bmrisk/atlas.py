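"""Label atlases: region definitions, volumes, and centroid-to-region assignment.

An atlas is an integer label raster (0 = background) plus a region table
mapping each label to a name and a *group*.  Groups exist because fine
parcellations (e.g. the 116-label AAL) are usually merged into coarser units
for counting; the grouping is configuration (an editable label->group table),
not code.  Probabilistic atlases must be reduced to a hard
maximum-probability label raster upstream.

Centroid assignment uses the nearest-voxel rule: the point's world coordinate
is mapped through the inverse grid affine and each axis is rounded to the
nearest voxel index (halves away from zero).  Background or out-of-bounds
points are UNASSIGNED — a valid outcome counted separately, mirroring cohorts
where a handful of lesion centroids fall outside labeled tissue.  An optional
snap mode reassigns such points to the nearest labeled voxel within a radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Volume3D
from .lesions import UNASSIGNED, CentroidRecord, round_half_away

logger = logging.getLogger(__name__)

__all__ = [
    "AtlasRegion",
    "LabelAtlas",
    "RegionCountTable",
    "GridMismatchError",
    "overlay_manual_structures",
    "region_volumes",
    "assign_centroid",
    "assign_centroids",
    "count_by_region",
]


class GridMismatchError(ValueError):
    """Two rasters expected on the same grid have different geometry."""


@dataclass(frozen=True)
class AtlasRegion:
    label: int
    name: str
    group: str
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError(f"region label must be positive, got {self.label}")
        if self.volume_mm3 < 0:
            raise ValueError(f"region volume must be nonnegative, got {self.volume_mm3}")


@dataclass
class LabelAtlas:
    """Integer label raster plus its region table.

    Build with :meth:`from_raster`, which computes volumes from the raster and
    checks that every positive raster label has a region entry.
    """

    raster: Volume3D
    regions: list[AtlasRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.issubdtype(self.raster.data.dtype, np.integer):
            raise ValueError(f"atlas raster must be integer-typed, got {self.raster.data.dtype}")
        known = {r.label for r in self.regions}
        if len(known) != len(self.regions):
            raise ValueError("duplicate labels in region table")
        present = set(np.unique(self.raster.data).tolist()) - {0}
        unknown = present - known
        if unknown:
            raise ValueError(f"raster labels missing from region table: {sorted(unknown)}")

    @classmethod
    def from_raster(
        cls,
        raster: Volume3D,
        names: dict[int, str] | None = None,
        grouping: dict[int, str] | None = None,
    ) -> "LabelAtlas":
        """Construct from a raster; volumes are counted from the raster itself.

        ``names`` and ``grouping`` default to ``"region_<label>"`` and the
        region's own name respectively.
        """
        labels, counts = np.unique(raster.data, return_counts=True)
        vv = raster.voxel_volume_mm3
        regions = []
        for lab, cnt in zip(labels.tolist(), counts.tolist()):
            if lab <= 0:
                continue
            name = (names or {}).get(lab, f"region_{lab}")
            group = (grouping or {}).get(lab, name)
            regions.append(AtlasRegion(label=int(lab), name=name, group=group, volume_mm3=cnt * vv))
        return cls(raster=raster, regions=regions)

    @classmethod
    def from_files(cls, raster: Volume3D, region_table: pd.DataFrame) -> "LabelAtlas":
        """Construct from a raster plus a lookup table (columns label, name[, group])."""
        if not {"label", "name"} <= set(region_table.columns):
            raise ValueError("region table needs columns 'label' and 'name'")
        names = dict(zip(region_table["label"].astype(int), region_table["name"]))
        if "group" in region_table.columns:
            grouping = dict(zip(region_table["label"].astype(int), region_table["group"]))
        else:
            grouping = {lab: nm for lab, nm in names.items()}
        return cls.from_raster(raster, names=names, grouping=grouping)

    @property
    def label_to_group(self) -> dict[int, str]:
        return {r.label: r.group for r in self.regions}

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r.group, None)
        return list(seen)

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.label, r.name, r.group, r.volume_mm3) for r in self.regions],
            columns=["label", "name", "group", "volume_mm3"],
        )


def overlay_manual_structures(
    base: LabelAtlas, overlays: list[tuple[Volume3D, str, str]]
) -> LabelAtlas:
    """Stamp manually delineated structures onto an atlas.

    Each overlay is a ``(mask_volume, name, group)`` triple on the base grid.
    Overlay voxels get a fresh label and *replace* base labels where they
    overlap (manual structures like the brainstem are absent or differently
    bounded in standard atlases, so they win); later overlays win over earlier
    ones.  Region volumes are recomputed from the stamped raster.
    """
    if not overlays:
        return base
    data = base.raster.data.copy()
    names: dict[int, str] = {r.label: r.name for r in base.regions}
    grouping: dict[int, str] = {r.label: r.group for r in base.regions}
    next_label = max(names, default=0) + 1
    for vol, name, group in overlays:
        if vol.shape != base.raster.shape or not np.allclose(
            vol.voxel_to_world, base.raster.voxel_to_world, atol=1e-6
        ):
            raise GridMismatchError(f"overlay '{name}' is not on the base atlas grid")
        mask = vol.data > 0
        if not mask.any():
            warnings.warn(f"overlay '{name}' is empty; skipped", stacklevel=2)
            continue
        data[mask] = next_label
        names[next_label] = name
        grouping[next_label] = group
        next_label += 1
    new_raster = base.raster.like(data)
    return LabelAtlas.from_raster(new_raster, names=names, grouping=grouping)


def region_volumes(
    atlas: LabelAtlas, grouping: dict[int, str] | None = None
) -> pd.DataFrame:
    """Per-group volumes in mm3 (columns ``group``, ``volume_mm3``).

    ``grouping`` overrides the atlas's own label->group map; labels absent
    from an explicit grouping are excluded from the totals with a warning.
    """
    if grouping is None:
        grouping = atlas.label_to_group
    vols: dict[str, float] = {}
    excluded = []
    for r in atlas.regions:
        group = grouping.get(r.label)
        if group is None:
            excluded.append(r.label)
            continue
        vols[group] = vols.get(group, 0.0) + r.volume_mm3
    if excluded:
        warnings.warn(f"labels excluded by grouping: {excluded}", stacklevel=2)
    for g, v in vols.items():
        if v == 0:
            warnings.warn(f"group '{g}' has zero volume", stacklevel=2)
    return pd.DataFrame(
        {"group": list(vols), "volume_mm3": list(vols.values())}
    )


def assign_centroid(
    atlas: LabelAtlas, c: CentroidRecord, snap_radius_mm: float = 0.0
) -> CentroidRecord:
    """Assign a centroid to the group of the voxel containing it.

    World -> voxel via the inverse grid affine, each axis rounded to the
    nearest index (half away from zero).  Background (label 0) or
    out-of-bounds points are UNASSIGNED unless ``snap_radius_mm`` > 0, in
    which case the nearest labeled voxel center within that radius is used.
    """
    vox = round_half_away(atlas.raster.world_to_voxel_points(c.location_mm))[0]
    shape = np.asarray(atlas.raster.shape)
    label = 0
    if np.all(vox >= 0) and np.all(vox < shape):
        label = int(atlas.raster.data[tuple(vox)])
    if label == 0 and snap_radius_mm > 0:
        label = _nearest_labeled_voxel(atlas, c.location_mm, snap_radius_mm)
    group = atlas.label_to_group.get(label, UNASSIGNED) if label > 0 else UNASSIGNED
    return replace(c, assigned_label=group)


def _nearest_labeled_voxel(atlas: LabelAtlas, point_mm: np.ndarray, radius_mm: float) -> int:
    """Label of the nearest foreground voxel center within radius_mm, else 0."""
    vox_c = atlas.raster.world_to_voxel_points(point_mm)[0]
    # conservative voxel-space search window from the world-space radius
    spacing = np.linalg.norm(atlas.raster.voxel_to_world[:3, :3], axis=0)
    half = np.ceil(radius_mm / spacing).astype(int) + 1
    lo = np.maximum(np.floor(vox_c).astype(int) - half, 0)
    hi = np.minimum(np.ceil(vox_c).astype(int) + half, np.asarray(atlas.raster.shape) - 1)
    if np.any(lo > hi):
        return 0
    sub = atlas.raster.data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    idx = np.argwhere(sub > 0)
    if idx.size == 0:
        return 0
    centers = atlas.raster.voxel_to_world_points(idx + lo)
    d = np.linalg.norm(centers - np.asarray(point_mm, dtype=float), axis=1)
    best = np.argmin(d)
    if d[best] > radius_mm:
        return 0
    return int(sub[tuple(idx[best])])


def assign_centroids(
    atlas: LabelAtlas, centroids, snap_radius_mm: float = 0.0
) -> list[CentroidRecord]:
    return [assign_centroid(atlas, c, snap_radius_mm=snap_radius_mm) for c in centroids]


@dataclass
class RegionCountTable:
    """Observed lesion counts per region group.

    Invariant: ``sum(counts.values()) == n_assigned`` and
    ``n_assigned + n_unassigned`` equals the number of input centroids.
    """

    counts: dict[str, int]
    n_assigned: int
    n_unassigned: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative region count")
        if sum(self.counts.values()) != self.n_assigned:
            raise ValueError("group counts do not sum to n_assigned")


def count_by_region(
    centroids, atlas: LabelAtlas | None = None, grouping: dict[int, str] | None = None
) -> RegionCountTable:
    """Tally assigned centroids per group.

    Centroids must already carry assignments (see :func:`assign_centroids`).
    All groups of ``atlas`` (or of the explicit ``grouping``) appear in the
    table, zero-filled, so downstream tests cover unhit regions too.
    """
    if grouping is not None:
        group_names = list(dict.fromkeys(grouping.values()))
    elif atlas is not None:
        group_names = atlas.groups
    else:
        group_names = []
    counts = {g: 0 for g in group_names}
    n_unassigned = 0
    for c in centroids:
        if c.assigned_label == UNASSIGNED:
            n_unassigned += 1
        else:
            counts[c.assigned_label] = counts.get(c.assigned_label, 0) + 1
    n_assigned = sum(counts.values())
    return RegionCountTable(counts=counts, n_assigned=n_assigned, n_unassigned=n_unassigned)
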