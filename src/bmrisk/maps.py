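"""Map rasterizers: sphere-overlap frequency maps and z-score risk maps.

The frequency map places a binary sphere of fixed diameter (default 20 mm) at
every lesion centroid and counts, at each voxel, how many spheres cover it.
Sphere membership uses the voxel *center* and a closed ball (distance <=
radius).  The risk map paints every voxel of a region with that region's test
z-score; background voxels carry NaN as a sentinel (0 is a legal z-score, so
it cannot mark background).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .atlas import LabelAtlas
from .io import Volume3D

logger = logging.getLogger(__name__)

__all__ = ["FrequencyMap", "RiskMap", "frequency_map", "risk_map", "BACKGROUND_Z"]

BACKGROUND_Z = np.nan


@dataclass
class FrequencyMap:
    raster: Volume3D  # nonnegative integer counts
    sphere_diameter_mm: float = 20.0


@dataclass
class RiskMap:
    raster: Volume3D  # float z per voxel, NaN background


def frequency_map(
    centroids, grid: Volume3D, diameter_mm: float = 20.0
) -> FrequencyMap:
    """Sphere-overlap counts on ``grid`` for the given centroids.

    A voxel is covered by a centroid's sphere iff the Euclidean distance from
    the voxel center to the centroid is <= ``diameter_mm / 2``.  Overlapping
    spheres accumulate.  A centroid whose sphere misses the grid entirely
    contributes nothing (logged).
    """
    if diameter_mm <= 0:
        raise ValueError(f"sphere diameter must be positive, got {diameter_mm}")
    radius = diameter_mm / 2.0
    counts = np.zeros(grid.shape, dtype=np.int32)
    inv = np.linalg.inv(grid.voxel_to_world)
    shape = np.asarray(grid.shape)
    for c in centroids:
        loc = np.asarray(c.location_mm, dtype=float)
        # conservative voxel bbox: map the corners of the world-space cube
        # enclosing the ball, then floor/ceil
        corners = loc + radius * np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
        )
        vox = corners @ inv[:3, :3].T + inv[:3, 3]
        lo = np.maximum(np.floor(vox.min(axis=0)).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 1, shape - 1)
        if np.any(lo > hi):
            logger.info(
                "centroid %s/%s sphere lies entirely off the grid; skipped",
                c.patient_id,
                c.lesion_id,
            )
            continue
        axes = [np.arange(lo[d], hi[d] + 1) for d in range(3)]
        idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        centers = idx @ grid.voxel_to_world[:3, :3].T + grid.voxel_to_world[:3, 3]
        inside = np.linalg.norm(centers - loc, axis=-1) <= radius
        if not inside.any():
            logger.info(
                "centroid %s/%s sphere covers no voxel center; skipped",
                c.patient_id,
                c.lesion_id,
            )
            continue
        counts[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] += inside
    return FrequencyMap(raster=grid.like(counts), sphere_diameter_mm=diameter_mm)


def risk_map(atlas: LabelAtlas, results) -> RiskMap:
    """Paint each atlas region's voxels with its test z-score.

    Regions (groups) present in the raster but absent from ``results`` are
    painted background with a warning.
    """
    z_by_group = {r.group: r.z for r in results}
    max_label = max((r.label for r in atlas.regions), default=0)
    lut = np.full(max_label + 1, BACKGROUND_Z, dtype=np.float64)
    missing = []
    for region in atlas.regions:
        z = z_by_group.get(region.group)
        if z is None:
            missing.append(region.group)
        else:
            lut[region.label] = z
    if missing:
        warnings.warn(
            f"atlas groups without a test result painted background: {sorted(set(missing))}",
            stacklevel=2,
        )
    painted = lut[atlas.raster.data]
    return RiskMap(raster=atlas.raster.like(painted))


def save_slice_png(vol: Volume3D, path, axis: int = 2, index: int | None = None) -> None:
    """Export one 2-D slice as a PNG for quick visual inspection.

    Color mapping for publication figures is left to downstream viewers; this
    is a debugging aid only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if index is None:
        index = vol.shape[axis] // 2
    sl = np.take(vol.data, index, axis=axis)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(sl, dtype=float).T, origin="lower", cmap="coolwarm")
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(f"axis {axis}, slice {index}")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
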