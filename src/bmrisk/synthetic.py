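"""Synthetic atlases, lesion sets, and affines with known ground truth.

The generator instantiates the null model the statistics assume — equal
metastatic risk per voxel — and perturbs it with per-region risk multipliers:
a lesion center is drawn from the categorical distribution over foreground
voxels with weight proportional to its region's multiplier (1.0 everywhere is
the exact null).  The lesion mask is a digital ball around the sampled center.
Sampling is per-voxel, not per-region-then-uniform, so regions' hit
probabilities are exactly volume-proportional under the null regardless of
region shape.

Atlas geometry uses box and ellipsoid primitives with closed-form volumes, so
region-volume code paths are checkable analytically.  Everything is
deterministic given the scenario seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .atlas import LabelAtlas
from .io import AffineTransform, Volume3D
from .lesions import LesionVOI

__all__ = [
    "RegionSpec",
    "SyntheticScenario",
    "make_atlas",
    "make_slab_atlas",
    "sample_lesions",
    "make_random_affine",
]


@dataclass
class RegionSpec:
    """One synthetic region: a box or ellipsoid placed in world mm.

    ``size_mm`` is full edge lengths for a box, semi-axes for an ellipsoid.
    """

    name: str
    group: str
    shape: str  # "box" | "ellipsoid"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.shape not in {"box", "ellipsoid"}:
            raise ValueError(f"region shape must be 'box' or 'ellipsoid', got '{self.shape}'")
        if min(self.size_mm) <= 0:
            raise ValueError(f"region size must be positive, got {self.size_mm}")


@dataclass
class SyntheticScenario:
    """Region geometry + per-group risk multipliers + lesion sampling plan."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    regions: list[RegionSpec]
    risk_multipliers: dict[str, float] = field(default_factory=dict)
    n_lesions: int = 0
    lesion_radius_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if any(m < 0 for m in self.risk_multipliers.values()):
            raise ValueError("risk multipliers must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            regions = [
                RegionSpec(
                    name=r["name"],
                    group=r.get("group", r["name"]),
                    shape=r["shape"],
                    center_mm=tuple(r["center_mm"]),
                    size_mm=tuple(r["size_mm"]),
                )
                for r in raw["regions"]
            ]
            return cls(
                grid_shape=tuple(raw["grid_shape"]),
                voxel_size_mm=float(raw["voxel_size_mm"]),
                regions=regions,
                risk_multipliers=dict(raw.get("risk_multipliers", {})),
                n_lesions=int(raw.get("n_lesions", 0)),
                lesion_radius_mm=float(raw.get("lesion_radius_mm", 2.0)),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ValueError(f"scenario file {path} missing key: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "regions": [
                {
                    "name": r.name,
                    "group": r.group,
                    "shape": r.shape,
                    "center_mm": list(r.center_mm),
                    "size_mm": list(r.size_mm),
                }
                for r in self.regions
            ],
            "risk_multipliers": dict(self.risk_multipliers),
            "n_lesions": self.n_lesions,
            "lesion_radius_mm": self.lesion_radius_mm,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def make_atlas(scenario: SyntheticScenario) -> LabelAtlas:
    """Rasterize the scenario's regions into a label atlas.

    Regions are stamped in order; where primitives overlap, the *earlier* spec
    keeps the voxel (later specs are clipped against earlier ones).  Primitives
    extending past the grid are clipped with a warning.
    """
    vs = scenario.voxel_size_mm
    affine = np.diag([vs, vs, vs, 1.0])
    data = np.zeros(scenario.grid_shape, dtype=np.int16)
    grids = np.indices(scenario.grid_shape, dtype=float)
    centers = [grids[d] * vs for d in range(3)]  # world mm of voxel centers
    names: dict[int, str] = {}
    grouping: dict[int, str] = {}
    for label, spec in enumerate(scenario.regions, start=1):
        c = spec.center_mm
        s = spec.size_mm
        if spec.shape == "box":
            inside = np.ones(scenario.grid_shape, dtype=bool)
            for d in range(3):
                inside &= np.abs(centers[d] - c[d]) <= s[d] / 2.0
        else:
            q = sum(((centers[d] - c[d]) / s[d]) ** 2 for d in range(3))
            inside = q <= 1.0
        # check for clipping against the grid extent
        extent = np.array(scenario.grid_shape) * vs
        half = np.array(s) / 2.0 if spec.shape == "box" else np.array(s)
        if np.any(np.array(c) - half < -vs / 2) or np.any(np.array(c) + half > extent - vs / 2):
            warnings.warn(f"region '{spec.name}' extends past the grid; clipped", stacklevel=2)
        inside &= data == 0  # later specs clipped against earlier regions
        if not inside.any():
            warnings.warn(f"region '{spec.name}' rasterized to zero voxels", stacklevel=2)
        data[inside] = label
        names[label] = spec.name
        grouping[label] = spec.group
    raster = Volume3D(data=data, voxel_to_world=affine)
    return LabelAtlas.from_raster(raster, names=names, grouping=grouping)


def make_slab_atlas(
    lengths_voxels: list[int],
    cross_section: tuple[int, int] = (20, 20),
    voxel_size_mm: float = 1.0,
    groups: list[str] | None = None,
    pad_voxels: int = 2,
) -> LabelAtlas:
    """An atlas of contiguous slabs stacked along z with *exact* voxel counts.

    Slab ``k`` occupies ``lengths_voxels[k]`` whole z-planes of a
    ``cross_section`` column, so region volume fractions equal
    ``lengths / sum(lengths)`` exactly — convenient for calibration studies
    where the expected rates must be known in closed form.  ``groups`` merges
    slabs into named groups (default: one group per slab).
    """
    if any(l < 1 for l in lengths_voxels):
        raise ValueError("slab lengths must be >= 1 voxel")
    n = len(lengths_voxels)
    groups = groups if groups is not None else [f"region_{k + 1}" for k in range(n)]
    if len(groups) != n:
        raise ValueError("groups must match lengths_voxels in length")
    nz = sum(lengths_voxels) + 2 * pad_voxels
    shape = (cross_section[0] + 2 * pad_voxels, cross_section[1] + 2 * pad_voxels, nz)
    data = np.zeros(shape, dtype=np.int16)
    z0 = pad_voxels
    sl_x = slice(pad_voxels, pad_voxels + cross_section[0])
    sl_y = slice(pad_voxels, pad_voxels + cross_section[1])
    for k, length in enumerate(lengths_voxels, start=1):
        data[sl_x, sl_y, z0 : z0 + lengths_voxels[k - 1]] = k
        z0 += length
    vs = voxel_size_mm
    raster = Volume3D(data=data, voxel_to_world=np.diag([vs, vs, vs, 1.0]))
    names = {k: f"slab_{k}" for k in range(1, n + 1)}
    grouping = {k: groups[k - 1] for k in range(1, n + 1)}
    return LabelAtlas.from_raster(raster, names=names, grouping=grouping)


def _ball_offsets(radius_mm: float, voxel_to_world: np.ndarray) -> np.ndarray:
    """Voxel-index offsets whose world displacement is within radius of 0."""
    spacing = np.linalg.norm(voxel_to_world[:3, :3], axis=0)
    half = np.maximum(np.floor(radius_mm / spacing).astype(int), 0)
    axes = [np.arange(-h, h + 1) for h in half]
    off = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    disp = off @ voxel_to_world[:3, :3].T
    return off[np.linalg.norm(disp, axis=1) <= radius_mm]


def sample_lesions(
    atlas: LabelAtlas,
    multipliers: dict[str, float] | None = None,
    n_lesions: int = 0,
    lesion_radius_mm: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> list[LesionVOI]:
    """Draw lesions with per-voxel risk weighted by each group's multiplier.

    Each lesion center is one foreground voxel drawn with probability
    proportional to its group's multiplier (default 1.0); the mask is the
    digital ball of ``lesion_radius_mm`` around the center, clipped to the
    grid.  Reproducible under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = atlas.raster.data
    fg = np.argwhere(data > 0)
    if n_lesions > 0 and fg.size == 0:
        raise ValueError("cannot sample lesions: atlas has no foreground voxels")
    multipliers = multipliers or {}
    group_of = atlas.label_to_group
    mult_by_label = np.zeros(int(data.max()) + 1)
    for r in atlas.regions:
        mult_by_label[r.label] = multipliers.get(group_of[r.label], 1.0)
    weights = mult_by_label[data[fg[:, 0], fg[:, 1], fg[:, 2]]]
    total = weights.sum()
    if n_lesions > 0 and total <= 0:
        raise ValueError("all risk multipliers are zero; nothing to sample")
    lesions: list[LesionVOI] = []
    if n_lesions == 0:
        return lesions
    picks = rng.choice(len(fg), size=n_lesions, replace=True, p=weights / total)
    offsets = _ball_offsets(lesion_radius_mm, atlas.raster.voxel_to_world)
    shape = np.asarray(atlas.raster.shape)
    for i, pick in enumerate(picks):
        idx = fg[pick] + offsets
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        lesions.append(
            LesionVOI(
                patient_id="sim",
                lesion_id=f"L{i:05d}",
                indices=idx[ok],
                grid_shape=atlas.raster.shape,
                voxel_to_world=atlas.raster.voxel_to_world,
            )
        )
    return lesions


def make_random_affine(
    seed: int | np.random.Generator = 0,
    max_rotation_deg: float = 10.0,
    max_translation_mm: float = 5.0,
    max_scale: float = 0.05,
) -> tuple[AffineTransform, AffineTransform]:
    """A random invertible world affine and its exact inverse.

    Rotation angles are uniform in +/-``max_rotation_deg`` per axis, per-axis
    scale factors uniform in 1 +/- ``max_scale``, translations uniform in
    +/-``max_translation_mm``.  Zero bounds give the identity pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scales = rng.uniform(1 - max_scale, 1 + max_scale, 3)
    linear = rot_z @ rot_y @ rot_x @ np.diag(scales)
    matrix = np.eye(4)
    matrix[:3, :3] = linear
    matrix[:3, 3] = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    t = AffineTransform(matrix)
    t_inv = t.inverse()
    assert np.allclose(t.matrix @ t_inv.matrix, np.eye(4), atol=1e-8)
    return t, t_inv
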