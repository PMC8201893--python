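"""Volumetric image, transform, and results-table I/O.

Conventions
-----------
World coordinates are millimetres in the template's native orientation (RAS
assumed for MNI-style templates); voxel indices are 0-based.  The voxel-to-world
matrix is the standard 4x4 homogeneous affine carried by the NIfTI-1 header.

Plain-text 4x4 transform files are interpreted as **world-mm -> world-mm**
maps.  Registration tools that emit scaled-voxel-convention matrices (e.g.
FSL-FLIRT ``.mat`` files) use a different dialect; converting such matrices to
world-mm form is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume3D",
    "AffineTransform",
    "VolumeFormatError",
    "TransformFormatError",
    "load_volume",
    "save_volume",
    "load_transform",
    "save_transform",
    "write_results_table",
    "RESULTS_COLUMNS",
]


class VolumeFormatError(ValueError):
    """A volume file is not a valid 3-D image in the supported format."""


class TransformFormatError(ValueError):
    """A transform file does not hold a valid invertible 4x4 affine."""


def _check_homogeneous(matrix: np.ndarray, err: type) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise err(f"expected a 4x4 matrix, got shape {matrix.shape}")
    if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0]):
        raise err(f"last row must be [0, 0, 0, 1], got {matrix[3].tolist()}")
    if abs(np.linalg.det(matrix[:3, :3])) < 1e-12:
        raise err("matrix is singular (zero determinant in the linear part)")
    return matrix


@dataclass
class Volume3D:
    """A 3-D scalar raster with its voxel-to-world geometry.

    Parameters
    ----------
    data:
        3-D array of integer labels or float intensities.
    voxel_to_world:
        4x4 homogeneous matrix mapping 0-based voxel indices to world mm.
    """

    data: np.ndarray
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"data must be 3-D with all dimensions >= 1, got shape {self.data.shape}"
            )
        self.voxel_to_world = _check_homogeneous(self.voxel_to_world, VolumeFormatError)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel: |det| of the 3x3 linear part of the affine."""
        return float(abs(np.linalg.det(self.voxel_to_world[:3, :3])))

    def voxel_to_world_points(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world-mm voxel centers."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.voxel_to_world[:3, :3].T + self.voxel_to_world[:3, 3]

    def world_to_voxel_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (N, 3) world-mm points to continuous (N, 3) voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.voxel_to_world)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume with the same geometry and different data."""
        return Volume3D(data=data, voxel_to_world=self.voxel_to_world.copy())


@dataclass
class AffineTransform:
    """A world-mm -> world-mm homogeneous affine (e.g. from registration)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.matrix = _check_homogeneous(self.matrix, TransformFormatError)

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Apply to (N, 3) or (3,) world points; returns the same shape."""
        pts = np.asarray(points_mm, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


def load_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1 volume, preserving integer data without rescaling.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    VolumeFormatError
        If the image is not 3-D or the header is corrupt.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several header-specific types
        raise VolumeFormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3-D data, got {data.ndim}-D")
    return Volume3D(data=data, voxel_to_world=img.affine)


def save_volume(vol: Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1; round-trips integer data bit-exactly."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data, vol.voxel_to_world)
    img.header.set_data_dtype(vol.data.dtype)
    try:
        nib.save(img, path)
    except OSError as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def load_transform(path: str | Path) -> AffineTransform:
    """Read a plain-text 4x4 world-mm affine (4 rows of 4 numbers).

    Raises
    ------
    TransformFormatError
        On wrong shape, non-numeric content, a bad last row, or singularity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transform file not found: {path}")
    try:
        matrix = np.loadtxt(path, dtype=float)
    except ValueError as exc:
        raise TransformFormatError(f"{path}: non-numeric transform file: {exc}") from exc
    if matrix.shape != (4, 4):
        raise TransformFormatError(f"{path}: expected 4x4 matrix, got shape {matrix.shape}")
    try:
        return AffineTransform(matrix)
    except TransformFormatError as exc:
        raise TransformFormatError(f"{path}: {exc}") from exc


def save_transform(t: AffineTransform, path: str | Path) -> None:
    """Write a 4x4 affine as whitespace-separated plain text."""
    np.savetxt(path, t.matrix, fmt="%.10g")


RESULTS_COLUMNS = [
    "region",
    "volume_mm3",
    "expected_rate",
    "observed_count",
    "observed_rate",
    "z",
    "p_two_tailed",
    "significant",
    "direction",
]


def results_frame(results) -> pd.DataFrame:
    """Risk-test results as a DataFrame in deterministic row order.

    Rows are ordered by descending \\|z\\|, ties broken by region name.
    """
    if not results:
        raise ValueError("results list is empty; refusing to write an empty table")
    rows = [
        {
            "region": r.group,
            "volume_mm3": r.volume_mm3,
            "expected_rate": r.expected_rate,
            "observed_count": r.observed_count,
            "observed_rate": r.observed_rate,
            "z": r.z,
            "p_two_tailed": r.p_two_tailed,
            "significant": r.significant,
            "direction": r.direction,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    order = sorted(range(len(df)), key=lambda i: (-abs(df["z"][i]), df["region"][i]))
    return df.iloc[order].reset_index(drop=True)


def write_results_table(results, path: str | Path) -> None:
    """Write risk-test results as TSV with a fixed column order.

    Floats are formatted at 6 significant digits so repeated runs on the same
    inputs produce byte-identical files.
    """
    df = results_frame(results)
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise OSError(f"cannot write results table to {path}: {exc}") from exc
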