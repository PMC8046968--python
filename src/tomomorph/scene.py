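"""Core scene data model: label volumes, membranes, fibril polylines.

Conventions
-----------
* All internal lengths are in nanometres (MRC headers in ångström are
  divided by 10 on read).
* Voxel indices are 0-based; the world position of voxel ``(i, j, k)``
  is ``(i, j, k) * voxel_size`` (voxel centres).
* Volumes are indexed ``[x, y, z]``; label 0 is background/cytosol and
  labels ``k >= 1`` are organelle lumina.
* Membranes are the 26-connected boundary voxels of each lumen label
  (voxels of the label with at least one 26-neighbour, or the grid
  edge, outside the label).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import mrcio
from .errors import UnitError, ValidationError

logger = logging.getLogger(__name__)

#: Default fibril cylinder radius in nm.
DEFAULT_FIBRIL_RADIUS = 5.0
#: Default minimum fibril contour length in nm; shorter traces are dropped.
DEFAULT_MIN_FIBRIL_LENGTH = 100.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Fibril:
    """An ordered 3D polyline in world coordinates (nm)."""

    points: np.ndarray
    id: str = "fibril"
    radius: float = DEFAULT_FIBRIL_RADIUS

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(f"fibril {self.id!r}: points must be (N, 3)")
        if len(self.points) < 2:
            raise ValidationError(f"fibril {self.id!r}: needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValidationError(
                f"fibril {self.id!r}: duplicate consecutive points"
            )
        if not self.radius > 0:
            raise ValidationError(f"fibril {self.id!r}: radius must be > 0")

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Total contour length in nm."""
        return float(self.segment_lengths.sum())

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Fibril":
        """Rigid motion: rotate about the centroid, then translate."""
        c = self.centroid
        pts = (self.points - c) @ np.asarray(rotation).T + c + np.asarray(translation)
        return Fibril(points=pts, id=self.id, radius=self.radius)


def label_boundary_voxels(label_volume: np.ndarray, label: int) -> np.ndarray:
    """Indices (N, 3) of 26-connected boundary voxels of ``label``.

    A voxel of the label is a boundary voxel when at least one of its
    26 neighbours (with outside-grid treated as background) does not
    carry the label.
    """
    mask = label_volume == label
    interior = ndimage.binary_erosion(mask, structure=_STRUCT_26, border_value=0)
    return np.argwhere(mask & ~interior)


@dataclass
class TomogramScene:
    """A segmented tomogram: label grid, membranes, physical extents."""

    label_volume: np.ndarray
    voxel_size: float
    membrane_points: dict[int, np.ndarray] = field(default_factory=dict)
    lamella_thickness: float | None = None
    tomogram_id: str = "tomogram"

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValidationError("label_volume must be 3-dimensional")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValidationError("label_volume must hold integer labels")
        if not self.voxel_size > 0:
            raise UnitError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.lamella_thickness is None:
            self.lamella_thickness = self.label_volume.shape[2] * self.voxel_size
        z_extent = self.label_volume.shape[2] * self.voxel_size
        if self.lamella_thickness > z_extent + 1e-9:
            raise ValidationError(
                f"lamella_thickness {self.lamella_thickness} nm exceeds "
                f"Z extent {z_extent} nm"
            )
        if not self.membrane_points:
            self.membrane_points = self._derive_membranes()

    def _derive_membranes(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        for lab in self.organelle_ids:
            idx = label_boundary_voxels(self.label_volume, lab)
            out[lab] = idx.astype(np.float64) * self.voxel_size
        return out

    @property
    def organelle_ids(self) -> list[int]:
        labs = np.unique(self.label_volume)
        return [int(v) for v in labs if v > 0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape  # type: ignore[return-value]

    @property
    def bounds(self) -> np.ndarray:
        """Axis-aligned box ``[[0,0,0],[X,Y,Z]]`` in nm."""
        hi = np.array(self.shape, dtype=np.float64) * self.voxel_size
        return np.array([[0.0, 0.0, 0.0], hi])

    @property
    def membrane_mask(self) -> np.ndarray:
        """Boolean grid of all membrane voxels (union over organelles)."""
        mask = np.zeros(self.shape, dtype=bool)
        for pts in self.membrane_points.values():
            idx = np.round(pts / self.voxel_size).astype(int)
            inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
            idx = idx[inside]
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return mask

    def lumen_volume(self) -> float:
        """Total volume of all organelle lumina in nm^3."""
        return float(np.count_nonzero(self.label_volume > 0)) * self.voxel_size**3

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        """Label values at world coordinates (nearest voxel)."""
        idx = np.round(np.asarray(points) / self.voxel_size).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return self.label_volume[idx[:, 0], idx[:, 1], idx[:, 2]]

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether each world point lies inside the scene bounds."""
        pts = np.asarray(points)
        lo, hi = self.bounds
        return np.all((pts >= lo) & (pts <= hi), axis=1)


def read_label_volume(
    path: str | Path,
    voxel_size_nm: float | None = None,
    tomogram_id: str | None = None,
) -> TomogramScene:
    """Read an MRC label volume into a :class:`TomogramScene`.

    The voxel size is taken from the MRC header (Å, converted to nm)
    unless ``voxel_size_nm`` overrides it.  Anisotropic voxels are
    rejected rather than averaged.
    """
    path = Path(path)
    data, voxel_angstrom = mrcio.read_mrc(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValidationError(f"{path}: volume is not integer-convertible")
        data = rounded.astype(np.int32)
    if voxel_size_nm is None:
        vs = np.asarray(voxel_angstrom, dtype=float) / 10.0
        if np.any(vs <= 0):
            raise UnitError(
                f"{path}: header voxel size {voxel_angstrom} Å is not positive; "
                "pass an explicit override"
            )
        if not np.allclose(vs, vs[0], rtol=1e-3):
            raise UnitError(f"{path}: anisotropic voxels {vs} nm are not supported")
        voxel_size_nm = float(vs[0])
    return TomogramScene(
        label_volume=data.astype(np.int32),
        voxel_size=float(voxel_size_nm),
        tomogram_id=tomogram_id or path.stem,
    )


def write_label_volume(path: str | Path, scene: TomogramScene) -> None:
    """Write the scene's label volume as MRC2014 (voxel size in Å)."""
    mrcio.write_mrc(path, scene.label_volume, scene.voxel_size * 10.0)


def resample_polyline(fibril: Fibril, step: float) -> Fibril:
    """Resample at uniform arc-length spacing ``step`` (nm) by linear
    interpolation; endpoints are preserved.

    If ``step`` is not shorter than the fibril, the two endpoints are
    returned with a warning.
    """
    if not step > 0:
        raise ValidationError("resample step must be > 0")
    total = fibril.length
    if step >= total:
        warnings.warn(
            f"fibril {fibril.id!r}: step {step} nm >= length {total:.3g} nm; "
            "returning endpoints only",
            stacklevel=2,
        )
        return Fibril(
            points=fibril.points[[0, -1]], id=fibril.id, radius=fibril.radius
        )
    targets = np.arange(0.0, total, step)
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)
    pts = _interp_at(fibril, targets)
    return Fibril(points=pts, id=fibril.id, radius=fibril.radius)


def resample_uniform(fibril: Fibril, step: float) -> Fibril:
    """Resample at exact multiples of ``step``, dropping the tail
    remainder so that every segment has identical arc spacing.

    Used by tangent-correlation estimation, which requires strictly
    uniform spacing; the discarded tail is shorter than one step.
    """
    if not step > 0:
        raise ValidationError("resample step must be > 0")
    total = fibril.length
    n = int(np.floor(total / step + 1e-9))
    if n < 1:
        raise ValidationError(
            f"fibril {fibril.id!r}: length {total:.3g} nm shorter than step {step} nm"
        )
    targets = np.arange(n + 1) * step
    return Fibril(points=_interp_at(fibril, targets), id=fibril.id, radius=fibril.radius)


def _interp_at(fibril: Fibril, arc_targets: np.ndarray) -> np.ndarray:
    s = fibril.arc_lengths
    return np.column_stack(
        [np.interp(arc_targets, s, fibril.points[:, d]) for d in range(3)]
    )


def filter_fibrils(
    fibrils: list[Fibril], min_length: float = DEFAULT_MIN_FIBRIL_LENGTH
) -> list[Fibril]:
    """Drop fibrils below the minimum contour length, logging the count."""
    kept = [f for f in fibrils if f.length >= min_length - 1e-9]
    dropped = len(fibrils) - len(kept)
    if dropped:
        logger.info(
            "dropped %d of %d fibrils below minimum length %.3g nm",
            dropped, len(fibrils), min_length,
        )
    return kept
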