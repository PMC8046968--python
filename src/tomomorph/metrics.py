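"""Descriptive fibril metrics: lengths, cytosolic density, label periodicity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ValidationError
from .scene import Fibril, TomogramScene


def fibril_length(fibril: Fibril) -> float:
    """Contour length in nm: sum of consecutive segment norms."""
    return fibril.length


@dataclass
class DensityResult:
    """Fraction of cytosolic volume occupied by fibril cylinders."""

    tomogram_id: str
    cytosolic_volume: float  # nm^3
    fibril_volume: float  # nm^3
    density: float
    n_fibrils: int


def cytosolic_fibril_density(
    scene: TomogramScene, fibrils: list[Fibril]
) -> DensityResult:
    """Cytosolic fibril density.

    The cell volume is the full X x Y grid extent times the lamella
    thickness; organelle lumina are subtracted to give the cytosolic
    volume.  Each fibril contributes a cylinder of volume
    ``pi * r^2 * L``; overlaps between crossing fibrils are not
    de-duplicated.
    """
    nx, ny, _ = scene.shape
    cell_volume = (nx * scene.voxel_size) * (ny * scene.voxel_size) * float(
        scene.lamella_thickness
    )
    cytosolic = cell_volume - scene.lumen_volume()
    if cytosolic <= 0:
        raise ConfigurationError(
            f"{scene.tomogram_id}: cytosolic volume {cytosolic:.3g} nm^3 is "
            "not positive; check lamella thickness and segmentation"
        )
    fibril_volume = float(
        sum(np.pi * f.radius**2 * f.length for f in fibrils)
    )
    return DensityResult(
        tomogram_id=scene.tomogram_id,
        cytosolic_volume=cytosolic,
        fibril_volume=fibril_volume,
        density=fibril_volume / cytosolic,
        n_fibrils=len(fibrils),
    )


def gold_label_periodicity(mean_gold_distance: float, strand_spacing: float) -> float:
    """Number of beta-strands per gold label.

    Both arguments in ångström; returns the (float) ratio of mean
    label-to-label distance to the per-strand axial rise.
    """
    if not mean_gold_distance > 0 or not strand_spacing > 0:
        raise ValidationError("gold distance and strand spacing must be > 0")
    return mean_gold_distance / strand_spacing
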