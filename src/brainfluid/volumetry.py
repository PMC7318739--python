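"""Segmentation-mask volumetry.

Region volumes are the product of the voxel count and the physical voxel
volume — a direct transcription of how volumes are read off a manual
segmentation: no smoothing, no partial-volume correction, no inter-slice
interpolation. The parenchymal volume is derived by subtracting the
ventricular volumes from the total intracranial volume.

A mask stores one integer label per voxel (0 = unlabelled). Regions that
physically contain other regions — the total intracranial space contains the
ventricles — are represented as *composite regions*: named unions of base
labels, so that a single-valued label array can still answer "how large is
the intracranial space including CSF".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "SegmentationMask",
    "VolumeReport",
    "region_volume",
    "parenchymal_volume",
]

Spacing = tuple[float, float, float]


@dataclass
class VoxelGrid:
    """A 3-D intensity volume with physical voxel spacing in mm (RAS by default)."""

    intensities: np.ndarray
    spacing: Spacing
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 3-D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class SegmentationMask:
    """Integer label volume plus a label table, aligned to a :class:`VoxelGrid`.

    ``label_table`` maps region name -> base label id (> 0). ``composites``
    maps a region name to a tuple of base region names whose union it denotes.
    """

    labels: np.ndarray
    label_table: Mapping[str, int]
    composites: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    spacing: Spacing | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative (0 = unlabelled)")
        for name, lab in self.label_table.items():
            if lab <= 0:
                raise ValueError(f"base label for {name!r} must be positive, got {lab}")

    def label_ids(self, region: str) -> set[int]:
        """Base label ids making up ``region`` (resolving composites)."""
        if region in self.label_table:
            return {int(self.label_table[region])}
        if region in self.composites:
            ids: set[int] = set()
            for part in self.composites[region]:
                ids |= self.label_ids(part)
            return ids
        raise KeyError(f"unknown region {region!r}; known: "
                       f"{sorted(self.label_table) + sorted(self.composites)}")

    def region_indicator(self, region: str) -> np.ndarray:
        """Boolean volume: voxels belonging to ``region``."""
        ids = self.label_ids(region)
        return np.isin(self.labels, sorted(ids))


@dataclass(frozen=True)
class VolumeReport:
    region: str
    voxel_count: int
    volume_mm3: float


def region_volume(mask: SegmentationMask, region: str, spacing: Spacing) -> VolumeReport:
    """Exact volume of ``region``: voxel count x voxel volume.

    ``spacing`` must agree with the mask's own spacing when the mask carries
    one (guards against quantifying a mask against the wrong grid).
    """
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing}")
    if mask.spacing is not None and not np.allclose(mask.spacing, spacing):
        raise ValueError(f"spacing mismatch: mask carries {mask.spacing}, got {spacing}")
    count = int(mask.region_indicator(region).sum())
    dx, dy, dz = spacing
    return VolumeReport(region=region, voxel_count=count, volume_mm3=count * dx * dy * dz)


def parenchymal_volume(ic: VolumeReport, lv: VolumeReport, v3: VolumeReport) -> float:
    """Parenchymal volume in mm³: intracranial minus lateral + third ventricle.

    A negative result signals inconsistent masks (ventricles not contained in
    the intracranial segmentation) and raises.
    """
    vol = ic.volume_mm3 - (lv.volume_mm3 + v3.volume_mm3)
    if vol < 0:
        raise ValueError(
            f"negative parenchymal volume ({vol:.3f} mm³): ventricle masks "
            "exceed the intracranial mask"
        )
    return vol
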