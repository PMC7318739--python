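"""Apparent diffusion coefficient (ADC) mapping from DWI.

The signal model is mono-exponential, ``S(b) = S0 * exp(-b * ADC)``. Per
gradient direction the ADC is the negative least-squares slope of ``ln S``
against ``b``; with exactly two b-values this reduces to the closed form
``ln(S0/Sb) / b``. The voxel ADC is the mean over directions. Voxels with
any non-positive signal cannot be log-fitted and are flagged invalid rather
than silently clamped; negative fitted ADCs are likewise retained and left
to the reporting layer, because clamping would bias ROI means.

ROI summaries exclude CSF-containing voxels (by ventricle labels, supplied
through the segmentation mask) since free water raises the mean ADC of a
parenchymal region substantially.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .volumetry import SegmentationMask, Spacing

__all__ = ["DwiSeries", "AdcMap", "RegionAdcReport", "fit_adc", "roi_adc"]


@dataclass
class DwiSeries:
    """DWI signal volumes indexed ``(b-value, direction, x, y, z)``."""

    signals: np.ndarray
    b_values: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signals.ndim != 5:
            raise ValueError("signals must be 5-D: (b, direction, x, y, z)")
        if self.signals.shape[0] != self.b_values.size:
            raise ValueError("first axis of signals must match number of b-values")
        if not np.any(self.b_values == 0):
            raise ValueError("acquisition must include b = 0")
        if np.min(self.signals) < 0:
            raise ValueError("DWI signals must be non-negative")

    @property
    def n_directions(self) -> int:
        return self.signals.shape[1]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.signals.shape[2:]


@dataclass
class AdcMap:
    """Voxelwise ADC in mm²/s with a validity flag per voxel."""

    adc: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.adc.shape != self.valid.shape:
            raise ValueError("adc and valid must share a shape")
        if not np.all(np.isfinite(self.adc[self.valid])):
            raise ValueError("adc must be finite wherever valid")


@dataclass(frozen=True)
class RegionAdcReport:
    region: str
    mean_adc: float
    n_voxels: int


def fit_adc(dwi: DwiSeries) -> AdcMap:
    """Log-linear least-squares ADC fit, averaged over gradient directions."""
    b = dwi.b_values
    if np.unique(b).size < 2:
        raise ValueError("ADC fitting needs at least two distinct b-values")
    signals = dwi.signals
    valid = np.all(signals > 0, axis=(0, 1))
    # avoid log warnings on flagged voxels; their fitted value is discarded
    safe = np.where(signals > 0, signals, 1.0)
    logs = np.log(safe)
    bc = b - b.mean()
    denom = float(np.sum(bc**2))
    # slope of ln S on b, per direction, then negate and average over directions
    slope = np.tensordot(bc, logs, axes=([0], [0])) / denom  # (dir, x, y, z)
    adc = -slope.mean(axis=0)
    adc[~valid] = np.nan
    return AdcMap(adc=adc, valid=valid)


def roi_adc(
    adc_map: AdcMap,
    mask: SegmentationMask,
    region: str,
    csf_labels: Iterable[str] = (),
) -> RegionAdcReport:
    """Mean ADC over a region's valid voxels, excluding CSF-labelled voxels."""
    if mask.labels.shape != adc_map.adc.shape:
        raise ValueError("segmentation mask is not aligned to the ADC map")
    sel = mask.region_indicator(region) & adc_map.valid
    for csf in csf_labels:
        sel &= ~mask.region_indicator(csf)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"empty ROI: region {region!r} has no valid voxels after CSF exclusion")
    return RegionAdcReport(region=region, mean_adc=float(adc_map.adc[sel].mean()), n_voxels=n)
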