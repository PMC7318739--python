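"""Electropherogram peak quantification (capillary-based simple western).

A run of the instrument yields a trace of chemiluminescent signal against
apparent molecular weight. Protein abundance is scored as the baseline-
subtracted area of the peak at the protein's apparent weight — AQP4 near
34 kDa (33 kDa in some calibrations) and the beta-actin loading control near
48 kDa (46 kDa) — and expression is reported as the AQP4/actin area ratio
averaged over replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Electropherogram",
    "PeakWindow",
    "AQP4_WINDOW",
    "ACTIN_WINDOW",
    "integrate_peak",
    "aqp4_actin_ratio",
]


@dataclass
class Electropherogram:
    """One separation trace: signal against apparent molecular weight (kDa)."""

    kda: np.ndarray
    signal: np.ndarray
    run_id: str = ""
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.kda = np.asarray(self.kda, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.kda.ndim != 1 or self.kda.shape != self.signal.shape:
            raise ValueError("kda and signal must be 1-D arrays of equal length")
        if not np.all(np.diff(self.kda) > 0):
            raise ValueError("kda grid must be strictly increasing")


@dataclass(frozen=True)
class PeakWindow:
    """Integration window ``centre_kda ± half_width_kda``."""

    centre_kda: float
    half_width_kda: float

    def __post_init__(self) -> None:
        if self.centre_kda <= 0 or self.half_width_kda <= 0:
            raise ValueError("peak window centre and half-width must be positive")

    @property
    def lo(self) -> float:
        return self.centre_kda - self.half_width_kda

    @property
    def hi(self) -> float:
        return self.centre_kda + self.half_width_kda


# Defaults span both the 34/48 kDa (methods) and 33/46 kDa (supplement)
# apparent weights reported for AQP4 and beta-actin.
AQP4_WINDOW = PeakWindow(centre_kda=34.0, half_width_kda=4.0)
ACTIN_WINDOW = PeakWindow(centre_kda=48.0, half_width_kda=4.0)


def integrate_peak(trace: Electropherogram, window: PeakWindow) -> float:
    """Baseline-subtracted trapezoidal peak area over ``window``.

    The baseline is the straight segment joining the trace values at the two
    window edges, so a constant offset added to the whole trace contributes
    zero area. No deconvolution is attempted: a single dominant peak per
    window is assumed.
    """
    kda, signal = trace.kda, trace.signal
    if window.lo < kda[0] or window.hi > kda[-1]:
        raise ValueError(
            f"window [{window.lo}, {window.hi}] kDa outside trace range "
            f"[{kda[0]}, {kda[-1]}] kDa"
        )
    inside = (kda > window.lo) & (kda < window.hi)
    x = np.concatenate(([window.lo], kda[inside], [window.hi]))
    y = np.concatenate(
        ([np.interp(window.lo, kda, signal)], signal[inside], [np.interp(window.hi, kda, signal)])
    )
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return float(np.trapezoid(y - baseline, x))


def aqp4_actin_ratio(runs: Iterable[Sequence[float]]) -> float:
    """Mean over runs of the per-run AQP4/actin area ratio.

    Parameters
    ----------
    runs
        Iterable of ``(area_aqp4, area_actin)`` pairs, one per replicate run.
    """
    ratios = []
    for area_34, area_48 in runs:
        if area_48 <= 0:
            raise ValueError("actin (loading control) peak area must be positive")
        ratios.append(area_34 / area_48)
    if not ratios:
        raise ValueError("no runs supplied")
    return float(np.mean(ratios))
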