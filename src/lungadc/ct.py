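"""CT lung densitometry: density-threshold emphysema metrics.

Emphysematous tissue destruction lowers CT attenuation, so the fraction of
lung voxels below fixed Hounsfield thresholds quantifies emphysema extent:

* ``RA_950`` / ``RA_910`` / ``RA_856`` — the relative area (percentage of
  lung voxels) with attenuation strictly below -950 / -910 / -856 HU;
* ``HU_15%`` — the attenuation value below which 15% of lung voxels fall
  (the 15th percentile of the lung density histogram, nearest-rank);
* the emphysema classification ``RA_950 > 6.8%`` (strict), 6.8% being the
  upper 95% limit of predicted normal values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CtError
from .volume import ImageVolume, LungMask

#: RA950 percentage above which a lung is classified as emphysematous.
EMPHYSEMA_RA950_CUTOFF = 6.8

#: The standard densitometry thresholds, HU.
RA_THRESHOLDS = (-950, -910, -856)


@dataclass
class CTDensityMetrics:
    ra950_pct: float
    ra910_pct: float
    ra856_pct: float
    hu15_hu: float
    emphysema: bool


def _lung_values(hu: ImageVolume, mask: LungMask) -> np.ndarray:
    mask.check_aligned(hu)
    if not mask.data.any():
        raise CtError("empty lung mask")
    return hu.data[mask.data]


def relative_area(hu: ImageVolume, mask: LungMask, threshold: float) -> float:
    """Percentage of lung voxels with attenuation strictly below ``threshold``."""
    values = _lung_values(hu, mask)
    return 100.0 * float(np.count_nonzero(values < threshold)) / values.size


def hu_percentile(hu: ImageVolume, mask: LungMask, p: float,
                  interpolate: bool = False) -> float:
    """The p-th percentile of lung HU values.

    Nearest-rank by default (the smallest value with at least p% of voxels
    at or below it), matching a frequency-histogram reading; linear
    interpolation is available as an option.
    """
    if not 0 < p < 100:
        raise CtError(f"percentile must be in (0, 100); got {p}")
    values = np.sort(_lung_values(hu, mask))
    if interpolate:
        return float(np.percentile(values, p))
    rank = max(math.ceil(p / 100.0 * values.size), 1)
    return float(values[rank - 1])


def classify_emphysema(ra950_pct: float) -> bool:
    """True iff RA950 strictly exceeds the 6.8% normal-limit cutoff."""
    return ra950_pct > EMPHYSEMA_RA950_CUTOFF


def ct_density_metrics(hu: ImageVolume, mask: LungMask) -> CTDensityMetrics:
    """All densitometry metrics for one HU volume and lung mask."""
    ra = [relative_area(hu, mask, t) for t in RA_THRESHOLDS]
    hu15 = hu_percentile(hu, mask, 15)
    return CTDensityMetrics(ra[0], ra[1], ra[2], hu15, classify_emphysema(ra[0]))
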