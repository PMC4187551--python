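"""Regional ADC statistics: anterior-posterior gradient and SI thirds.

In a supine breath-hold acquisition, gravity compresses the dependent
(posterior) lung, so healthy lungs show lower ADC posteriorly; emphysema
flattens this gradient. Two regional summaries capture this:

* ``AP_G`` — the ordinary-least-squares slope of per-slice mean ADC versus
  the AP position of the slice centre, in cm (positive slope = ADC
  increases posteriorly);
* ``dSI`` — the difference in mean ADC between the superior and inferior
  thirds of the lung, defined by dividing the SI extent of the lung on the
  centre coronal slice into three equal-height bands and applying those row
  boundaries to every slice (superior minus inferior, so an apex-dominant
  emphysema pattern gives a positive value).

When the lung height is not divisible by three the remainder rows go to the
inferior band; mask rows outside the centre-slice extent (overhang on other
slices) are assigned to the nearest band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adc import ADCMap
from .errors import RegionalError
from .volume import LungMask

SUPERIOR, MIDDLE, INFERIOR = 0, 1, 2


@dataclass
class SIBands:
    """Row partition of the SI axis into superior/middle/inferior bands.

    ``row_band[r]`` gives the band index (0=superior, 1=middle, 2=inferior)
    of row ``r``; ``bounds`` are the half-open row ranges of the three bands
    on the centre-slice lung extent.
    """

    row_band: np.ndarray
    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class APGradient:
    slope: float          # cm^2/s per cm, anterior -> posterior
    intercept: float      # cm^2/s at the anterior face
    positions_cm: np.ndarray
    slice_means: np.ndarray
    residual: float       # sum of squared OLS residuals


@dataclass
class RegionalMetrics:
    ap: APGradient
    roi_means: tuple[float, float, float]   # superior, middle, inferior
    delta_si: float


def si_bands(mask: LungMask) -> SIBands:
    """Partition the SI axis into thirds from the centre-slice lung extent."""
    n_ap, n_si, _ = mask.shape
    center = n_ap // 2
    rows = np.where(mask.data[center].any(axis=1))[0]
    if rows.size == 0:
        raise RegionalError(f"centre slice {center} has an empty mask")
    r0, r1 = int(rows[0]), int(rows[-1])
    extent = r1 - r0 + 1
    if extent < 3:
        raise RegionalError(f"lung SI extent is {extent} rows; need >= 3")
    base = extent // 3
    b0 = (r0, r0 + base)                 # superior
    b1 = (b0[1], b0[1] + base)           # middle
    b2 = (b1[1], r1 + 1)                 # inferior, takes the remainder
    row_band = np.empty(n_si, dtype=int)
    row_band[: b0[1]] = SUPERIOR         # overhang above extent -> superior
    row_band[b1[0]: b1[1]] = MIDDLE
    row_band[b2[0]:] = INFERIOR          # overhang below extent -> inferior
    return SIBands(row_band, (b0, b1, b2))


def ap_gradient(adc_map: ADCMap, pitch_cm: float | None = None) -> APGradient:
    """Fit the AP gradient of per-slice mean ADC.

    Slices with no valid voxels are dropped; at least three usable slices
    are required. Positions are slice centres in cm from the anterior face.
    """
    pitch = adc_map.ap_pitch_cm if pitch_cm is None else float(pitch_cm)
    n_ap = adc_map.shape[0]
    means, pos = [], []
    for i in range(n_ap):
        v = adc_map.valid[i]
        if v.any():
            means.append(float(np.nanmean(adc_map.data[i][v])))
            pos.append((i + 0.5) * pitch)
    if len(means) < 3:
        raise RegionalError(f"only {len(means)} usable slices; AP gradient needs >= 3")
    x = np.asarray(pos)
    y = np.asarray(means)
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sum((y - (slope * x + intercept)) ** 2))
    return APGradient(float(slope), float(intercept), x, y, resid)


def roi_means(adc_map: ADCMap, bands: SIBands) -> tuple[float, float, float]:
    """Mean ADC in the superior, middle, and inferior bands, pooled over slices."""
    out = []
    for band in (SUPERIOR, MIDDLE, INFERIOR):
        sel = adc_map.valid & (bands.row_band[None, :, None] == band)
        out.append(float(np.nanmean(adc_map.data[sel])) if sel.any() else np.nan)
    return tuple(out)  # type: ignore[return-value]


def delta_si(adc_map: ADCMap, bands: SIBands) -> float:
    """dSI = mean ADC(superior third) - mean ADC(inferior third)."""
    sup, _, inf = roi_means(adc_map, bands)
    if np.isnan(sup) or np.isnan(inf):
        raise RegionalError("superior or inferior ROI has no valid voxels")
    return sup - inf


def regional_metrics(adc_map: ADCMap, mask: LungMask) -> RegionalMetrics:
    """All regional summaries for one ADC map."""
    bands = si_bands(mask)
    ap = ap_gradient(adc_map)
    means = roi_means(adc_map, bands)
    return RegionalMetrics(ap, means, delta_si(adc_map, bands))
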