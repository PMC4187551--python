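"""Voxel-wise apparent diffusion coefficient mapping.

With mono-exponential diffusion attenuation ``S = S0 * exp(-b * ADC)``, the
ADC at each lung voxel is recovered as

    ADC = ln(S0 / S) / b        (cm^2/s, b in s/cm^2)

from the paired non-diffusion-weighted (S0) and diffusion-weighted (S)
images. Voxels with non-positive S or S0 are undefined. At low SNR, noise
can push S above S0 and produce negative ADC values; by default these are
retained (excluding or clamping them biases the whole-lung mean upward),
with clamping and exclusion available as explicit policies. No noise-floor
subtraction is applied; noise is quantified, not corrected, by the SNR
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AdcError
from .volume import FREE_DIFFUSION_CEILING, DWAcquisition, ImageVolume, LungMask

#: Policies for noise-induced negative ADC voxels.
NEGATIVE_POLICIES = ("retain", "clamp", "exclude")


@dataclass
class ADCMap:
    """An ADC grid (cm^2/s) with its validity mask and provenance.

    ``data`` is NaN wherever ``valid`` is False; the validity mask is a
    subset of the lung mask used to compute the map.
    """

    data: np.ndarray
    valid: np.ndarray
    b_value: float
    gas: str = "3He"
    spacing: tuple[float, float, float] = (30.0, 3.125, 3.125)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def ap_pitch_cm(self) -> float:
        return self.spacing[0] / 10.0

    def to_volume(self) -> ImageVolume:
        return ImageVolume(self.data, self.spacing, "adc")


def compute_adc_map(
    acq: DWAcquisition,
    mask: LungMask,
    negative_policy: str = "retain",
    clamp_ceiling: bool = False,
) -> ADCMap:
    """Compute the voxel-wise ADC map for a paired NDW/DW acquisition.

    Parameters
    ----------
    acq:
        The NDW/DW pair; ``b_value`` must be strictly positive.
    mask:
        Lung mask defining the voxels considered.
    negative_policy:
        ``"retain"`` keeps negative ADC values (default), ``"clamp"`` sets
        them to 0, ``"exclude"`` drops them from the validity mask.
    clamp_ceiling:
        If true, values above the gas free-diffusion ceiling are clamped to
        the ceiling.
    """
    if acq.b_value == 0:
        raise AdcError("ADC is undefined at b = 0 (division by zero)")
    if negative_policy not in NEGATIVE_POLICIES:
        raise AdcError(f"negative_policy must be one of {NEGATIVE_POLICIES}")
    mask.check_aligned(acq.ndw)

    s0 = acq.ndw.data
    s = acq.dw.data
    valid = mask.data & (s0 > 0) & (s > 0) & np.isfinite(s0) & np.isfinite(s)
    adc = np.full(s0.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s0[valid] / s[valid]) / acq.b_value

    if negative_policy == "clamp":
        adc[valid & (adc < 0)] = 0.0
    elif negative_policy == "exclude":
        drop = valid & (adc < 0)
        valid = valid & ~drop
        adc[drop] = np.nan
    if clamp_ceiling:
        ceiling = FREE_DIFFUSION_CEILING[acq.gas]
        adc[valid & (adc > ceiling)] = ceiling
    return ADCMap(adc, valid, acq.b_value, acq.gas, acq.ndw.spacing)


def mean_adc(adc_map: ADCMap) -> float:
    """Arithmetic mean ADC over valid voxels (cm^2/s)."""
    if not adc_map.valid.any():
        raise AdcError("no valid voxels in ADC map")
    return float(np.nanmean(adc_map.data[adc_map.valid]))
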