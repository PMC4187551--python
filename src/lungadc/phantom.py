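"""Synthetic lung phantoms with known ground truth.

The generator emulates a coronal multislice hyperpolarized-gas acquisition:
seven 30-mm coronal slices by default, two ellipsoidal lungs, and a true
ADC field built as

    ADC(ap, si) = baseline + ap_slope * ap_cm      (linear AP gradient)
                + si_offset on the superior third  (step, matching the
                                                    three-ROI analysis)

with optional spherical high-ADC lesions (emphysema-like heterogeneity)
overwritten last, and the whole field clipped to (0, free-diffusion
ceiling]. Paired NDW/DW images follow the mono-exponential attenuation
``S = S0 * exp(-b * ADC)`` with Rician magnitude noise (the magnitude of
the signal plus a two-component zero-mean Gaussian), Gaussian noise being
available for analytic checks. A CT companion draws lung Hounsfield values
from a bimodal mixture with a controllable fraction below -950 HU.

Every stochastic operation is reproducible from its seed, and the ground
truth carries exactly the regional summaries the analysis modules estimate,
so the generator doubles as a recovery oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PhantomError
from .regional import INFERIOR, SUPERIOR, si_bands
from .volume import (
    FREE_DIFFUSION_CEILING,
    DWAcquisition,
    ImageVolume,
    LungMask,
)


@dataclass
class Lesion:
    """A spherical region of altered ADC (index-space radius in voxels)."""

    center: tuple[int, int, int]
    radius_vox: float
    adc: float


@dataclass
class PhantomSpec:
    """Full parameterisation of the synthetic lung generator.

    Defaults reproduce the acquisition geometry the pipeline targets: seven
    coronal slices of 30 mm pitch over a 40 cm field of view (128 x 128
    in-plane), a healthy-lung baseline ADC for a He-3/N2 mixture, and no
    regional structure or noise unless requested.
    """

    shape: tuple[int, int, int] = (7, 128, 128)
    spacing: tuple[float, float, float] = (30.0, 3.125, 3.125)
    baseline_adc: float = 0.23        # cm^2/s
    ap_slope: float = 0.0             # cm^2/s per cm, anterior -> posterior
    si_offset: float = 0.0            # cm^2/s added to the superior third
    lesions: tuple[Lesion, ...] = ()
    s0_level: float = 100.0           # arbitrary signal units
    noise_sigma: float = 0.0          # same units; 0 = noiseless
    gas: str = "3He"
    noise_model: str = "rician"       # "rician" | "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise PhantomError("shape must be (n_ap, n_si, n_lr)")
        n_ap, n_si, _ = self.shape
        if n_ap < 3 or n_si < 3:
            raise PhantomError(
                f"grid {self.shape} too small: regional analyses need >= 3 AP "
                "slices and >= 3 SI rows"
            )
        if self.baseline_adc <= 0:
            raise PhantomError(f"baseline ADC must be > 0; got {self.baseline_adc}")
        if self.gas not in FREE_DIFFUSION_CEILING:
            raise PhantomError(f"unknown gas {self.gas!r}")
        ceiling = self.ceiling
        for les in self.lesions:
            if les.adc > ceiling:
                raise PhantomError(
                    f"lesion ADC {les.adc} exceeds the {self.gas} free-diffusion "
                    f"ceiling {ceiling} cm^2/s"
                )
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")
        if self.s0_level < 0:
            raise PhantomError("s0_level must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise PhantomError(f"unknown noise model {self.noise_model!r}")

    @property
    def ceiling(self) -> float:
        return FREE_DIFFUSION_CEILING[self.gas]

    @property
    def ap_pitch_cm(self) -> float:
        return self.spacing[0] / 10.0


@dataclass
class GroundTruth:
    """The phantom's true ADC field and the regional summaries it implies.

    ``region_means`` are the exact arithmetic means of the true field over
    the whole lung and the superior/middle/inferior bands; ``ap_slope`` is
    the OLS slope of the true per-slice means versus slice-centre position,
    i.e. exactly what a noiseless analysis should recover.
    """

    adc: np.ndarray                   # cm^2/s, NaN outside the mask
    mask: LungMask
    whole_lung_mean: float
    region_means: tuple[float, float, float]   # superior, middle, inferior
    ap_slope: float
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.adc.shape  # type: ignore[return-value]


def _ellipsoid_lungs(shape: tuple[int, int, int]) -> np.ndarray:
    """Two ellipsoidal lungs occupying roughly a quarter of the grid."""
    n_ap, n_si, n_lr = shape
    ap, si, lr = np.ogrid[:n_ap, :n_si, :n_lr]
    mask = np.zeros(shape, dtype=bool)
    semi = (0.45 * n_ap, 0.38 * n_si, 0.16 * n_lr)
    for lr_frac in (0.27, 0.73):
        c = (0.5 * (n_ap - 1), 0.5 * (n_si - 1), lr_frac * (n_lr - 1))
        d = ((ap - c[0]) / semi[0]) ** 2 + ((si - c[1]) / semi[1]) ** 2 \
            + ((lr - c[2]) / semi[2]) ** 2
        mask |= d <= 1.0
    return mask


def generate_lung_phantom(spec: PhantomSpec) -> tuple[LungMask, GroundTruth]:
    """Build the lung mask and true ADC field for a phantom specification."""
    from scipy import ndimage

    raw = _ellipsoid_lungs(spec.shape)
    _, n_comp = ndimage.label(raw, structure=ndimage.generate_binary_structure(3, 1))
    frac = raw.mean()
    if n_comp != 2 or not (0.2 <= frac <= 0.6):
        raise PhantomError(
            f"grid {spec.shape} cannot host two lung regions at a plausible "
            f"volume fraction (got {n_comp} components, fraction {frac:.2f})"
        )
    mask = LungMask(raw, spec.spacing)

    n_ap, n_si, n_lr = spec.shape
    ap_cm = (np.arange(n_ap) + 0.5) * spec.ap_pitch_cm
    field = spec.baseline_adc + spec.ap_slope * ap_cm[:, None, None]
    field = np.broadcast_to(field, spec.shape).copy()

    bands = si_bands(mask)
    if spec.si_offset != 0.0:
        field[:, bands.row_band == SUPERIOR, :] += spec.si_offset

    for les in spec.lesions:
        ap, si, lr = np.ogrid[:n_ap, :n_si, :n_lr]
        d2 = (ap - les.center[0]) ** 2 + (si - les.center[1]) ** 2 \
            + (lr - les.center[2]) ** 2
        field[(d2 <= les.radius_vox ** 2) & raw] = les.adc

    field = np.clip(field, np.finfo(float).tiny, spec.ceiling)

    adc = np.where(raw, field, np.nan)
    in_mask = field[raw]
    whole = float(in_mask.mean())
    region = []
    for band in (SUPERIOR, 1, INFERIOR):
        sel = raw & (bands.row_band[None, :, None] == band)
        region.append(float(field[sel].mean()) if sel.any() else float("nan"))
    slice_means = np.array([field[i][raw[i]].mean() for i in range(n_ap)])
    slope = float(np.polyfit(ap_cm, slice_means, 1)[0])
    return mask, GroundTruth(adc, mask, whole, tuple(region), slope, spec.spacing)


def simulate_dw_pair(
    truth: GroundTruth,
    b: float,
    s0_level: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    gas: str = "3He",
    noise_model: str = "rician",
) -> DWAcquisition:
    """Simulate a paired NDW/DW acquisition from a true ADC field.

    Noiseless voxel signals are ``S0 = s0_level`` inside the mask (0
    outside) and ``S = S0 * exp(-b * ADC)``. With ``noise_sigma > 0`` both
    images receive magnitude (Rician) noise; identical seeds give identical
    output.
    """
    if b < 0:
        raise PhantomError(f"b-value must be >= 0; got {b}")
    if s0_level < 0 or noise_sigma < 0:
        raise PhantomError("s0_level and noise_sigma must be >= 0")
    m = truth.mask.data
    s0 = np.where(m, s0_level, 0.0)
    s = np.where(m, s0_level * np.exp(-b * np.nan_to_num(truth.adc)), 0.0)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "rician":
            s0 = np.hypot(s0 + rng.normal(0, noise_sigma, s0.shape),
                          rng.normal(0, noise_sigma, s0.shape))
            s = np.hypot(s + rng.normal(0, noise_sigma, s.shape),
                         rng.normal(0, noise_sigma, s.shape))
        elif noise_model == "gaussian":
            s0 = s0 + rng.normal(0, noise_sigma, s0.shape)
            s = s + rng.normal(0, noise_sigma, s.shape)
        else:
            raise PhantomError(f"unknown noise model {noise_model!r}")

    ndw = ImageVolume(s0, truth.spacing, "signal")
    dw = ImageVolume(s, truth.spacing, "signal")
    return DWAcquisition(ndw, dw, b, gas)


def simulate_from_spec(spec: PhantomSpec, b: float) -> tuple[DWAcquisition, LungMask, GroundTruth]:
    """Convenience wrapper: phantom plus one simulated NDW/DW pair."""
    mask, truth = generate_lung_phantom(spec)
    acq = simulate_dw_pair(truth, b, spec.s0_level, spec.noise_sigma,
                           spec.seed, spec.gas, spec.noise_model)
    return acq, mask, truth


def generate_ct_phantom(
    frac_below_950: float,
    n_voxels: int = 100_000,
    seed: int = 0,
) -> tuple[ImageVolume, LungMask]:
    """CT-like lung volume with a controllable fraction below -950 HU.

    Lung voxels are drawn from a two-component Hounsfield mixture: an
    emphysema component centred at -990 HU (truncated below -950) chosen
    with probability ``frac_below_950``, and a parenchyma component centred
    at -860 HU (truncated above -950) otherwise. The realised fraction
    below -950 is therefore binomial around the request, and the degenerate
    requests 0 and 1 are exact.
    """
    if not 0.0 <= frac_below_950 <= 1.0:
        raise PhantomError(f"frac_below_950 must be in [0, 1]; got {frac_below_950}")
    if n_voxels < 100:
        raise PhantomError(
            f"n_voxels = {n_voxels} < 100: a relative-area fraction is meaningless"
        )
    rng = np.random.default_rng(seed)
    emph = rng.random(n_voxels) < frac_below_950
    hu = np.empty(n_voxels)
    hu[emph] = np.minimum(rng.normal(-990.0, 12.0, int(emph.sum())), -951.0)
    hu[~emph] = np.maximum(rng.normal(-860.0, 28.0, int((~emph).sum())), -949.0)
    hu = np.rint(hu)

    m = math.ceil(math.sqrt(n_voxels))
    grid = np.full((1, m, m), 40.0)          # soft tissue outside the lung
    lung = np.zeros((1, m, m), dtype=bool)
    flat = lung.reshape(-1)
    flat[:n_voxels] = True
    grid.reshape(-1)[:n_voxels] = hu
    spacing = (1.25, 0.625, 0.625)
    return ImageVolume(grid, spacing, "hu"), LungMask(lung, spacing)
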