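"""In-memory containers for image volumes, masks, and paired acquisitions.

Axis convention
---------------
All grids are indexed ``(ap_slice, si_row, lr_col)``, 0-based:

* axis 0 runs anterior (index 0) to posterior — the coronal slice stack;
* axis 1 runs superior (index 0) to inferior;
* axis 2 runs left to right.

Voxel spacing is stored in millimetres per axis. The anterior-posterior
pitch (slice thickness plus gap) is exposed in centimetres because all
gradient statistics are expressed per centimetre of AP distance. The AP
position of slice ``i`` is defined at the slice centre, ``(i + 0.5) * pitch``;
any affine choice of origin leaves fitted slopes unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import VolumeError

#: Recognised value-semantics tags.
SEMANTICS = ("signal", "adc", "hu")

#: Free-diffusion ceilings of the imaged gas mixtures (cm^2/s): the
#: self-diffusion coefficient of the unrestricted mixture is the physical
#: upper bound for any ADC measured with that gas.
FREE_DIFFUSION_CEILING = {"3He": 0.826, "129Xe": 0.211}

#: Self-diffusion coefficient of room air (cm^2/s), for context only.
ROOM_AIR_DIFFUSION = 0.218


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing and a value-semantics tag.

    Parameters
    ----------
    data:
        3-D array indexed ``(ap, si, lr)``. Stored as float64; NaN is the
        missing-value sentinel.
    spacing:
        Voxel spacing in mm per axis ``(ap, si, lr)``. Along AP this is the
        slice pitch (thickness + gap).
    semantics:
        One of ``"signal"`` (arbitrary MR units), ``"adc"`` (cm^2/s),
        ``"hu"`` (Hounsfield units).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (30.0, 3.125, 3.125)
    semantics: str = "signal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(
                f"volume must be 3-D (ap, si, lr); got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 1:
            raise VolumeError(f"all dimensions must be >= 1; got {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be three positive mm values; got {self.spacing}")
        if self.semantics not in SEMANTICS:
            raise VolumeError(f"semantics must be one of {SEMANTICS}; got {self.semantics!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        """Number of coronal (AP) slices."""
        return self.data.shape[0]

    @property
    def ap_pitch_cm(self) -> float:
        """Anterior-posterior slice pitch in centimetres."""
        return self.spacing[0] / 10.0

    def slice_centers_cm(self) -> np.ndarray:
        """AP positions of the slice centres in cm, origin at the anterior face."""
        return (np.arange(self.n_slices) + 0.5) * self.ap_pitch_cm

    def copy_with(self, data: np.ndarray, semantics: str | None = None) -> "ImageVolume":
        return ImageVolume(data, self.spacing, semantics or self.semantics)


@dataclass
class LungMask:
    """Binary parenchyma mask aligned to an :class:`ImageVolume`.

    Defines "lung" for every downstream statistic. Shape and spacing follow
    the source volume.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (30.0, 3.125, 3.125)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise VolumeError(f"mask must be 3-D; got {self.data.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def per_slice_counts(self) -> np.ndarray:
        return self.data.sum(axis=(1, 2))

    @property
    def ap_pitch_cm(self) -> float:
        return self.spacing[0] / 10.0

    def check_aligned(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape:
            raise VolumeError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


@dataclass
class PulseMetadata:
    """Diffusion-sensitisation pulse parameters, carried as metadata only.

    The b-value is consumed directly; these fields document the gradient
    waveform that produced it (amplitude in G/cm, times in ms).
    """

    gradient_amplitude: float | None = None
    rise_fall_ms: float | None = None
    duration_ms: float | None = None
    separation_ms: float | None = None
    diffusion_time_ms: float | None = None


@dataclass
class DWAcquisition:
    """A paired non-diffusion-weighted / diffusion-weighted volume set.

    ``ndw`` is the b~0 image (S0 of the mono-exponential attenuation model),
    ``dw`` the diffusion-sensitised image (S), with
    ``S = S0 * exp(-b * ADC)`` at every voxel.
    """

    ndw: ImageVolume
    dw: ImageVolume
    b_value: float
    gas: str = "3He"
    pulse: PulseMetadata = field(default_factory=PulseMetadata)

    def __post_init__(self) -> None:
        if self.ndw.shape != self.dw.shape:
            raise VolumeError(
                f"NDW shape {self.ndw.shape} != DW shape {self.dw.shape}"
            )
        if self.ndw.spacing != self.dw.spacing:
            raise VolumeError("NDW and DW volumes must share voxel spacing")
        if self.b_value < 0:
            raise VolumeError(f"b-value must be >= 0 s/cm^2; got {self.b_value}")
        if self.gas not in FREE_DIFFUSION_CEILING:
            raise VolumeError(
                f"gas must be one of {tuple(FREE_DIFFUSION_CEILING)}; got {self.gas!r}"
            )
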