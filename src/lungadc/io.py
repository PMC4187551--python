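"""NIfTI-1 readers/writers, flat-file configuration, and logging.

Volumes are stored with the package's ``(ap, si, lr)`` axis order mapped
directly onto the NIfTI array axes, with a diagonal affine built from the
voxel spacing. Any axis handling is logged; axes are never silently
reoriented.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, VolumeError
from .volume import SEMANTICS, ImageVolume, LungMask

log = logging.getLogger("lungadc")


def read_volume(path: str | Path, semantics: str = "signal") -> ImageVolume:
    """Read a 3-D NIfTI-1 volume.

    The array axes are interpreted as ``(ap, si, lr)`` as written by
    :func:`write_volume`; voxel spacing is taken from the header zooms.
    Raises :class:`VolumeError` for unreadable files, non-3-D data, or
    non-positive spacing.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several distinct types
        raise VolumeError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D data of shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise VolumeError(f"{path}: non-positive voxel spacing {zooms}")
    descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="replace")
    tag = descrip if descrip in SEMANTICS else semantics
    log.info(
        "read %s: shape %s, spacing %s mm, axes taken as (AP, SI, LR) without reorientation",
        path, data.shape, tuple(float(z) for z in zooms),
    )
    return ImageVolume(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), tag)


def write_volume(volume: ImageVolume | LungMask, path: str | Path) -> Path:
    """Write a volume or mask as NIfTI-1 with a diagonal spacing affine."""
    path = Path(path)
    if isinstance(volume, LungMask):
        data = volume.data.astype(np.uint8)
        semantics = "signal"
    else:
        data = volume.data
        semantics = volume.semantics
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = semantics.encode()
    nib.save(img, str(path))
    log.info("wrote %s: shape %s, axes (AP, SI, LR)", path, data.shape)
    return path


# --- configuration ----------------------------------------------------------

#: Known configuration keys with their defaults. The config file is a flat
#: YAML mapping; unknown keys are errors, not warnings.
CONFIG_SCHEMA: dict[str, object] = {
    "mode": "phantom",            # "phantom" | "fixture" | "files"
    "output_dir": "out",
    "seed": 0,
    # phantom mode
    "grid_shape": [7, 128, 128],
    "spacing_mm": [30.0, 3.125, 3.125],
    "baseline_adc": 0.23,
    "ap_slope": 0.0,
    "si_offset": 0.0,
    "lesions": [],                # list of [ap, si, lr, radius_vox, adc]
    "s0_level": 100.0,
    "noise_sigma": 0.0,
    "noise_model": "rician",
    "gas": "3He",
    "b_value": 1.6,
    "ct_frac_below_950": None,    # optional CT phantom
    "ct_n_voxels": 100000,
    # files mode
    "ndw_path": None,
    "dw_path": None,
    "ct_path": None,
    "ct_mask_path": None,
    # analysis options
    "kmeans_k": 4,
    "negative_adc_policy": "retain",
    "snr_noise_definition": "pooled",
}


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config, applying defaults and rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a flat mapping; got {type(raw).__name__}")
    unknown = sorted(set(raw) - set(CONFIG_SCHEMA))
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    cfg = dict(CONFIG_SCHEMA)
    cfg.update(raw)
    return cfg


def setup_logging(verbosity: int = 0, logfile: str | Path | None = None) -> None:
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile, mode="w"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
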