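"""ROI-based signal-to-noise estimation for NDW and DW images.

Per coronal slice, four 5x5-voxel ROIs are placed in the lung parenchyma
and four in the image background. The slice SNR is the mean of the four
parenchyma-ROI means divided by a noise estimate from the background ROIs;
the subject-level SNR is the mean over evaluable slices.

Two noise definitions are provided because the ROI recipe is ambiguous:

* ``"pooled"`` (default) — the standard deviation of all 100 voxel values
  pooled across the four background ROIs; statistically stable (n = 100);
* ``"roi_means"`` — the standard deviation of the four background-ROI
  means; a literal four-value SD, fragile (n = 4) and reported for
  comparison.

Placement is automated and deterministic: parenchyma ROIs target the
centroids of the four quadrants of the slice mask and are shifted to the
nearest fully-inside position; background ROIs target the slice corners
and are shifted until the whole ROI keeps a 2-voxel margin from the mask.
Optional seeded jitter perturbs the targets for sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import SnrError
from .volume import ImageVolume, LungMask

NOISE_DEFINITIONS = ("pooled", "roi_means")
ROI_SIZE = 5
BACKGROUND_MARGIN = 2


@dataclass
class SnrResult:
    value: float                       # subject-level SNR (mean over slices)
    per_slice: dict[int, float]        # slice index -> SNR
    placements: dict[int, dict[str, list[tuple[int, int]]]]  # ROI corner coords


def _valid_placements(allowed: np.ndarray) -> np.ndarray:
    """Top-left corners where a ROI_SIZE square lies wholly in ``allowed``."""
    ok = ndimage.minimum_filter(allowed.astype(np.uint8), size=ROI_SIZE,
                                mode="constant", cval=0).astype(bool)
    # minimum_filter is centred; shift to top-left corner coordinates
    h = ROI_SIZE // 2
    out = np.zeros_like(ok)
    out[:allowed.shape[0] - 2 * h, :allowed.shape[1] - 2 * h] = ok[h:-h or None, h:-h or None]
    return out


def _nearest_placement(valid: np.ndarray, target: tuple[float, float],
                       taken: list[tuple[int, int]]) -> tuple[int, int] | None:
    """Valid top-left corner nearest to ``target`` not overlapping ``taken``."""
    cand = np.argwhere(valid)
    if cand.size == 0:
        return None
    d2 = (cand[:, 0] - (target[0] - ROI_SIZE / 2 + 0.5)) ** 2 \
        + (cand[:, 1] - (target[1] - ROI_SIZE / 2 + 0.5)) ** 2
    for idx in np.argsort(d2, kind="stable"):
        r, c = int(cand[idx, 0]), int(cand[idx, 1])
        if all(abs(r - tr) >= ROI_SIZE or abs(c - tc) >= ROI_SIZE for tr, tc in taken):
            return (r, c)
    return None


def _slice_rois(mask2d: np.ndarray, jitter: float, rng: np.random.Generator
                ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]] | None:
    """Four parenchyma and four background ROI corners for one slice."""
    if not mask2d.any():
        return None
    rows, cols = np.nonzero(mask2d)
    cr, cc = rows.mean(), cols.mean()
    quadrants = [
        (rows < cr) & (cols < cc), (rows < cr) & (cols >= cc),
        (rows >= cr) & (cols < cc), (rows >= cr) & (cols >= cc),
    ]
    valid_par = _valid_placements(mask2d)
    parenchyma: list[tuple[int, int]] = []
    for q in quadrants:
        if not q.any():
            return None
        target = (rows[q].mean(), cols[q].mean())
        if jitter > 0:
            target = (target[0] + rng.normal(0, jitter), target[1] + rng.normal(0, jitter))
        p = _nearest_placement(valid_par, target, parenchyma)
        if p is None:
            return None
        parenchyma.append(p)

    dilated = ndimage.binary_dilation(mask2d, iterations=BACKGROUND_MARGIN)
    valid_bg = _valid_placements(~dilated)
    nr, nc = mask2d.shape
    corners = [(0.0, 0.0), (0.0, nc - 1.0), (nr - 1.0, 0.0), (nr - 1.0, nc - 1.0)]
    background: list[tuple[int, int]] = []
    for target in corners:
        if jitter > 0:
            target = (target[0] + rng.normal(0, jitter), target[1] + rng.normal(0, jitter))
        p = _nearest_placement(valid_bg, target, background)
        if p is None:
            return None
        background.append(p)
    return parenchyma, background


def _roi_values(img2d: np.ndarray, corner: tuple[int, int]) -> np.ndarray:
    r, c = corner
    return img2d[r:r + ROI_SIZE, c:c + ROI_SIZE]


def compute_snr(
    volume: ImageVolume,
    mask: LungMask,
    noise_definition: str = "pooled",
    jitter: float = 0.0,
    seed: int = 0,
) -> SnrResult:
    """Subject-level ROI SNR for one image volume.

    Slices that cannot host four disjoint parenchyma and four disjoint
    background placements are skipped; at least one evaluable slice is
    required, and a zero noise estimate is rejected.
    """
    if noise_definition not in NOISE_DEFINITIONS:
        raise SnrError(f"noise_definition must be one of {NOISE_DEFINITIONS}")
    mask.check_aligned(volume)
    rng = np.random.default_rng(seed)
    per_slice: dict[int, float] = {}
    placements: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for i in range(volume.n_slices):
        rois = _slice_rois(mask.data[i], jitter, rng)
        if rois is None:
            continue
        par, bg = rois
        img = volume.data[i]
        signal = float(np.mean([_roi_values(img, p).mean() for p in par]))
        if noise_definition == "pooled":
            noise = float(np.concatenate([_roi_values(img, p).ravel() for p in bg]).std(ddof=1))
        else:
            noise = float(np.std([_roi_values(img, p).mean() for p in bg], ddof=1))
        if noise == 0:
            raise SnrError(f"slice {i}: zero noise estimate")
        per_slice[i] = signal / noise
        placements[i] = {"parenchyma": par, "background": bg}
    if not per_slice:
        raise SnrError("no slice admits four parenchyma and four background ROIs")
    return SnrResult(float(np.mean(list(per_slice.values()))), per_slice, placements)
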