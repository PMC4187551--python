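"""Lung segmentation by 1-D k-means intensity clustering.

The non-diffusion-weighted image is clustered into ``k`` intensity groups;
the lowest-mean cluster is taken as background and the mask is the union of
the remaining clusters, cleaned up by keeping the largest connected
components (up to two, one per lung; 6-connectivity in 3-D) and filling
holes. The resulting binary mask is then applied to the diffusion-weighted
image so that both images share one parenchyma definition.

k-means runs on voxel intensities only (1-D), initialised at evenly spaced
intensity quantiles with a single deterministic restart, so the mask is
reproducible and invariant under positive affine rescaling of the image.
Non-finite voxels are treated as zero intensity (background air) before
clustering, which makes segmentation idempotent on already-masked images.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .errors import SegmentationError
from .volume import ImageVolume, LungMask


def kmeans_segment(
    ndw: ImageVolume,
    k: int = 4,
    seed: int = 0,
    max_components: int = 2,
) -> LungMask:
    """Segment the lungs from a non-diffusion-weighted image.

    Parameters
    ----------
    ndw:
        The b~0 image. Must contain at least ``k`` distinct intensities.
    k:
        Number of intensity clusters. The default is a multi-class
        clustering (k=4) with the lowest cluster as background.
    seed:
        Carried to the clusterer for reproducibility; with quantile
        initialisation and one restart the result is seed-independent.
    max_components:
        Largest connected components retained after thresholding.

    Raises
    ------
    SegmentationError
        For constant images, fewer than ``k`` distinct intensities, or an
        empty mask after cleanup.
    """
    values = np.nan_to_num(ndw.data, nan=0.0, posinf=0.0, neginf=0.0)
    flat = values.reshape(-1, 1)
    uniq = np.unique(flat)
    if uniq.size < 2:
        raise SegmentationError("constant-intensity image cannot be segmented")
    if uniq.size < k:
        raise SegmentationError(
            f"image has {uniq.size} distinct intensities; k={k} requires at least k"
        )
    init = np.quantile(flat, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300, tol=1e-8,
                random_state=seed)
    labels = km.fit_predict(flat).reshape(values.shape)
    background = int(np.argmin(km.cluster_centers_.ravel()))
    mask = labels != background

    # keep the largest components (6-connectivity) and fill holes
    structure = ndimage.generate_binary_structure(3, 1)
    comp, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        raise SegmentationError("empty mask after thresholding")
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
    keep = np.argsort(sizes)[::-1][:max_components] + 1
    mask = np.isin(comp, keep)
    mask = ndimage.binary_fill_holes(mask, structure=structure)
    if not mask.any():
        raise SegmentationError("empty mask after component cleanup")
    return LungMask(mask, ndw.spacing)


def apply_mask(volume: ImageVolume, mask: LungMask) -> ImageVolume:
    """Set voxels outside the mask to NaN; voxels inside are unchanged."""
    mask.check_aligned(volume)
    out = volume.data.copy()
    out[~mask.data] = np.nan
    return volume.copy_with(out)
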