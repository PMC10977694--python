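"""Nucleus-image condensation pipeline: contrast enhancement, background
subtraction, density heatmap and total aggregate area.

Mesenchymal condensations appear in the nucleus channel as dense cell
clusters.  The pipeline mirrors intensity-based cluster quantification:

1. circular crop (uneven illumination at well corners is excluded),
2. CLAHE contrast enhancement,
3. background subtraction via the combination of a global (Otsu) and a
   local adaptive (mean-of-neighborhood) foreground mask,
4. Gaussian (or uniform) density filtering and max-normalization to a
   [0, 1] heatmap,
5. thresholding at 0.5 and summing the surviving foreground area.

Manual removal of debris spots is replaced by a reproducible
minimum-component-area filter.  The "radius 100 px" density filter is
realized as a Gaussian with sigma = radius / 2 by default; a uniform
100-px averaging kernel (used for density colormaps around -1/2 defects)
is available via ``kernel="uniform"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, measure

from .io import CircularMask, WellImage

logger = logging.getLogger("swirlquant")


@dataclass
class DensityHeatmap:
    """Max-normalized nucleus density field in [0, 1]."""

    values: np.ndarray
    filter_radius_px: float
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1.0 + 1e-9):
            raise ValueError("heatmap values must lie in [0, 1]")


@dataclass
class AggregateMask:
    """Binary condensation mask and its total area."""

    mask: np.ndarray
    threshold: float
    total_area_px: int
    total_area_um2: float
    n_components: int


def preprocess_nuclei(
    image: WellImage,
    mask: Optional[CircularMask] = None,
    clahe_clip_limit: float = 0.01,
    clahe_tiles: int = 8,
    local_window_px: int = 101,
    combine: str = "and",
) -> np.ndarray:
    """Crop, CLAHE-enhance and background-subtract a nucleus image.

    Two foreground masks are built — a global Otsu threshold and a local
    adaptive (neighborhood-mean) threshold — and combined (``"and"`` by
    default: a pixel must pass both to survive; ``"or"`` keeps either).
    Background pixels are set to zero.  Returns the cleaned array (pixels
    outside the circular crop are zero as well).
    """
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    px = image.pixels
    inside = mask.boolean(px.shape) if mask is not None else np.ones(px.shape, bool)
    work = np.where(inside & np.isfinite(px), px, 0.0)

    lo, hi = work.min(), work.max()
    if hi <= lo:
        logger.warning("nucleus image is constant; empty foreground")
        return np.zeros_like(work)
    scaled = (work - lo) / (hi - lo)

    kernel = (max(px.shape[0] // clahe_tiles, 1), max(px.shape[1] // clahe_tiles, 1))
    enhanced = exposure.equalize_adapthist(scaled, kernel_size=kernel,
                                           clip_limit=clahe_clip_limit)

    vals = enhanced[inside]
    if np.ptp(vals) == 0:
        logger.warning("no contrast after equalization; empty foreground")
        return np.zeros_like(work)
    global_fg = enhanced > filters.threshold_otsu(vals)
    local_fg = enhanced > filters.threshold_local(
        enhanced, block_size=local_window_px, method="mean", offset=0.0)
    fg = (global_fg & local_fg) if combine == "and" else (global_fg | local_fg)
    fg &= inside
    if not fg.any():
        logger.warning("empty foreground after background subtraction")
    return np.where(fg, enhanced, 0.0)


def density_heatmap(
    cleaned: np.ndarray, filter_radius_px: float = 100.0, kernel: str = "gaussian"
) -> DensityHeatmap:
    """Smooth a cleaned nucleus image into a max-normalized density heatmap.

    ``kernel="gaussian"`` uses sigma = filter_radius_px / 2;
    ``kernel="uniform"`` averages over a square window of edge
    ``filter_radius_px`` (the density-colormap convention).
    An all-zero input yields an all-zero heatmap (normalization skipped).
    """
    if filter_radius_px <= 0:
        raise ValueError("filter_radius_px must be > 0")
    if kernel == "gaussian":
        smooth = ndimage.gaussian_filter(cleaned, filter_radius_px / 2.0, mode="constant")
    elif kernel == "uniform":
        smooth = ndimage.uniform_filter(cleaned, size=int(round(filter_radius_px)),
                                        mode="constant")
    else:
        raise ValueError("kernel must be 'gaussian' or 'uniform'")
    peak = smooth.max()
    if peak > 0:
        smooth = smooth / peak
    return DensityHeatmap(values=smooth, filter_radius_px=filter_radius_px, kernel=kernel)


def aggregate_area(
    heatmap: DensityHeatmap,
    threshold: float = 0.5,
    min_component_px: int = 0,
    pixel_size_um: float = 1.6,
) -> AggregateMask:
    """Binary condensation mask (heatmap >= threshold) and total area.

    Connected components smaller than *min_component_px* pixels are
    removed, replacing manual debris curation with a reproducible filter.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    binary = heatmap.values >= threshold
    if min_component_px > 0:
        labels = measure.label(binary)
        counts = np.bincount(labels.ravel())
        small = counts < min_component_px
        small[0] = False
        binary = binary & ~small[labels]
    n_components = int(measure.label(binary).max())
    area_px = int(binary.sum())
    return AggregateMask(
        mask=binary,
        threshold=threshold,
        total_area_px=area_px,
        total_area_um2=float(area_px) * pixel_size_um**2,
        n_components=n_components,
    )
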