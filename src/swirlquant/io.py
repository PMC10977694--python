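"""Image and table input/output, circular region masks, and run configuration.

Whole-well images are single-channel grayscale TIFFs.  On load, integer
pixel values are rescaled to floats in [0, 1] by the dtype maximum so every
downstream stage sees the same intensity scale regardless of bit depth.

Coordinate convention (used package-wide): pixel (x, y) has x = column
index and y = row index, both 0-based.  Angles are measured counter-
clockwise from the +x axis with the y axis pointing *up*, so a feature
running from lower-left to upper-right of the displayed image has a
positive angle.  Internally this means the row-derivative is negated when
gradients are formed (see ``orientation``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("swirlquant")

VALID_CHANNELS = ("actin", "nucleus", "phase", "other")
VALID_DAYS = (3, 6, 9, 12)

#: physical pixel edge of the reference acquisition setup (4x objective), µm
DEFAULT_PIXEL_SIZE_UM = 1.6

#: default circular-crop radii in pixels: whole-well crop, coherency
#: analysis crop (edge effects removed), nuclei analysis crop
RADIUS_WELL_PX = 3636
RADIUS_COHERENCY_PX = 3336
RADIUS_NUCLEI_PX = 2136


@dataclass
class WellImage:
    """A 2D grayscale intensity field plus acquisition metadata."""

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    channel: str = "other"
    well_id: Optional[str] = None
    donor_id: Optional[str] = None
    day: Optional[int] = None
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"expected a 2D single-channel image, got shape {self.pixels.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"channel must be one of {VALID_CHANNELS}")
        if self.day is not None and self.day not in VALID_DAYS:
            raise ValueError(f"day must be one of {VALID_DAYS} when set")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class CircularMask:
    """A circular analysis region: center (cx, cy) and radius, in pixels."""

    cx_px: float
    cy_px: float
    radius_px: float

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("mask radius must be > 0")

    @classmethod
    def centered(cls, shape: tuple[int, int], radius_px: Optional[float] = None) -> "CircularMask":
        """Mask centered on an image of the given (rows, cols) shape.

        When *radius_px* is omitted the largest inscribed circle is used.
        """
        h, w = shape
        if radius_px is None:
            radius_px = min(h, w) / 2.0
        return cls(cx_px=(w - 1) / 2.0, cy_px=(h - 1) / 2.0, radius_px=radius_px)

    def boolean(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean array: True inside the circle (clipped to the image)."""
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        inside = (xx - self.cx_px) ** 2 + (yy - self.cy_px) ** 2 <= self.radius_px**2
        if not inside.any():
            raise ValueError("circular mask lies entirely outside the image")
        full = (
            self.cx_px - self.radius_px >= -0.5
            and self.cx_px + self.radius_px <= w - 0.5
            and self.cy_px - self.radius_px >= -0.5
            and self.cy_px + self.radius_px <= h - 0.5
        )
        if not full:
            logger.warning("circular mask extends beyond the image; clipping")
        return inside


def _normalize_pixels(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    return arr.astype(np.float64)


def read_well_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                    channel: str = "other", well_id: Optional[str] = None,
                    donor_id: Optional[str] = None, day: Optional[int] = None,
                    replicate: Optional[int] = None) -> WellImage:
    """Read a single-channel grayscale TIFF as a :class:`WellImage`.

    8/16-bit integer data are rescaled to [0, 1]; float data are taken as-is.
    Multi-channel (RGB or stacked) TIFFs are rejected.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale TIFF (2D), "
            f"got array of shape {arr.shape} (multi-channel or stacked input)"
        )
    if not np.all(np.isfinite(arr.astype(np.float64))):
        raise ValueError(f"{path}: image contains non-finite pixel values")
    return WellImage(
        pixels=_normalize_pixels(arr), pixel_size_um=pixel_size_um, channel=channel,
        well_id=well_id, donor_id=donor_id, day=day, replicate=replicate,
    )


def write_well_image(path: str | Path, image: WellImage, dtype: str = "uint16") -> None:
    """Write a :class:`WellImage` to TIFF, rescaling [0, 1] floats to *dtype*."""
    px = np.clip(image.pixels, 0.0, 1.0)
    if dtype == "uint16":
        out = np.round(px * 65535.0).astype(np.uint16)
    elif dtype == "uint8":
        out = np.round(px * 255.0).astype(np.uint8)
    elif dtype == "float32":
        out = px.astype(np.float32)
    else:
        raise ValueError("dtype must be uint8, uint16 or float32")
    tifffile.imwrite(str(path), out)


def apply_circular_crop(image: WellImage, mask: CircularMask) -> WellImage:
    """Set pixels outside the circle to NaN (an excluded-value sentinel).

    NaN pixels are ignored by every downstream statistic (histograms,
    variance, density normalization); they are never zero-filled into
    averages.
    """
    inside = mask.boolean(image.shape)
    px = image.pixels.copy()
    px[~inside] = np.nan
    return dataclasses.replace(image, pixels=px)


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """All stage parameters with their defaults.

    Defaults mirror the reference acquisition setup: 100-px Gaussian
    analysis window for the structure tensor, circular crops of 3636 px
    (whole well), 3336 px (coherency) and 2136 px (nuclei), 100-px radius
    density filter, and a 0.5 normalized-density threshold.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    # orientation stage
    window_sigma: float = 100.0
    gradient_sigma: float = 1.0
    # defect stage
    block_px: int = 20
    min_abs_charge: float = 0.25
    merge_radius_blocks: int = 2
    # analysis masks
    well_radius_px: float = RADIUS_WELL_PX
    coherency_radius_px: float = RADIUS_COHERENCY_PX
    nuclei_radius_px: float = RADIUS_NUCLEI_PX
    # VoC stage
    histogram_bins: int = 256
    # nucleus stage
    density_filter_radius_px: float = 100.0
    density_kernel: str = "gaussian"
    aggregate_threshold: float = 0.5
    min_component_px: int = 5000
    clahe_clip_limit: float = 0.01
    clahe_tiles: int = 8
    local_threshold_window_px: int = 101
    mask_combine: str = "and"
    # correlation stage
    pooled_replicates: bool = False
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "pixel_size_um", "window_sigma", "gradient_sigma", "well_radius_px",
            "coherency_radius_px", "nuclei_radius_px", "density_filter_radius_px",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.block_px < 2:
            raise ValueError("block_px must be >= 2")
        if not 0 < self.min_abs_charge <= 0.5:
            raise ValueError("min_abs_charge must lie in (0, 0.5]")
        if self.merge_radius_blocks < 1:
            raise ValueError("merge_radius_blocks must be >= 1")
        if not 0 < self.aggregate_threshold < 1:
            raise ValueError("aggregate_threshold must lie in (0, 1)")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.density_kernel not in ("gaussian", "uniform"):
            raise ValueError("density_kernel must be 'gaussian' or 'uniform'")
        if self.mask_combine not in ("and", "or"):
            raise ValueError("mask_combine must be 'and' or 'or'")
        if self.local_threshold_window_px % 2 == 0:
            raise ValueError("local_threshold_window_px must be odd")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable digest of all parameters, stamped into output CSVs."""
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]
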