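"""Structure-tensor orientation, coherency and energy fields.

The local orientation of a fibrous texture is estimated from the structure
tensor

    J = [[ <Ix^2>_w   <Ix Iy>_w ],
         [ <Ix Iy>_w  <Iy^2>_w ]],

where Ix, Iy are Gaussian-derivative image gradients (scale
``gradient_sigma``) and <.>_w denotes Gaussian window averaging (scale
``window_sigma``).  The dominant feature orientation, coherency and energy
follow from the tensor's eigen-structure:

    theta = 1/2 * atan2(2 Jxy, Jyy - Jxx)           (degrees, [-90, +90))
    C     = sqrt((Jyy - Jxx)^2 + 4 Jxy^2) / (Jxx + Jyy)   in [0, 1]
    E     = Jxx + Jyy

Coherency is the normalized eigenvalue contrast (lmax - lmin)/(lmax + lmin):
1 for a perfectly oriented neighborhood, 0 for an isotropic or constant
one.  Degenerate pixels (E = 0, e.g. constant regions) are assigned C = 0
and theta = 0 by convention — a constant region carries no orientation and
is isotropic.

Angles follow the package convention (x right, y up, counter-clockwise
positive as the image is displayed).  With gradients taken along columns
(Ix) and rows (Iy) the atan2 form above returns exactly that display
angle, so no axis flip is applied.  All convolutions use reflective
boundary padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import WellImage


def wrap_angle_deg(theta: np.ndarray | float) -> np.ndarray | float:
    """Reduce director angles (mod 180) into [-90, +90) degrees."""
    return (np.asarray(theta, dtype=np.float64) + 90.0) % 180.0 - 90.0


@dataclass
class TensorField:
    """Window-averaged gradient-product components of the structure tensor."""

    jxx: np.ndarray
    jxy: np.ndarray
    jyy: np.ndarray

    def __post_init__(self) -> None:
        if not (self.jxx.shape == self.jxy.shape == self.jyy.shape):
            raise ValueError("tensor components must share one shape")


@dataclass
class OrientationField:
    """Per-pixel orientation theta (deg, [-90, +90)), coherency C, energy E."""

    theta_deg: np.ndarray
    coherency: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        if not (self.theta_deg.shape == self.coherency.shape == self.energy.shape):
            raise ValueError("field components must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_deg.shape  # type: ignore[return-value]


def compute_structure_tensor(
    image: WellImage | np.ndarray,
    gradient_sigma: float = 1.0,
    window_sigma: float = 100.0,
) -> TensorField:
    """Gaussian-derivative gradients, Gaussian-window-averaged outer products.

    Parameters
    ----------
    image : WellImage or 2D array of intensities.
    gradient_sigma : scale (px) of the Gaussian derivative operator.
    window_sigma : scale (px) of the Gaussian averaging window.  The default
        of 100 px matches the whole-well analysis window; use a smaller value
        for small test images.
    """
    px = image.pixels if isinstance(image, WellImage) else np.asarray(image, dtype=np.float64)
    if px.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {px.shape}")
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains NaN or infinite values; crop masks "
                         "apply after orientation analysis, not before")
    if gradient_sigma <= 0 or window_sigma <= 0:
        raise ValueError("gradient_sigma and window_sigma must be > 0")

    ix = ndimage.gaussian_filter(px, gradient_sigma, order=(0, 1), mode="reflect")
    iy = ndimage.gaussian_filter(px, gradient_sigma, order=(1, 0), mode="reflect")

    def window(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, window_sigma, mode="reflect")

    return TensorField(jxx=window(ix * ix), jxy=window(ix * iy), jyy=window(iy * iy))


def orientation_from_tensor(tensor: TensorField) -> OrientationField:
    """Orientation, coherency and energy from a structure-tensor field."""
    jxx, jxy, jyy = tensor.jxx, tensor.jxy, tensor.jyy
    energy = jxx + jyy
    degenerate = energy <= 0

    theta = np.degrees(0.5 * np.arctan2(2.0 * jxy, jyy - jxx))
    theta = wrap_angle_deg(theta)

    with np.errstate(divide="ignore", invalid="ignore"):
        coherency = np.sqrt((jyy - jxx) ** 2 + 4.0 * jxy**2) / energy
    theta = np.where(degenerate, 0.0, theta)
    coherency = np.where(degenerate, 0.0, coherency)
    coherency = np.clip(coherency, 0.0, 1.0)
    return OrientationField(theta_deg=theta, coherency=coherency,
                            energy=np.maximum(energy, 0.0))


def compute_orientation_field(
    image: WellImage | np.ndarray,
    gradient_sigma: float = 1.0,
    window_sigma: float = 100.0,
) -> OrientationField:
    """Convenience: structure tensor then orientation in one call."""
    return orientation_from_tensor(
        compute_structure_tensor(image, gradient_sigma, window_sigma)
    )


def orientation_vectorfield(field: OrientationField, step: int) -> np.ndarray:
    """Subsample the field on a regular grid for director-glyph display.

    Returns a structured array of (x, y, theta_deg, coherency) rows sampled
    every *step* pixels, matching the per-pixel field at those locations.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    h, w = field.shape
    if step >= max(h, w):
        raise ValueError(f"step {step} exceeds image extent {(h, w)}")
    rows = np.arange(0, h, step)
    cols = np.arange(0, w, step)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.empty(rr.size, dtype=[("x", float), ("y", float),
                                   ("theta_deg", float), ("coherency", float)])
    out["x"] = cc.ravel()
    out["y"] = rr.ravel()
    out["theta_deg"] = field.theta_deg[rr, cc].ravel()
    out["coherency"] = field.coherency[rr, cc].ravel()
    return out
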