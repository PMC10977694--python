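"""Synthetic fiber textures, director fields, nuclei point patterns and
donor panels with planted ground truth.

No public image data accompany the assay this package implements, so every
downstream stage is exercised on synthetic wells.  The generator plants
nematic topological defects of known half-integer charge using the
standard isolated-defect director solution

    theta(x, y) = sum_i k_i * atan2(y - y_i, x - x_i) + theta0,

which reproduces the comet (+1/2), spiral (+1) and tri-radius (-1/2)
geometries seen around mesenchymal condensations.  Fibrous "actin"
images are rendered by scattering short anti-aliased line segments
oriented by the local director; "nucleus" images are Poisson point
patterns with density enriched around positive charges and depleted
around negative ones, mimicking cell aggregation at swirl centers.

All coordinates are (x = column, y = row) with angles in the display
convention (counter-clockwise positive, y up); all randomness flows
through the explicit seed carried by each spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .io import WellImage
from .orientation import wrap_angle_deg

_HALF = 0.5


@dataclass(frozen=True)
class PlantedDefect:
    """A topological defect planted at a known position with known charge."""

    x_px: float
    y_px: float
    charge: float
    phase_deg: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.charge / _HALF - round(self.charge / _HALF)) > 1e-9:
            raise ValueError(f"charge must be a multiple of 1/2, got {self.charge}")
        if self.charge == 0:
            raise ValueError("a defect must have nonzero charge")


@dataclass(frozen=True)
class TextureSpec:
    """Rendering recipe for one synthetic fibrous well image."""

    width_px: int = 512
    height_px: int = 512
    defects: tuple[PlantedDefect, ...] = ()
    fiber_length_px: float = 15.0
    fiber_width_px: float = 1.5
    fiber_density: float = 0.02          # segment centers per px^2
    noise_sd: float = 0.05               # additive intensity noise, [0,1] scale
    background_theta_deg: float = 0.0    # uniform director when no defects
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image extents must be > 0")
        if min(self.fiber_length_px, self.fiber_width_px) <= 0:
            raise ValueError("fiber parameters must be > 0")
        if self.fiber_density < 0:
            raise ValueError("fiber_density must be >= 0")
        for d in self.defects:
            if not (0 <= d.x_px < self.width_px and 0 <= d.y_px < self.height_px):
                raise ValueError(f"defect core ({d.x_px}, {d.y_px}) outside field extent")
        positions = [(d.x_px, d.y_px) for d in self.defects]
        for i, p in enumerate(positions):
            for q in positions[i + 1:]:
                if math.hypot(p[0] - q[0], p[1] - q[1]) < 1e-6:
                    raise ValueError("two defect cores coincide")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


def comet_spec(size: int = 512, **kw) -> TextureSpec:
    """A single centered +1/2 (comet) defect."""
    d = PlantedDefect(x_px=size / 2, y_px=size / 2, charge=+0.5)
    return TextureSpec(width_px=size, height_px=size, defects=(d,), **kw)


def spiral_spec(size: int = 512, phase_deg: float = 45.0, **kw) -> TextureSpec:
    """A single centered +1 (spiral) defect.

    A nonzero phase offset makes the integer defect a spiral rather than
    a pure aster/vortex.
    """
    d = PlantedDefect(x_px=size / 2, y_px=size / 2, charge=+1.0, phase_deg=phase_deg)
    return TextureSpec(width_px=size, height_px=size, defects=(d,), **kw)


def triradius_spec(size: int = 512, **kw) -> TextureSpec:
    """A single centered -1/2 (tri-radius) defect."""
    d = PlantedDefect(x_px=size / 2, y_px=size / 2, charge=-0.5)
    return TextureSpec(width_px=size, height_px=size, defects=(d,), **kw)


def director_field_with_defects(spec: TextureSpec) -> np.ndarray:
    """Per-pixel director angle field (degrees, mod 180) for the spec.

    The winding of the returned field around a loop enclosing one planted
    defect equals that defect's charge; with no defects the field is the
    uniform background angle.
    """
    h, w = spec.shape
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)
    theta = np.zeros((h, w), dtype=np.float64)
    if not spec.defects:
        theta += spec.background_theta_deg
    for d in spec.defects:
        # y-up display frame: y - y_i = -(row - row_i)
        phi = np.degrees(np.arctan2(d.y_px - rows, cols - d.x_px))
        theta += d.charge * phi + d.phase_deg
    return wrap_angle_deg(theta)


def render_fiber_texture(angle_field: np.ndarray, spec: TextureSpec) -> WellImage:
    """Render a fibrous grayscale image whose local orientation follows
    *angle_field*.

    Short anti-aliased line segments are centered at Poisson-scattered
    points and oriented by the local angle; the stack is lightly blurred
    to the fiber width and Gaussian intensity noise is added.  Output is
    deterministic for a fixed spec seed.
    """
    h, w = spec.shape
    if angle_field.shape != (h, w):
        raise ValueError("angle field shape disagrees with spec extents")
    if spec.fiber_density <= 0:
        raise ValueError("fiber_density must be > 0 to render fibers")

    rng = np.random.default_rng(spec.seed)
    n_fibers = rng.poisson(spec.fiber_density * h * w)
    cx = rng.uniform(0, w, size=n_fibers)
    cy = rng.uniform(0, h, size=n_fibers)

    canvas = np.zeros((h, w), dtype=np.float64)
    half = spec.fiber_length_px / 2.0
    for x, y in zip(cx, cy):
        theta = math.radians(angle_field[int(y), int(x)])
        dx = half * math.cos(theta)
        dy = -half * math.sin(theta)        # display y-up -> rows decrease
        r0, c0 = int(round(y - dy)), int(round(x - dx))
        r1, c1 = int(round(y + dy)), int(round(x + dx))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(canvas, (rr[keep], cc[keep]), val[keep])

    canvas = ndimage.gaussian_filter(canvas, spec.fiber_width_px / 2.0, mode="reflect")
    peak = canvas.max()
    if peak > 0:
        canvas /= peak
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    return WellImage(pixels=np.clip(canvas, 0.0, 1.0), channel="actin")


def synthesize_texture(spec: TextureSpec) -> tuple[WellImage, np.ndarray]:
    """Director field + rendered image for one spec (convenience)."""
    angles = director_field_with_defects(spec)
    return render_fiber_texture(angles, spec), angles


def render_nuclei(
    defects: Sequence[PlantedDefect],
    base_density: float,
    spec: TextureSpec,
    enrichment: float = 5.0,
    depletion: float = 0.2,
    influence_radius_px: float = 40.0,
    psf_sigma_px: float = 2.0,
) -> WellImage:
    """Nucleus-channel image: Poisson nuclei, clustered at positive defects.

    A homogeneous Poisson point pattern of intensity *base_density*
    (points/px^2) is thinned/augmented inside discs of radius
    *influence_radius_px* around each defect: density is multiplied by
    *enrichment* at positive charges (cell aggregation) and by *depletion*
    at negative ones (cells recede from -1/2 sites).  Points are rendered
    as Gaussian spots of scale *psf_sigma_px*.
    """
    if base_density <= 0:
        raise ValueError("base_density must be > 0")
    if depletion < 0 or enrichment < 0:
        raise ValueError("density factors must be >= 0")
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)

    n_base = rng.poisson(base_density * h * w)
    xs = rng.uniform(0, w, size=n_base)
    ys = rng.uniform(0, h, size=n_base)

    # thin around negative charges
    keep = np.ones(n_base, dtype=bool)
    for d in defects:
        if d.charge < 0:
            inside = (xs - d.x_px) ** 2 + (ys - d.y_px) ** 2 <= influence_radius_px**2
            keep &= ~inside | (rng.uniform(size=n_base) < depletion)
    xs, ys = xs[keep], ys[keep]

    # augment around positive charges
    extra_x, extra_y = [], []
    disc_area = math.pi * influence_radius_px**2
    for d in defects:
        if d.charge > 0:
            n_extra = rng.poisson(base_density * disc_area * max(enrichment - 1.0, 0.0))
            r = influence_radius_px * np.sqrt(rng.uniform(size=n_extra))
            t = rng.uniform(0, 2 * math.pi, size=n_extra)
            extra_x.append(d.x_px + r * np.cos(t))
            extra_y.append(d.y_px + r * np.sin(t))
    if extra_x:
        xs = np.concatenate([xs, *extra_x])
        ys = np.concatenate([ys, *extra_y])

    canvas = np.zeros((h, w), dtype=np.float64)
    ri = np.clip(np.round(ys).astype(int), 0, h - 1)
    ci = np.clip(np.round(xs).astype(int), 0, w - 1)
    np.add.at(canvas, (ri, ci), 1.0)
    canvas = ndimage.gaussian_filter(canvas, psf_sigma_px, mode="constant")
    peak = canvas.max()
    if peak > 0:
        canvas /= peak
    return WellImage(pixels=canvas, channel="nucleus")


# ---------------------------------------------------------------------------
# Donor panels

def _linear_potency_map(latent: float) -> tuple[float, float]:
    """Default monotone map: latent defect density -> (sGAG, Col2).

    Scales chosen to land in plausible chondrogenic-assay ranges:
    sGAG ~ 4-16 ug per ug DNA and Col2 ~ 10-100 ng per ug DNA over
    latent densities of roughly 1-10 defects per well.
    """
    return 3.0 + 1.3 * latent, 5.0 + 9.0 * latent


@dataclass(frozen=True)
class PanelSpec:
    """Design of a simulated donor panel (donors x days x replicates)."""

    n_donors: int = 5
    n_replicates: int = 3
    days: tuple[int, ...] = (3, 6, 9, 12)
    latent_range: tuple[float, float] = (2.0, 10.0)   # defects per well
    potency_map: Callable[[float], tuple[float, float]] = _linear_potency_map
    noise_sd_voc: float = 0.05       # relative sd on per-replicate VoC
    noise_sd_protein: float = 0.05   # relative sd on protein readouts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.days:
            raise ValueError("at least one sampling day required")
        lo, hi = self.latent_range
        a, b = self.potency_map(lo), self.potency_map(hi)
        if not (lo < hi):
            raise ValueError("latent_range must be increasing")
        if not (a[0] != b[0] and a[1] != b[1]):
            raise ValueError("potency_map must be strictly monotone over latent_range")


def _defects_for_count(n: int, w: int, h: int, rng: np.random.Generator) -> tuple[PlantedDefect, ...]:
    """n well-separated defects, alternating +1/2 / -1/2 with occasional +1."""
    margin = 0.18 * min(w, h)
    min_sep = 0.22 * min(w, h)
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < 4000:
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - p) ** 2 + (y - q) ** 2 >= min_sep**2 for p, q in pts):
            pts.append((x, y))
    out = []
    for i, (x, y) in enumerate(pts):
        charge = +0.5 if i % 2 == 0 else -0.5
        out.append(PlantedDefect(x_px=x, y_px=y, charge=charge,
                                 phase_deg=float(rng.uniform(0, 180))))
    return tuple(out)


def simulate_donor_panel(
    spec: PanelSpec,
    mode: str = "voc",
    well_px: int = 512,
    texture_kwargs: Optional[dict] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a donor panel with planted potency ground truth.

    Each donor draws one latent defect density (evenly spread over
    ``latent_range`` plus jitter); protein readouts come from
    ``potency_map(latent)`` with multiplicative noise.  Replicate wells are
    produced either as

    - ``mode="voc"`` — per-replicate VoC values from a fixed monotone
      response ``voc = 0.01 + 0.004*latent`` with multiplicative noise
      (fast; exercises the statistics without rendering), or
    - ``mode="images"`` — fully rendered fiber textures with
      ``round(latent)`` planted defects per well, for end-to-end runs
      through orientation -> VoC.

    Returns
    -------
    wells : DataFrame
        One row per (donor, day, replicate).  Always carries donor_id,
        day, replicate; plus ``voc`` in voc mode or ``image``/``spec``
        (WellImage and TextureSpec objects) in images mode.
    proteins : DataFrame
        donor_id, sgag_ug_per_ugDNA, col2_ng_per_ugDNA.
    truth : DataFrame
        donor_id, latent_density (the planted ground truth).
    """
    if mode not in ("voc", "images"):
        raise ValueError("mode must be 'voc' or 'images'")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.latent_range
    base = np.linspace(lo, hi, spec.n_donors)
    jitter = rng.uniform(-0.05, 0.05, size=spec.n_donors) * (hi - lo)
    latents = np.clip(base + jitter, lo, hi)

    texture_kwargs = dict(texture_kwargs or {})
    well_rows, protein_rows, truth_rows = [], [], []
    for i, latent in enumerate(latents):
        donor = f"D{i + 1}"
        truth_rows.append({"donor_id": donor, "latent_density": float(latent)})
        sgag, col2 = spec.potency_map(float(latent))
        sgag *= 1.0 + rng.normal(0.0, spec.noise_sd_protein)
        col2 *= 1.0 + rng.normal(0.0, spec.noise_sd_protein)
        protein_rows.append({"donor_id": donor,
                             "sgag_ug_per_ugDNA": max(sgag, 0.0),
                             "col2_ng_per_ugDNA": max(col2, 0.0)})
        for day in spec.days:
            for rep in range(1, spec.n_replicates + 1):
                row = {"donor_id": donor, "day": day, "replicate": rep,
                       "well_id": f"{donor}_d{day}_r{rep}"}
                if mode == "voc":
                    voc = (0.01 + 0.004 * latent) * (1.0 + rng.normal(0.0, spec.noise_sd_voc))
                    row["voc"] = max(voc, 0.0)
                else:
                    sub_seed = int(rng.integers(0, 2**31 - 1))
                    sub_rng = np.random.default_rng(sub_seed)
                    defects = _defects_for_count(int(round(latent)), well_px, well_px, sub_rng)
                    tspec = TextureSpec(width_px=well_px, height_px=well_px,
                                        defects=defects, seed=sub_seed, **texture_kwargs)
                    image, _ = synthesize_texture(tspec)
                    image = replace(image, donor_id=donor, day=day, replicate=rep,
                                    well_id=row["well_id"])
                    row["image"] = image
                    row["spec"] = tspec
                well_rows.append(row)

    return pd.DataFrame(well_rows), pd.DataFrame(protein_rows), pd.DataFrame(truth_rows)
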