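"""Synthetic generators: planted-defect fields, fiber rendering, nuclei
patterns and donor panels against brute-force ground truth."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from swirlquant import (
    PanelSpec,
    PlantedDefect,
    TextureSpec,
    comet_spec,
    compute_orientation_field,
    correlate_by_day,
    director_field_with_defects,
    render_fiber_texture,
    render_nuclei,
    simulate_donor_panel,
    synthesize_texture,
    wrap_angle_deg,
)


def loop_winding_bruteforce(angles: np.ndarray, cx: float, cy: float,
                            radius: float, n: int = 720) -> float:
    """Winding of a raw per-pixel angle field along a circle, by direct
    loop integration (nearest-pixel sampling, wrapped increments)."""
    t = np.linspace(0, 2 * np.pi, n + 1)
    cols = np.clip(np.round(cx + radius * np.cos(t)).astype(int), 0, angles.shape[1] - 1)
    rows = np.clip(np.round(cy - radius * np.sin(t)).astype(int), 0, angles.shape[0] - 1)
    th = angles[rows, cols]
    d = np.diff(th)
    d = (d + 90.0) % 180.0 - 90.0
    return float(np.sum(d) / 360.0)


class TestDirectorField:
    def test_no_defects_gives_uniform_background(self):
        spec = TextureSpec(width_px=64, height_px=64, background_theta_deg=30.0)
        assert np.all(director_field_with_defects(spec) == 30.0)

    @pytest.mark.parametrize("charge", [0.5, 1.0, -0.5, -1.0])
    def test_single_defect_winding_matches_charge(self, charge):
        spec = TextureSpec(width_px=128, height_px=128,
                           defects=(PlantedDefect(64, 64, charge),))
        angles = director_field_with_defects(spec)
        for radius in (10, 25, 50):
            w = loop_winding_bruteforce(angles, 64, 64, radius)
            assert w == pytest.approx(charge, abs=0.05)

    def test_boundary_winding_is_sum_of_charges(self):
        spec = TextureSpec(width_px=128, height_px=128, defects=(
            PlantedDefect(40, 64, +0.5), PlantedDefect(90, 64, -0.5)))
        angles = director_field_with_defects(spec)
        assert loop_winding_bruteforce(angles, 64, 64, 60) == pytest.approx(0.0, abs=0.05)
        # a loop around only the positive core sees only its charge
        assert loop_winding_bruteforce(angles, 40, 64, 12) == pytest.approx(0.5, abs=0.05)

    def test_angles_reduced_to_director_range(self):
        spec = TextureSpec(width_px=64, height_px=64,
                           defects=(PlantedDefect(30, 30, 1.0, phase_deg=170.0),))
        angles = director_field_with_defects(spec)
        assert angles.min() >= -90.0 and angles.max() < 90.0

    def test_rejects_core_outside_extent_and_coincident_cores(self):
        with pytest.raises(ValueError):
            TextureSpec(width_px=64, height_px=64, defects=(PlantedDefect(70, 10, 0.5),))
        with pytest.raises(ValueError):
            TextureSpec(width_px=64, height_px=64, defects=(
                PlantedDefect(30, 30, 0.5), PlantedDefect(30, 30, -0.5)))

    def test_charge_must_be_half_integer(self):
        with pytest.raises(ValueError):
            PlantedDefect(10, 10, 0.3)


class TestFiberRendering:
    def test_seed_determinism(self):
        spec = comet_spec(128, seed=5)
        a, _ = synthesize_texture(spec)
        b, _ = synthesize_texture(spec)
        assert np.array_equal(a.pixels, b.pixels)
        c, _ = synthesize_texture(comet_spec(128, seed=6))
        assert not np.array_equal(a.pixels, c.pixels)

    def test_uniform_field_orientation_recovered(self):
        for alpha in (0.0, 45.0):
            spec = TextureSpec(width_px=256, height_px=256,
                               background_theta_deg=alpha, seed=3, noise_sd=0.0)
            image, angles = synthesize_texture(spec)
            f = compute_orientation_field(image, window_sigma=10)
            med = np.median(f.theta_deg[64:192, 64:192])
            assert abs(wrap_angle_deg(med - alpha)) < 3.0

    def test_defect_field_recovered_outside_core(self, comet_well):
        spec, image, angles = comet_well
        f = compute_orientation_field(image, window_sigma=10)
        h, w = image.shape
        yy, xx = np.mgrid[0:h, 0:w]
        d = spec.defects[0]
        excl = 3 * spec.fiber_length_px
        far = (xx - d.x_px) ** 2 + (yy - d.y_px) ** 2 > excl**2
        far[:30, :] = far[-30:, :] = far[:, :30] = far[:, -30:] = False
        err = np.abs(wrap_angle_deg(f.theta_deg - angles))[far]
        assert err.mean() < 5.0

    def test_zero_density_rejected(self):
        spec = TextureSpec(width_px=64, height_px=64, fiber_density=0.0)
        with pytest.raises(ValueError):
            render_fiber_texture(director_field_with_defects(spec), spec)

    def test_shape_mismatch_rejected(self):
        spec = TextureSpec(width_px=64, height_px=64)
        with pytest.raises(ValueError):
            render_fiber_texture(np.zeros((32, 32)), spec)


class TestNucleiRendering:
    @staticmethod
    def _disc_mass(img, x, y, r):
        h, w = img.shape
        yy, xx = np.mgrid[0:h, 0:w]
        return img[(xx - x) ** 2 + (yy - y) ** 2 <= r**2].sum()

    def test_positive_defect_enriches_core(self):
        spec = TextureSpec(width_px=256, height_px=256, seed=21)
        d = PlantedDefect(128, 128, +0.5)
        img = render_nuclei([d], base_density=2e-3, spec=spec, enrichment=5.0)
        core = self._disc_mass(img.pixels, 128, 128, 30)
        bg = self._disc_mass(img.pixels, 50, 50, 30)
        assert core > 2.5 * bg

    def test_negative_defect_depletes_core(self):
        spec = TextureSpec(width_px=256, height_px=256, seed=22)
        d = PlantedDefect(128, 128, -0.5)
        img = render_nuclei([d], base_density=2e-3, spec=spec, depletion=0.2)
        core = self._disc_mass(img.pixels, 128, 128, 30)
        bg = self._disc_mass(img.pixels, 50, 50, 30)
        assert core < 0.6 * bg

    def test_homogeneous_without_defects(self):
        spec = TextureSpec(width_px=256, height_px=256, seed=23)
        img = render_nuclei([], base_density=1e-2, spec=spec)
        px = img.pixels
        quadrants = [px[:128, :128].sum(), px[:128, 128:].sum(),
                     px[128:, :128].sum(), px[128:, 128:].sum()]
        assert max(quadrants) < 1.3 * min(quadrants)

    def test_invalid_density_rejected(self):
        spec = TextureSpec(width_px=64, height_px=64)
        with pytest.raises(ValueError):
            render_nuclei([], base_density=-1.0, spec=spec)


class TestDonorPanel:
    def test_zero_noise_linear_map_gives_perfect_correlation(self):
        spec = PanelSpec(noise_sd_voc=0.0, noise_sd_protein=0.0, seed=1)
        wells, proteins, _ = simulate_donor_panel(spec, mode="voc")
        corr = correlate_by_day(wells, proteins)
        assert np.allclose(corr["r"], 1.0, atol=1e-12)

    def test_reversed_potency_map_flips_sign(self):
        spec = PanelSpec(noise_sd_voc=0.0, noise_sd_protein=0.0, seed=2,
                         potency_map=lambda d: (20.0 - 1.3 * d, 100.0 - 9.0 * d))
        wells, proteins, _ = simulate_donor_panel(spec, mode="voc")
        corr = correlate_by_day(wells, proteins)
        assert np.all(corr["r"] < -0.99)

    def test_ground_truth_retained_and_design_respected(self):
        spec = PanelSpec(n_donors=4, n_replicates=2, days=(3, 9), seed=3)
        wells, proteins, truth = simulate_donor_panel(spec, mode="voc")
        assert len(truth) == 4 and len(proteins) == 4
        assert len(wells) == 4 * 2 * 2
        assert truth["latent_density"].is_monotonic_increasing or \
            truth["latent_density"].iloc[0] < truth["latent_density"].iloc[-1]

    def test_images_mode_produces_renderable_wells(self):
        spec = PanelSpec(n_donors=2, n_replicates=1, days=(3,), seed=4,
                         latent_range=(1.0, 3.0))
        wells, _, _ = simulate_donor_panel(spec, mode="images", well_px=128)
        assert len(wells) == 2
        for rec in wells.to_dict("records"):
            assert rec["image"].shape == (128, 128)
            assert len(rec["spec"].defects) >= 1

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PanelSpec(n_donors=1)
        with pytest.raises(ValueError):
            PanelSpec(potency_map=lambda d: (1.0, 1.0))  # not monotone
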