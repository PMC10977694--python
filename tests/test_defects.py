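"""Defect detection: coarse-graining, winding numbers, charge taxonomy,
conservation, and detection accuracy on planted textures."""

from __future__ import annotations

import numpy as np
import pytest

from swirlquant import (
    PlantedDefect,
    TextureSpec,
    boundary_winding,
    classify_charge,
    coarse_grain_director,
    compute_orientation_field,
    detect_defects,
    director_field_with_defects,
    synthesize_texture,
    winding_number,
)
from swirlquant.defects import _circle_loop, plaquette_windings
from swirlquant.synthetic import _defects_for_count

from conftest import make_field


def analytic_grid(spec: TextureSpec, block: int = 8):
    angles = director_field_with_defects(spec)
    return coarse_grain_director(make_field(angles), block, coherency_weighted=False)


class TestCoarseGraining:
    def test_uniform_field_preserved(self):
        grid = coarse_grain_director(make_field(np.full((80, 80), 30.0)), 8)
        assert np.allclose(grid.theta_deg, 30.0, atol=1e-9)

    def test_q_averaging_respects_mod180_topology(self):
        """+89 and -89 average near the +/-90 boundary, not to zero."""
        theta = np.empty((16, 16))
        theta[:, ::2], theta[:, 1::2] = 89.0, -89.0
        grid = coarse_grain_director(make_field(theta), 4)
        assert np.all(np.abs(grid.theta_deg) > 88.0)

    def test_comet_field_blocks_match_analytic_solution(self):
        spec = TextureSpec(width_px=160, height_px=160,
                           defects=(PlantedDefect(80, 80, 0.5),))
        angles = director_field_with_defects(spec)
        grid = coarse_grain_director(make_field(angles), 8, coherency_weighted=False)
        nr, nc = grid.shape
        for i in (2, nr - 3):
            for j in (2, nc - 3):
                x, y = grid.block_center_px(i, j)
                expected = angles[int(y), int(x)]
                diff = (grid.theta_deg[i, j] - expected + 90) % 180 - 90
                assert abs(diff) < 3.0

    def test_block_size_bounds(self):
        f = make_field(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            coarse_grain_director(f, 1)
        with pytest.raises(ValueError):
            coarse_grain_director(f, 40)


class TestWindingNumber:
    @pytest.mark.parametrize("charge,expected", [(0.5, 0.5), (1.0, 1.0), (-0.5, -0.5)])
    def test_planted_charge_recovered(self, charge, expected):
        spec = TextureSpec(width_px=160, height_px=160,
                           defects=(PlantedDefect(80, 80, charge),))
        grid = analytic_grid(spec)
        k, raw = winding_number(grid, _circle_loop(9.5, 9.5, 5))
        assert k == expected
        assert raw == pytest.approx(expected, abs=0.1)

    def test_empty_loop_reads_zero(self):
        spec = TextureSpec(width_px=160, height_px=160,
                           defects=(PlantedDefect(20, 20, 0.5),))
        grid = analytic_grid(spec)
        k, _ = winding_number(grid, _circle_loop(14, 14, 3))
        assert k == 0.0

    def test_loop_radius_independence(self):
        spec = TextureSpec(width_px=320, height_px=320,
                           defects=(PlantedDefect(160, 160, -0.5),))
        grid = analytic_grid(spec)
        charges = [winding_number(grid, _circle_loop(19.5, 19.5, r))[0]
                   for r in (2, 3, 5)]
        assert charges == [-0.5, -0.5, -0.5]

    def test_open_or_sparse_loops_rejected(self):
        grid = analytic_grid(TextureSpec(width_px=160, height_px=160,
                                         defects=(PlantedDefect(80, 80, 0.5),)))
        with pytest.raises(ValueError):
            winding_number(grid, [(2, 2), (2, 5), (5, 5), (5, 2)])  # not closed
        with pytest.raises(ValueError):
            winding_number(grid, [(2, 2), (2, 8), (8, 8), (2, 2)])  # aliased steps

    def test_returned_charge_is_half_integer(self):
        spec = TextureSpec(width_px=160, height_px=160,
                           defects=(PlantedDefect(80, 80, 1.0, phase_deg=30),))
        grid = analytic_grid(spec)
        k, _ = winding_number(grid, _circle_loop(9.5, 9.5, 6))
        assert k * 2 == round(k * 2)


class TestDetection:
    def test_uniform_texture_has_no_defects(self, uniform_well):
        _, image, _ = uniform_well
        field = compute_orientation_field(image, window_sigma=10)
        ds = detect_defects(coarse_grain_director(field, 20), field)
        assert len(ds) == 0

    def test_pair_detected_with_correct_charges(self):
        spec = TextureSpec(width_px=512, height_px=512, seed=31, defects=(
            PlantedDefect(150, 256, +0.5), PlantedDefect(370, 256, -0.5)))
        image, _ = synthesize_texture(spec)
        field = compute_orientation_field(image, window_sigma=10)
        ds = detect_defects(coarse_grain_director(field, 20), field)
        assert sorted(ds.charges()) == [-0.5, 0.5]
        for det in ds.defects:
            truth = spec.defects[0] if det.charge > 0 else spec.defects[1]
            assert np.hypot(det.x_px - truth.x_px, det.y_px - truth.y_px) <= 40

    def test_spiral_reports_single_plus_one(self, spiral_well):
        _, image, _ = spiral_well
        field = compute_orientation_field(image, window_sigma=10)
        ds = detect_defects(coarse_grain_director(field, 20), field)
        assert [d.charge for d in ds.defects] == [1.0]
        assert ds.defects[0].type == "spiral"

    def test_charge_conservation_on_synthetic_textures(self):
        for seed in (41, 42, 43):
            rng = np.random.default_rng(seed)
            defs = _defects_for_count(int(rng.integers(2, 6)), 512, 512, rng)
            spec = TextureSpec(width_px=512, height_px=512, defects=defs, seed=seed)
            image, _ = synthesize_texture(spec)
            field = compute_orientation_field(image, window_sigma=10)
            grid = coarse_grain_director(field, 20)
            ds = detect_defects(grid, field)
            assert ds.total_charge() == pytest.approx(boundary_winding(grid, inset=2))
            assert ds.total_charge() == pytest.approx(sum(d.charge for d in defs))

    def test_precision_and_recall_on_seeded_suite(self):
        tp = fp = fn = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            defs = _defects_for_count(int(rng.integers(1, 7)), 512, 512, rng)
            spec = TextureSpec(width_px=512, height_px=512, defects=defs, seed=2000 + s)
            image, _ = synthesize_texture(spec)
            field = compute_orientation_field(image, window_sigma=10)
            ds = detect_defects(coarse_grain_director(field, 20), field)
            matched: set[int] = set()
            for det in ds.defects:
                hit = next((i for i, d in enumerate(defs) if i not in matched
                            and np.hypot(det.x_px - d.x_px, det.y_px - d.y_px) <= 40
                            and np.isclose(det.charge, d.charge)), None)
                if hit is None:
                    fp += 1
                else:
                    matched.add(hit)
                    tp += 1
            fn += len(defs) - len(matched)
        assert tp / (tp + fp) >= 0.9
        assert tp / (tp + fn) >= 0.9

    def test_detection_invariant_to_affine_rescale(self, comet_well):
        _, image, _ = comet_well
        f0 = compute_orientation_field(image, window_sigma=10)
        f1 = compute_orientation_field(3.0 * image.pixels + 0.2, window_sigma=10)
        d0 = detect_defects(coarse_grain_director(f0, 20), f0)
        d1 = detect_defects(coarse_grain_director(f1, 20), f1)
        assert d0.charges() == d1.charges()
        for a, b in zip(d0.defects, d1.defects):
            assert (a.x_px, a.y_px) == (b.x_px, b.y_px)

    def test_detection_equivariant_to_90deg_rotation(self, comet_well):
        _, image, _ = comet_well
        f0 = compute_orientation_field(image, window_sigma=10)
        f1 = compute_orientation_field(np.rot90(image.pixels), window_sigma=10)
        d0 = detect_defects(coarse_grain_director(f0, 20), f0)
        d1 = detect_defects(coarse_grain_director(f1, 20), f1)
        assert sorted(d0.charges()) == sorted(d1.charges())


class TestTaxonomy:
    @pytest.mark.parametrize("charge,label", [
        (0.5, "comet"), (1.0, "spiral"), (-0.5, "triradius"),
        (-1.0, "other"), (1.5, "other")])
    def test_charge_taxonomy(self, charge, label):
        assert classify_charge(charge) == label
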