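"""Particle analysis, wound/colony/space metrics, normalization, ddCt."""

import numpy as np
import pytest

from dysmark.assays import (
    AssayImage,
    analyze_particles,
    colony_metrics,
    ddct_fold_change,
    intercellular_space,
    normalize_to_control,
    threshold_image,
    wound_area_remaining,
)
from dysmark.errors import DegenerateDataError, NoWoundError
from dysmark.synthetic import (
    CellFieldParams,
    ColonyPlateParams,
    WoundPairParams,
    generate_assay_images,
)


def flood_fill_components(mask):
    """Brute-force 8-connected component areas via stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = []
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, area = [(i, j)], 0
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    area += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = y + dy, x + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and mask[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                areas.append(area)
    return sorted(areas)


class TestThreshold:
    def test_otsu_separates_two_level_image(self):
        px = np.full((20, 20), 20, dtype=np.uint8)
        px[5:10, 5:10] = 220
        mask = threshold_image(AssayImage(px, bit_depth=8))
        assert mask.sum() == 25
        assert mask[5:10, 5:10].all()

    def test_fixed_threshold_counts_above(self):
        ramp = np.tile(np.arange(256, dtype=np.uint8), (4, 1))
        mask = threshold_image(AssayImage(ramp, bit_depth=8), method="fixed",
                               value=128)
        assert mask.sum() == 4 * 127

    def test_constant_image_rejected_under_otsu(self):
        img = AssayImage(np.full((5, 5), 7, dtype=np.uint8), bit_depth=8)
        with pytest.raises(DegenerateDataError):
            threshold_image(img)
        assert threshold_image(img, method="fixed", value=3).all()


class TestAnalyzeParticles:
    def test_two_disjoint_squares(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[2:12, 2:12] = True
        mask[20:30, 20:30] = True
        ps = analyze_particles(mask)
        assert ps.count == 2
        assert sorted(p.pixel_area for p in ps.particles) == [100, 100]

    def test_corner_touch_is_one_particle_at_8_connectivity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:3, 0:3] = True
        mask[3:6, 3:6] = True
        assert analyze_particles(mask, connectivity=8).count == 1
        assert analyze_particles(mask, connectivity=4).count == 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((40, 60)) < 0.35
            ps = analyze_particles(mask)
            assert sorted(p.pixel_area for p in ps.particles) == (
                flood_fill_components(mask)
            )

    def test_min_area_filter(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[0:2, 0:2] = True  # area 4
        mask[10:16, 10:16] = True  # area 36
        ps = analyze_particles(mask, min_area_px=10)
        assert ps.count == 1
        assert ps.particles[0].pixel_area == 36


class TestSpaceAndBookkeeping:
    def test_all_background_full_frame(self):
        img = AssayImage(np.zeros((960, 1280), dtype=np.uint16))
        space = intercellular_space(img, method="fixed", value=100)
        assert space == 1_228_800.0

    def test_fully_occupied_zero_space(self):
        img = AssayImage(np.full((100, 100), 40000, dtype=np.uint16))
        assert intercellular_space(img, method="fixed", value=100) == 0.0

    def test_particle_area_plus_space_conserves_image_area(self):
        imgs, truth = generate_assay_images("cell_field",
                                            CellFieldParams(width=320, height=240,
                                                            n_cells=25), seed=4)
        img = imgs[0]
        mask = threshold_image(img)
        ps = analyze_particles(mask)
        assert ps.total_area_um2 + intercellular_space(img) == img.area_um2

    def test_rotation_invariance(self):
        imgs, _ = generate_assay_images("cell_field",
                                        CellFieldParams(width=160, height=120,
                                                        n_cells=10), seed=5)
        img = imgs[0]
        rot = AssayImage(np.rot90(img.pixels, 2), img.bit_depth)
        assert intercellular_space(img) == intercellular_space(rot)
        assert analyze_particles(threshold_image(img)).count == (
            analyze_particles(threshold_image(rot)).count
        )


class TestWound:
    def test_identical_followup_is_one(self):
        imgs, _ = generate_assay_images(
            "wound_pair", WoundPairParams(width=320, height=240, noise_sd=0.0,
                                          remaining_frac=1.0), seed=0)
        base, follow = imgs
        rel = wound_area_remaining(base, [base, follow])
        assert rel == [1.0, 1.0]

    def test_half_closed_wound(self):
        imgs, truth = generate_assay_images(
            "wound_pair", WoundPairParams(width=320, height=240,
                                          remaining_frac=0.5), seed=1)
        assert truth["true_relative_remaining"] == 0.5
        rel = wound_area_remaining(imgs[0], [imgs[1]])
        assert rel[0] == pytest.approx(0.5, abs=0.02)

    def test_fully_closed_wound_is_zero(self):
        imgs, _ = generate_assay_images(
            "wound_pair", WoundPairParams(width=320, height=240, noise_sd=0.0,
                                          remaining_frac=0.0), seed=2)
        rel = wound_area_remaining(imgs[0], [imgs[1]])
        assert rel == [0.0]

    def test_no_baseline_wound_rejected(self):
        full = AssayImage(np.full((50, 50), 40000, dtype=np.uint16))
        with pytest.raises(NoWoundError):
            wound_area_remaining(full, [full], method="fixed", value=20000)


class TestColony:
    def test_ten_equal_disks(self):
        imgs, truth = generate_assay_images(
            "colony_plate", ColonyPlateParams(noise_sd=0.0, n_colonies=10,
                                              radius=10), seed=3)
        count, mean_area = colony_metrics(imgs[0], method="fixed", value=20000)
        assert count == 10
        assert len(set(truth["per_colony_px"])) == 1  # identical rasterization
        assert mean_area == pytest.approx(truth["per_colony_px"][0])

    def test_min_area_excludes_half(self):
        mask = np.zeros((60, 60), dtype=bool)
        for k in range(3):  # three small (4 px) and three large (36 px)
            mask[k * 20: k * 20 + 2, 0:2] = True
            mask[k * 20: k * 20 + 6, 30:36] = True
        ps = analyze_particles(mask, min_area_px=10)
        assert ps.count == 3

    def test_empty_plate(self):
        count, mean_area = colony_metrics(
            AssayImage(np.zeros((50, 50), dtype=np.uint16)),
            method="fixed", value=100)
        assert count == 0
        assert mean_area is None


class TestNormalizeAndDdct:
    def test_control_normalizes_to_100(self):
        assert normalize_to_control([5.0], [5.0, 5.0]) == [100.0]

    def test_strong_reduction(self):
        out = normalize_to_control([1.5], [10.0, 10.0])
        assert out == [15.0]

    def test_zero_control_rejected(self):
        with pytest.raises(DegenerateDataError):
            normalize_to_control([1.0], [0.0, 0.0])

    def test_equal_cts_give_unit_fold(self):
        res = ddct_fold_change(22.0, 22.0, 22.0, 22.0)
        assert res.fold_change == 1.0

    @pytest.mark.parametrize("ddct,fold", [(-1.0, 2.0), (1.0, 0.5)])
    def test_unit_ddct_folds(self, ddct, fold):
        res = ddct_fold_change(20.0 + ddct, 18.0, 21.0, 19.0)
        assert res.ddct == pytest.approx(ddct)
        assert res.fold_change == pytest.approx(fold)

    def test_control_vs_itself_with_replicates(self, rng):
        ct_t = rng.normal(24, 0.2, 3)
        ct_r = rng.normal(18, 0.2, 3)
        res = ddct_fold_change(ct_t, ct_r, ct_t, ct_r)
        assert res.fold_change == pytest.approx(1.0)
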