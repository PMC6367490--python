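"""The four standard threshold operators and their sub-procedures."""

import numpy as np
import pytest

from petseg import (
    DelineationConfig,
    detect_candidates,
    generate_study,
    label_components,
    local_background,
    run_method,
    segment_a50p,
    segment_fixed_threshold,
    segment_41max,
    suv_peak,
)
from petseg.delineation import (
    STANDARD_METHODS,
    _suv_peak_with_position,
    lesion_context,
    peak_sphere_radius_mm,
)
from petseg.image_model import BinaryMask

from conftest import make_image


def brute_force_suv_peak(image, lesion_mask, radius_mm):
    """Exhaustive centre scan: sphere mean at every lesion voxel centre."""
    spacing = np.asarray(image.grid.spacing)
    shape = image.grid.shape
    best = -np.inf
    for centre in zip(*np.nonzero(lesion_mask)):
        vals = []
        half = np.floor(radius_mm / spacing).astype(int)
        for dx in range(-half[0], half[0] + 1):
            for dy in range(-half[1], half[1] + 1):
                for dz in range(-half[2], half[2] + 1):
                    if (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2 > radius_mm**2:
                        continue
                    v = (centre[0] + dx, centre[1] + dy, centre[2] + dz)
                    if all(0 <= v[k] < shape[k] for k in range(3)):
                        vals.append(image.values[v])
        best = max(best, float(np.mean(vals)))
    return best


def uniform_lesion_image(lesion_suv=5.0, background=0.0, size=16, box=(4, 12)):
    vals = np.full((size, size, size), background, dtype=float)
    sl = slice(*box)
    vals[sl, sl, sl] = lesion_suv
    return make_image(vals)


class TestFixedThreshold:
    def test_uniform_field(self):
        img = make_image(np.full((4, 4, 4), 3.0))
        assert segment_fixed_threshold(img, 2.5).n_voxels == 64
        assert segment_fixed_threshold(img, 4.0).is_empty()

    def test_threshold_monotonicity(self, rng):
        img = make_image(rng.random((12, 12, 12)) * 6)
        hi = segment_fixed_threshold(img, 4.0).values
        lo = segment_fixed_threshold(img, 2.5).values
        assert np.all(hi <= lo)

    def test_inclusive_comparison(self):
        img = make_image(np.full((2, 2, 2), 2.5))
        assert segment_fixed_threshold(img, 2.5).n_voxels == 8

    def test_matches_voxelwise_oracle_on_sphere_phantom(self):
        from test_phantom import single_sphere_spec
        study = generate_study(single_sphere_spec())
        img = study.patients[0].images[(1, 60, "earl")]
        mask = segment_fixed_threshold(img, 2.5)
        assert mask.n_voxels == int((img.values >= 2.5).sum())

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            segment_fixed_threshold(make_image(np.ones((2, 2, 2))), 0.0)


class TestDetectCandidates:
    def test_clean_phantom_one_candidate_per_lesion(self, clean_spec):
        study = generate_study(clean_spec)
        for patient in study.patients:
            cands = detect_candidates(patient.images[(1, 60, "earl")])
            assert cands.n_lesions == len(patient.lesions[1])

    def test_all_below_threshold_gives_zero(self):
        img = make_image(np.ones((6, 6, 6)))
        assert detect_candidates(img).n_lesions == 0

    def test_min_size_filter_dominates(self, clean_spec):
        study = generate_study(clean_spec)
        img = study.patients[0].images[(1, 60, "earl")]
        cfg = DelineationConfig(min_lesion_ml=1e6)
        assert detect_candidates(img, cfg).n_lesions == 0


class TestSuvPeak:
    def test_uniform_large_lesion_peak_equals_suv(self):
        img = uniform_lesion_image(lesion_suv=5.0, background=0.0, size=20, box=(2, 18))
        cands = detect_candidates(img)
        assert suv_peak(img, cands, 1) == pytest.approx(5.0)

    def test_peak_not_above_max(self, small_spec):
        study = generate_study(small_spec)
        for patient in study.patients:
            img = patient.images[(1, 60, "psf")]
            cands = detect_candidates(img)
            for lid in cands.lesion_ids():
                ctx = lesion_context(img, cands, lid)
                assert suv_peak(img, cands, lid) <= ctx.suv_max + 1e-12

    def test_single_hot_voxel_matches_brute_force(self):
        vals = np.ones((12, 12, 12))
        vals[6, 6, 6] = 10.0
        img = make_image(vals)
        lesion = np.zeros((12, 12, 12), dtype=bool)
        lesion[6, 6, 6] = True
        cfg = DelineationConfig()
        got, _ = _suv_peak_with_position(img, lesion, cfg)
        radius = peak_sphere_radius_mm(cfg.peak_sphere_ml)
        assert got == pytest.approx(brute_force_suv_peak(img, lesion, radius), abs=1e-12)

    def test_empty_lesion_rejected(self):
        img = make_image(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            _suv_peak_with_position(img, np.zeros((4, 4, 4), dtype=bool), DelineationConfig())

    def test_one_ml_sphere_radius(self):
        assert peak_sphere_radius_mm(1.0) == pytest.approx(6.2035, abs=1e-3)


class TestSegment41Max:
    def test_uniform_lesion_zero_background_full_recovery(self):
        img = uniform_lesion_image(lesion_suv=5.0, background=0.0)
        cands = detect_candidates(img)
        ctx = lesion_context(img, cands, 1)
        mask = segment_41max(img, ctx)
        np.testing.assert_array_equal(mask.values, cands.labels == 1)

    def test_rim_below_41_percent_excluded(self):
        # core SUV 10 with rim SUV 3: threshold 4.1 keeps only the core
        vals = np.zeros((16, 16, 16))
        vals[4:12, 4:12, 4:12] = 3.0
        vals[6:10, 6:10, 6:10] = 10.0
        img = make_image(vals)
        cands = detect_candidates(img)
        ctx = lesion_context(img, cands, 1)
        mask = segment_41max(img, ctx)
        np.testing.assert_array_equal(mask.values, vals >= 4.1)

    def test_mask_contains_argmax_voxel(self, small_spec):
        study = generate_study(small_spec)
        img = study.patients[0].images[(1, 60, "earl")]
        cands = detect_candidates(img)
        for lid in cands.lesion_ids():
            ctx = lesion_context(img, cands, lid)
            mask = segment_41max(img, ctx)
            assert mask.values[ctx.max_index]


class TestLocalBackground:
    def sphere_in_background(self, background=1.0, size=40):
        vals = np.full((size, size, size), background)
        centre = size // 2
        xx, yy, zz = np.meshgrid(*[np.arange(size)] * 3, indexing="ij")
        sphere = ((xx - centre) ** 2 + (yy - centre) ** 2 + (zz - centre) ** 2) <= (10 / 4) ** 2
        vals[sphere] = 10.0
        return make_image(vals), sphere

    def test_uniform_background_recovered(self):
        img, _ = self.sphere_in_background(background=1.0)
        cands = detect_candidates(img)
        ctx = lesion_context(img, cands, 1)
        assert local_background(img, ctx) == pytest.approx(1.0)

    def test_hot_background_triggers_fallback(self):
        img, _ = self.sphere_in_background(background=3.0)
        cands = detect_candidates(img, DelineationConfig(detection_threshold=5.0))
        ctx = lesion_context(img, cands, 1)
        with pytest.warns(UserWarning, match="exclusion"):
            bg = local_background(img, ctx)
        assert bg == pytest.approx(3.0)

    def test_shell_mean_invariant_to_lesion_interior(self):
        img, sphere = self.sphere_in_background(background=1.0)
        cands = detect_candidates(img)
        ctx = lesion_context(img, cands, 1)
        ref = local_background(img, ctx)
        hotter = img.values.copy()
        hotter[sphere] = 9.0   # same 70% isocontour support, different interior
        img2 = make_image(hotter)
        cands2 = detect_candidates(img2)
        ctx2 = lesion_context(img2, cands2, 1)
        assert local_background(img2, ctx2) == pytest.approx(ref)


class TestSegmentA50P:
    def make_case(self, lesion_suv, background, size=40):
        vals = np.full((size, size, size), float(background))
        c = size // 2
        xx, yy, zz = np.meshgrid(*[np.arange(size)] * 3, indexing="ij")
        sphere = ((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2) <= 3.0**2
        vals[sphere] = lesion_suv
        img = make_image(vals)
        cfg = DelineationConfig(detection_threshold=(lesion_suv + background) / 2)
        cands = detect_candidates(img, cfg)
        return img, lesion_context(img, cands, 1, cfg), sphere, cfg

    def test_uniform_lesion_threshold_formula(self):
        # SUV 6 lesion over background 2: T = 0.5*(peak-2)+2 <= 4, lesion kept whole
        img, ctx, sphere, cfg = self.make_case(6.0, 2.0)
        mask = segment_a50p(img, ctx, cfg)
        np.testing.assert_array_equal(mask.values, sphere)

    def test_low_contrast_lesion_still_segmented(self):
        # uptake below twice the local background: T = 2.5 < peak
        img, ctx, sphere, cfg = self.make_case(3.0, 2.0)
        mask = segment_a50p(img, ctx, cfg)
        np.testing.assert_array_equal(mask.values, sphere)

    def test_zero_background_is_half_peak(self):
        img, ctx, sphere, cfg = self.make_case(8.0, 0.0)
        mask = segment_a50p(img, ctx, cfg)
        np.testing.assert_array_equal(mask.values, sphere)

    def test_inverted_contrast_warns_and_returns_empty(self):
        # background shell hotter than the lesion peak: SUVpeak <= BG
        size = 40
        vals = np.full((size, size, size), 0.5)
        c = size // 2
        xx, yy, zz = np.meshgrid(*[np.arange(size)] * 3, indexing="ij")
        r_mm = 4.0 * np.sqrt((xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2)
        vals[r_mm >= 22.0] = 8.0
        vals[c - 1:c + 2, c - 1:c + 2, c - 1:c + 2] = 3.0
        img = make_image(vals)
        cfg = DelineationConfig(detection_threshold=2.5, shell_exclusion_suv=10.0,
                                margin_mm=8.0)
        cands = detect_candidates(img, cfg)
        cube_id = int(cands.labels[c, c, c])
        ctx = lesion_context(img, cands, cube_id, cfg)
        with pytest.warns(UserWarning, match="empty mask"):
            mask = segment_a50p(img, ctx, cfg)
        assert mask.is_empty()


class TestRunMethod:
    def test_suv25_is_fixed_threshold(self, small_spec):
        study = generate_study(small_spec)
        img = study.patients[0].images[(1, 60, "earl")]
        cands = detect_candidates(img)
        np.testing.assert_array_equal(
            run_method(img, "SUV25", cands).values,
            segment_fixed_threshold(img, 2.5).values,
        )

    def test_no_candidates_adaptive_methods_empty(self):
        img = make_image(np.ones((6, 6, 6)))
        cands = detect_candidates(img)
        assert run_method(img, "41MAX", cands).is_empty()
        assert run_method(img, "A50P", cands).is_empty()

    def test_unknown_method_rejected(self):
        img = make_image(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            run_method(img, "SUV99", detect_candidates(img))

    def test_per_lesion_masks_disjoint_and_connected(self, small_spec):
        study = generate_study(small_spec)
        cfg = DelineationConfig()
        for patient in study.patients:
            img = patient.images[(1, 60, "earl")]
            cands = detect_candidates(img, cfg)
            per_lesion = []
            for lid in cands.lesion_ids():
                ctx = lesion_context(img, cands, lid, cfg)
                m = segment_41max(img, ctx, cfg)
                comps = label_components(m, cfg.connectivity)
                assert comps.n_lesions <= 1   # connected under configured order
                per_lesion.append(m.values)
            for i in range(len(per_lesion)):
                for j in range(i + 1, len(per_lesion)):
                    assert not np.any(per_lesion[i] & per_lesion[j])

    def test_noiseless_recovery_all_methods(self, clean_spec):
        study = generate_study(clean_spec)
        for patient in study.patients:
            img = patient.images[(1, 60, "earl")]
            cands = detect_candidates(img)
            truth = patient.truth[1].labels > 0
            for method in STANDARD_METHODS:
                mask = run_method(img, method, cands)
                np.testing.assert_array_equal(mask.values, truth), method
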