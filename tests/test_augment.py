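"""Augmentation stack: identity at probability zero, geometric/label
consistency, border-connectivity preservation, distractor provenance,
padding geometry and standardization arithmetic."""

import numpy as np
import pytest

from chromablend import (
    AugmentConfig,
    BackgroundSample,
    ContractError,
    FixtureSpec,
    add_endoscopic_padding,
    add_flying_distractors,
    augment_background,
    augment_blended,
    augment_foreground,
    blend_trivial,
    make_foreground_fixture,
    make_rng,
    standardize_pair,
)
from chromablend.augment import apply_cutout, flip_horizontal, rotate90


class TestForegroundAugment:
    def test_zero_probabilities_are_identity(self, fg_sample):
        out = augment_foreground(fg_sample, AugmentConfig.disabled(), make_rng(0, "a"))
        assert np.array_equal(out.image, fg_sample.image)
        assert np.array_equal(out.mask, fg_sample.mask)

    def test_horizontal_flip_is_an_involution(self, fg_sample):
        assert np.array_equal(flip_horizontal(flip_horizontal(fg_sample.image)), fg_sample.image)

    def test_droplets_never_touch_background_pixels(self):
        cfg = AugmentConfig.disabled()
        cfg.p_droplets = 1.0
        for seed in range(20):
            fg, _ = make_foreground_fixture(FixtureSpec(n_tools=2, seed=seed))
            out = augment_foreground(fg, cfg, make_rng(seed, "drop"))
            off_tool = fg.mask == 0
            assert np.array_equal(out.image[off_tool], fg.image[off_tool])
            assert np.array_equal(out.mask, fg.mask)

    @pytest.mark.parametrize("seed", range(40))
    def test_border_connectivity_survives_full_stack(self, seed):
        cfg = AugmentConfig(
            p_zoom=1.0, p_rotate=1.0, p_flip=0.5, p_shift=1.0,
            p_brightness=1.0, p_droplets=0.5,
        )
        fg, _ = make_foreground_fixture(FixtureSpec(n_tools=1 + seed % 3, seed=seed))
        out = augment_foreground(fg, cfg, make_rng(seed, "full"))
        # the ForegroundSample constructor re-validates border connectivity;
        # reaching here without ValidationError is the assertion
        assert out.mask.any()

    def test_geometric_ops_commute_with_mask_for_flips(self, fg_sample):
        # flips are exact: transforming the mask equals masking the transform
        assert np.array_equal(
            flip_horizontal(fg_sample.mask[..., None])[..., 0], fg_sample.mask[:, ::-1]
        )


class TestBackgroundAugment:
    def test_zero_probabilities_are_identity(self, bg_sample):
        out = augment_background(bg_sample, AugmentConfig.disabled(), make_rng(0, "b"))
        assert np.array_equal(out.image, bg_sample.image)

    def test_four_quarter_turns_restore_original(self, bg_sample):
        img = bg_sample.image
        assert np.array_equal(rotate90(rotate90(rotate90(rotate90(img)))), img)

    def test_brightness_shift_pair_cancels(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.3, 0.7, (32, 32, 3))  # away from clipping
        up = np.clip(img + 0.1, 0, 1)
        down = np.clip(up - 0.1, 0, 1)
        assert np.abs(down - img).max() <= 1.0 / 255.0


class TestFlyingDistractors:
    def test_zero_count_is_identity(self, bg_sample, bg_pool, fg_sample):
        cfg = AugmentConfig.disabled()
        out = add_flying_distractors(
            bg_sample, bg_pool, fg_sample, blend_trivial, cfg, make_rng(0, "d"), count=0
        )
        assert np.array_equal(out.image, bg_sample.image)

    def test_distractor_pixels_come_from_donor(self, fg_sample):
        base = BackgroundSample(image=np.zeros((128, 128, 3)), id="base")
        donor = BackgroundSample(image=np.full((128, 128, 3), 0.75), id="donor")
        cfg = AugmentConfig.disabled()
        out = add_flying_distractors(
            base, [donor], fg_sample, blend_trivial, cfg, make_rng(1, "d"), count=1
        )
        changed = np.any(out.image != base.image, axis=-1)
        assert changed.any()
        assert np.allclose(out.image[changed], 0.75)

    def test_label_unaffected_by_distractors(self, fg_sample, bg_sample, bg_pool):
        cfg = AugmentConfig.disabled()
        distracted = add_flying_distractors(
            bg_sample, bg_pool, fg_sample, blend_trivial, cfg, make_rng(2, "d"), count=2
        )
        clean = blend_trivial(fg_sample, bg_sample)
        dirty = blend_trivial(fg_sample, distracted)
        assert np.array_equal(clean.label, dirty.label)

    def test_empty_donor_list_rejected(self, bg_sample, fg_sample):
        with pytest.raises(ContractError):
            add_flying_distractors(
                bg_sample, [], fg_sample, blend_trivial, AugmentConfig(), make_rng(0, "d")
            )


class TestEndoscopicPadding:
    def test_zero_probability_is_identity(self, bg_sample):
        cfg = AugmentConfig.disabled()
        out = add_endoscopic_padding(bg_sample, cfg, make_rng(0, "p"))
        assert np.array_equal(out.image, bg_sample.image)

    def test_corners_are_dark(self, bg_sample):
        cfg = AugmentConfig.disabled()
        cfg.p_padding = 1.0
        for seed in range(10):
            out = add_endoscopic_padding(bg_sample, cfg, make_rng(seed, "p"))
            corners = np.stack(
                [out.image[0, 0], out.image[0, -1], out.image[-1, 0], out.image[-1, -1]]
            )
            assert corners.max() <= 3 * cfg.pad_noise_sigma + 1e-9

    def test_interior_window_untouched_by_rectangular_padding(self, bg_sample):
        cfg = AugmentConfig.disabled()
        cfg.p_padding = 1.0
        h, w = bg_sample.image.shape[:2]
        max_w = int(cfg.pad_width_fraction * min(h, w))
        for seed in range(10):
            out = add_endoscopic_padding(bg_sample, cfg, make_rng(seed, "p"))
            interior = (
                out.image[max_w:-max_w, max_w:-max_w],
                bg_sample.image[max_w:-max_w, max_w:-max_w],
            )
            changed = np.any(interior[0] != interior[1], axis=-1)
            if changed.any():
                # circular padding may enter the window; the untouched region
                # must then be exactly the outside-of-disc complement
                yy, xx = np.mgrid[0:h, 0:w]
                r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
                inner = r <= cfg.disc_radius_range[0] * min(h, w)
                assert np.array_equal(
                    out.image[inner], bg_sample.image[inner]
                )
            else:
                assert not changed.any()


class TestBlendedAugment:
    def test_zero_probabilities_are_identity(self, bg_sample):
        out = augment_blended(bg_sample.image, AugmentConfig.disabled(), make_rng(0, "x"))
        assert np.array_equal(out, bg_sample.image)

    def test_jpeg_quality_100_is_nearly_lossless(self, bg_sample):
        from chromablend.augment import _jpeg_roundtrip

        out = _jpeg_roundtrip(bg_sample.image, 100)
        assert np.abs(out - bg_sample.image).max() <= 8.0 / 255.0  # 4:2:0 chroma

    def test_single_cutout_changes_exactly_its_area(self):
        cfg = AugmentConfig.disabled()
        cfg.cutout_count = (1, 1)
        cfg.cutout_size = (16, 16)
        img = np.full((64, 64, 3), 0.5)
        out = apply_cutout(img, make_rng(3, "c"), cfg, fill=0.0)
        changed = np.any(out != img, axis=-1)
        assert changed.sum() == 256

    def test_output_stays_in_unit_interval(self, bg_sample):
        cfg = AugmentConfig()
        cfg.p_photo = 1.0
        out = augment_blended(bg_sample.image, cfg, make_rng(5, "x"))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestStandardizePair:
    def test_aspect_ratio_arithmetic(self):
        rng = np.random.default_rng(0)
        img = rng.random((960, 1280, 3))
        mask = np.zeros((960, 1280), dtype=np.uint8)
        mask[0:300, 100:400] = 1
        from chromablend import ForegroundSample

        fg = ForegroundSample(image=img, mask=mask, id="f")
        bg = BackgroundSample(image=rng.random((960, 1280, 3)), id="b")
        fg2, bg2 = standardize_pair(fg, bg, 640, make_rng(0, "s"))
        assert fg2.image.shape == (480, 640, 3)
        assert bg2.image.shape == (480, 640, 3)

    def test_taller_element_cropped_to_common_height(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((960, 1280), dtype=np.uint8)
        mask[:, 0:200] = 1  # touches left border at every height
        from chromablend import ForegroundSample

        fg = ForegroundSample(image=rng.random((960, 1280, 3)), mask=mask, id="f")
        bg = BackgroundSample(image=rng.random((720, 1280, 3)), id="b")
        fg2, bg2 = standardize_pair(fg, bg, 640, make_rng(1, "s"))
        # bg: 720 * 640/1280 = 360 is the shorter element
        assert fg2.image.shape[0] == bg2.image.shape[0] == 360
        assert fg2.mask.shape == fg2.image.shape[:2]
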