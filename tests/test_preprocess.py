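"""ROI cropping, denoising, CLAHE, normalization, and paired augmentation."""

import numpy as np
import pytest
from skimage.color import rgb2gray
from skimage.measure import label

from ffunet import (AugmentConfig, FundusImage, NormStats, augment,
                    compute_dataset_stats, crop_to_roi, denoise, denormalize,
                    enhance_contrast, find_roi, generate_fundus, normalize,
                    SynthConfig)
from ffunet.preprocess import GAUSSIAN_KERNEL_3X3
from ffunet.errors import DegenerateInputError, ShapeError


def brute_force_otsu(gray_u8: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization over all thresholds."""
    best_t, best_v = 0, -1.0
    flat = gray_u8.ravel().astype(float)
    for t in range(256):
        lo = flat[flat <= t]
        hi = flat[flat > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def disc_image(h=200, w=200, centre=(100, 100), radius=50, value=200.0):
    yy, xx = np.mgrid[0:h, 0:w]
    disc = np.hypot(yy - centre[0], xx - centre[1]) <= radius
    px = np.zeros((h, w, 3))
    px[disc] = value
    return FundusImage(pixels=px), disc


class TestFindRoi:
    def test_disc_box_matches_brute_force_threshold_oracle(self):
        img, disc = disc_image()
        gray = np.round(rgb2gray(img.pixels / 255.0) * 255).astype(np.uint8)
        t = brute_force_otsu(gray)
        fg = gray > t
        comp = label(fg, connectivity=2)
        areas = np.bincount(comp.ravel())
        areas[0] = 0
        biggest = comp == areas.argmax()
        rows = np.where(biggest.any(axis=1))[0]
        cols = np.where(biggest.any(axis=0))[0]
        box, roi = find_roi(img)
        assert (box.row_start, box.row_end) == (rows[0], rows[-1] + 1)
        assert (box.col_start, box.col_end) == (cols[0], cols[-1] + 1)
        np.testing.assert_array_equal(roi, biggest)
        # geometry sanity: radius-50 disc at (100, 100)
        assert abs(box.row_start - 50) <= 1 and abs(box.row_end - 151) <= 1

    def test_largest_component_wins(self):
        px = np.zeros((120, 120, 3))
        px[10:35, 10:30] = 220.0   # 500 px blob
        px[80:90, 80:88] = 220.0   # 80 px blob
        box, roi = find_roi(FundusImage(pixels=px))
        assert (box.row_start, box.row_end, box.col_start, box.col_end) == \
            (10, 35, 10, 30)
        assert roi.sum() == 500

    def test_crop_loses_no_roi_pixel(self):
        img, _ = disc_image()
        box, roi = find_roi(img)
        assert roi.sum() == roi[box.slices()].sum()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateInputError):
            find_roi(FundusImage(pixels=np.full((32, 32, 3), 77.0)))

    def test_idempotent_on_cropped_output(self):
        img, _ = disc_image()
        cropped, box = crop_to_roi(img)
        box2, _ = find_roi(cropped)
        # re-running on the crop returns (near-)full frame
        assert box2.height >= cropped.height - 2
        assert box2.width >= cropped.width - 2

    def test_entirely_bright_image_returns_full_frame(self, rng):
        # no black border anywhere: the ROI box spans (nearly) the whole frame
        px = rng.uniform(180, 220, size=(40, 50, 3))
        box, _ = find_roi(FundusImage(pixels=px))
        assert box.height >= 38 and box.width >= 48


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = FundusImage(pixels=np.full((16, 16, 3), 90.0))
        np.testing.assert_allclose(denoise(img).pixels, 90.0, atol=1e-9)

    def test_single_bright_pixel_scaled_by_kernel_centre(self):
        px = np.zeros((11, 11, 3))
        px[5, 5] = 255.0
        out = denoise(FundusImage(pixels=px))
        centre_weight = GAUSSIAN_KERNEL_3X3[1, 1]
        np.testing.assert_allclose(out.pixels[5, 5], 255.0 * centre_weight,
                                   rtol=1e-12)
        # hand-convolve the full 3x3 neighbourhood
        np.testing.assert_allclose(out.pixels[4:7, 4:7, 0],
                                   255.0 * GAUSSIAN_KERNEL_3X3[::-1, ::-1],
                                   rtol=1e-12)

    def test_kernel_is_normalized(self):
        assert GAUSSIAN_KERNEL_3X3.shape == (3, 3)
        assert GAUSSIAN_KERNEL_3X3.sum() == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_variance_reduced(self, rng):
        px = rng.uniform(0, 255, size=(64, 64, 3))
        out = denoise(FundusImage(pixels=px))
        for c in range(3):
            assert out.pixels[..., c].var() < px[..., c].var()


class TestEnhanceContrast:
    def test_constant_image_stays_constant(self):
        img = FundusImage(pixels=np.full((32, 32, 3), 120.0))
        out = enhance_contrast(img)
        assert np.ptp(rgb2gray(out.pixels / 255.0)) < 1e-6

    def test_low_contrast_ramp_gains_contrast(self):
        ramp = np.linspace(100, 130, 64)[None, :, None]
        px = np.broadcast_to(ramp, (64, 64, 3)).copy()
        img = FundusImage(pixels=px)
        out = enhance_contrast(img)
        assert rgb2gray(out.pixels / 255.0).std() > rgb2gray(px / 255.0).std()

    def test_deterministic(self, small_synth_config):
        img, _ = generate_fundus(small_synth_config)
        a = enhance_contrast(img).pixels
        b = enhance_contrast(img).pixels
        np.testing.assert_array_equal(a, b)


class TestDatasetStats:
    def test_constant_dataset_raises(self):
        with pytest.raises(DegenerateInputError):
            compute_dataset_stats([FundusImage(np.full((4, 4, 3), 100.0))])

    def test_two_single_pixel_images_hand_arithmetic(self):
        imgs = [FundusImage(np.full((1, 1, 3), 0.0)),
                FundusImage(np.full((1, 1, 3), 2.0))]
        stats = compute_dataset_stats(imgs)
        np.testing.assert_allclose(stats.mean, 1.0)
        np.testing.assert_allclose(stats.std, 1.0)

    def test_single_pass_matches_concatenation_oracle(self):
        imgs = [generate_fundus(SynthConfig(image_height=64, image_width=64,
                                            seed=s))[0] for s in range(10)]
        stats = compute_dataset_stats(imgs)
        pooled = np.concatenate([i.pixels.reshape(-1, 3) for i in imgs])
        np.testing.assert_allclose(stats.mean, pooled.mean(axis=0), rtol=1e-10)
        np.testing.assert_allclose(stats.std, pooled.std(axis=0), rtol=1e-10)


class TestNormalize:
    def test_pixel_at_mean_maps_to_zero_and_sigma_to_one(self):
        stats = NormStats(mean=np.array([50.0] * 3), std=np.array([10.0] * 3))
        img = FundusImage(np.full((2, 2, 3), 50.0))
        np.testing.assert_allclose(normalize(img, stats).pixels, 0.0)
        img2 = FundusImage(np.full((2, 2, 3), 60.0))
        np.testing.assert_allclose(normalize(img2, stats).pixels, 1.0)
        img3 = FundusImage(np.full((2, 2, 3), 30.0))
        np.testing.assert_allclose(normalize(img3, stats).pixels, -2.0)

    def test_round_trip_identity(self, rng):
        stats = NormStats(mean=np.array([100.0, 80.0, 40.0]),
                          std=np.array([30.0, 25.0, 20.0]))
        img = FundusImage(rng.uniform(0, 255, size=(8, 8, 3)))
        back = denormalize(normalize(img, stats), stats)
        np.testing.assert_allclose(back.pixels, img.pixels, atol=1e-6)
        assert normalize(img, stats).value_range == "normalized"

    def test_zero_std_rejected(self):
        with pytest.raises(DegenerateInputError):
            NormStats(mean=np.zeros(3), std=np.array([1.0, 0.0, 1.0]))


class TestAugment:
    def test_horizontal_flip_moves_lesion_column(self):
        px = np.zeros((10, 10, 3))
        mask = np.zeros((10, 10), bool)
        px[4, 2] = 200.0
        mask[4, 2] = True
        cfg = AugmentConfig(flip_prob=1.0, rotation_deg=0.0,
                            shift_fraction=0.0, rescale_range=(1.0, 1.0))
        img2, msk2 = augment(FundusImage(px), mask, seed=0, config=cfg)
        assert msk2[4, 10 - 1 - 2]
        assert img2.pixels[4, 10 - 1 - 2, 0] == 200.0
        # image and mask moved identically
        assert (np.argwhere(msk2) == np.argwhere(img2.pixels[..., 0] > 0)).all()

    def test_identity_config_returns_input_unchanged(self, rng):
        px = rng.uniform(0, 255, size=(12, 12, 3))
        mask = rng.uniform(size=(12, 12)) < 0.2
        cfg = AugmentConfig(flip_prob=0.0, rotation_deg=0.0,
                            shift_fraction=0.0, rescale_range=(1.0, 1.0))
        img2, msk2 = augment(FundusImage(px), mask, seed=3, config=cfg)
        np.testing.assert_array_equal(img2.pixels, px)
        np.testing.assert_array_equal(msk2, mask)

    def test_same_seed_reproduces_transform(self, rng):
        px = rng.uniform(0, 255, size=(16, 16, 3))
        mask = rng.uniform(size=(16, 16)) < 0.3
        a_img, a_msk = augment(FundusImage(px), mask, seed=42)
        b_img, b_msk = augment(FundusImage(px), mask, seed=42)
        np.testing.assert_array_equal(a_img.pixels, b_img.pixels)
        np.testing.assert_array_equal(a_msk, b_msk)

    def test_mask_stays_binary_under_rotation(self, rng):
        px = rng.uniform(0, 255, size=(32, 32, 3))
        mask = rng.uniform(size=(32, 32)) < 0.3
        _, msk2 = augment(FundusImage(px), mask, seed=9)
        assert set(np.unique(msk2)).issubset({False, True})

    def test_misaligned_shapes_raise(self):
        with pytest.raises(ShapeError):
            augment(FundusImage(np.zeros((8, 8, 3))), np.zeros((9, 8)), seed=0)
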