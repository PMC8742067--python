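"""Architecture contracts and training behaviour of the segmentation network."""

import numpy as np
import pytest
from skimage.transform import resize

from depthplate.edfn import EDFN, EDFNConfig, augment_background_hue, train_edfn
from depthplate.errors import ConfigError, DataError


@pytest.fixture(scope="module")
def model():
    return EDFN(seed=0)


@pytest.fixture(scope="module")
def toy_dataset():
    """Small coloured-rectangle scenes with exact masks."""
    rng = np.random.default_rng(1)
    imgs, masks = [], []
    for _ in range(10):
        im = np.full((120, 160, 3), (180, 160, 90), np.uint8)
        msk = np.zeros((120, 160), bool)
        r0, c0 = rng.integers(20, 70), rng.integers(30, 100)
        msk[r0 : r0 + 30, c0 : c0 + 40] = True
        im[msk] = (200, 40, 30)
        imgs.append(im)
        masks.append(msk)
    return imgs, masks


class TestArchitecture:
    def test_encoder_output_contract(self, model):
        """120x160x3 input -> 256 feature maps at 15x20 (1/8 scale)."""
        img = np.random.default_rng(0).random((120, 160, 3))
        feats = model.encode(img)
        assert feats.shape == (256, 15, 20)

    def test_two_class_full_resolution_head(self, model):
        img = np.random.default_rng(0).random((120, 160, 3))
        logits = model.forward(img)
        assert logits.shape == (2, 120, 160)
        mask = model.predict_mask(img)
        assert mask.shape == (120, 160) and mask.dtype == bool

    def test_forward_deterministic(self, model):
        img = np.random.default_rng(3).random((120, 160, 3))
        assert np.array_equal(model.forward(img), model.forward(img))

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigError):
            EDFNConfig(input_shape=(121, 160, 3))

    def test_mask_upsampling_preserves_area_ratio(self, model, toy_dataset):
        """Nearest-neighbour 120x160 -> 480x640 keeps the food-area ratio."""
        img, _ = toy_dataset[0][0], toy_dataset[1][0]
        mask = model.predict_mask(np.asarray(img, float) / 255.0)
        up = resize(mask.astype(float), (480, 640), order=0, anti_aliasing=False) > 0.5
        ratio_small = mask.mean()
        ratio_big = up.mean()
        assert ratio_big == pytest.approx(ratio_small, abs=0.02 * max(ratio_small, 1e-6) + 1e-9)


class TestTraining:
    def test_loss_decreases_and_encoder_frozen(self, toy_dataset):
        imgs, masks = toy_dataset
        before = EDFN(seed=0).n_encoder_params()
        result = train_edfn(imgs, masks, seed=0, epochs=5)
        assert all(b < a for a, b in zip(result.train_loss, result.train_loss[1:]))
        assert result.model.n_encoder_params() == before
        ref = EDFN(seed=0)
        for key, (w, _) in result.model.encoder_weights.items():
            assert np.array_equal(w, ref.encoder_weights[key][0])

    def test_split_reproducible(self, toy_dataset):
        imgs, masks = toy_dataset
        a = train_edfn(imgs, masks, seed=4, epochs=1)
        b = train_edfn(imgs, masks, seed=4, epochs=1)
        assert np.array_equal(a.split[0], b.split[0])
        assert np.array_equal(a.split[1], b.split[1])

    def test_identical_dataset_approaches_entropy_floor(self, toy_dataset):
        """Overfit check: copies of one sample drive validation loss down."""
        img, msk = toy_dataset[0][0], toy_dataset[1][0]
        result = train_edfn([img] * 6, [msk] * 6, seed=0, epochs=25)
        assert result.val_loss[result.best_epoch] < 0.25
        assert result.val_loss[result.best_epoch] < result.val_loss[0] / 2

    def test_missing_mask_rejected(self, toy_dataset):
        imgs, masks = toy_dataset
        with pytest.raises(DataError):
            train_edfn(imgs, masks[:-1] + [None])


class TestHueAugmentation:
    def test_all_food_mask_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (20, 30, 3), dtype=np.uint8)
        out = augment_background_hue(img, np.ones((20, 30), bool), seed=5)
        assert np.array_equal(out, img)

    def test_food_pixels_bitwise_unchanged(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 255, (30, 30, 3), dtype=np.uint8)
        mask = np.zeros((30, 30), bool)
        mask[5:15, 5:15] = True
        out = augment_background_hue(img, mask, seed=7)
        assert np.array_equal(out[mask], img[mask])
        assert not np.array_equal(out[~mask], img[~mask])

    def test_saturation_value_preserved(self):
        from skimage.color import rgb2hsv

        img = np.full((16, 16, 3), (160, 120, 60), np.uint8)
        mask = np.zeros((16, 16), bool)
        out = augment_background_hue(img, mask, seed=11)
        hsv_in, hsv_out = rgb2hsv(img), rgb2hsv(out)
        # value/saturation survive the HSV round-trip to 8-bit quantisation
        assert np.allclose(hsv_in[..., 1:], hsv_out[..., 1:], atol=0.02)
        assert not np.allclose(hsv_in[..., 0], hsv_out[..., 0], atol=0.02)
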