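"""Dataset I/O, splitting, augmentation, and the synthetic generator."""

import numpy as np
import pytest

from dhmfmlp.data import (SegmentationSample, augment, load_dataset,
                          save_dataset, split)
from dhmfmlp.synth import SynthConfig, synthesize


@pytest.fixture(scope="module")
def samples():
    return synthesize(SynthConfig(image_size=32, n_images=6, seed=7))


class TestSynthesize:
    def test_requested_count_and_types(self, samples):
        assert len(samples) == 6
        for s in samples:
            assert s.image.shape == (32, 32, 3) and s.image.dtype == np.float32
            assert s.mask.shape == (32, 32) and set(np.unique(s.mask)) <= {0, 1}
            assert s.provenance == "synthetic"
            assert s.mask.any()  # at least one lesion

    def test_same_seed_reproduces_bit_identical_data(self):
        cfg = SynthConfig(image_size=32, n_images=4, seed=11)
        a, b = synthesize(cfg), synthesize(cfg)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.image, sb.image)
            np.testing.assert_array_equal(sa.mask, sb.mask)

    def test_small_lesion_mode_keeps_foreground_under_two_percent(self):
        cfg = SynthConfig(image_size=128, n_images=10, seed=3,
                          lesions_per_image=(1, 1),
                          lesion_radius_fraction=(0.03, 0.05))
        for s in synthesize(cfg):
            # area of one ellipse with semi-axes <= 0.05*side: pi*0.05^2 < 1%
            assert s.mask.mean() < 0.02

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(lesion_radius_fraction=(0.1, 0.6))


class TestDiskRoundTrip:
    @pytest.mark.parametrize("layout", ["two_dirs", "paired_suffix"])
    def test_masks_survive_write_then_load_exactly(self, samples, tmp_path, layout):
        save_dataset(samples, tmp_path / layout, layout=layout)
        loaded = load_dataset(tmp_path / layout, layout=layout, target_size=32)
        assert [s.identifier for s in loaded] == sorted(s.identifier for s in samples)
        by_id = {s.identifier: s for s in samples}
        for s in loaded:
            np.testing.assert_array_equal(s.mask, by_id[s.identifier].mask)
            np.testing.assert_allclose(s.image, by_id[s.identifier].image,
                                       atol=1 / 255 + 1e-6)

    def test_mask_values_become_binary(self, samples, tmp_path):
        save_dataset(samples[:1], tmp_path, layout="two_dirs")
        loaded = load_dataset(tmp_path, layout="two_dirs", target_size=32)
        assert set(np.unique(loaded[0].mask)) <= {0, 1}

    def test_orphan_files_reported(self, samples, tmp_path):
        save_dataset(samples[:2], tmp_path, layout="two_dirs")
        orphan = tmp_path / "images" / "lonely.png"
        orphan.write_bytes((tmp_path / "images" / "synthetic_0000.png").read_bytes())
        with pytest.raises(ValueError, match="lonely"):
            load_dataset(tmp_path, layout="two_dirs", target_size=32)

    def test_multi_mask_pairs_merge_by_or(self, samples, tmp_path):
        from dhmfmlp.data import _write_png
        s = samples[0]
        _write_png(tmp_path / "case.png", s.image)
        half_a = s.mask.copy()
        half_a[16:] = 0
        half_b = s.mask.copy()
        half_b[:16] = 0
        _write_png(tmp_path / "case_mask.png", half_a * 255)
        _write_png(tmp_path / "case_mask_1.png", half_b * 255)
        loaded = load_dataset(tmp_path, layout="paired_suffix", target_size=32)
        np.testing.assert_array_equal(loaded[0].mask, s.mask)


class TestSplit:
    def test_floor_rule_and_disjoint_exhaustive(self, samples):
        train, test = split(samples, ratio=0.8, seed=0)
        assert len(train) == 4 and len(test) == 2  # floor(0.8*6)
        ids = sorted(s.identifier for s in train + test)
        assert ids == sorted(s.identifier for s in samples)

    def test_647_images_split_517_130(self):
        fake = list(range(647))
        train, test = split(fake, ratio=0.8, seed=1)
        assert (len(train), len(test)) == (517, 130)

    def test_same_seed_same_split(self, samples):
        a = split(samples, seed=42)[0]
        b = split(samples, seed=42)[0]
        assert [s.identifier for s in a] == [s.identifier for s in b]


class TestAugment:
    def test_identity_draw_returns_equal_sample(self, samples):
        class AllOff:
            def random(self):
                return 0.9  # above both flip thresholds

            def integers(self, lo, hi):
                return 0

        out = augment(samples[0], AllOff())
        np.testing.assert_array_equal(out.image, samples[0].image)
        np.testing.assert_array_equal(out.mask, samples[0].mask)

    def test_mask_stays_binary_and_area_preserved(self, samples, rng):
        for s in samples:
            for _ in range(5):
                out = augment(s, rng)
                assert set(np.unique(out.mask)) <= {0, 1}
                assert out.mask.sum() == s.mask.sum()
                assert out.image.shape == s.image.shape

    def test_double_180_rotation_is_identity(self, samples):
        class Rot180Only:
            def random(self):
                return 0.9

            def integers(self, lo, hi):
                return 2

        once = augment(samples[0], Rot180Only())
        twice = augment(once, Rot180Only())
        np.testing.assert_array_equal(twice.image, samples[0].image)
        np.testing.assert_array_equal(twice.mask, samples[0].mask)
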