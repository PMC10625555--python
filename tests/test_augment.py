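"""Augmentation transforms: geometric consistency with landmarks, label
integrality, noise statistics, protocol reproducibility."""

import numpy as np
import pytest

from otoseg.augment import (
    AugmentationProtocol,
    Sample,
    apply_protocol,
    fixed_rotation,
    free_rotation,
    get_protocol,
    intensity_augment,
)
from otoseg.io_core import ValidationError


def _one_hot_sample(n=16, pt=(3, 5, 11)):
    img = np.zeros((n, n, n), np.float32)
    img[pt] = 1.0
    lab = (img > 0).astype(np.uint8)
    lms = np.tile(np.asarray(pt, float), (3, 1))
    return Sample(image=img, label=lab, landmarks=lms)


class TestFixedRotation:
    def test_four_quarter_turns_are_identity(self):
        s = _one_hot_sample()
        r = s
        for _ in range(4):
            r = fixed_rotation(r, axis=1, k=1)
        np.testing.assert_array_equal(r.image, s.image)
        np.testing.assert_array_equal(r.label, s.label)
        np.testing.assert_allclose(r.landmarks, s.landmarks)

    def test_center_is_fixed_point(self):
        n = 17
        c = (n - 1) / 2
        s = _one_hot_sample(n=n, pt=(8, 8, 8))
        s.landmarks[:] = c
        for axis in (0, 1, 2):
            for k in (1, 2, 3):
                r = fixed_rotation(s, axis, k)
                np.testing.assert_allclose(r.landmarks, c)

    @pytest.mark.parametrize("axis", [0, 1, 2])
    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_landmark_follows_one_hot_voxel(self, axis, k):
        s = _one_hot_sample()
        r = fixed_rotation(s, axis, k)
        marked = np.array(np.unravel_index(np.argmax(r.image), r.image.shape))
        np.testing.assert_allclose(r.landmarks[0], marked)

    def test_inverse_composition(self, rng):
        img = rng.normal(size=(12, 12, 12)).astype(np.float32)
        s = Sample(image=img, label=(img > 0).astype(np.uint8),
                   landmarks=rng.uniform(0, 11, (3, 3)))
        r = fixed_rotation(fixed_rotation(s, 2, 1), 2, 3)
        np.testing.assert_array_equal(r.image, s.image)
        np.testing.assert_allclose(r.landmarks, s.landmarks)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            fixed_rotation(_one_hot_sample(), 0, 4)

    def test_noncubic_plane_rejected(self):
        img = np.zeros((8, 8, 12), np.float32)
        s = Sample(image=img, label=img.astype(np.uint8),
                   landmarks=np.zeros((3, 3)))
        with pytest.raises(ValidationError, match="unequal"):
            fixed_rotation(s, 0, 1)  # plane (1, 2) has extents 8 vs 12


class TestFreeRotation:
    def test_zero_angle_is_identity(self, rng):
        img = rng.normal(size=(12, 12, 12)).astype(np.float32)
        s = Sample(image=img, label=(img > 0.5).astype(np.uint8),
                   landmarks=rng.uniform(0, 11, (3, 3)))
        r = free_rotation(s, axis=0, angle_deg=0.0)
        np.testing.assert_allclose(r.image, s.image, atol=1e-5)
        np.testing.assert_allclose(r.landmarks, s.landmarks)

    def test_labels_stay_binary(self, rng):
        lab = (rng.random((16, 16, 16)) < 0.3).astype(np.uint8)
        s = Sample(image=lab.astype(np.float32), label=lab,
                   landmarks=np.zeros((3, 3)))
        r = free_rotation(s, axis=1, angle_deg=33.0)
        assert set(np.unique(r.label)) <= {0, 1}

    @pytest.mark.parametrize("axis,angle", [(0, 17.0), (1, -33.0), (2, 44.0)])
    def test_landmark_tracks_one_hot_voxel(self, axis, angle):
        s = _one_hot_sample()
        r = free_rotation(s, axis, angle)
        marked = np.array(np.unravel_index(np.argmax(r.image), r.image.shape))
        assert np.linalg.norm(r.landmarks[0] - marked) <= 1.0

    def test_out_of_bounds_filled_with_background(self):
        img = np.full((16, 16, 16), 5.0, np.float32)
        s = Sample(image=img, label=np.zeros_like(img, np.uint8),
                   landmarks=np.zeros((3, 3)), background=-2.0)
        r = free_rotation(s, axis=0, angle_deg=45.0)
        assert r.image.min() == pytest.approx(-2.0, abs=1e-5)


class TestIntensityAugment:
    def test_identity_when_disabled(self, rng):
        img = rng.normal(size=(8, 8, 8)).astype(np.float32)
        s = Sample(image=img, label=np.zeros_like(img, np.uint8),
                   landmarks=np.zeros((3, 3)))
        r = intensity_augment(s, scale=1.0)
        np.testing.assert_array_equal(r.image, img)

    def test_scale_doubles_noiseless_chunk(self):
        img = np.full((8, 8, 8), 3.0, np.float32)
        s = Sample(image=img, label=np.zeros_like(img, np.uint8),
                   landmarks=np.zeros((3, 3)))
        r = intensity_augment(s, scale=2.0)
        np.testing.assert_allclose(r.image, 6.0)

    def test_gaussian_noise_moment(self, rng):
        img = np.zeros((64, 64, 64), np.float32)
        s = Sample(image=img, label=np.zeros_like(img, np.uint8),
                   landmarks=np.zeros((3, 3)))
        r = intensity_augment(s, gaussian_sigma=0.5, rng=rng)
        assert abs(r.image.std() - 0.5) <= 0.05 * 0.5

    def test_poisson_noise_handles_negative_values(self, rng):
        img = rng.normal(-3.0, 1.0, size=(16, 16, 16)).astype(np.float32)
        s = Sample(image=img, label=np.zeros_like(img, np.uint8),
                   landmarks=np.zeros((3, 3)))
        r = intensity_augment(s, poisson_lambda=60.0, rng=rng)
        assert np.isfinite(r.image).all()
        assert abs(r.image.mean() - img.mean()) <= 0.1

    def test_labels_and_landmarks_untouched(self, rng):
        lab = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
        lms = rng.uniform(0, 7, (3, 3))
        s = Sample(image=rng.normal(size=(8, 8, 8)).astype(np.float32),
                   label=lab, landmarks=lms)
        r = intensity_augment(s, scale=1.7, gaussian_sigma=0.2, rng=rng)
        np.testing.assert_array_equal(r.label, lab)
        np.testing.assert_array_equal(r.landmarks, lms)


class TestProtocols:
    def test_none_protocol_is_identity(self, rng):
        s = _one_hot_sample()
        r = apply_protocol(s, "none", rng)
        np.testing.assert_array_equal(r.image, s.image)

    def test_same_seed_reproduces_sample(self):
        s = _one_hot_sample()
        a = apply_protocol(s, "beta", np.random.default_rng(33))
        b = apply_protocol(s, "beta", np.random.default_rng(33))
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_allclose(a.landmarks, b.landmarks)

    def test_alpha_restricts_fixed_rotations_to_axis0(self):
        assert get_protocol("alpha").fixed_rotation_axes == (0,)
        assert get_protocol("alpha").free_rotation_amplitude == 30.0

    def test_beta_uses_all_axes_and_wider_amplitude(self):
        assert get_protocol("beta").fixed_rotation_axes == (0, 1, 2)
        assert get_protocol("beta").free_rotation_amplitude == 45.0

    def test_beta_axis_frequencies_cover_all_axes(self):
        proto = AugmentationProtocol(
            name="beta", fixed_rotation_axes=(0, 1, 2), p_fixed_rotation=1.0,
            p_free_rotation=0.0, p_scale=0.0, p_noise=0.0,
        )
        rng = np.random.default_rng(0)
        seen = set()
        s = _one_hot_sample()
        for _ in range(200):
            r = apply_protocol(s, proto, rng)
            moved = np.array(np.unravel_index(np.argmax(r.image), r.image.shape))
            # infer the axis whose coordinate was left unchanged
            for ax in (0, 1, 2):
                if moved[ax] == s.landmarks[0][ax]:
                    seen.add(ax)
        assert seen == {0, 1, 2}

    def test_unknown_protocol_rejected(self, rng):
        with pytest.raises(ValidationError):
            apply_protocol(_one_hot_sample(), "delta", rng)

    def test_label_integrality_and_landmark_consistency(self, rng):
        # landmark stays within 1 voxel (interpolation tolerance) of its
        # transformed foreground neighbourhood over random draws
        from scipy import ndimage

        for _ in range(30):
            s = _one_hot_sample(pt=tuple(rng.integers(4, 12, 3)))
            s.label = ndimage.binary_dilation(s.label).astype(np.uint8)
            r = apply_protocol(s, "beta", rng)
            assert set(np.unique(r.label)) <= {0, 1}
            if r.label.any():
                dist = ndimage.distance_transform_edt(~r.label.astype(bool))
                c = np.clip(np.round(r.landmarks[0]).astype(int), 0, 15)
                assert dist[tuple(c)] <= 2.0
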