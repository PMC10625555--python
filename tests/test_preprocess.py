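"""Intensity normalization: clipping, z-normalization, histogram matching."""

import numpy as np
import pytest

from otoseg.io_core import Volume
from otoseg.phantom import apply_domain_shift
from otoseg.preprocess import (
    NormalizationError,
    clip_quantiles,
    histogram_match,
    preprocess_external,
    preprocess_internal,
    reference_from_volumes,
    load_reference,
    save_reference,
    validate_reference,
    znormalize,
)
from otoseg.io_core import ValidationError


def _vol(data):
    return Volume(np.asarray(data, dtype=np.float32), spacing=(99.0,) * 3)


class TestClipQuantiles:
    def test_constant_volume_unchanged(self):
        v = _vol(np.full((4, 4, 4), 3.0))
        np.testing.assert_array_equal(clip_quantiles(v).data, v.data)

    def test_bounds_match_sort_based_oracle(self, rng):
        vals = rng.permutation(1000).astype(np.float32)
        v = _vol(vals.reshape(10, 10, 10))
        out = clip_quantiles(v, 0.01, 0.99)
        # oracle: sorted order statistics with linear interpolation
        s = np.sort(vals)
        lo = np.interp(0.01 * 999, np.arange(1000), s)
        hi = np.interp(0.99 * 999, np.arange(1000), s)
        assert out.data.min() == pytest.approx(lo)
        assert out.data.max() == pytest.approx(hi)

    def test_outlier_clamped_median_unchanged(self, rng):
        vals = rng.normal(size=(10, 10, 10)).astype(np.float32)
        vals[0, 0, 0] = 1e6
        v = _vol(vals)
        out = clip_quantiles(v)
        q99 = np.quantile(vals, 0.99)
        assert out.data[0, 0, 0] == pytest.approx(q99)
        mid = (vals > np.quantile(vals, 0.1)) & (vals < np.quantile(vals, 0.9))
        np.testing.assert_array_equal(out.data[mid], vals[mid])

    def test_invalid_quantiles_rejected(self):
        with pytest.raises(ValidationError):
            clip_quantiles(_vol(np.zeros((3, 3, 3))), 0.9, 0.1)


class TestZNormalize:
    def test_output_standardized(self, rng):
        v = _vol(rng.normal(5, 3, size=(12, 12, 12)))
        out, stats = znormalize(v)
        assert abs(out.data.mean()) <= 1e-6
        assert abs(out.data.std() - 1) <= 1e-6
        assert stats.mean == pytest.approx(5, abs=0.2)

    def test_two_voxel_population_convention(self):
        out, stats = znormalize(_vol(np.array([0.0, 2.0]).reshape(2, 1, 1)))
        np.testing.assert_allclose(out.data.ravel(), [-1.0, 1.0])
        assert stats.mean == pytest.approx(1.0)
        assert stats.sd == pytest.approx(1.0)  # population sd, not sample

    def test_idempotent_within_tolerance(self, rng):
        v = _vol(rng.normal(size=(10, 10, 10)))
        once, _ = znormalize(v)
        twice, stats = znormalize(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-5)
        assert stats.mean == pytest.approx(0.0, abs=1e-6)
        assert stats.sd == pytest.approx(1.0, abs=1e-6)

    def test_constant_input_raises(self):
        with pytest.raises(NormalizationError):
            znormalize(_vol(np.full((3, 3, 3), 2.0)))


class TestHistogramMatch:
    def test_self_match_is_near_identity(self, rng):
        v = _vol(rng.normal(size=(12, 12, 12)))
        lv = np.linspace(0, 1, 256)
        ref = np.stack([lv, np.quantile(v.data, lv)], axis=1)
        out = histogram_match(v, ref)
        bin_width = np.diff(ref[:, 1]).max()
        assert np.abs(out.data - v.data).max() <= bin_width + 1e-6

    def test_uniform_to_uniform_is_affine(self, rng):
        v = _vol(rng.uniform(0, 1, size=(16, 16, 16)))
        lv = np.linspace(0, 1, 256)
        ref = np.stack([lv, 10 + 10 * lv], axis=1)  # uniform[10, 20]
        out = histogram_match(v, ref)
        expected = 10 + 10 * v.data
        bin_width = 10 / 255
        assert np.abs(out.data - expected).max() <= 3 * bin_width

    def test_rank_preservation(self, rng):
        v = _vol(rng.normal(size=(10, 10, 10)))
        lv = np.linspace(0, 1, 64)
        ref = np.stack([lv, np.exp(lv)], axis=1)
        out = histogram_match(v, ref)
        order_in = np.argsort(v.data.ravel(), kind="stable")
        matched = out.data.ravel()[order_in]
        assert (np.diff(matched) >= -1e-9).all()

    def test_invariant_to_monotone_pretransform(self, rng):
        lv = np.linspace(0, 1, 128)
        ref = np.stack([lv, np.quantile(rng.normal(size=4096), lv)], axis=1)
        for _ in range(20):
            v = _vol(rng.normal(size=(8, 8, 8)))
            warped = _vol(np.exp(0.5 * v.data))  # strictly monotone warp
            a = histogram_match(v, ref)
            b = histogram_match(warped, ref)
            bin_width = np.abs(np.diff(ref[:, 1])).max()
            assert np.abs(a.data - b.data).max() <= 2 * bin_width

    def test_non_monotone_reference_rejected(self, rng):
        bad = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 2.0]])
        with pytest.raises(ValidationError):
            histogram_match(_vol(np.zeros((3, 3, 3))), bad)


class TestPipelines:
    def test_clip_then_znormalize_standardizes(self, rng):
        v = _vol(rng.gamma(2.0, 2.0, size=(12, 12, 12)))
        out, _ = preprocess_internal(v)
        assert abs(out.data.mean()) <= 1e-6
        assert abs(out.data.std() - 1) <= 1e-6

    def test_reference_round_trip(self, tmp_path, rng):
        ref = reference_from_volumes([_vol(rng.normal(size=(8, 8, 8)))])
        p = save_reference(ref, tmp_path / "ref.json")
        np.testing.assert_allclose(load_reference(p), ref)

    def test_single_cluster_equals_global_chain(self, small_phantom, rng):
        from otoseg.preprocess import _chain_external

        vol = small_phantom[0]
        ref = reference_from_volumes([_vol(rng.normal(size=(16, 16, 16)))])
        a = preprocess_external(vol, ref, cluster_bounds=None)
        chained = _chain_external(vol, ref, 0.01, 0.99)
        b, _ = znormalize(chained)
        np.testing.assert_allclose(a.data, b.data, atol=1e-5)

    def test_offset_cluster_mapped_into_reference_band(self, small_phantom):
        vol, lab, _ = small_phantom
        ref = reference_from_volumes([vol])
        # shift one half of the histogram by a constant, as a second scanner
        # cluster; the threshold between the modes separates the clusters
        shifted = apply_domain_shift(vol, "offset_cluster", offset=4000.0)
        mixed = Volume(
            np.where(vol.data > vol.data.mean(), shifted.data, vol.data),
            spacing=vol.spacing,
        )
        bound = float(mixed.data.mean())
        out = preprocess_external(mixed, ref, cluster_bounds=[bound])
        ref_sd = 1.0  # reference is z-normalized by construction
        fg_mean = out.data[lab.data.astype(bool)].mean()
        assert abs(fg_mean) <= 5 * ref_sd

    def test_invert_fluid_restores_contrast_ordering(self, small_phantom):
        vol, lab, _ = small_phantom
        fg = lab.data.astype(bool)
        ref = reference_from_volumes([vol])
        inverted = apply_domain_shift(vol, "invert_fluid")
        # single-cluster matching cannot flip ranks; the check is that the
        # normalized output distribution lands in the reference's range
        out = preprocess_external(inverted, ref)
        assert abs(out.data.mean()) <= 1e-6
        ref_vol, _ = preprocess_internal(vol)
        assert out.data.min() >= ref_vol.data.min() - 0.5
        assert out.data.max() <= ref_vol.data.max() + 0.5

    def test_labels_untouched_by_preprocessing(self, small_phantom):
        vol, lab, lms = small_phantom
        before_lab = lab.data.copy()
        before_lms = lms.as_array().copy()
        preprocess_internal(vol)
        np.testing.assert_array_equal(lab.data, before_lab)
        np.testing.assert_array_equal(lms.as_array(), before_lms)

    def test_validate_reference_shape(self):
        with pytest.raises(ValidationError):
            validate_reference(np.zeros((1, 2)))
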