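"""Angiogram formation, downsampling, pairing, sectioning and augmentation."""

import numpy as np
import pytest

from octarec import metrics, phantom
from octarec.angio import (AngiogramVolume, compute_angiogram,
                           dihedral_inverse, dihedral_transform,
                           downsample_enface, make_pairs, mip,
                           section_and_filter, split_dataset, augment)
from octarec.phantom import PhantomSpec, VolumeSeries


def _constant_series(value=0.4, shape=(8, 8, 8, 8)):
    spec = PhantomSpec(grid_size=shape[1:], n_vessels=0, seed=0)
    return VolumeSeries(frames=np.full(shape, value),
                        vessel_mask=np.zeros(shape[1:], bool), spec=spec)


class TestComputeAngiogram:
    def test_identical_repeats_map_to_zero(self):
        vol = compute_angiogram(_constant_series())
        assert np.all(vol.values == 0.0)

    def test_vessel_signal_above_background(self, small_series):
        vol = compute_angiogram(small_series)
        m = small_series.vessel_mask
        assert vol.values[m].mean() > vol.values[~m].mean()

    def test_requires_two_frames(self, small_series):
        with pytest.raises(ValueError):
            compute_angiogram(small_series, n_use=1)
        with pytest.raises(ValueError):
            compute_angiogram(small_series, first_repeat=7, n_use=2)

    def test_more_repeats_reduce_estimator_dispersion(self):
        """Across 50 seeded phantoms, the raw decorrelation estimate at
        vessel voxels varies less when averaged over 8 repeats than 2."""
        est2, est8 = [], []
        for seed in range(50):
            spec = PhantomSpec(grid_size=(16, 16, 8), n_vessels=3, seed=seed)
            series = phantom.make_series(spec, n_repeats=8)
            m = series.vessel_mask
            if not m.any():
                continue
            est2.append(compute_angiogram(series, 0, 2,
                                          normalize=False).values[m])
            est8.append(compute_angiogram(series, 0, 8,
                                          normalize=False).values[m])
        sd2 = np.concatenate(est2).std()
        sd8 = np.concatenate(est8).std()
        assert sd8 < sd2


class TestDownsample:
    def test_identity_at_ratio_one(self, small_series):
        vol = compute_angiogram(small_series)
        assert np.array_equal(downsample_enface(vol, 1).values, vol.values)

    def test_strided_index_selection_oracle(self):
        values = np.arange(16, dtype=float).reshape(4, 4, 1) / 15.0
        vol = AngiogramVolume(values=values, n_repeats_used=2)
        out = downsample_enface(vol, 2).values[:, :, 0]
        expected = values[[0, 0, 2, 2], [0, 2, 0, 2], 0].reshape(2, 2)
        assert np.array_equal(out, expected)

    def test_shape_contract_and_composition(self, small_series):
        ds = downsample_enface(small_series, 2)
        assert ds.frames.shape == (8, 16, 16, 16)
        twice = downsample_enface(ds, 2)
        once = downsample_enface(small_series, 4)
        assert np.array_equal(twice.frames, once.frames)
        assert twice.sampling_ratio == once.sampling_ratio == 4

    def test_non_divisible_shape_rejected(self, small_series):
        with pytest.raises(ValueError):
            downsample_enface(small_series, 3)


class TestMakePairs:
    def test_deterministic_under_seed(self, small_series):
        a = make_pairs(small_series, 2, seed=9)
        b = make_pairs(small_series, 2, seed=9)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.lr_lq.pixels, pb.lr_lq.pixels)
            assert np.array_equal(pa.hr_hq.pixels, pb.hr_hq.pixels)

    def test_shapes_honour_ratio(self, small_pairs):
        for p in small_pairs:
            hx, hy = p.hr_hq.shape
            assert p.hr_lq.shape == (hx, hy)
            assert p.lr_lq.shape == (hx // p.ratio, hy // p.ratio)

    def test_low_quality_differs_from_target(self, small_pairs):
        vals = [metrics.ssim(p.hr_lq.pixels, p.hr_hq.pixels)
                for p in small_pairs]
        assert np.mean(vals) < 1.0

    def test_requires_eight_repeats(self, small_spec):
        series = phantom.make_series(small_spec, n_repeats=4)
        with pytest.raises(ValueError):
            make_pairs(series, 2, seed=0)


class TestMip:
    def test_single_slice_range(self, small_series):
        vol = compute_angiogram(small_series)
        img = mip(vol, (3, 4))
        assert img.kind == "mip" and img.depth_index is None
        assert np.array_equal(img.pixels, vol.values[:, :, 3])

    def test_dominates_every_slice(self, small_series):
        vol = compute_angiogram(small_series)
        img = mip(vol, (2, 7))
        for z in range(2, 7):
            assert np.all(img.pixels >= vol.values[:, :, z])

    def test_pointwise_maximum(self):
        values = np.zeros((8, 8, 2))
        values[0, 0, 0], values[0, 0, 1] = 0.2, 0.7
        img = mip(AngiogramVolume(values, 2))
        assert img.pixels[0, 0] == 0.7

    def test_empty_range_rejected(self, small_series):
        vol = compute_angiogram(small_series)
        with pytest.raises(ValueError):
            mip(vol, (5, 5))


class TestSectionAndFilter:
    def test_zero_fraction_keeps_all(self, small_series):
        vol = compute_angiogram(small_series)
        kept = section_and_filter(vol, min_vessel_fraction=0.0)
        assert len(kept) == vol.values.shape[2]
        assert all(img.kind == "sectioned" for img in kept)
        assert [img.depth_index for img in kept] == list(range(16))

    def test_empty_volume_gives_empty_list(self):
        vol = AngiogramVolume(np.zeros((8, 8, 4)), 2)
        assert section_and_filter(vol, min_vessel_fraction=0.01) == []

    def test_kept_count_matches_pixel_count_oracle(self, small_series):
        vol = compute_angiogram(small_series)
        thr, frac = 0.1, 0.02
        kept = section_and_filter(vol, frac, thr)
        expected = sum(
            1 for z in range(vol.values.shape[2])
            if (vol.values[:, :, z] > thr).sum() >= frac * vol.values[:, :, z].size)
        assert len(kept) == expected


class TestSplitDataset:
    @pytest.mark.parametrize("n,expected", [(2000, (1800, 200)), (10, (9, 1))])
    def test_nine_to_one_sizes(self, n, expected):
        tr, va = split_dataset(n, (9, 1), seed=0)
        assert (len(tr), len(va)) == expected

    def test_disjoint_and_exhaustive(self):
        tr, va = split_dataset(123, (9, 1), seed=4)
        union = np.sort(np.concatenate([tr, va]))
        assert np.array_equal(union, np.arange(123))


class TestAugment:
    def test_identity_element(self, rng):
        img = rng.uniform(0, 1, (8, 8))
        assert np.array_equal(dihedral_transform(img, 0), img)

    @pytest.mark.parametrize("element", range(8))
    def test_multiset_preserved_and_inverse(self, element, rng):
        img = rng.uniform(0, 1, (8, 8))
        out = dihedral_transform(img, element)
        assert sorted(out.ravel()) == sorted(img.ravel())
        back = dihedral_transform(out, dihedral_inverse(element))
        assert np.array_equal(back, img)

    def test_pair_transformed_consistently(self, small_pairs):
        pair = small_pairs[0]
        aug = augment(pair, seed=5)
        assert aug.lr_lq.shape == pair.lr_lq.shape
        assert aug.hr_hq.shape == pair.hr_hq.shape
        # the same group element applies to all three images: relative
        # structure is preserved, so downsampling commutes with augmenting
        assert sorted(aug.hr_hq.pixels.ravel()) == \
            sorted(pair.hr_hq.pixels.ravel())

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            dihedral_transform(np.zeros((4, 6)), 1)
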