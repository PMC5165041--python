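import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mriqa.core import TISSUE_CLASSES, TissueMapSet, VolumeGrid
from mriqa.volumetric import (
    AllZeroVolumeError,
    EmptyClassMaskError,
    gw_t_score,
    vf1_histogram,
    vf2_class_histogram,
)


def brute_force_counts(values, domain_max):
    """Independent per-voxel binning oracle: bin n (1-based) covers
    ((n-1) d, n d] with d = domain_max / 100; zeros land in bin 1."""
    d = domain_max / 100
    counts = np.zeros(100, dtype=int)
    for v in np.ravel(values):
        if v == 0:
            counts[0] += 1
            continue
        for n in range(1, 101):
            if (n - 1) * d < v <= n * d or (n == 100 and v >= domain_max):
                counts[n - 1] += 1
                break
    return counts


def _two_class_maps(shape, gm_region, wm_region):
    maps = {c: np.zeros(shape) for c in TISSUE_CLASSES}
    maps["gm"][gm_region] = 1.0
    maps["wm"][wm_region] = 1.0
    return TissueMapSet({c: VolumeGrid(m) for c, m in maps.items()})


class TestVf1:
    def test_matches_brute_force_oracle(self, rng):
        data = rng.uniform(0, 7.3, size=(8, 8, 8))
        hist = vf1_histogram(VolumeGrid(data))
        np.testing.assert_array_equal(
            hist.counts, brute_force_counts(data, data.max())
        )

    def test_constant_volume_fills_last_bin(self):
        hist = vf1_histogram(VolumeGrid(np.full((16, 16, 16), 3.7)))
        assert hist.counts[99] == 16**3
        assert hist.counts[:99].sum() == 0

    def test_conserves_voxel_count(self, rng):
        data = rng.exponential(2.0, size=(9, 7, 5))
        hist = vf1_histogram(VolumeGrid(data))
        assert hist.counts.sum() == data.size

    def test_all_zero_volume_rejected(self):
        with pytest.raises(AllZeroVolumeError):
            vf1_histogram(VolumeGrid(np.zeros((4, 4, 4))))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False),
            min_size=8,
            max_size=8,
        ).filter(lambda v: max(v) > 0)
    )
    def test_conservation_property(self, values):
        data = np.array(values).reshape(2, 2, 2)
        hist = vf1_histogram(VolumeGrid(data))
        assert hist.counts.sum() == data.size


class TestVf2:
    def test_half_probability_lands_in_bin_50(self):
        hist = vf2_class_histogram(VolumeGrid(np.full((6, 6, 6), 0.5)))
        assert hist.counts[49] == 6**3  # bin 50 covers (0.49, 0.50]

    def test_zeros_land_in_first_bin(self):
        hist = vf2_class_histogram(VolumeGrid(np.zeros((5, 5, 5))))
        assert hist.counts[0] == 5**3

    def test_domain_is_fixed_to_unit(self, rng):
        data = rng.uniform(0, 0.3, size=(6, 6, 6))
        hist = vf2_class_histogram(VolumeGrid(data))
        assert hist.domain_max == 1.0
        np.testing.assert_array_equal(hist.counts, brute_force_counts(data, 1.0))

    def test_values_above_one_rejected(self):
        vol = VolumeGrid(np.full((4, 4, 4), 1.0))
        vol.data[0, 0, 0] = 1.5  # bypass [0,1] check in TissueMapSet
        with pytest.raises(ValueError):
            vf2_class_histogram(vol)


class TestGwTScore:
    def test_identical_distributions_score_zero(self, rng):
        shape = (20, 10, 10)
        vals = rng.normal(5.0, 0.5, size=1000).clip(min=0.01)
        data = np.zeros(shape)
        data[:10].flat = vals
        data[10:].flat = vals  # same values in both class regions
        maps = _two_class_maps(
            shape, (slice(0, 10), slice(None)), (slice(10, 20), slice(None))
        )
        stats = gw_t_score(VolumeGrid(data), maps, mode="intensity")
        assert stats.x1 == pytest.approx(0.0)
        assert stats.gw_t_score == pytest.approx(0.0)

    def test_two_gaussian_closed_form(self, rng):
        """Means 2 and 3, per-class sd 0.1: score -> 1/sqrt(0.02)."""
        shape = (20, 32, 32)
        data = np.zeros(shape)
        data[:10] = rng.normal(2.0, 0.1, size=(10, 32, 32))
        data[10:] = rng.normal(3.0, 0.1, size=(10, 32, 32))
        data = data.clip(min=1e-6)
        maps = _two_class_maps(
            shape, (slice(0, 10), slice(None)), (slice(10, 20), slice(None))
        )
        stats = gw_t_score(VolumeGrid(data), maps, mode="intensity")
        assert stats.gw_t_score == pytest.approx(1 / np.sqrt(0.02), rel=0.05)

    def test_literal_mode_ignores_contrast_on_equal_counts(self, rng):
        """Averaging bin counts makes the mean difference depend only on
        the class sizes, not on the intensities."""
        shape = (20, 16, 16)
        data = np.zeros(shape)
        data[:10] = rng.normal(2.0, 0.1, size=(10, 16, 16)).clip(min=0.01)
        data[10:] = rng.normal(9.0, 0.4, size=(10, 16, 16)).clip(min=0.01)
        maps = _two_class_maps(
            shape, (slice(0, 10), slice(None)), (slice(10, 20), slice(None))
        )
        stats = gw_t_score(VolumeGrid(data), maps, mode="literal")
        assert stats.x1 == pytest.approx(0.0)
        assert stats.gw_t_score == pytest.approx(0.0)

    def test_monotone_in_contrast(self, rng):
        shape = (20, 16, 16)
        maps = _two_class_maps(
            shape, (slice(0, 10), slice(None)), (slice(10, 20), slice(None))
        )
        scores = []
        for wm_mean in (2.5, 3.0, 4.0):
            data = np.zeros(shape)
            data[:10] = rng.normal(2.0, 0.1, size=(10, 16, 16)).clip(min=0.01)
            data[10:] = rng.normal(wm_mean, 0.1, size=(10, 16, 16)).clip(min=0.01)
            scores.append(gw_t_score(VolumeGrid(data), maps).gw_t_score)
        assert scores[0] < scores[1] < scores[2]

    def test_blur_lowers_contrast_score(self, noisy_phantom):
        vol, maps, _ = noisy_phantom
        sharp = gw_t_score(vol, maps).gw_t_score
        blurred = VolumeGrid(ndimage.gaussian_filter(vol.data, 1.5))
        assert gw_t_score(blurred, maps).gw_t_score < sharp

    def test_empty_class_mask_rejected(self):
        shape = (8, 8, 8)
        maps = _two_class_maps(shape, (slice(0, 4), slice(None)), (slice(0, 0),))
        with pytest.raises(EmptyClassMaskError):
            gw_t_score(VolumeGrid(np.ones(shape)), maps)
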