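"""Single-scale suppression filter and the cumulative multi-scale method."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lmsf import (
    as_scale_set,
    cumulative_lmsf,
    gen_sine_signal,
    lmsf_1d,
    lmsf_2d,
    n_max,
    select_scales,
)

images = hnp.arrays(
    np.float64,
    st.tuples(st.integers(8, 24), st.integers(8, 24)),
    elements=st.floats(0, 1e5),
)


class TestNMax:
    @pytest.mark.parametrize(
        "K,M,expected",
        [(200, 200, 99), (1000, 1000, 499), (4, 4, 1), (10, 7, 2)],
    )
    def test_bound(self, K, M, expected):
        assert n_max(K, M) == expected

    def test_too_small_image_is_an_error(self):
        with pytest.raises(ValueError):
            n_max(3, 100)


class TestLmsf1D:
    def test_suppresses_sample_below_half_its_local_mean(self):
        out, flags = lmsf_1d([10, 1, 10], 1, theta=0.5)
        # local means are (5.5, 7, 5.5); only 1/7 < 0.5
        np.testing.assert_array_equal(out, [10, 0, 10])
        np.testing.assert_array_equal(flags, [False, True, False])

    def test_constant_signal_unchanged_at_theta_one(self):
        # ratio is exactly 1 and the comparison is strict
        x = np.full(31, 6.5)
        out, flags = lmsf_1d(x, 4, theta=1.0)
        np.testing.assert_array_equal(out, x)
        assert not flags.any()

    @pytest.mark.parametrize("theta,cutoff", [(0.5, 0.25), (1.0, 0.5)])
    def test_sine_squared_zeroed_below_theta_over_two(self, theta, cutoff):
        # with the window spanning one period the local mean is 0.5, so the
        # filter zeroes exactly the samples below theta/2
        spp = 1001
        x = gen_sine_signal(4, spp)
        n = (spp - 1) // 2
        _, flags = lmsf_1d(x, n, theta=theta)
        interior = slice(n, x.size - n)
        np.testing.assert_array_equal(flags[interior], x[interior] < cutoff)

    def test_rejects_negative_samples_and_bad_theta(self):
        with pytest.raises(ValueError):
            lmsf_1d([1.0, -0.5], 1)
        with pytest.raises(ValueError):
            lmsf_1d([1.0, 2.0], 1, theta=0.0)


class TestLmsf2D:
    def test_constant_image_unchanged_for_theta_up_to_one(self):
        img = np.full((9, 9), 42.0)
        for theta in (0.5, 1.0):
            out, mask = lmsf_2d(img, 2, theta=theta)
            np.testing.assert_array_equal(out, img)
            assert not mask.any()

    def test_isolated_bright_pixel_survives_zero_neighbors_do_not(self):
        img = np.zeros((5, 5))
        img[2, 2] = 100.0
        out, mask = lmsf_2d(img, 1, theta=0.5)
        expected = np.zeros((5, 5))
        expected[2, 2] = 100.0
        np.testing.assert_array_equal(out, expected)
        # all zero pixels are background: ratio 0 (or empty-signal window)
        assert mask.sum() == 24 and not mask[2, 2]

    def test_n_above_bound_is_rejected(self):
        with pytest.raises(ValueError):
            lmsf_2d(np.ones((10, 10)), n_max(10, 10) + 1)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(img=images, n=st.integers(1, 3), theta=st.floats(0.3, 1.1))
    def test_output_pixels_are_zero_or_bitwise_original(self, img, n, theta):
        out, mask = lmsf_2d(img, n, theta=theta)
        assert out.shape == img.shape
        np.testing.assert_array_equal(out[~mask], img[~mask])
        assert (out[mask] == 0).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(img=images, n=st.integers(1, 3))
    def test_background_grows_with_theta(self, img, n):
        _, small = lmsf_2d(img, n, theta=0.4)
        _, large = lmsf_2d(img, n, theta=0.9)
        assert (small <= large).all()

    def test_integer_input_round_trips_dtype(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 4096, (20, 20), dtype=np.uint16)
        out, mask = lmsf_2d(img, 3, theta=0.5)
        assert out.dtype == np.uint16
        np.testing.assert_array_equal(out[~mask], img[~mask])


class TestCumulative:
    def test_singleton_scale_set_matches_single_scale_filter(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (30, 30))
        out1, mask1 = lmsf_2d(img, 4, theta=0.5)
        out2, mask2 = cumulative_lmsf(img, [4], theta=0.5)
        np.testing.assert_array_equal(out1, out2)
        np.testing.assert_array_equal(mask1, mask2)

    def test_background_is_union_of_per_scale_backgrounds(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 255, (40, 40)) ** 2
        scales = (2, 5, 9)
        union = np.zeros(img.shape, dtype=bool)
        for n in scales:
            union |= lmsf_2d(img, n, theta=0.5)[1]
        _, cum = cumulative_lmsf(img, scales, theta=0.5)
        np.testing.assert_array_equal(cum, union)
        # permuting the scale order changes nothing
        _, perm = cumulative_lmsf(img, scales[::-1], theta=0.5)
        np.testing.assert_array_equal(perm, cum)
        # adding a scale never shrinks the background
        _, more = cumulative_lmsf(img, scales + (13,), theta=0.5)
        assert (cum <= more).all()

    def test_constant_image_has_empty_background(self):
        img = np.full((16, 16), 3.0)
        out, mask = cumulative_lmsf(img, [1, 3, 5], theta=1.0)
        np.testing.assert_array_equal(out, img)
        assert not mask.any()

    def test_empty_and_oversized_scale_sets_are_rejected(self):
        img = np.ones((16, 16))
        with pytest.raises(ValueError):
            cumulative_lmsf(img, [], theta=0.5)
        with pytest.raises(ValueError):
            cumulative_lmsf(img, [1, n_max(16, 16) + 1], theta=0.5)

    def test_saturation_on_wide_uniform_strip(self, strip_image):
        # once n exceeds the strip half-width (20 px) the identified
        # background inside the strip stops changing with n
        img, strip = strip_image
        _, m25 = lmsf_2d(img, 25, theta=0.5)
        _, m50 = lmsf_2d(img, 50, theta=0.5)
        np.testing.assert_array_equal(m25[:, strip], m50[:, strip])
        # below the half-width the strip is not yet fully resolved
        _, m10 = lmsf_2d(img, 10, theta=0.5)
        assert not np.array_equal(m10[:, strip], m25[:, strip])


class TestScaleSelection:
    def test_halving_family_from_worked_example(self):
        # max gap ~80 px -> max(N)=40, then 20, 10, 5
        assert select_scales(80, min_scale=5) == (5, 10, 20, 40)

    def test_single_halving_step(self):
        assert select_scales(4, min_scale=2) == (2,)

    def test_large_background_appends_n_max(self):
        got = select_scales(80, image_shape=(1000, 1000),
                            large_background=True, min_scale=5)
        assert got == (5, 10, 20, 40, 499)

    def test_infeasible_gap_is_an_error(self):
        with pytest.raises(ValueError):
            select_scales(8, min_scale=5)

    def test_scale_set_validation(self):
        assert as_scale_set([10, 5, 5, 20]) == (5, 10, 20)
        with pytest.raises(ValueError):
            as_scale_set([0, 5])
        with pytest.raises(ValueError):
            as_scale_set([5, 200], shape=(100, 100))
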