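"""Path-based Retinex variants: threshold chains, spiral, pyramid."""

import math

import numpy as np
import pytest

from retinexmed import (
    PathConfig,
    PyramidConfig,
    SpiralConfig,
    conversion_operator,
    frankle_mccann,
    mccann99,
    path_log_ratio,
    random_path_retinex,
    spiral_offsets,
    threshold_ratio,
)
from retinexmed.errors import ConfigError, DomainError, SizeError
from retinexmed.path_retinex import image_pyramid


class TestThresholdRatio:
    def test_as_printed_keeps_ratio_in_band(self):
        assert threshold_ratio(1.05, 0.1) == 1.05

    def test_as_printed_resets_ratio_outside_band(self):
        assert threshold_ratio(1.5, 0.1) == 1.0

    def test_classic_mode_inverts_branches(self):
        assert threshold_ratio(1.05, 0.1, mode="classic") == 1.0
        assert threshold_ratio(1.5, 0.1, mode="classic") == 1.5

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            threshold_ratio(0.0, 0.1)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(DomainError):
            threshold_ratio(1.0, -0.5)


class TestPathLogRatio:
    def test_constant_image_gives_zero(self):
        img = np.full((3, 3), 7.0)
        path = [(0, 0), (0, 1), (1, 1), (2, 1)]
        assert path_log_ratio(img, path, T=0.5) == 0.0

    def test_two_pixel_unit_to_e_path(self):
        img = np.array([[1.0, math.e], [1.0, 1.0]])
        # ratio e needs a band wider than (0,1); T > e-1 lets it pass
        assert path_log_ratio(img, [(0, 0), (0, 1)], T=2.0) == pytest.approx(1.0, abs=1e-5)

    def test_agrees_with_termwise_oracle(self, rng):
        """Independent oracle: apply the ratio threshold term by term and sum
        the logs of the thresholded ratios."""
        img = rng.uniform(10.0, 200.0, (3, 3))
        path = [(0, 0), (1, 0), (1, 1), (2, 1)]
        T = 0.5
        expected = 0.0
        for (r0, c0), (r1, c1) in zip(path, path[1:]):
            expected += math.log(threshold_ratio(img[r1, c1] / img[r0, c0], T))
        got = path_log_ratio(img, path, T)
        assert got == pytest.approx(expected, abs=1e-6)  # epsilon log guard

    def test_path_leaving_bounds_raises(self):
        with pytest.raises(IndexError):
            path_log_ratio(np.ones((3, 3)), [(0, 0), (0, 3)], T=0.5)

    def test_short_path_rejected(self):
        with pytest.raises(ConfigError):
            path_log_ratio(np.ones((3, 3)), [(0, 0)], T=0.5)


class TestRandomPath:
    def test_uniform_image_gives_zero_reflectance(self):
        out = random_path_retinex(np.full((8, 8), 50.0), PathConfig(seed=1))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_same_seed_is_bit_identical(self, random_image):
        cfg = PathConfig(seed=7, n_paths=3, path_length=16)
        a = random_path_retinex(random_image, cfg)
        b = random_path_retinex(random_image, cfg)
        np.testing.assert_array_equal(a, b)

    def test_different_seed_changes_output(self, random_image):
        a = random_path_retinex(random_image, PathConfig(seed=1, n_paths=2))
        b = random_path_retinex(random_image, PathConfig(seed=2, n_paths=2))
        assert not np.array_equal(a, b)

    def test_zero_paths_rejected(self):
        with pytest.raises(ConfigError):
            PathConfig(n_paths=0)

    def test_threshold_outside_unit_band_rejected(self):
        with pytest.raises(ConfigError):
            PathConfig(threshold_T=1.5)


class TestConversionOperator:
    @pytest.mark.parametrize(
        "rows,cols,expected",
        [(256, 256, 128), (512, 256, 128), (100, 100, 32), (4, 4, 2)],
    )
    def test_values(self, rows, cols, expected):
        assert conversion_operator(rows, cols) == expected

    def test_degenerate_dimension_rejected(self):
        with pytest.raises(DomainError):
            conversion_operator(1, 256)

    def test_offset_magnitudes_halve_until_below_one(self):
        """Oracle: iterate D <- D/2 from the initial magnitude."""
        mags = [max(abs(a), abs(b)) for a, b in spiral_offsets(256, 256)]
        expected, d = [], 128.0
        while d >= 1:
            expected.append(d)
            d /= 2
        assert mags == expected
        assert len(mags) == 8  # 128 down to 1

    def test_offsets_rotate_clockwise(self):
        offs = spiral_offsets(256, 256)
        # consecutive offsets are perpendicular
        for (a1, b1), (a2, b2) in zip(offs, offs[1:]):
            assert a1 * a2 + b1 * b2 == 0


class TestFrankleMcCann:
    def test_constant_image_gives_constant_output(self):
        out = frankle_mccann(np.full((16, 16), 80.0))
        np.testing.assert_allclose(out, out.flat[0], atol=1e-12)

    def test_output_clamped_at_white_reference(self, random_image):
        # reset step: no estimate may exceed the log of the image maximum
        assert frankle_mccann(random_image).max() <= 1e-12

    def test_explicit_reset_ceiling(self, random_image):
        out = frankle_mccann(random_image, SpiralConfig(max_value=100.0))
        assert np.exp(out.max()) * 100.0 <= 100.0 + 1e-6

    def test_shape_preserved(self, rng):
        img = rng.uniform(10, 255, (12, 20))
        assert frankle_mccann(img).shape == (12, 20)


class TestMcCann99:
    def test_constant_image_gives_constant_output(self):
        out = mccann99(np.full((16, 16), 80.0))
        np.testing.assert_allclose(out, out.flat[0], atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(SizeError):
            mccann99(np.ones((3, 8)))

    def test_pyramid_coarse_level_is_block_mean(self, rng):
        """Oracle: hand-computed 2×2 block averages of a 4×4 image."""
        img = rng.uniform(1, 255, (4, 4))
        levels = image_pyramid(img)
        assert len(levels) == 2
        expected = np.array(
            [
                [img[0:2, 0:2].mean(), img[0:2, 2:4].mean()],
                [img[2:4, 0:2].mean(), img[2:4, 2:4].mean()],
            ]
        )
        np.testing.assert_allclose(levels[1], expected, atol=1e-12)

    def test_reset_keeps_estimates_below_white_reference(self, random_image):
        assert mccann99(random_image).max() <= 1e-12

    def test_shape_preserved_for_odd_sizes(self, rng):
        img = rng.uniform(10, 255, (13, 9))
        assert mccann99(img).shape == (13, 9)


@pytest.mark.parametrize("k", [0.1, 2.0, 10.0])
@pytest.mark.parametrize(
    "enhance",
    [
        lambda a: random_path_retinex(a, PathConfig(seed=3, n_paths=2, path_length=12)),
        frankle_mccann,
        mccann99,
    ],
    ids=["random-path", "frankle-mccann", "mccann99"],
)
def test_scale_invariance(enhance, k, random_image):
    """Multiplying the input by k > 0 leaves the log-reflectance unchanged."""
    np.testing.assert_allclose(
        enhance(k * random_image), enhance(random_image), atol=1e-5
    )
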