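"""Block matching (exhaustive search), motion profiles, period estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrdmd import (
    BlockMatchConfig,
    FrameStack,
    InvalidConfigError,
    InvalidInputError,
    block_match,
    estimate_period,
    mean_motion_magnitude,
)


def _textured(rng, shape=(32, 32)):
    return rng.random(shape) * 100


class TestBlockMatch:
    def test_identity_gives_zero_field(self):
        f = _textured(np.random.default_rng(30))
        field = block_match(f, f, BlockMatchConfig())
        assert np.all(field.displacements == 0)
        assert field.mean_magnitude == 0.0

    def test_cyclic_shift_recovered_on_interior_blocks(self):
        rng = np.random.default_rng(31)
        f = _textured(rng, (48, 48))
        g = np.roll(f, (2, 0), axis=(0, 1))
        field = block_match(f, g, BlockMatchConfig())
        # every block's true (zero-cost) match lies within the search range
        assert np.all(field.displacements == np.array([2, 0]))
        assert field.mean_magnitude == pytest.approx(2.0)

    def test_matches_brute_force_oracle_bit_for_bit(self, block_match_oracle):
        cfg = BlockMatchConfig()
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            ref, target = _textured(rng), _textured(rng)
            field = block_match(ref, target, cfg)
            expected = block_match_oracle(ref, target, cfg)
            np.testing.assert_array_equal(field.displacements, expected)

    def test_mad_cost_matches_oracle(self, block_match_oracle):
        cfg = BlockMatchConfig(cost="mad")
        rng = np.random.default_rng(2000)
        ref, target = _textured(rng), _textured(rng)
        np.testing.assert_array_equal(
            block_match(ref, target, cfg).displacements,
            block_match_oracle(ref, target, cfg),
        )

    def test_frame_smaller_than_block_rejected(self):
        with pytest.raises(InvalidInputError):
            block_match(np.ones((10, 10)), np.ones((10, 10)), BlockMatchConfig())

    def test_bad_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            BlockMatchConfig(overlap_r=15)  # overlap must be < block height

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        max_r=st.integers(0, 4),
        max_c=st.integers(0, 4),
    )
    def test_displacements_bounded_by_search_range(self, seed, max_r, max_c):
        rng = np.random.default_rng(seed)
        cfg = BlockMatchConfig(
            block_height=8, block_width=8, overlap_r=2, overlap_c=2,
            max_disp_r=max_r, max_disp_c=max_c,
        )
        field = block_match(_textured(rng, (24, 24)), _textured(rng, (24, 24)), cfg)
        assert np.all(np.abs(field.displacements[:, 0]) <= max_r)
        assert np.all(np.abs(field.displacements[:, 1]) <= max_c)


class TestMeanMotionMagnitude:
    def test_static_sequence_all_zero(self):
        f = _textured(np.random.default_rng(32))
        profile = mean_motion_magnitude(
            FrameStack(np.stack([f] * 5), dt=1.0), BlockMatchConfig()
        )
        assert np.all(profile.magnitudes == 0)
        assert profile.global_mean == 0.0

    def test_alternating_shift_measures_three_pixels_exactly(self):
        # vertically 6-periodic texture: a cyclic roll by 3 has exact matches
        # at both dr=+3 and dr=-3 for every block, so the tie rule still
        # reports magnitude 3
        rng = np.random.default_rng(33)
        tile = rng.random((6, 48)) * 100
        f = np.tile(tile, (8, 1))
        g = np.roll(f, 3, axis=0)
        stack = FrameStack(np.stack([f, g, f, g, f]), dt=1.0)
        profile = mean_motion_magnitude(stack, BlockMatchConfig(), "consecutive")
        np.testing.assert_allclose(profile.magnitudes, 3.0)
        assert profile.global_mean == pytest.approx(3.0)

    def test_vs_first_scheme_pairs_against_frame_zero(self):
        f = _textured(np.random.default_rng(34))
        g = np.roll(f, 2, axis=0)
        stack = FrameStack(np.stack([f, f, g, f]), dt=1.0)
        profile = mean_motion_magnitude(stack, BlockMatchConfig(), "vs_first")
        assert profile.magnitudes.shape == (3,)
        assert profile.magnitudes[0] == 0.0
        assert profile.magnitudes[2] == 0.0
        assert profile.magnitudes[1] > 0.0

    def test_profile_serialises_to_csv(self, tmp_path):
        f = _textured(np.random.default_rng(35))
        profile = mean_motion_magnitude(
            FrameStack(np.stack([f] * 3), dt=1.0), BlockMatchConfig()
        )
        path = tmp_path / "profile.csv"
        profile.to_csv(path)
        text = path.read_text()
        assert "frame_pair" in text and "mean_magnitude_px" in text

    def test_unknown_scheme_rejected(self):
        f = _textured(np.random.default_rng(36))
        with pytest.raises(InvalidInputError):
            mean_motion_magnitude(
                FrameStack(np.stack([f] * 3), dt=1.0), BlockMatchConfig(), "zigzag"
            )


class TestEstimatePeriod:
    def test_exact_period_three(self):
        assert estimate_period([0, 1, 2] * 6) == 3

    def test_constant_series_no_periodicity(self):
        assert estimate_period([5.0] * 20) == 0

    def test_noisy_periodic_series(self):
        rng = np.random.default_rng(37)
        base = np.tile([0.0, 2.0, 2.0], 40)
        assert estimate_period(base + rng.normal(0, 0.2, base.size)) == 3

    def test_phantom_motion_series_period_three(self, vs_first_profile):
        assert estimate_period(vs_first_profile.magnitudes) == 3

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_period([1.0, 2.0])
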