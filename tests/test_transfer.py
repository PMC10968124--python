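"""Transfer-function catalog, schedules and binarization rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasshopper_fs import (
    TransferSchedule,
    binarize_sine,
    binarize_static,
    s_shaped,
    schedules,
    sine_probability,
    tvg_flip,
    tvg_probability,
    v_shaped,
)
from grasshopper_fs.transfer import S_VARIANTS, V_VARIANTS

GRID = np.linspace(-10.0, 10.0, 2001)


class TestStaticCatalog:
    @pytest.mark.parametrize("variant, x, expected", [
        ("s1", 0.0, 0.5),
        ("s2", 1.0, 0.880797077977882),   # frozen closed-form evaluation
        ("v2", 0.0, 0.0),
        ("v3", 1.0, 0.707106781186548),   # 1/sqrt(2)
    ])
    def test_known_values(self, variant, x, expected):
        fn = s_shaped if variant.startswith("s") else v_shaped
        assert fn(variant, x) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("variant", S_VARIANTS)
    def test_s_family_strictly_increasing_in_unit_range(self, variant):
        vals = s_shaped(variant, GRID)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))

    @pytest.mark.parametrize("variant", S_VARIANTS)
    def test_s_family_antisymmetric_about_half(self, variant):
        assert np.allclose(s_shaped(variant, -GRID), 1 - s_shaped(variant, GRID),
                           atol=1e-12)

    @pytest.mark.parametrize("variant", V_VARIANTS)
    def test_v_family_even_zero_at_origin_nondecreasing(self, variant):
        vals = v_shaped(variant, GRID)
        assert np.allclose(vals, v_shaped(variant, -GRID), atol=1e-15)
        assert v_shaped(variant, 0.0) == 0.0
        assert np.all((vals >= 0) & (vals <= 1))
        pos = v_shaped(variant, np.linspace(0, 10, 500))
        assert np.all(np.diff(pos) >= 0)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            s_shaped("s9", 0.0)
        with pytest.raises(ValueError):
            v_shaped("v9", 0.0)


class TestSchedules:
    def test_endpoints_hit_printed_ranges_exactly(self):
        sched = TransferSchedule(max_iterations=100)
        assert schedules(0, sched) == (0.05, 10.0, 10.0)
        assert schedules(100, sched) == (5.0, 0.05, 0.01)

    def test_midpoint_is_mean_of_endpoints(self):
        sched = TransferSchedule(max_iterations=100)
        alpha, beta, sigma = schedules(50, sched)
        assert alpha == pytest.approx((0.05 + 5.0) / 2)
        assert beta == pytest.approx((10.0 + 0.05) / 2)
        assert sigma == pytest.approx((10.0 + 0.01) / 2)

    def test_alpha_increases_beta_sigma_decrease(self):
        sched = TransferSchedule(max_iterations=20)
        vals = np.array([schedules(i, sched) for i in range(21)])
        assert np.all(np.diff(vals[:, 0]) > 0)
        assert np.all(np.diff(vals[:, 1]) < 0)
        assert np.all(np.diff(vals[:, 2]) < 0)

    def test_rejects_iteration_out_of_range(self):
        sched = TransferSchedule(max_iterations=10)
        with pytest.raises(ValueError):
            schedules(11, sched)
        with pytest.raises(ValueError):
            schedules(-1, sched)


class TestSineTransfer:
    def test_known_points(self):
        alpha = 0.7
        assert sine_probability(0.0, alpha) == 0.0
        assert sine_probability(alpha * np.pi / 2, alpha) == pytest.approx(1.0)
        assert sine_probability(alpha * np.pi / 6, alpha) == pytest.approx(0.5)

    def test_probability_bounded_on_grid(self):
        for alpha in (0.05, 1.0, 5.0):
            vals = sine_probability(GRID, alpha)
            assert np.all((vals >= 0) & (vals <= 1))

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            sine_probability(1.0, 0.0)

    def test_set_rule_comparison(self):
        # probabilities (0.5, 0.5) at position alpha*pi/6; draws straddle them
        alpha = 1.0
        pos = np.array([np.pi / 6, np.pi / 6])
        bits = binarize_sine(pos, alpha, np.array([0.3, 0.7]))
        assert bits.tolist() == [1, 0]

    def test_extreme_probabilities(self):
        assert binarize_sine(np.zeros(3), 1.0, np.full(3, 0.0)).tolist() == [0, 0, 0]
        peak = np.full(3, np.pi / 2)
        assert binarize_sine(peak, 1.0, np.full(3, 0.999)).tolist() == [1, 1, 1]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binarize_sine(np.zeros(3), 1.0, np.zeros(2))


class TestTVGTransfer:
    def test_known_points(self):
        assert tvg_probability(0.0, beta=2.0, sigma=0.0, gaussian_draw=0.0) == 0.0
        assert tvg_probability(1e9, beta=1.0, sigma=0.0, gaussian_draw=0.0) == pytest.approx(1.0, abs=1e-6)
        # position == beta: |2/pi * arctan(pi/2)| frozen from closed form
        assert tvg_probability(3.0, beta=3.0, sigma=0.0, gaussian_draw=0.0) == pytest.approx(
            0.639092926771892, abs=1e-12)

    def test_reduces_to_v4_when_sigma_zero_beta_one(self):
        assert np.allclose(tvg_probability(GRID, 1.0, 0.0, np.zeros_like(GRID)),
                           v_shaped("v4", GRID), atol=1e-12)

    def test_gaussian_term_clipped_into_unit_interval(self):
        vals = tvg_probability(GRID, 1.0, 10.0, np.linspace(-3, 3, GRID.size))
        assert np.all((vals >= 0) & (vals <= 1))

    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            tvg_probability(1.0, beta=0.0, sigma=1.0, gaussian_draw=0.0)
        with pytest.raises(ValueError):
            tvg_probability(1.0, beta=1.0, sigma=-1.0, gaussian_draw=0.0)

    def test_flip_rule_identity_and_involution(self):
        bits = np.array([0, 1, 1, 0], dtype=np.int8)
        zeros = np.zeros(4)
        # probability 0 everywhere: unchanged
        out = tvg_flip(bits, zeros, 1.0, 0.0, np.full(4, 0.5), zeros)
        assert np.array_equal(out, bits)
        # probability clipped to 1 (huge positive Gaussian term): all complemented
        ones_g = np.full(4, 100.0)
        out = tvg_flip(bits, zeros, 1.0, 1.0, np.full(4, 0.5), ones_g)
        assert np.array_equal(out, 1 - bits)
        # flipping twice with identical draws restores the original
        again = tvg_flip(out, zeros, 1.0, 1.0, np.full(4, 0.5), ones_g)
        assert np.array_equal(again, bits)


class TestStaticBinarization:
    def test_set_and_flip_rules(self):
        bits = np.array([1, 0], dtype=np.int8)
        draws = np.array([0.5, 0.5])
        assert binarize_static(np.array([0.2, 0.8]), "set", bits, draws).tolist() == [0, 1]
        assert binarize_static(np.array([0.0, 0.0]), "set", bits, draws).tolist() == [0, 0]
        assert binarize_static(np.array([0.0, 0.0]), "flip", bits, draws).tolist() == [1, 0]
        assert binarize_static(np.array([1.0, 1.0]), "flip", bits, draws).tolist() == [0, 1]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            binarize_static(np.array([0.5]), "toggle", np.array([1]), np.array([0.1]))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30)
    def test_binarization_replays_against_independent_comparison(self, seed):
        # an independent re-implementation of the comparison rules reproduces
        # the bits exactly from the recorded draw sequence
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-2, 2, size=12)
        bits = rng.integers(0, 2, size=12).astype(np.int8)
        u1, u2 = rng.random(12), rng.random(12)
        g = rng.standard_normal(12)
        alpha, beta, sigma = 0.4, 2.0, 0.3

        stage1 = binarize_sine(pos, alpha, u1)
        final = tvg_flip(stage1, pos, beta, sigma, u2, g)

        expect1 = np.array([1 if u1[i] < abs(np.sin(pos[i] / alpha)) else 0
                            for i in range(12)])
        p2 = [min(1.0, max(0.0, abs(2 / np.pi * np.arctan(np.pi / 2 * pos[i] / beta))
                           + sigma * g[i])) for i in range(12)]
        expect2 = np.array([1 - expect1[i] if u2[i] < p2[i] else expect1[i]
                            for i in range(12)])
        assert np.array_equal(stage1, expect1)
        assert np.array_equal(final, expect2)
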