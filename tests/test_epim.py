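import numpy as np
import pytest

from flimupscale.bicubic import bicubic_upscale
from flimupscale.epim import (
    W4,
    DirectionLabel,
    EPIMParams,
    directional_variation,
    epim_upscale,
    select_direction,
    snake_sequence,
    step1_embed,
    step2_fill_diagonal_centers,
    step3_fill_axial,
    _STEP2_STENCILS,
    _masked_stencil_apply,
)

from conftest import make_frame
from oracles import SNAKE4, oracle_step2_center, oracle_variation

RAMP = np.arange(1, 17, dtype=float).reshape(4, 4)
ALL_VALID4 = np.ones((4, 4), bool)


class TestSnakeSequence:
    def test_horizontal_boustrophedon(self):
        expected = [1, 2, 3, 4, 8, 7, 6, 5, 9, 10, 11, 12, 16, 15, 14, 13]
        assert snake_sequence(RAMP, DirectionLabel.HORIZONTAL).tolist() == expected

    @pytest.mark.parametrize("direction", list(DirectionLabel)[:4])
    @pytest.mark.parametrize("k", [4, 5])
    def test_is_a_permutation_with_adjacent_steps(self, direction, k):
        """Every serialization visits each pixel once, and consecutive
        elements are spatially adjacent (8-neighborhood)."""
        idx = np.arange(k * k, dtype=float).reshape(k, k)
        seq = snake_sequence(idx, direction)
        assert sorted(seq.tolist()) == list(range(k * k))
        coords = [(int(v) // k, int(v) % k) for v in seq]
        for (r0, c0), (r1, c1) in zip(coords, coords[1:]):
            assert max(abs(r1 - r0), abs(c1 - c0)) == 1

    def test_pure_function(self):
        a = snake_sequence(RAMP, DirectionLabel.DIAG_MAIN)
        b = snake_sequence(RAMP, DirectionLabel.DIAG_MAIN)
        assert np.array_equal(a, b)

    def test_constant_window_any_direction(self):
        const = np.full((5, 5), 3.5)
        for d in list(DirectionLabel)[:4]:
            assert np.all(snake_sequence(const, d) == 3.5)

    def test_isotropic_has_no_order(self):
        with pytest.raises(ValueError):
            snake_sequence(RAMP, DirectionLabel.ISOTROPIC)


class TestDirectionalVariation:
    def test_constant_window_is_zero(self):
        var, cnt = directional_variation(np.full((4, 4), 9.0), ALL_VALID4,
                                         DirectionLabel.HORIZONTAL)
        assert var == 0.0 and cnt == 15

    # frozen values computed with the independent looped oracle on the
    # 1..16 row-major ramp
    @pytest.mark.parametrize(
        "direction, expected",
        [
            (DirectionLabel.HORIZONTAL, 24.0),
            (DirectionLabel.VERTICAL, 51.0),
            (DirectionLabel.DIAG_MAIN, 57.0),
            (DirectionLabel.DIAG_ANTI, 45.0),
        ],
    )
    def test_ramp_values(self, direction, expected):
        var, cnt = directional_variation(RAMP, ALL_VALID4, direction)
        assert var == expected and cnt == 15

    def test_agrees_with_oracle_under_masking(self):
        rng = np.random.default_rng(11)
        keys = {"H": DirectionLabel.HORIZONTAL, "V": DirectionLabel.VERTICAL,
                "DM": DirectionLabel.DIAG_MAIN, "DA": DirectionLabel.DIAG_ANTI}
        for _ in range(50):
            w = rng.uniform(0, 100, (4, 4))
            v = rng.random((4, 4)) > 0.3
            for key, d in keys.items():
                expect_var, expect_cnt = oracle_variation(w, v, SNAKE4[key])
                var, cnt = directional_variation(w, v, d)
                assert var == pytest.approx(expect_var, abs=1e-12)
                assert cnt == expect_cnt

    def test_invalid_pixel_value_is_ignored(self):
        w = RAMP.copy()
        v = ALL_VALID4.copy()
        v[1, 2] = False
        ref = directional_variation(w, v, DirectionLabel.VERTICAL)
        w[1, 2] = 1e9
        assert directional_variation(w, v, DirectionLabel.VERTICAL) == ref


class TestSelectDirection:
    def test_minimum_variation_wins(self):
        stats = {
            DirectionLabel.HORIZONTAL: (24.0, 15),
            DirectionLabel.VERTICAL: (51.0, 15),
            DirectionLabel.DIAG_MAIN: (57.0, 15),
            DirectionLabel.DIAG_ANTI: (45.0, 15),
        }
        assert select_direction(stats) == DirectionLabel.HORIZONTAL

    def test_all_equal_is_isotropic(self):
        stats = {d: (5.0, 15) for d in list(DirectionLabel)[:4]}
        assert select_direction(stats) == DirectionLabel.ISOTROPIC

    def test_low_pair_count_forces_isotropic(self):
        stats = {
            DirectionLabel.HORIZONTAL: (1.0, 15),
            DirectionLabel.VERTICAL: (99.0, 4),  # fewer than half the max pairs
        }
        assert select_direction(stats) == DirectionLabel.ISOTROPIC

    def test_main_diagonal_step_edge_selects_main_diagonal(self):
        """Ideal step edge along the main diagonal: interpolation follows it."""
        w = np.where(np.add.outer(np.arange(4), -np.arange(4)) > 0, 100.0, 0.0)
        stats = {
            d: directional_variation(w, ALL_VALID4, d) for d in list(DirectionLabel)[:4]
        }
        assert select_direction(stats) == DirectionLabel.DIAG_MAIN


class TestStep1:
    def test_embedding_and_counts(self):
        src = RAMP
        grid, filled, valid = step1_embed(src)
        assert grid.shape == (8, 8)
        assert filled.sum() == 16
        assert np.array_equal(grid[::2, ::2], src)
        assert sorted(grid[filled].tolist()) == sorted(src.ravel().tolist())

    def test_invalid_source_pixel_stays_invalid(self):
        sv = ALL_VALID4.copy()
        sv[2, 1] = False
        _, filled, valid = step1_embed(RAMP, sv)
        assert filled[4, 2] and not valid[4, 2]


class TestStep2:
    def test_forced_diagonal_stencil_weights(self):
        """Unit impulse at window pixels 6 and 1 (row-major 1..16) under the
        main-diagonal stencil reproduces the 9/16 and -1/16 weights."""
        for (r, c), expected in (((1, 1), 9 / 16), ((0, 0), -1 / 16)):
            w = np.zeros((1, 1, 4, 4))
            w[0, 0, r, c] = 1.0
            val, ok = _masked_stencil_apply(
                w, np.ones_like(w, bool), _STEP2_STENCILS[DirectionLabel.DIAG_MAIN], 0.5
            )
            assert ok[0, 0]
            assert val[0, 0] == pytest.approx(expected, abs=1e-15)

    def test_horizontal_stencil_touches_exactly_8_pixels(self):
        nonzero = set()
        for r in range(4):
            for c in range(4):
                w = np.zeros((1, 1, 4, 4))
                w[0, 0, r, c] = 1.0
                val, _ = _masked_stencil_apply(
                    w, np.ones_like(w, bool),
                    _STEP2_STENCILS[DirectionLabel.HORIZONTAL], 0.5,
                )
                if val[0, 0] != 0.0:
                    nonzero.add((r, c))
        assert nonzero == {(r, c) for r in (1, 2) for c in range(4)}

    def test_constant_fill(self):
        grid, filled, valid = step1_embed(np.full((6, 6), 4.5))
        grid, filled, valid, _, _ = step2_fill_diagonal_centers(grid, filled, valid)
        np.testing.assert_allclose(grid[1::2, 1::2], 4.5, atol=1e-12)
        assert valid[1::2, 1::2].all()

    def test_matches_brute_force_oracle_on_random_windows(self):
        """200 random 4x4 windows with random masks: the vectorized step-2
        center agrees with the explicit-loop oracle to 1e-12."""
        rng = np.random.default_rng(2024)
        for trial in range(200):
            window = rng.uniform(0, 100, (4, 4))
            valid = rng.random((4, 4)) > (0.3 if trial % 2 else 0.0)
            src = np.zeros((6, 6))
            src_valid = np.zeros((6, 6), bool)
            src[1:5, 1:5] = window  # center (2*2+1, 2*2+1)=(5,5) sees exactly `window`
            src_valid[1:5, 1:5] = valid
            grid, filled, v = step1_embed(src, src_valid)
            grid, filled, v, _, _ = step2_fill_diagonal_centers(grid, filled, v)
            expect_val, expect_ok, _ = oracle_step2_center(window, valid)
            assert v[5, 5] == expect_ok
            if expect_ok:
                assert grid[5, 5] == pytest.approx(expect_val, abs=1e-12)


class TestStep3:
    def test_constant_fill(self):
        grid, filled, valid = step1_embed(np.full((6, 6), 2.25))
        grid, filled, valid, _, _ = step2_fill_diagonal_centers(grid, filled, valid)
        grid, filled, valid, _, _ = step3_fill_axial(grid, filled, valid)
        assert filled.all() and valid.all()
        np.testing.assert_allclose(grid, 2.25, atol=1e-12)

    def test_vertical_step_edge_selects_vertical_on_edge_columns(self):
        src = np.zeros((10, 10))
        src[:, 5:] = 100.0
        grid, filled, valid = step1_embed(src)
        grid, filled, valid, _, _ = step2_fill_diagonal_centers(grid, filled, valid)
        _, _, _, direction, _ = step3_fill_axial(grid, filled, valid)
        # step-3 pixels on the edge's own columns (9, 10 in the 2x grid)
        dcol = direction[4:16, 9:11]
        sel = dcol[(dcol == int(DirectionLabel.VERTICAL)) | (dcol == int(DirectionLabel.HORIZONTAL))]
        assert (sel == int(DirectionLabel.VERTICAL)).all()
        assert sel.size > 0

    def test_masked_neighbor_renormalizes(self):
        """Axial stencil with the far (-3) neighbor masked, survivors all
        800 ps -> renormalized value is exactly 800."""
        from flimupscale.epim import _axial_estimate

        lattice = np.full((1, 8), 800.0)
        mask = np.ones((1, 8), bool)
        mask[0, 2] = False
        idx = np.array([[2, 3, 4, 5]])  # one target: offsets -3,-1,+1,+3
        val, ok = _axial_estimate(lattice, mask, idx, 1, 0.5)
        assert ok[0, 0]
        assert val[0, 0] == pytest.approx(800.0, abs=1e-12)
        # brute force renormalization: (9+9-1)/16 mass, value unchanged
        w = np.array([-1, 9, 9, -1]) / 16.0
        assert val[0, 0] == pytest.approx(800.0 * w[1:].sum() / w[1:].sum(), abs=1e-12)


class TestPipeline:
    def test_shapes_and_step1_exactness(self):
        rng = np.random.default_rng(5)
        inten = rng.uniform(0, 200, (16, 16))
        tau = rng.uniform(700, 1400, (16, 16))
        frame = make_frame(inten, tau)
        ires, lres = epim_upscale(frame, 2)
        assert ires.shape == lres.shape == (32, 32)
        assert np.array_equal(ires.values[::2, ::2], inten)
        assert np.array_equal(lres.values[::2, ::2], tau)

    def test_factor4_shape(self):
        frame = make_frame(np.full((8, 8), 3.0), np.full((8, 8), 1000.0))
        ires, lres = epim_upscale(frame, 4)
        assert ires.shape == (32, 32)
        np.testing.assert_allclose(ires.values, 3.0, atol=1e-12)
        np.testing.assert_allclose(lres.values[lres.valid], 1000.0, atol=1e-12)

    def test_masked_lifetime_values_never_influence_output(self):
        rng = np.random.default_rng(9)
        valid = rng.random((12, 12)) > 0.35
        tau = np.where(valid, rng.uniform(700, 1400, (12, 12)), 0.0)
        inten = rng.uniform(0, 100, (12, 12))
        f1 = make_frame(inten, tau, valid)
        _, l1 = epim_upscale(f1, 2)
        # randomize every masked entry; outputs must be bit-identical
        f2 = make_frame(inten, np.where(valid, tau, rng.uniform(1, 9e5, (12, 12))), valid)
        f2.lifetime.values = np.where(valid, tau, rng.uniform(-1e6, 1e6, (12, 12)))
        _, l2 = epim_upscale(f2, 2)
        assert np.array_equal(l1.values, l2.values)
        assert np.array_equal(l1.valid, l2.valid)

    def test_fully_masked_lifetime_gives_invalid_output(self):
        frame = make_frame(np.full((8, 8), 50.0), np.zeros((8, 8)),
                           np.zeros((8, 8), bool))
        ires, lres = epim_upscale(frame, 2)
        assert not lres.valid.any()
        np.testing.assert_allclose(ires.values, 50.0, atol=1e-12)

    @pytest.mark.parametrize("orientation", ["vertical", "horizontal", "diag_main", "diag_anti"])
    def test_edge_sharper_than_bicubic(self, orientation):
        """On an ideal step edge of any candidate orientation, the maximum
        cross-edge finite difference of the EPIM output is at least that of
        plain bicubic interpolation."""
        n = 16
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        img = {
            "vertical": (cc >= n // 2),
            "horizontal": (rr >= n // 2),
            "diag_main": (cc > rr),
            "diag_anti": (rr + cc >= n),
        }[orientation] * 100.0
        frame = make_frame(img, np.full((n, n), 1000.0))
        ires, _ = epim_upscale(frame, 2)
        bres = bicubic_upscale(img, 2)

        def max_step(a):
            return max(np.abs(np.diff(a, axis=0)).max(), np.abs(np.diff(a, axis=1)).max())

        assert max_step(ires.values) >= max_step(bres.values)

    def test_no_lifetime_invention_with_nonnegative_weights(self):
        """Where every surviving stencil weight is nonnegative, output
        lifetimes stay inside the global [min, max] of valid inputs; the
        negative lobes can overshoot by at most 1/8 of the local range."""
        rng = np.random.default_rng(13)
        tau = rng.uniform(700, 1400, (16, 16))
        frame = make_frame(np.full((16, 16), 100.0), tau)
        _, lres = epim_upscale(frame, 2)
        lo, hi = tau.min(), tau.max()
        bound = (hi - lo) / 8.0 + 1e-9
        out = lres.values[lres.valid]
        assert out.min() >= lo - bound
        assert out.max() <= hi + bound

    def test_gradient_contrast_range_and_coverage(self):
        rng = np.random.default_rng(21)
        frame = make_frame(rng.uniform(0, 200, (12, 12)), np.full((12, 12), 900.0))
        ires, _ = epim_upscale(frame, 2)
        g = ires.gradient_contrast
        assert g.shape == (24, 24)
        assert (g >= 0).all() and (g <= 1).all()
        assert g.max() > 0  # random image has anisotropy somewhere

    def test_too_small_image_rejected(self):
        frame = make_frame(np.ones((3, 3)), np.ones((3, 3)) * 900)
        with pytest.raises(ValueError):
            epim_upscale(frame, 2)
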