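"""ASAM attention, grid/ungrid re-layout, and the gated axial MLP."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dhmfmlp.dsla import (ASAM, AxialMLP, DSLA, GridBlocks, channel_pool,
                          effective_grid_size, grid, ungrid)
from dhmfmlp.nn.engine import Tensor

from oracles import axial_mlp_loop, channel_pool_loop


class TestChannelPool:
    def test_constant_input_gives_constant_map(self):
        x = np.full((1, 3, 4, 4), 2.5)
        for mode in ("avg", "max"):
            np.testing.assert_allclose(channel_pool(x, mode).data,
                                       np.full((1, 1, 4, 4), 2.5))

    def test_two_channel_definition(self):
        x = np.zeros((1, 2, 1, 1))
        x[0, 0], x[0, 1] = 3.0, -1.0
        assert channel_pool(x, "avg").item() == 1.0
        assert channel_pool(x, "max").item() == 3.0

    def test_matches_per_pixel_loop_oracle(self, rng):
        x = rng.normal(size=(1, 3, 4, 4))
        for mode in ("avg", "max"):
            np.testing.assert_allclose(channel_pool(x, mode).data,
                                       channel_pool_loop(x, mode), rtol=1e-12)


class TestASAM:
    def test_zero_input_annihilates_output(self):
        asam = ASAM()
        out = asam(np.zeros((1, 4, 6, 6)))
        np.testing.assert_array_equal(out.data, 0)

    def test_unit_input_gives_logistic_of_one(self):
        # mu*1 + (1-mu)*1 = 1 for any mu, so w = logistic(1) ~ 0.73106
        asam = ASAM()
        asam.mu_pre.data[...] = 0.7  # arbitrary mu
        out = asam(np.ones((1, 3, 2, 2)))
        np.testing.assert_allclose(out.data, 1 / (1 + np.exp(-1.0)), rtol=1e-6)

    def test_extreme_mu_selects_max_pool(self, rng):
        asam = ASAM()
        asam.mu_pre.data[...] = -40.0  # mu -> 0: only the channel max matters
        x = rng.normal(size=(1, 5, 3, 3))
        w = asam.attention(x).data
        expected = 1 / (1 + np.exp(-np.maximum(x.max(axis=1, keepdims=True), 0)))
        np.testing.assert_allclose(w, expected, rtol=1e-5)

    def test_attention_range_invariant(self, rng):
        # >= 1e4 random pixels: every weight in [0.5, 1) because the logistic
        # argument is ReLU-rectified, and |out| <= |input| elementwise.
        asam = ASAM()
        asam.mu_pre.data[...] = rng.normal()
        x = rng.normal(size=(4, 8, 64, 64))
        w = asam.attention(x).data
        assert w.size >= 10_000
        assert (w >= 0.5).all() and (w < 1.0).all()
        assert (np.abs(asam(x).data) <= np.abs(x)).all()

    def test_mu_constrained_to_unit_interval(self):
        asam = ASAM()
        for pre in (-50.0, 0.0, 50.0):
            asam.mu_pre.data[...] = pre
            assert 0.0 < asam.mu < 1.0
        assert ASAM(learnable=False).mu == 0.5

    def test_fixed_mu_has_no_parameters(self):
        assert len(list(ASAM(learnable=False).parameters())) == 0
        assert len(list(ASAM(learnable=True).parameters())) == 1


class TestGrid:
    def test_exhaustive_4x4_d2_mapping(self):
        x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        g = grid(x, d=2)
        assert g.values.shape == (1, 1, 4, 4)  # 4 tiles x 4 offsets
        for y in range(4):
            for xx in range(4):
                tile = 2 * (y // 2) + (xx // 2)
                offset = 2 * (y % 2) + (xx % 2)
                assert g.values.data[0, 0, tile, offset] == x[0, 0, y, xx]

    def test_single_pixel_tiles_when_d_equals_size(self, rng):
        x = rng.normal(size=(1, 2, 3, 3))
        g = grid(x, d=3)
        assert g.values.shape == (1, 2, 9, 1)
        np.testing.assert_array_equal(ungrid(g).data, x)

    def test_indivisible_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            grid(np.zeros((1, 1, 6, 6)), d=4)

    def test_inconsistent_metadata_rejected(self, rng):
        g = grid(rng.normal(size=(1, 1, 4, 4)), d=2)
        bad = GridBlocks(g.values, grid_size=4, height=4, width=4)
        with pytest.raises(ValueError, match="inconsistent"):
            ungrid(bad)

    @given(st.data())
    def test_round_trip_is_bit_exact(self, data):
        d = data.draw(st.sampled_from([1, 2, 4, 8]))
        th = data.draw(st.integers(1, 3))
        tw = data.draw(st.integers(1, 3))
        b = data.draw(st.integers(1, 2))
        c = data.draw(st.integers(1, 3))
        rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 16)))
        x = rng.normal(size=(b, c, d * th, d * tw))
        assert (ungrid(grid(x, d)).data == x).all()


class TestAxialMLP:
    def test_zeroed_projection_is_exact_identity(self, rng):
        mlp = AxialMLP(4, rng, d=4)
        mlp.project.weight.data[...] = 0
        mlp.project.bias.data[...] = 0
        x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        assert np.max(np.abs(mlp(x).data - x)) == 0.0

    def test_shape_closed(self, rng):
        mlp = AxialMLP(32, rng, d=8)
        assert mlp(rng.normal(size=(2, 32, 16, 16)).astype(np.float32)
                   ).shape == (2, 32, 16, 16)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_straight_line_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mlp = AxialMLP(2, rng, d=8)
        x = rng.normal(size=(1, 2, 8, 8))
        params = {
            "ln_g": mlp.norm.weight.data.astype(np.float64),
            "ln_b": mlp.norm.bias.data.astype(np.float64),
            "w1": mlp.expand.weight.data.astype(np.float64),
            "b1": mlp.expand.bias.data.astype(np.float64),
            "wg": mlp.tile_mix.weight.data.astype(np.float64),
            "bg": mlp.tile_mix.bias.data.astype(np.float64),
            "w2": mlp.project.weight.data.astype(np.float64),
            "b2": mlp.project.bias.data.astype(np.float64),
        }
        expected = axial_mlp_loop(x, params, d=8)
        np.testing.assert_allclose(mlp(x).data, expected, rtol=1e-5, atol=1e-7)


class TestDSLA:
    def test_no_asam_reduces_to_axial_mlp(self, rng):
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        block = DSLA(8, np.random.default_rng(3), d=4, use_asam=False)
        ref = AxialMLP(8, np.random.default_rng(3), d=4)
        ref.load_state_dict(block.axial.state_dict())
        np.testing.assert_array_equal(block(x).data, ref(x).data)

    def test_no_axial_reduces_to_asam(self, rng):
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        block = DSLA(8, rng, use_axial=False)
        ref = ASAM()
        np.testing.assert_array_equal(block(x).data, ref(x).data)

    def test_full_composition_is_serial_asam_then_axial(self, rng):
        x = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
        block = DSLA(8, np.random.default_rng(7), d=4)
        manual = block.axial(block.asam(x))
        np.testing.assert_array_equal(block(x).data, manual.data)
        assert np.isfinite(block(x).data).all()

    def test_both_branches_disabled_is_identity(self, rng, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="dhmfmlp.dsla"):
            block = DSLA(8, rng, use_asam=False, use_axial=False)
        assert "identity" in caplog.text
        x = rng.normal(size=(1, 8, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(block(x).data, x)


def test_effective_grid_size_degrades_with_resolution():
    assert effective_grid_size(128, 128) == 8
    assert effective_grid_size(4, 4) == 4
    assert effective_grid_size(2, 2) == 2
    assert effective_grid_size(1, 1) == 1
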