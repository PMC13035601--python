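"""Shift-grid enumeration and split-attention fusion vs explicit-loop oracle."""

import numpy as np
import pytest

from symfenet.blocks import SymFEConfig, SymFEBlock
from symfenet.fusion import (MultiSymFE, ShiftGrid, attention_weights,
                             enumerate_shift_grid, global_avg_pool,
                             grid_by_name, multisymfe_forward,
                             split_attention_fuse)
from symfenet.geometry import ShiftParam, flip_lr


class TestShiftGridEnumeration:
    @pytest.mark.parametrize("max_offset,count", [
        (8, 33), (6, 25), (4, 17), (2, 9), (0, 1),
    ])
    def test_ablation_family_counts(self, max_offset, count):
        grid = enumerate_shift_grid(max_offset, step=2)
        assert len(grid) == count

    def test_grid_contents_full_model(self):
        grid = enumerate_shift_grid(8, step=2)
        tuples = {s.astuple() for s in grid}
        assert (0, 0, 0) in tuples
        for k in (2, 4, 6, 8):
            assert (k, 0, 0) in tuples and (-k, 0, 0) in tuples
            assert (0, k, 0) in tuples and (0, -k, 0) in tuples
            for sw in (k, -k):
                for sh in (k, -k):
                    assert (sw, sh, 0) in tuples
        assert all(s.s_d == 0 for s in grid)

    def test_zero_shift_first_and_unique(self):
        for name in ("33", "25", "17", "9", "1"):
            grid = grid_by_name(name)
            assert grid.shifts[0].astuple() == (0, 0, 0)
            assert len({s.astuple() for s in grid}) == len(grid)

    def test_axis_families_switchable(self):
        only_w = enumerate_shift_grid(4, step=2, include_axis_h=False,
                                      include_diagonals=False)
        assert len(only_w) == 5
        with_z = enumerate_shift_grid(2, step=2, include_axis_d=True)
        assert (0, 0, 2) in {s.astuple() for s in with_z}
        assert len(with_z) == 11

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            enumerate_shift_grid(3, step=2)
        with pytest.raises(ValueError):
            enumerate_shift_grid(4, step=0)
        with pytest.raises(ValueError):
            ShiftGrid((ShiftParam(2, 0, 0),))  # missing zero shift


class TestAttentionPrimitives:
    def test_global_avg_pool_examples(self):
        f = np.full((3, 2, 2, 4), 7.5)
        assert np.allclose(global_avg_pool(f), 7.5)
        vals = np.array([1.0, 2.0, 3.0, 4.0]).reshape(2, 2, 1, 1)
        assert global_avg_pool(vals)[0] == pytest.approx(2.5)
        assert np.all(global_avg_pool(np.zeros((2, 2, 2, 3))) == 0.0)

    def test_sigmoid_values_and_monotonicity(self):
        assert attention_weights(np.zeros((2, 3))) == pytest.approx(0.5)
        assert attention_weights(np.log(3.0)) == pytest.approx(0.75)
        s = np.linspace(-5, 5, 11)
        a = attention_weights(s)
        assert np.all(np.diff(a) > 0)
        assert np.all((a > 0) & (a < 1))

    def test_saturation_never_nan(self):
        a = attention_weights(np.array([-1e6, 1e6]))
        assert np.all(np.isfinite(a))


def oracle_fuse(features):
    """Explicit-loop implementation of pooling, sigmoid, weighted sum."""
    I = len(features)
    w, h, d, k = features[0].shape
    out = np.zeros((w, h, d, k))
    for c in range(k):
        for i in range(I):
            s = 0.0
            for x in range(w):
                for y in range(h):
                    for z in range(d):
                        s += features[i][x, y, z, c]
            s /= w * h * d
            a = 1.0 / (1.0 + np.exp(-s))
            out[..., c] += a * features[i][..., c]
    return out


class TestSplitAttentionFuse:
    def test_single_zero_volume(self):
        f = np.zeros((4, 4, 2, 3))
        assert np.all(split_attention_fuse([f]) == 0.0)

    def test_single_constant_volume(self):
        c = 1.7
        f = np.full((4, 4, 2, 1), c)
        out = split_attention_fuse([f])
        expected = c / (1.0 + np.exp(-c))
        assert out == pytest.approx(expected, rel=1e-6)

    def test_two_identical_volumes_double(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((4, 4, 2, 3)).astype(np.float32)
        out = split_attention_fuse([f, f])
        s = f.mean(axis=(0, 1, 2))
        expected = 2.0 / (1.0 + np.exp(-s)) * f
        assert np.allclose(out, expected, rtol=1e-5)

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(1)
        feats = [rng.standard_normal((4, 4, 2, 3)).astype(np.float32)
                 for _ in range(5)]
        got = split_attention_fuse(feats)
        want = oracle_fuse(feats)
        assert np.allclose(got, want, rtol=1e-5, atol=1e-6)

    def test_boundedness(self):
        rng = np.random.default_rng(2)
        m = 3.0
        feats = [rng.uniform(-m, m, (4, 2, 2, 2)) for _ in range(7)]
        out = split_attention_fuse(feats)
        assert np.all(np.abs(out) <= 7 * m)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            split_attention_fuse([np.zeros((4, 4, 2)), np.zeros((4, 4, 2))])


class TestMultiSymFE:
    def make_module(self, c_in=1, grid="9", kernels=2, seed=0, **kw):
        return MultiSymFE(c_in, grid_by_name(grid), kernels,
                          np.random.default_rng(seed), dropout_p=0.1, **kw)

    def test_degenerate_grid_reduces_to_scaled_block(self):
        mod = self.make_module(grid="1", kernels=3, seed=1)
        v = np.random.default_rng(3).standard_normal((8, 8, 4, 1)).astype(np.float32)
        out = multisymfe_forward(v, mod)
        f = mod.blocks[0].forward(v[None])[0]
        s = f.mean(axis=(0, 1, 2))
        expected = (1.0 / (1.0 + np.exp(-s))) * f
        assert np.allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_shape_contract_grid33(self):
        mod = self.make_module(grid="33", kernels=8, seed=2)
        v = np.zeros((16, 16, 8, 1), dtype=np.float32)
        assert multisymfe_forward(v, mod).shape == (16, 16, 8, 8)

    def test_eval_equals_brute_force_reference(self):
        # materialize all I=9 block outputs and fuse them with the
        # explicit-loop oracle; the module must agree to 1e-5 relative
        mod = self.make_module(grid="9", kernels=2, seed=4)
        v = np.random.default_rng(5).standard_normal((8, 8, 4, 1)).astype(np.float32)
        feats = [b.forward(v[None])[0] for b in mod.blocks]
        want = oracle_fuse(feats)
        got = multisymfe_forward(v, mod)
        assert np.allclose(got, want, rtol=1e-5, atol=1e-6)

    def test_mirror_symmetry_preserved(self):
        mod = self.make_module(grid="9", kernels=3, seed=6)
        v = np.random.default_rng(7).standard_normal((12, 8, 4, 1)).astype(np.float32)
        out = multisymfe_forward(v, mod)
        assert np.array_equal(out, flip_lr(out))

    def test_shared_weights_mode(self):
        mod = self.make_module(grid="9", kernels=2, seed=8, share_weights=True)
        assert all(b.params is mod.blocks[0].params for b in mod.blocks)
        assert len(dict(mod.named_params())) == 2  # one W, one b

    def test_gradient_matches_finite_differences(self):
        mod = self.make_module(grid="9", kernels=2, seed=9)
        rng = np.random.default_rng(10)
        v = rng.standard_normal((1, 8, 4, 4, 1)).astype(np.float32)
        g = rng.standard_normal((1, 8, 4, 4, 2)).astype(np.float32)
        mod.forward(v)
        dx = mod.backward(g)
        eps = 1e-3
        for idx in [(0, 0, 0, 0, 0), (0, 4, 2, 1, 0), (0, 7, 3, 3, 0)]:
            vp, vm = v.copy(), v.copy()
            vp[idx] += eps
            vm[idx] -= eps
            fd = ((mod.forward(vp) * g).sum()
                  - (mod.forward(vm) * g).sum()) / (2 * eps)
            assert dx[idx] == pytest.approx(float(fd), rel=2e-2, abs=2e-3)
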