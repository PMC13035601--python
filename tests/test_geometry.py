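"""Geometry operators vs a brute-force voxel-correspondence oracle."""

import numpy as np
import pytest

from symfenet.geometry import (LRFusionVolume, ShiftParam, flip_lr,
                               make_lr_fusion, mirror_index, split_lr,
                               shift3d, unfold_output, unfold_backward)


def oracle_fusion(v, s, fill=0.0):
    """Triple-loop reference: explicit index arithmetic, no vectorization.

    Channel c of the fusion holds v[x]; channel C+c holds the mirrored,
    shifted partner v[W-1-(x - s_w), y - s_h, z - s_d] (fill outside).
    """
    w, h, d, c = v.shape
    w2 = w // 2
    out = np.full((w2, h, d, 2 * c), fill, dtype=v.dtype)
    for x in range(w2):
        for y in range(h):
            for z in range(d):
                for ch in range(c):
                    out[x, y, z, ch] = v[x, y, z, ch]
                    sx, sy, sz = x - s.s_w, y - s.s_h, z - s.s_d
                    if 0 <= sx < w2 and 0 <= sy < h and 0 <= sz < d:
                        # flipped second half at sx carries the voxel at the
                        # mirror index w-1-sx of the full volume
                        out[x, y, z, c + ch] = v[mirror_index(sx, w), sy, sz, ch]
    return out


def profile_volume(values):
    """A (W,1,1,1) volume from a 1-D intensity profile along x."""
    return np.asarray(values, dtype=np.float32).reshape(-1, 1, 1, 1)


class TestMirrorIndex:
    def test_endpoints_and_innermost_pair(self):
        assert mirror_index(0, 144) == 143
        assert mirror_index(71, 144) == 72

    def test_involution(self):
        for w in (2, 4, 144):
            for x in range(w):
                assert mirror_index(mirror_index(x, w), w) == x

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            mirror_index(144, 144)
        with pytest.raises(IndexError):
            mirror_index(-1, 10)


class TestSplitFlip:
    def test_split_definition_and_round_trip(self):
        v = profile_volume([1.0, 2.0, 3.0, 4.0])
        a, b = split_lr(v)
        assert np.array_equal(a.ravel(), [1, 2])
        assert np.array_equal(b.ravel(), [3, 4])
        rng = np.random.default_rng(0)
        v = rng.standard_normal((8, 4, 4, 2)).astype(np.float32)
        a, b = split_lr(v)
        assert np.array_equal(np.concatenate([a, b], axis=0), v)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            split_lr(np.zeros((5, 4, 4, 1)))

    def test_flip_definition_involution_fixed_point(self):
        v = profile_volume([1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(flip_lr(v).ravel(), [4, 3, 2, 1])
        rng = np.random.default_rng(1)
        v = rng.standard_normal((6, 3, 5, 2)).astype(np.float32)
        assert np.array_equal(flip_lr(flip_lr(v)), v)
        sym = v + flip_lr(v)
        assert np.array_equal(flip_lr(sym), sym)


class TestShift3D:
    def test_zero_shift_is_identity(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((6, 5, 4, 2)).astype(np.float32)
        assert np.array_equal(shift3d(v, ShiftParam(0, 0, 0)), v)

    @pytest.mark.parametrize("s_w,expected", [
        (+1, [0, 1, 2, 3]),
        (-1, [2, 3, 4, 0]),
    ])
    def test_sign_convention_with_zero_fill(self, s_w, expected):
        v = profile_volume([1.0, 2.0, 3.0, 4.0])
        out = shift3d(v, ShiftParam(s_w, 0, 0))
        assert np.array_equal(out.ravel(), expected)

    def test_fill_count_matches_vacated_slab(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(1.0, 2.0, size=(8, 6, 4, 2)).astype(np.float32)
        for s in [ShiftParam(2, 0, 0), ShiftParam(0, -3, 0),
                  ShiftParam(1, 2, -1)]:
            out = shift3d(v, s)
            w, h, d, c = v.shape
            kept = ((w - abs(s.s_w)) * (h - abs(s.s_h)) * (d - abs(s.s_d))) * c
            assert int((out == 0).sum()) == v.size - kept

    def test_oversized_shift_rejected(self):
        with pytest.raises(ValueError):
            shift3d(np.zeros((8, 4, 4, 1)), ShiftParam(8, 0, 0))
        with pytest.raises(ValueError):
            shift3d(np.zeros((8, 4, 4, 1)), ShiftParam(0, 0, -4))
        # in the fusion context the bound is the *half* width
        with pytest.raises(ValueError):
            make_lr_fusion(np.zeros((8, 4, 4, 1)), ShiftParam(4, 0, 0))


class TestMakeLRFusion:
    def test_profile_zero_shift(self):
        v = profile_volume([1.0, 2.0, 3.0, 4.0])
        f = make_lr_fusion(v).data
        assert f.shape == (2, 1, 1, 2)
        assert np.array_equal(f[..., 0].ravel(), [1, 2])
        assert np.array_equal(f[..., 1].ravel(), [4, 3])

    def test_profile_shift_plus_one(self):
        v = profile_volume([1.0, 2.0, 3.0, 4.0])
        f = make_lr_fusion(v, ShiftParam(1, 0, 0)).data
        assert np.array_equal(f[..., 1].ravel(), [0, 4])

    def test_alignment_property_zero_shift(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal((10, 5, 4, 3)).astype(np.float32)
        f = make_lr_fusion(v).data
        w, _, _, c = v.shape
        for x in range(w // 2):
            assert np.array_equal(f[x, :, :, :c], v[x])
            assert np.array_equal(f[x, :, :, c:], v[w - 1 - x])

    def test_matches_brute_force_oracle_exhaustively(self):
        rng = np.random.default_rng(5)
        for shape in [(4, 3, 2, 1), (8, 4, 3, 2), (16, 8, 8, 3)]:
            v = rng.standard_normal(shape).astype(np.float32)
            for sw in (-2, -1, 0, 1, 2):
                for sh in (-2, 0, 2):
                    s = ShiftParam(sw, sh, 0)
                    if abs(sw) >= shape[0] // 2 or abs(sh) >= shape[1]:
                        continue
                    got = make_lr_fusion(v, s).data
                    assert np.array_equal(got, oracle_fusion(v, s)), \
                        f"fusion mismatch at shape={shape} shift={s.astuple()}"

    def test_shape_and_channel_contract(self):
        v = np.zeros((12, 6, 4, 3), dtype=np.float32)
        f = make_lr_fusion(v)
        assert isinstance(f, LRFusionVolume)
        assert f.data.shape == (6, 6, 4, 6)


class TestUnfoldOutput:
    def test_profile_example(self):
        f = profile_volume([5.0, 7.0])
        out = unfold_output(f)
        assert np.array_equal(out.ravel(), [5, 7, 7, 5])

    def test_mirror_symmetry_and_width(self):
        rng = np.random.default_rng(6)
        f = rng.standard_normal((72, 14, 8, 4)).astype(np.float32)
        out = unfold_output(f)
        assert out.shape == (144, 14, 8, 4)
        assert np.array_equal(out, flip_lr(out))
        assert np.array_equal(out[:72], f)

    def test_round_trip_with_fusion(self):
        rng = np.random.default_rng(7)
        v = rng.standard_normal((8, 4, 4, 2)).astype(np.float32)
        fused = make_lr_fusion(v).data
        retained = unfold_output(fused[..., :2])[:4]
        assert np.array_equal(retained, v[:4])

    def test_backward_is_adjoint(self):
        # <unfold(f), g> == <f, unfold_backward(g)> for random f, g
        rng = np.random.default_rng(8)
        f = rng.standard_normal((4, 3, 2, 2))
        g = rng.standard_normal((8, 3, 2, 2))
        lhs = float((unfold_output(f) * g).sum())
        rhs = float((f * unfold_backward(g)).sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)
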