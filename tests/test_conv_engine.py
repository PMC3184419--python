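"""Convolution primitives against brute-force oracles; validity accounting."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from denoise4d.conv_engine import (CertaintyMask, Volume4D, default_modes,
                                   fft_filter, fft_filter_pair,
                                   nonseparable_conv, normalized_conv,
                                   plan_valid_slices, separable_conv)


def circ_conv_oracle(v: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Brute-force circular convolution by shifted accumulation."""
    out = np.zeros_like(v, dtype=float)
    centre = [(s - 1) // 2 for s in k.shape]
    for idx in np.ndindex(k.shape):
        shift = [i - c for i, c in zip(idx, centre)]
        out += k[idx] * np.roll(v, shift, axis=range(v.ndim))
    return out


class TestSeparableConv:
    def test_identity_kernels_leave_volume_unchanged(self, rng):
        vol = Volume4D(rng.standard_normal((6, 6, 6, 3)))
        out = separable_conv(vol, [[1.0]] * 4, ("circular",) * 4)
        assert np.array_equal(out.values, vol.values)
        assert out.valid == vol.valid

    def test_unit_sum_kernel_preserves_constants(self):
        vol = Volume4D(np.full((8, 8, 8, 4), 2.5))
        k = [np.array([1, 2, 1]) / 4.0] * 4
        out = separable_conv(vol, k, default_modes(True))
        sl = out.valid_slices()
        assert np.allclose(out.values[sl], 2.5)

    def test_matches_outer_product_brute_force(self, rng):
        v = rng.standard_normal((8, 8, 8, 4))
        k1 = [rng.standard_normal(3) for _ in range(4)]
        outer = k1[0][:, None, None, None] * k1[1][None, :, None, None] \
            * k1[2][None, None, :, None] * k1[3][None, None, None, :]
        sep = separable_conv(Volume4D(v), k1, ("circular",) * 4)
        assert np.abs(sep.values - circ_conv_oracle(v, outer)).max() < 1e-10

    def test_valid_interval_shrinks_on_valid_axes(self, rng):
        vol = Volume4D(rng.standard_normal((8, 8, 8, 4)))
        out = separable_conv(vol, [[1.0], [1.0], np.ones(5) / 5, [1.0]],
                             default_modes(True))
        assert out.valid[2] == (2, 6)
        assert out.valid[3] == (0, 4)

    def test_kernel_longer_than_valid_axis_rejected(self, rng):
        vol = Volume4D(rng.standard_normal((8, 8, 4, 4)))
        with pytest.raises(ValueError):
            separable_conv(vol, [[1.0], [1.0], np.ones(5) / 5, [1.0]],
                           ("circular", "circular", "valid", "circular"))

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(7)
        v1 = rng.standard_normal((6, 6, 6, 3))
        v2 = rng.standard_normal((6, 6, 6, 3))
        k = [np.array([1.0, 2.0, 1.0]) / 4] * 4
        modes = ("circular",) * 4
        lhs = separable_conv(Volume4D(a * v1 + b * v2), k, modes).values
        rhs = a * separable_conv(Volume4D(v1), k, modes).values \
            + b * separable_conv(Volume4D(v2), k, modes).values
        assert np.abs(lhs - rhs).max() < 1e-9


class TestNonseparableConv:
    def test_delta_kernel_is_identity(self, rng):
        v = rng.standard_normal((7, 7, 7, 3))
        k = np.zeros((3, 3, 3, 3))
        k[1, 1, 1, 1] = 1.0
        out = nonseparable_conv(Volume4D(v), k, ("circular",) * 4)
        assert np.abs(out.values - v).max() < 1e-12

    def test_impulse_reproduces_kernel(self, rng):
        # convolution of a centred impulse copies the kernel at the impulse
        v = np.zeros((9, 9, 9, 5))
        v[4, 4, 4, 2] = 1.0
        k = rng.standard_normal((3, 3, 3, 3))
        out = nonseparable_conv(Volume4D(v), k, ("circular",) * 4)
        assert np.abs(out.values[3:6, 3:6, 3:6, 1:4] - k).max() < 1e-12

    def test_matches_brute_force_with_mixed_modes(self, rng):
        v = rng.standard_normal((8, 8, 8, 4))
        k = rng.standard_normal((3, 3, 3, 3))
        out = nonseparable_conv(Volume4D(v), k, default_modes(True))
        vp = np.pad(v, ((1, 1), (1, 1), (0, 0), (1, 1)), mode="wrap")
        vp = np.pad(vp, ((0, 0), (0, 0), (1, 1), (0, 0)))
        oracle = np.zeros((8, 8, 8, 4))
        for idx in np.ndindex(k.shape):
            sl = tuple(slice(2 - i, 2 - i + n)
                       for i, n in zip(idx, (8, 8, 8, 4)))
            oracle += k[idx] * vp[sl]
        assert np.abs(out.values - oracle).max() < 1e-9

    def test_monomial_kernel_matches_quadruple_loop_oracle(self, rng):
        from denoise4d.filter_bank import build_monomial_bank

        kern = build_monomial_bank(4).kernels[5]  # an order-2 kernel, 7^4
        v = rng.standard_normal((12, 12, 12, 12))
        out = nonseparable_conv(Volume4D(v), kern, ("circular",) * 4)
        oracle = circ_conv_oracle(v, kern.values)
        assert np.abs(out.values - oracle).max() < 1e-9

    def test_even_kernel_support_rejected(self, rng):
        with pytest.raises(ValueError):
            nonseparable_conv(Volume4D(np.zeros((6, 6, 6, 3))),
                              np.ones((2, 3, 3, 3)), ("circular",) * 4)

    def test_agrees_with_separable_on_outer_product(self, rng):
        v = rng.standard_normal((8, 8, 8, 4))
        ks = [rng.standard_normal(3) for _ in range(4)]
        outer = ks[0][:, None, None, None] * ks[1][None, :, None, None] \
            * ks[2][None, None, :, None] * ks[3][None, None, None, :]
        modes = default_modes(True)
        a = separable_conv(Volume4D(v), ks, modes)
        b = nonseparable_conv(Volume4D(v), outer, modes)
        assert np.abs(a.values - b.values).max() < 1e-9
        assert a.valid == b.valid


class TestFFTFilter:
    def test_allpass_response_returns_input(self, rng):
        v = rng.standard_normal((8, 8, 6, 4))
        out = fft_filter(Volume4D(v), response=np.ones((8, 8, 6, 4)))
        assert np.abs(out.values - v).max() < 1e-12

    def test_spatial_kernel_path_matches_circular_oracle(self, rng):
        v = rng.standard_normal((8, 8, 8, 4))
        k = rng.standard_normal((3, 5, 3, 3))
        out = fft_filter(Volume4D(v), kernel=k)
        assert np.abs(out.values - circ_conv_oracle(v, k)).max() < 1e-9

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fft_filter(Volume4D(np.zeros((6, 6, 6, 3))),
                       response=np.ones((6, 6, 6, 4)))

    def test_packed_pair_filtering_recovers_both_responses(self, rng):
        # two kernels in one complex pass: real/imaginary parts separate
        v = Volume4D(rng.standard_normal((8, 8, 8, 4)))
        ka = rng.standard_normal((3, 3, 3, 3))
        kb = rng.standard_normal((3, 3, 3, 3))
        ra, rb = fft_filter_pair(v, ka, kb)
        assert np.abs(ra.values - fft_filter(v, kernel=ka).values).max() < 1e-9
        assert np.abs(rb.values - fft_filter(v, kernel=kb).values).max() < 1e-9


class TestNormalizedConv:
    def test_full_certainty_equals_plain_convolution(self, rng):
        v = Volume4D(rng.standard_normal((8, 8, 8, 4)))
        cert = CertaintyMask(np.ones(v.shape))
        k = [np.array([1, 2, 1]) / 4.0] * 4
        modes = ("circular",) * 4
        nc, defined = normalized_conv(v, cert, k, modes)
        plain = separable_conv(v, k, modes)
        assert defined.all()
        assert np.abs(nc.values - plain.values).max() < 1e-12

    def test_constant_signal_preserved_under_partial_certainty(self, rng):
        v = Volume4D(np.full((8, 8, 8, 4), 3.25))
        c = (rng.uniform(size=v.shape) > 0.3).astype(float)
        nc, defined = normalized_conv(v, CertaintyMask(c),
                                      [np.array([1, 2, 1]) / 4.0] * 4,
                                      ("circular",) * 4)
        assert np.allclose(nc.values[defined], 3.25)

    def test_hand_computed_border_value(self):
        # 1D toy embedded along x: s = [5,7,9], c = [1,1,0], f = [1,1,1]
        s = np.zeros((3, 1, 1, 1))
        s[:, 0, 0, 0] = [5.0, 7.0, 9.0]
        c = np.zeros((3, 1, 1, 1))
        c[:, 0, 0, 0] = [1.0, 1.0, 0.0]
        k = [np.ones(3), [1.0], [1.0], [1.0]]
        nc, _ = normalized_conv(Volume4D(s), CertaintyMask(c), k,
                                ("valid", "circular", "circular", "circular"))
        assert nc.values[1, 0, 0, 0] == pytest.approx(6.0)

    def test_all_zero_certainty_yields_all_invalid(self):
        v = Volume4D(np.ones((4, 4, 4, 2)))
        nc, defined = normalized_conv(v, CertaintyMask(np.zeros(v.shape)),
                                      [np.array([1, 2, 1]) / 4.0] * 4,
                                      ("circular",) * 4)
        assert not defined.any()
        assert np.all(nc.values == 0)

    def test_signed_kernel_rejected(self):
        v = Volume4D(np.ones((4, 4, 4, 2)))
        with pytest.raises(ValueError):
            normalized_conv(v, CertaintyMask(np.ones(v.shape)),
                            [np.array([-1, 2, -1])] + [[1.0]] * 3,
                            ("circular",) * 4)

    def test_single_hole_matches_direct_ratio(self, rng):
        v = Volume4D(rng.standard_normal((8, 8, 8, 4)))
        c = np.ones(v.shape)
        c[4, 4, 4, 2] = 0.0
        k = [np.array([1, 2, 1]) / 4.0] * 4
        modes = ("circular",) * 4
        nc, _ = normalized_conv(v, CertaintyMask(c), k, modes)
        num = separable_conv(Volume4D(c * v.values), k, modes).values
        den = separable_conv(Volume4D(c), k, modes).values
        assert np.abs(nc.values - num / den).max() < 1e-10


class TestValidSlicePlanning:
    def test_standard_convolution_chain_34_slices(self):
        # 34 slices: 32 after the 3x3x3 lowpass, 16 after downsampling,
        # 10 after monomial filtering, 6 and finally 2 after the two
        # tensor lowpass stages
        p = plan_valid_slices(34, use_normalized_conv=False)
        assert p.after_lowpass == 32
        assert p.after_downsample == 16
        assert p.after_monomial == 10
        assert p.after_tensor_lowpass == 6
        assert p.after_control_lowpass == 2

    def test_normalized_convolution_chain_51_slices(self):
        p = plan_valid_slices(51, use_normalized_conv=True)
        assert p.after_downsample == 26
        assert p.after_monomial == 20
        assert p.after_control_lowpass == 20
        assert p.output_slices == 39

    def test_fft_slab_sizes_downsample(self):
        p = plan_valid_slices(31, use_normalized_conv=True)
        assert p.after_downsample == 16
        assert p.after_monomial == 10

    def test_tiny_input_floors_at_zero(self):
        p = plan_valid_slices(7, use_normalized_conv=False)
        assert p.after_control_lowpass == 0
        assert p.output_slices == 0
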