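"""Filter-bank construction: radial profiles, ideal responses, kernels."""

import math

import numpy as np
import pytest

from denoise4d.filter_bank import (FrequencyGrid, RadialSpec,
                                   build_monomial_bank,
                                   build_reconstruction_bank,
                                   design_spatial_kernel, load_bank,
                                   lognormal_radial,
                                   monomial_frequency_response, monomial_pairs,
                                   quadrature_frequency_response,
                                   reconstruction_highpass_response,
                                   reconstruction_lowpass_response, save_bank,
                                   tensor_component_count)

U0 = 3 * math.pi / 5


class TestLognormalRadial:
    def test_unity_at_centre_frequency(self):
        assert lognormal_radial(U0, RadialSpec()) == pytest.approx(1.0)

    @pytest.mark.parametrize("bandwidth", [1.0, 2.0, 2.5, 4.0])
    def test_half_amplitude_half_bandwidth_away(self, bandwidth):
        # amplitude 1/2 at u0 * 2^(B/2) pins down the exponent constant
        spec = RadialSpec(u0=0.4, bandwidth=bandwidth)
        rho = spec.u0 * 2 ** (bandwidth / 2)
        assert lognormal_radial(rho, spec) == pytest.approx(0.5, abs=1e-12)

    def test_zero_at_dc_by_continuity(self):
        assert lognormal_radial(0.0, RadialSpec()) == 0.0

    def test_default_centre_frequency_and_bandwidth(self):
        spec = RadialSpec()
        assert spec.u0 == pytest.approx(3 * math.pi / 5)
        assert spec.bandwidth == 2.5

    def test_non_finite_rho_rejected(self):
        with pytest.raises(ValueError):
            lognormal_radial(np.nan, RadialSpec())

    def test_strictly_positive_off_dc(self):
        rho = np.linspace(1e-6, math.pi, 50)
        assert np.all(lognormal_radial(rho, RadialSpec()) > 0)


class TestFrequencyGrid:
    def test_dc_bin_is_zero(self):
        g = FrequencyGrid((8, 8, 8, 4))
        assert g.rho[0, 0, 0, 0] == 0.0
        for ax in range(4):
            assert g.unit(ax)[0, 0, 0, 0] == 0.0

    def test_coordinates_in_half_open_pi_interval(self):
        g = FrequencyGrid((8, 6))
        for c in g.coords:
            flat = np.ravel(c)
            assert flat.min() > -math.pi
            assert flat.max() <= math.pi

    def test_unit_vectors_have_unit_norm_off_dc(self):
        g = FrequencyGrid((6, 6, 6, 6))
        sq = sum(g.unit(ax) ** 2 for ax in range(4))
        mask = g.rho > 0
        assert np.allclose(sq[mask], 1.0)


class TestMonomialResponses:
    # grid of 10 samples puts u0 = 3*pi/5 exactly on bin 3
    def test_order2_diagonal_is_one_at_centre_frequency(self):
        g = FrequencyGrid((10, 10))
        r = monomial_frequency_response(2, (0, 0), g, RadialSpec())
        assert r[3, 0] == pytest.approx(1.0, abs=1e-12)

    def test_order1_zero_at_dc(self):
        g = FrequencyGrid((10, 10))
        r = monomial_frequency_response(1, (0,), g, RadialSpec())
        assert r[0, 0] == 0.0

    def test_order2_cross_term_vanishes_on_axis(self):
        g = FrequencyGrid((10, 10))
        r = monomial_frequency_response(2, (0, 1), g, RadialSpec())
        assert r[3, 0] == 0.0

    def test_order1_purely_imaginary_and_odd(self):
        # odd grid size: every bin has a distinct negation partner
        g = FrequencyGrid((9, 9))
        r = monomial_frequency_response(1, (1,), g, RadialSpec())
        assert np.abs(r.real).max() == 0.0
        # odd symmetry: r(-u) = -r(u) on the grid
        flipped = np.roll(r[::-1, ::-1], (1, 1), axis=(0, 1))
        assert np.abs(flipped + r).max() < 1e-12

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            monomial_frequency_response(3, (0, 0, 0), FrequencyGrid((8, 8)),
                                        RadialSpec())


class TestQuadratureResponse:
    def test_unity_along_direction_at_centre_frequency(self):
        g = FrequencyGrid((10, 10))
        r = quadrature_frequency_response((1.0, 0.0), g, RadialSpec())
        assert r[3, 0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_perpendicular_and_opposite(self):
        g = FrequencyGrid((10, 10))
        r = quadrature_frequency_response((1.0, 0.0), g, RadialSpec())
        assert r[0, 3] == 0.0   # perpendicular
        assert r[-3, 0] == 0.0  # opposite half-space

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            quadrature_frequency_response((0.0, 0.0), FrequencyGrid((8, 8)),
                                          RadialSpec())


class TestKernelDesign:
    def test_allpass_response_gives_identity_kernel(self):
        resp = np.ones((9, 9), dtype=complex)
        k = design_spatial_kernel(resp, 1, order=0, band="lowpass")
        assert k.values.shape == (1, 1)
        assert k.values[0, 0] == pytest.approx(1.0)

    def test_order1_kernel_exactly_antisymmetric(self):
        g = FrequencyGrid((24, 24))
        resp = monomial_frequency_response(1, (0,), g, RadialSpec())
        k = design_spatial_kernel(resp, 7, order=1, indices=(0,))
        assert np.array_equal(k.values, -k.values[::-1, ::-1])

    def test_even_support_rejected(self):
        with pytest.raises(ValueError):
            design_spatial_kernel(np.ones((8, 8), dtype=complex), 4, order=0)

    def test_windowed_design_residual_regression(self):
        # relative L2 error of the realized vs ideal 4D order-2 response,
        # measured once for the 7^4 monomial design and frozen
        import scipy.fft

        bank = build_monomial_bank(4)
        kern = next(k for k in bank if k.indices == (0, 0) and k.order == 2)
        n = 24
        g = FrequencyGrid((n,) * 4)
        ideal = monomial_frequency_response(2, (0, 0), g, RadialSpec())
        padded = np.zeros((n,) * 4)
        padded[tuple(slice(0, 7) for _ in range(4))] = kern.values
        padded = np.roll(padded, (-3,) * 4, axis=range(4))
        realized = scipy.fft.fftn(padded)
        err = np.linalg.norm(realized - ideal) / np.linalg.norm(ideal)
        assert err < 0.35  # frozen: 0.3183 measured for this design


class TestBanks:
    @pytest.mark.parametrize("dim,expected", [(2, 5), (3, 9), (4, 14)])
    def test_monomial_bank_counts(self, dim, expected):
        assert build_monomial_bank(dim).n_filters == expected

    @pytest.mark.parametrize("dim,expected", [(2, 4), (3, 7), (4, 11)])
    def test_reconstruction_bank_counts(self, dim, expected):
        assert build_reconstruction_bank(dim, support=7).n_filters == expected

    def test_unsupported_dim_rejected(self):
        with pytest.raises(ValueError):
            build_monomial_bank(5)
        with pytest.raises(ValueError):
            build_reconstruction_bank(1)

    def test_minimum_filter_count_matches_tensor_components(self):
        assert tensor_component_count(4) == 10
        assert tensor_component_count(2) == 3
        assert tensor_component_count(3) == 6

    def test_kernel_parity_exact(self):
        for k in build_monomial_bank(4):
            flip = k.values[(slice(None, None, -1),) * 4]
            if k.parity == "odd":
                assert np.array_equal(flip, -k.values)
            else:
                assert np.array_equal(flip, k.values)

    def test_bandpass_kernels_have_zero_sum(self):
        for k in build_monomial_bank(4):
            assert abs(k.values.sum()) < 1e-6 * np.abs(k.values).max()

    def test_highpass_kernels_zero_sum_lowpass_unit_sum(self):
        bank = build_reconstruction_bank(4, support=7)
        assert bank.kernels[0].values.sum() == pytest.approx(1.0, abs=1e-12)
        for k in bank.kernels[1:]:
            assert abs(k.values.sum()) < 1e-6 * np.abs(k.values).max()

    def test_lowpass_response_is_one_at_dc(self):
        g = FrequencyGrid((8, 8, 8, 4))
        assert reconstruction_lowpass_response(g)[0, 0, 0, 0] == 1.0

    def test_allpass_identity_on_grid(self):
        # L + (1 - L) * sum_m u_m^2 = 1 at every non-DC bin, exactly
        g = FrequencyGrid((8, 6, 8, 4))
        total = reconstruction_lowpass_response(g).astype(float)
        for m, n in monomial_pairs(4):
            w = 1.0 if m == n else 0.0  # identity-tensor weighting
            total = total + w * reconstruction_highpass_response(m, n, g)
        mask = g.rho > 0
        assert np.abs(total[mask] - 1.0).max() < 1e-14

    def test_bank_round_trip_through_container(self, tmp_path):
        bank = build_monomial_bank(2)
        path = tmp_path / "bank.h5"
        save_bank(bank, path)
        loaded = load_bank(path)
        assert loaded.n_filters == bank.n_filters
        assert loaded.radial == bank.radial
        for a, b in zip(bank, loaded):
            assert a.order == b.order and a.indices == b.indices
            assert np.array_equal(a.values, b.values)
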