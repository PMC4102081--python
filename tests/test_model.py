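"""Activity-flow core: local statistics, contrast term, energies, steady states."""

import numpy as np
import pytest

from visioneq._signpoly import eval_odd_poly, ramp, sign_poly, sign_poly_error
from visioneq.model import (
    KernelSpec,
    ModelParams,
    contrast_term,
    energy,
    evolve_base,
    evolve_induction,
    local_mean,
    local_std,
    naka_rushton,
)
from visioneq.model import _exact_kernel_sum


class TestNakaRushton:
    def test_semisaturation_maps_to_half(self):
        assert naka_rushton(np.full((4, 4), 2.0), semisaturation=2.0) == pytest.approx(0.5)

    def test_zero_radiance_maps_to_zero(self):
        out = naka_rushton(np.array([[0.0, 1.0], [2.0, 3.0]]), semisaturation=1.0)
        assert out[0, 0] == 0.0

    def test_linear_exponent_closed_form(self):
        out = naka_rushton(np.full((2, 2), 3.0), semisaturation=1.0, exponent_n=1.0)
        assert np.allclose(out, 0.75)

    def test_auto_semisaturation_is_median_of_positive(self):
        rad = np.array([[0.0, 1.0], [2.0, 8.0]])
        out = naka_rushton(rad, "auto", exponent_n=1.0)
        assert out[1, 0] == pytest.approx(0.5)  # median of {1,2,8} is 2

    def test_all_zero_auto_rejected(self):
        with pytest.raises(ValueError):
            naka_rushton(np.zeros((3, 3)))


class TestLocalStats:
    def test_constant_mean_any_radius(self):
        img = np.full((10, 12), 0.3)
        for r in (1.0, 3.0, 50.0):
            assert np.allclose(local_mean(img, r), 0.3, atol=1e-12)

    def test_huge_radius_approaches_global_mean(self, rng):
        img = rng.random((16, 16))
        assert np.allclose(local_mean(img, 1e4), img.mean(), atol=1e-6)

    def test_mean_matches_weighted_brute_force(self, rng):
        img = rng.random((4, 4))
        r = 1.5
        out = local_mean(img, r)
        ii, jj = np.mgrid[0:4, 0:4]
        for i in range(4):
            for j in range(4):
                w = np.exp(-((ii - i) ** 2 + (jj - j) ** 2) / (2 * r * r))
                # gaussian_filter is separable with truncated taps; compare loosely
                assert out[i, j] == pytest.approx((w * img).sum() / w.sum(), abs=5e-3)

    def test_constant_std_is_zero(self):
        assert np.allclose(local_std(np.full((8, 8), 0.4), 2.0), 0.0)

    def test_checkerboard_box_window_hand_value(self):
        img = np.indices((9, 9)).sum(axis=0) % 2.0
        out = local_std(img, 1, window="box")
        # interior 3x3 window holds five of one value, four of the other
        assert out[4, 4] == pytest.approx(np.sqrt(20.0) / 9.0, abs=1e-12)

    def test_std_matches_weighted_brute_force(self, rng):
        img = rng.random((8, 8))
        out = local_std(img, 1, window="box")
        padded = np.pad(img, 1, constant_values=np.nan)
        for i in range(1, 7):
            for j in range(1, 7):
                win = padded[i : i + 3, j : j + 3].ravel()
                assert out[i, j] == pytest.approx(np.std(win), abs=1e-10)


class TestContrastTerm:
    def test_constant_image_gives_zero_field(self, small_kernel):
        img = np.full((12, 12), 0.6)
        for mode in ("exact", "polynomial"):
            assert np.allclose(contrast_term(img, small_kernel, mode=mode), 0.0, atol=1e-9)

    def test_two_pixel_signs_with_unit_weights(self):
        kernel = KernelSpec(family="inverse-distance", scale=1.0, support_radius=1.0,
                            normalize=False)
        img = np.array([[0.0, 1.0]])
        out = contrast_term(img, kernel, mode="exact", response="sign")
        assert np.array_equal(out, [[-1.0, 1.0]])

    def test_polynomial_matches_exact_within_fit_error(self, rng):
        kernel = KernelSpec(scale=8.0, support_radius=24.0, normalize=True)
        tol = sign_poly_error(9, 2.0) + 0.01  # fit error plus interpolation slack
        for _ in range(5):
            img = rng.random((32, 32))
            ex = contrast_term(img, kernel, mode="exact")
            po = contrast_term(img, kernel, mode="polynomial")
            assert np.abs(ex - po).max() <= tol

    def test_exact_mode_refuses_large_images(self, small_kernel):
        with pytest.raises(ValueError):
            contrast_term(np.zeros((200, 200)), small_kernel, mode="exact")

    def test_fitted_polynomial_tracks_ramp(self):
        coeffs = sign_poly(9, 2.0)
        d = np.linspace(-1, 1, 201)
        assert np.abs(eval_odd_poly(d, coeffs) - ramp(d, 2.0)).max() <= sign_poly_error(9, 2.0) + 2e-3


class TestEnergy:
    def test_uniform_half_state_has_zero_energy(self, small_kernel):
        img = np.full((8, 8), 0.5)
        p = ModelParams(kernel=small_kernel, contrast_mode="exact")
        assert energy(img, img, p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation_oracle(self, rng):
        img = rng.random((4, 4))
        img0 = rng.random((4, 4))
        kernel = KernelSpec(scale=2.0, support_radius=5.0, normalize=False)
        p = ModelParams(alpha=1.0, beta=0.7, gamma=0.4, kernel=kernel, contrast_mode="exact",
                        sigma_radius=1.0, mu_radius=2.0)
        K = kernel.build()
        R = K.shape[0] // 2
        nonlocal_sum = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    for l in range(4):
                        if (i, j) == (k, l):
                            continue
                        di, dj = k - i, l - j
                        if abs(di) <= R and abs(dj) <= R:
                            w = K[di + R, dj + R]
                            d = img[i, j] - img[k, l]
                            knee = 1.0 / p.sign_slope
                            rampint = (0.5 * p.sign_slope * d * d if abs(d) <= knee
                                       else abs(d) - 0.5 * knee)
                            nonlocal_sum += w * rampint
        expected = (0.5 * p.alpha * np.sum((img - 0.5) ** 2)
                    - 0.5 * p.gamma * nonlocal_sum
                    + 0.5 * p.beta * np.sum((img - img0) ** 2))
        assert energy(img, img0, p) == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch_rejected(self, small_kernel):
        with pytest.raises(ValueError):
            energy(np.zeros((4, 4)), np.zeros((5, 4)), ModelParams(kernel=small_kernel))

    def test_non_increasing_along_base_flow(self, rng):
        # symmetric (unnormalized) kernel makes the flow an exact gradient descent
        img = rng.random((16, 16))
        kernel = KernelSpec(scale=2.0, support_radius=5.0, normalize=False)
        p = ModelParams(alpha=1.0, beta=1.0, gamma=0.01, kernel=kernel, dt=0.01,
                        max_iter=60, track_energy=True, sigma_radius=1.0, mu_radius=4.0)
        _, trace = evolve_base(img, p)
        energies = trace["energy"].to_numpy()
        assert np.all(np.diff(energies) <= 1e-9)


class TestFlows:
    def test_identity_model_returns_input(self, rng, small_kernel):
        img = rng.random((12, 12))
        p = ModelParams(alpha=0.0, beta=1.0, gamma=0.0, kernel=small_kernel,
                        tol=1e-9, mu_radius=4.0, sigma_radius=1.0)
        out, _ = evolve_base(img, p)
        assert np.allclose(out, img, atol=1e-7)

    def test_gamma_zero_closed_form_base(self, rng, small_kernel):
        img = rng.random((12, 12))
        p = ModelParams(alpha=1.0, beta=2.0, gamma=0.0, kernel=small_kernel,
                        tol=3e-7, mu_radius=4.0, sigma_radius=1.0)
        out, _ = evolve_base(img, p)
        assert np.allclose(out, (1.0 * 0.5 + 2.0 * img) / 3.0, atol=1e-6)

    def test_gamma_zero_closed_form_induction(self, rng, small_kernel):
        img = rng.random((12, 12))
        p = ModelParams(alpha=1.0, beta=1.0, gamma=0.0, kernel=small_kernel,
                        tol=2e-7, mu_radius=3.0, sigma_radius=1.0)
        out, _ = evolve_induction(img, p)
        expected = (local_mean(img, 3.0) + img) / 2.0
        assert np.allclose(out, expected, atol=1e-6)

    def test_constant_image_is_fixed_point_of_both_flows(self, small_kernel):
        img = np.full((10, 10), 0.42)
        p = ModelParams(kernel=small_kernel, tol=1e-8, mu_radius=3.0, sigma_radius=1.0)
        for evolve in (evolve_base, evolve_induction):
            out, trace = evolve(img, p)
            if evolve is evolve_induction:
                assert np.allclose(out, img, atol=1e-7)
            else:  # base flow pulls constants toward the gray-world anchor
                expected = (0.5 * p.alpha + img * p.beta) / (p.alpha + p.beta)
                assert np.allclose(out, expected, atol=1e-6)

    def test_constant_at_half_fixed_for_base(self, small_kernel):
        img = np.full((10, 10), 0.5)
        out, trace = evolve_base(img, ModelParams(kernel=small_kernel, tol=1e-9,
                                                  mu_radius=3.0, sigma_radius=1.0))
        assert np.allclose(out, 0.5, atol=1e-9)
        assert len(trace) == 1

    def test_steady_state_satisfies_fixed_point_residual(self, rng, small_kernel):
        img = rng.random((16, 16))
        p = ModelParams(kernel=small_kernel, tol=1e-5, mu_radius=4.0, sigma_radius=2.0)
        out, trace = evolve_induction(img, p)
        assert trace["max_change"].iloc[-1] < 10 * p.tol

    def test_semi_implicit_reaches_same_fixed_point(self, rng, small_kernel):
        img = rng.random((16, 16))
        common = dict(kernel=small_kernel, tol=1e-7, mu_radius=4.0, sigma_radius=2.0)
        out_e, _ = evolve_induction(img, ModelParams(stepper="explicit", **common))
        out_s, _ = evolve_induction(img, ModelParams(stepper="semi-implicit", dt=0.5, **common))
        assert np.abs(out_e - out_s).max() < 1e-5

    def test_induction_degenerates_to_base_with_doubled_gamma(self, rng, small_kernel):
        img = rng.random((32, 32))
        img += 0.5 - img.mean()  # centre so the global mean equals the gray-world anchor
        base = ModelParams(alpha=1.0, beta=1.0, gamma=1.0, kernel=small_kernel,
                           tol=1e-7, mu_radius=4.0, sigma_radius=2.0)
        out_b, _ = evolve_base(img, base)
        ind = ModelParams(alpha=1.0, beta=1.0, gamma=0.5, c=0.0, kernel=small_kernel,
                          tol=1e-7, mu_radius=1e5, sigma_radius=2.0)
        out_i, _ = evolve_induction(img, ind)
        assert np.abs(out_b - out_i).max() < 1e-4

    def test_unclamped_state_stays_near_nominal_range(self, rng):
        from visioneq.presets import grating_params, grating_spec
        from visioneq.stimuli import make_bar_grating

        g = make_bar_grating(grating_spec())
        out, trace = evolve_induction(g.image, grating_params())
        assert trace["min"].iloc[-1] > -0.25
        assert trace["max"].iloc[-1] < 1.25

    def test_divergence_aborts_with_diagnostic(self, rng, small_kernel):
        img = rng.random((8, 8))
        p = ModelParams(alpha=1.0, beta=1.0, gamma=0.0, kernel=small_kernel, dt=50.0,
                        max_iter=500, mu_radius=3.0, sigma_radius=1.0)
        with pytest.raises(FloatingPointError):
            evolve_base(img, p)

    def test_invalid_params_rejected(self, small_kernel):
        with pytest.raises(ValueError):
            ModelParams(alpha=0.0, beta=0.0, gamma=0.0, kernel=small_kernel)
        with pytest.raises(ValueError):
            ModelParams(sign_degree=8, kernel=small_kernel)
        with pytest.raises(ValueError):
            ModelParams(mu_radius=2.0, sigma_radius=5.0, kernel=small_kernel)
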