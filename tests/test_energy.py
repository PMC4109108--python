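"""Region statistics, energy terms and the evolution force.

The double-sum quantities are checked against the explicit-loop oracles in
conftest (which share no code with the scipy-based implementation), and the
force field against independently coded limiting models.
"""

import numpy as np
import pytest

from rsdfseg import (
    DegenerateDiscriminantError,
    InvalidParameterError,
    OneSidedRegionError,
    RSDFParams,
    ShapeMismatchError,
    compute_stats,
    dirac_eps,
    discriminant_energy,
    distreg_energy,
    fitting_energy,
    force_field,
    heaviside_eps,
    length_energy,
    local_fitting_means,
    make_uniform_kernel,
    membership_fields,
    region_means_counts,
    total_energy,
)
from rsdfseg.energy import EnergyBreakdown

from oracles import (
    brute_discriminant,
    brute_fitting_energy,
    brute_fitting_means,
    brute_means_counts,
)


class TestParams:
    def test_cfl_bound_enforced_at_construction(self):
        with pytest.raises(InvalidParameterError, match="CFL"):
            RSDFParams(mu=3.0, dt=0.1)
        # saturating below the bound is fine
        RSDFParams(mu=2.0, dt=0.1)

    @pytest.mark.parametrize("kwargs", [
        {"w": 1.2}, {"w": -0.1}, {"k": -1.0}, {"nu": -5.0},
        {"dt": 0.0}, {"eps": 0.0}, {"sigma_local": 0.0},
        {"kernel_family": "triangle"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            RSDFParams(**kwargs)

    def test_k_above_one_accepted(self):
        # the discriminant weight may exceed 1 (search ranges go up to 10)
        assert RSDFParams(k=10.0).k == 10.0


class TestMemberships:
    def test_partition_of_unity(self, small_phi):
        M1, M2 = membership_fields(small_phi, 1.5)
        assert np.allclose(M1 + M2, 1.0)

    def test_saturation_far_from_contour(self):
        M1, M2 = membership_fields(np.full((8, 8), 10.0), 1.5)
        assert np.all(M1 == 1.0) and np.all(M2 == 0.0)

    def test_half_on_the_contour(self):
        M1, _ = membership_fields(np.zeros((4, 4)), 1.5)
        assert np.allclose(M1, 0.5)


class TestLocalFittingMeans:
    def test_constant_image_gives_constant_means(self, small_phi):
        I = np.full((8, 8), 42.0)
        M1, M2 = membership_fields(small_phi, 1.5)
        f1, f2 = local_fitting_means(I, M1, M2, make_uniform_kernel(1))
        assert np.allclose(f1, 42.0) and np.allclose(f2, 42.0)

    def test_matches_double_loop_oracle(self, small_image, small_phi):
        M1, M2 = membership_fields(small_phi, 1.5)
        k = make_uniform_kernel(1)
        f1, f2 = local_fitting_means(small_image, M1, M2, k)
        b1, b2 = brute_fitting_means(small_image, M1, M2, k)
        assert np.max(np.abs(f1 - b1)) < 1e-10
        assert np.max(np.abs(f2 - b2)) < 1e-10

    def test_degenerate_side_falls_back_to_windowed_image(self, small_image):
        # all-inside membership: side 2 has no support anywhere
        M1 = np.ones_like(small_image)
        M2 = np.zeros_like(small_image)
        k = make_uniform_kernel(1)
        f1, f2 = local_fitting_means(small_image, M1, M2, k)
        smoothed = k.convolve(small_image)
        assert np.allclose(f1, smoothed)
        assert np.allclose(f2, smoothed)  # fallback = windowed average

    def test_shape_mismatch_rejected(self, small_image):
        with pytest.raises(ShapeMismatchError):
            local_fitting_means(small_image, np.ones((4, 4)), np.zeros((4, 4)),
                                make_uniform_kernel(1))


class TestRegionMeansCounts:
    def test_exact_partition_recovers_levels(self):
        I = np.full((10, 10), 50.0)
        I[3:7, 3:7] = 150.0
        M1 = (I == 150.0).astype(float)
        C1, C2, N1, N2 = region_means_counts(I, M1, 1 - M1, kernel=None)
        assert (C1, C2) == (150.0, 50.0)
        assert (N1, N2) == (16.0, 84.0)

    def test_constant_image_means_agree(self, small_phi):
        I = np.full((8, 8), 7.0)
        M1, M2 = membership_fields(small_phi, 1.5)
        C1, C2, *_ = region_means_counts(I, M1, M2, kernel=None)
        assert C1 == pytest.approx(7.0) and C2 == pytest.approx(7.0)

    def test_matches_double_sum_oracle(self, rng):
        I = rng.uniform(0, 255, (6, 6))
        phi = rng.uniform(-3, 3, (6, 6))
        M1, M2 = membership_fields(phi, 1.5)
        k = make_uniform_kernel(1)
        got = region_means_counts(I, M1, M2, kernel=k)
        want = brute_means_counts(I, M1, M2, k)
        assert np.max(np.abs(np.array(got) - np.array(want))) < 1e-10

    def test_collapsed_region_raises(self, small_image):
        M1 = np.ones_like(small_image)
        with pytest.raises(OneSidedRegionError):
            region_means_counts(small_image, M1, 1 - M1, kernel=None)


class TestDiscriminantEnergy:
    def test_zero_for_perfect_partition(self):
        I = np.full((10, 10), 50.0)
        I[2:6, 2:6] = 150.0
        M1 = (I == 150.0).astype(float)
        J = discriminant_energy(I, M1, 1 - M1, 150.0, 50.0, 16.0, 84.0)
        assert J == pytest.approx(0.0, abs=1e-12)

    def test_shift_and_scale_invariance(self, rng):
        I = rng.uniform(0, 255, (8, 8))
        phi = rng.uniform(-3, 3, (8, 8))
        M1, M2 = membership_fields(phi, 1.5)
        C1, C2, N1, N2 = region_means_counts(I, M1, M2, kernel=None)
        J = discriminant_energy(I, M1, M2, C1, C2, N1, N2)
        for transform in (lambda x: x + 37.0, lambda x: 2.5 * x):
            It = transform(I)
            C1t, C2t, *_ = region_means_counts(It, M1, M2, kernel=None)
            Jt = discriminant_energy(It, M1, M2, C1t, C2t, N1, N2)
            assert Jt == pytest.approx(J, rel=1e-9)

    def test_matches_direct_formula(self, rng):
        I = rng.uniform(0, 255, (6, 6))
        M1 = np.zeros((6, 6))
        M1[:3] = 1.0
        C1, C2, N1, N2 = region_means_counts(I, M1, 1 - M1, kernel=None)
        J = discriminant_energy(I, M1, 1 - M1, C1, C2, N1, N2)
        assert J == pytest.approx(brute_discriminant(I, M1, 1 - M1, C1, C2, N1, N2),
                                  abs=1e-10)

    def test_coincident_means_degenerate(self):
        I = np.full((8, 8), 5.0)
        M1 = np.full((8, 8), 0.5)
        with pytest.raises(DegenerateDiscriminantError):
            discriminant_energy(I, M1, 1 - M1, 5.0, 5.0, 32.0, 32.0)

    def test_tiny_count_raises(self, small_image):
        with pytest.raises(OneSidedRegionError):
            discriminant_energy(small_image, np.ones((8, 8)), np.zeros((8, 8)),
                                100.0, 50.0, 0.5, 63.5)


class TestFittingEnergy:
    def test_zero_when_means_are_exact(self):
        I = np.full((8, 8), 9.0)
        M1 = np.full((8, 8), 0.5)
        e = fitting_energy(I, M1, 1 - M1, 9.0, 9.0, kernel=None)
        assert e == pytest.approx(0.0)

    def test_global_exact_partition_is_zero(self):
        I = np.full((10, 10), 50.0)
        I[2:6, 2:6] = 150.0
        M1 = (I == 150.0).astype(float)
        assert fitting_energy(I, M1, 1 - M1, 150.0, 50.0, None) == pytest.approx(0.0)

    def test_matches_double_sum_oracle(self, rng):
        I = rng.uniform(0, 255, (6, 6))
        phi = rng.uniform(-3, 3, (6, 6))
        M1, M2 = membership_fields(phi, 1.5)
        k = make_uniform_kernel(1)
        f1, f2 = local_fitting_means(I, M1, M2, k)
        got = fitting_energy(I, M1, M2, f1, f2, kernel=k,
                             lambda1=1.0, lambda2=1.3)
        want = brute_fitting_energy(I, M1, M2, f1, f2, k, 1.0, 1.3)
        assert got == pytest.approx(want, abs=1e-9 * max(1.0, abs(want)))


class TestGeometricEnergies:
    def test_constant_phi_has_zero_length(self):
        assert length_energy(np.full((16, 16), 3.0), 1.5) == pytest.approx(0.0)

    def test_disc_length_approximates_perimeter(self):
        rr, cc = np.mgrid[0:128, 0:128]
        phi = 20.0 - np.hypot(rr - 64, cc - 64)  # signed distance, r = 20
        L = length_energy(phi, 1.5)
        assert L == pytest.approx(2 * np.pi * 20, rel=0.05)

    def test_length_scales_linearly_with_size(self):
        def disc_length(n, r):
            rr, cc = np.mgrid[0:n, 0:n]
            return length_energy(r - np.hypot(rr - n / 2, cc - n / 2), 1.5)

        assert disc_length(256, 40) == pytest.approx(2 * disc_length(128, 20),
                                                     rel=0.05)

    def test_distance_regulariser_on_reference_fields(self):
        rr, cc = np.mgrid[0:64, 0:64]
        sdf = 20.0 - np.hypot(rr - 32, cc - 32)
        # interior of an exact signed distance function contributes ~0
        assert distreg_energy(sdf) < 0.02 * sdf.size
        # constant field: integrand 1/2 everywhere
        n_half = distreg_energy(np.full((64, 64), 5.0))
        assert n_half == pytest.approx(0.5 * 64 * 64, rel=0.05)
        # linear field of slope 2: integrand 1/2 on interior nodes
        plane = 2.0 * cc.astype(float)
        assert distreg_energy(plane) == pytest.approx(0.5 * 64 * 64, rel=0.05)


class TestTotalEnergyAndForce:
    def test_total_is_weighted_sum_of_components(self, rng):
        I = rng.uniform(0, 255, (16, 16))
        phi = rng.uniform(-3, 3, (16, 16))
        params = RSDFParams(w=0.7, k=0.4, nu=50.0, mu=2.0, sigma_local=1.0,
                            kernel_family="uniform")
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        e = total_energy(I, phi, params, stats)
        recomputed = ((1 - params.w) * e.E_G + params.w * e.E_L
                      + params.k * ((1 - params.w) * e.J_G + params.w * e.J_L)
                      + params.nu * e.L_len + params.mu * e.R_reg)
        assert e.F_total == pytest.approx(recomputed, abs=1e-9 * abs(e.F_total))

    def test_weight_selection_isolates_terms(self, rng):
        I = rng.uniform(0, 255, (16, 16))
        phi = rng.uniform(-3, 3, (16, 16))
        params = RSDFParams(w=1.0, k=0.0, nu=0.0, mu=1e-9, sigma_local=1.0,
                            kernel_family="uniform")
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        e = total_energy(I, phi, params, stats)
        assert e.F_total == pytest.approx(e.E_L + 1e-9 * e.R_reg, rel=1e-9)

    def test_cv_reduction_of_force(self, rng):
        """With the global window and w = k = 0 the data force must equal an
        independently coded piecewise-constant (Chan--Vese) force."""
        I = rng.uniform(0, 255, (16, 16))
        phi = rng.uniform(-3, 3, (16, 16))
        params = RSDFParams(w=0.0, k=0.0, nu=0.0, mu=1e-13, dt=0.1)
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        got = force_field(I, phi, params, stats)

        # independent CV coding: soft means + arctan-pair from first principles
        H = np.where(phi > 1.5, 1.0,
                     np.where(phi < -1.5, 0.0,
                              0.5 + np.arctan(phi / 1.5) / np.pi))
        c1 = (I * H).sum() / H.sum()
        c2 = (I * (1 - H)).sum() / (1 - H).sum()
        delta = (1.5 / np.pi) / (1.5**2 + phi**2)
        want = -delta * ((I - c1) ** 2 - (I - c2) ** 2)
        scale = np.max(np.abs(want))
        assert np.max(np.abs(got - want)) < 1e-10 * scale

    def test_rsf_reduction_of_force(self, rng):
        """With w = 1, k = 0 the data force must equal an independently coded
        region-scalable fitting force built from double-loop means."""
        I = rng.uniform(0, 255, (8, 8))
        phi = rng.uniform(-3, 3, (8, 8))
        params = RSDFParams(w=1.0, k=0.0, nu=0.0, mu=1e-13, dt=0.1,
                            sigma_local=1.0, kernel_family="uniform")
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        got = force_field(I, phi, params, stats)

        f1, f2 = brute_fitting_means(I, M1, M2, make_uniform_kernel(1))
        delta = (1.5 / np.pi) / (1.5**2 + phi**2)
        want = -delta * ((I - f1) ** 2 - (I - f2) ** 2)
        scale = np.max(np.abs(want))
        assert np.max(np.abs(got - want)) < 1e-9 * scale

    def test_fitting_force_sign_pushes_pixel_toward_matching_side(self):
        I = np.full((16, 16), 50.0)
        I[4:12, 4:12] = 150.0
        phi = np.where(I == 150.0, 2.0, -2.0)
        # perturb one bright pixel to start outside
        phi[5, 5] = -2.0
        params = RSDFParams(w=0.0, k=0.0, nu=0.0, mu=1e-13)
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        force = force_field(I, phi, params, stats)
        assert force[5, 5] > 0  # bright pixel is pulled inside

    def test_constant_image_has_no_data_force(self):
        I = np.full((16, 16), 77.0)
        phi = np.where(np.arange(16)[:, None] < 8, 2.0, -2.0) * np.ones((16, 16))
        params = RSDFParams(w=0.0, k=0.0, nu=0.0, mu=2.0)
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        force = force_field(I, phi, params, stats)
        # only the mu-term remains; it is independent of I
        from rsdfseg.stencils import curvature, laplacian
        from rsdfseg.energy import CURVATURE_CLIP
        want = params.mu * (laplacian(phi) - curvature(phi, clip=CURVATURE_CLIP))
        assert np.allclose(force, want, atol=1e-10)

    def test_degenerate_discriminant_zeroes_that_branch(self):
        I = np.full((16, 16), 10.0)
        I[0, 0] = 10.000001  # means nearly coincide
        phi = np.where(np.arange(16)[:, None] < 8, 2.0, -2.0) * np.ones((16, 16))
        params = RSDFParams(w=0.0, k=0.5, nu=0.0, mu=1e-13)
        M1, M2 = membership_fields(phi, params.eps)
        stats = compute_stats(I, M1, M2, params)
        force = force_field(I, phi, params, stats)  # must not raise
        assert np.all(np.isfinite(force))
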