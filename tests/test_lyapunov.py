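"""Lyapunov diagnostics, dimensions, and theoretical expansion rates."""

import numpy as np
import pytest

import hierchaos as hc
from hierchaos.connectivity import HierarchySpec
from hierchaos.lyapunov import _macro_project


class TestJacobian:
    def test_at_origin_equals_weights(self, small_micro_net):
        N = small_micro_net.n_units
        J = hc.jacobian(small_micro_net, np.zeros(N))
        assert np.allclose(J, small_micro_net.weights)

    def test_zero_weights_give_zero(self):
        spec = HierarchySpec(sizes=(2, 5), strengths=(0.0, 0.0))
        Jm = hc.build_multilevel(spec, seed=0)
        assert np.allclose(hc.jacobian(Jm, np.ones(10)), 0.0)

    def test_matches_finite_differences(self):
        spec = HierarchySpec(sizes=(5, 6), strengths=(1.5, 2.0))
        Jm = hc.build_multilevel(spec, seed=1)
        x = np.random.default_rng(2).uniform(-0.5, 0.5, 30)
        J = hc.jacobian(Jm, x)
        h = 1e-6
        fd = np.empty((30, 30))
        for j in range(30):
            e = np.zeros(30)
            e[j] = h
            fd[:, j] = (hc.step(Jm, x + e) - hc.step(Jm, x - e)) / (2 * h)
        assert np.allclose(J, fd, atol=1e-6)


class TestKYDimension:
    @pytest.mark.parametrize(
        "exponents,expected",
        [
            ((-0.1, -0.2), 0.0),
            ((0.5, -1.0), 1.5),
            ((0.3, 0.1, -0.2, -0.5), 3.4),  # 3 + 0.2/0.5
        ],
    )
    def test_interpolation_formula(self, exponents, expected):
        assert hc.ky_dimension(exponents) == pytest.approx(expected, abs=1e-12)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            hc.ky_dimension([0.1, 0.3, -0.2])

    def test_all_positive_truncates_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert hc.ky_dimension([0.3, 0.2]) == 2.0


class TestPRDimension:
    def test_isotropic_data(self):
        X = np.random.default_rng(0).standard_normal((4000, 10))
        assert hc.pr_dimension(X) == pytest.approx(10.0, rel=0.05)

    def test_rank_one_data(self):
        t = np.random.default_rng(1).standard_normal(500)
        X = np.outer(t, np.ones(8))
        assert hc.pr_dimension(X) == pytest.approx(1.0, abs=1e-8)

    def test_prescribed_spectrum(self):
        # whiten empirically, then rescale: sample covariance exactly diag(nu)
        nu = np.array([4.0, 2.0, 1.0, 1.0])
        Z = np.random.default_rng(2).standard_normal((400, 4))
        Zc = Z - Z.mean(axis=0)
        L = np.linalg.cholesky(np.linalg.inv(Zc.T @ Zc / 400))
        X = Zc @ L @ np.diag(np.sqrt(nu))
        assert hc.pr_dimension(X) == pytest.approx(64.0 / 22.0, rel=1e-10)

    def test_zero_variance_is_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert hc.pr_dimension(np.zeros((100, 5))) == 0.0


class TestTheoryRates:
    def test_incoherent_branch_closed_relation(self):
        # at qm = 0: R_coherent^2 = sigma_mu^2 g(sigma sqrt(q))^2, so the
        # coherent rate crosses zero exactly at the onset sigma_mu*
        sigma = 4.0
        sol = hc.fixed_point(sigma, 1.0, branch="incoherent")
        star = hc.sigma_mu_star(sigma)
        rep = hc.theory_rates(sigma, star, sol.q, 0.0)
        assert rep.lambda_coherent == pytest.approx(0.0, abs=1e-8)
        g = hc.g_factor(sigma * np.sqrt(sol.q))
        rep2 = hc.theory_rates(sigma, 2.0, sol.q, 0.0)
        assert rep2.rate_sq_coherent == pytest.approx(4.0 * g**2, abs=1e-10)

    @pytest.mark.parametrize(
        "sigma,sigma_mu", [(4.0, 0.5), (4.0, 6.0), (1.0, 5.0), (2.0, 2.5), (4.0, 12.0)]
    )
    def test_coupling_constant_nonnegative(self, sigma, sigma_mu):
        sol = hc.fixed_point(sigma, sigma_mu)
        qm = 0.0 if sol.qm < 1e-8 else sol.qm
        rep = hc.theory_rates(sigma, sigma_mu, sol.q, qm)
        assert rep.C >= -1e-10
        # D is lower triangular with the rates on the diagonal
        assert rep.D[0, 1] == 0.0
        assert rep.D[0, 0] == pytest.approx(rep.rate_sq_coherent)

    def test_strong_modularity_contracts_microscopic(self):
        # beyond the edge of high-dimensional chaos: R_random^2 < 1
        sol = hc.fixed_point(4.0, 12.0)
        rep = hc.theory_rates(4.0, 12.0, sol.q, sol.qm)
        assert rep.rate_sq_random < 1.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            hc.theory_rates(1.0, 1.0, 0.3, 0.5)


class TestMultilevelRates:
    def test_two_level_reduction(self):
        rep2 = hc.theory_rates(4.0, 6.0, 0.85, 0.26)
        repm = hc.multilevel_rates([0.26, 0.85], [6.0, 4.0])
        assert np.allclose(rep2.rates_sq, repm.rates_sq, atol=1e-14)

    def test_closed_form_at_designed_fixed_point(self):
        qs = np.array([0.25, 0.55, 0.8])
        sigmas = hc.design_sigmas(qs)
        rep = hc.multilevel_rates(qs, sigmas)
        expected = [
            hc.rate_sq_closed_form(qs[j], qs[j - 1] if j else 0.0)
            for j in range(3)
        ]
        assert np.allclose(rep.rates_sq, expected, atol=1e-8)

    def test_first_active_level_expands(self):
        # q_1 = 0 (silent coarse level), first active level is chaotic
        qs = np.array([0.0, 0.4, 0.7])
        sigmas = hc.design_sigmas(qs)
        rep = hc.multilevel_rates(qs, sigmas)
        assert rep.lambdas[1] > 0


class TestSpectrumMethods:
    def test_quiescent_exponent_is_log_spectral_radius(self):
        Jm = hc.build_two_level(n=20, P=10, sigma=0.5, sigma_mu=0.5, seed=3)
        rep = hc.lyapunov_spectrum(Jm, k=1, T=600, burn_in=400, seed=3)
        rho = np.max(np.abs(hc.spectrum(Jm)))
        assert rep.exponents[0] == pytest.approx(np.log(rho), abs=0.02)
        assert rep.exponents[0] < 0

    def test_qr_matches_two_replica(self, small_micro_net):
        lam_qr = hc.lyapunov_spectrum(small_micro_net, k=1, T=800, burn_in=300, seed=4)
        lam_dir = hc.mle_direct(small_micro_net, T=800, burn_in=300, seed=4)
        assert lam_qr.exponents[0] == pytest.approx(lam_dir, abs=0.01)

    def test_volume_contraction_identity(self):
        # sum of all N exponents = time average of ln |det(Jacobian)|
        spec = HierarchySpec.two_level(n=10, P=5, sigma=2.0, sigma_mu=1.0)
        Jm = hc.build_multilevel(spec, seed=5)
        T, burn = 220, 20
        rep = hc.lyapunov_spectrum(Jm, k=50, T=T, burn_in=burn, seed=5)
        x = hc.initial_state(50, 5)
        logdets = []
        for t in range(T):
            J = hc.jacobian(Jm, x)
            x = hc.step(Jm, x)
            if t >= burn:
                logdets.append(np.linalg.slogdet(J)[1])
        # both sides evaluate a determinant with dynamic range ~e^50, so
        # agreement is limited by conditioning, not by the identity itself
        assert rep.exponents.sum() == pytest.approx(np.mean(logdets), abs=0.01)

    def test_invalid_arguments(self, small_micro_net):
        with pytest.raises(ValueError):
            hc.lyapunov_spectrum(small_micro_net, k=0)
        with pytest.raises(ValueError):
            hc.lyapunov_spectrum(small_micro_net, k=1, T=10, burn_in=10)


class TestSubspaceMLE:
    def test_projectors_decompose_identity(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(60)
        mac = _macro_project(v, 6, 10)
        mic = v - mac
        assert np.allclose(mac + mic, v, atol=1e-12)
        assert np.allclose(_macro_project(mac, 6, 10), mac, atol=1e-12)
        assert np.allclose(_macro_project(mic, 6, 10), 0.0, atol=1e-12)

    def test_macroscopic_phase_signature(self):
        # M phase: coherent chaos expands, microscopic residuals contract
        Jm = hc.build_two_level(n=25, P=80, sigma=1.0, sigma_mu=5.0, seed=6)
        lam_mac, lam_mic = hc.subspace_mle(Jm, T=800, burn_in=300, seed=6)
        assert lam_mic < 0 < lam_mac

    def test_requires_two_levels(self):
        spec = HierarchySpec(sizes=(4, 5, 10), strengths=(1.0, 1.0, 1.0))
        Jm = hc.build_multilevel(spec, seed=0)
        with pytest.raises(ValueError):
            hc.subspace_mle(Jm)
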