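"""Hierarchical connectivity generation and spectra."""

import numpy as np
import pytest

import hierchaos as hc
from hierchaos.connectivity import HierarchySpec


class TestHierarchySpec:
    def test_level_sizes_cumulative(self):
        spec = HierarchySpec(sizes=(4, 5, 10), strengths=(1.0, 1.0, 1.0))
        assert spec.level_sizes == (4, 20, 200)
        assert spec.n_units == 200
        assert spec.levels == 3

    def test_two_level_identification(self):
        spec = HierarchySpec.two_level(n=30, P=5, sigma=2.0, sigma_mu=3.0)
        assert spec.sizes == (5, 30)
        assert spec.strengths == (3.0, 2.0)

    @pytest.mark.parametrize(
        "sizes,strengths",
        [((0, 5), (1.0, 1.0)), ((5,), (1.0, 1.0)), ((5, 5), (-1.0, 1.0)), ((), ())],
    )
    def test_invalid_specs_rejected(self, sizes, strengths):
        with pytest.raises(ValueError):
            HierarchySpec(sizes=sizes, strengths=strengths)


class TestRandomBulk:
    def test_entry_statistics(self):
        m = 2000
        X = hc.random_bulk(m, seed=0)
        # variance 1/m within 3 standard errors (chi^2 sampling error)
        se = (1.0 / m) * np.sqrt(2.0 / m**2)
        assert abs(X.var() - 1.0 / m) < 3 * se
        assert abs(X.mean()) < 4 / m  # mean ~ N(0, 1/m^(3/2))

    def test_single_entry_is_unit_scale(self):
        draws = np.array([hc.random_bulk(1, seed=s)[0, 0] for s in range(500)])
        assert abs(draws.var() - 1.0) < 0.2

    def test_seeded_determinism(self):
        assert np.array_equal(hc.random_bulk(50, seed=7), hc.random_bulk(50, seed=7))

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            hc.random_bulk(0, seed=1)


class TestMeanProjector:
    @pytest.mark.parametrize("n", [1, 2, 7, 64])
    def test_projector_identities(self, n):
        O = hc.mean_projector(n)
        assert np.allclose(O @ O, O, atol=1e-14)
        assert np.allclose(O, O.T, atol=1e-14)
        assert np.trace(O) == pytest.approx(1.0, abs=1e-14)

    def test_averaging_action(self):
        assert np.allclose(hc.mean_projector(3) @ [1, 2, 3], [2, 2, 2])

    def test_n1_is_identity(self):
        assert np.array_equal(hc.mean_projector(1), [[1.0]])


class TestBuildTwoLevel:
    def test_pure_bulk_when_sigma_mu_zero(self):
        Jm = hc.build_two_level(n=40, P=10, sigma=1.5, sigma_mu=0.0, seed=3)
        N = 400
        assert abs(Jm.weights.var() - 1.5**2 / N) / (1.5**2 / N) < 0.2

    def test_pure_structure_when_sigma_zero(self):
        Jm = hc.build_two_level(n=20, P=5, sigma=0.0, sigma_mu=2.0, seed=4)
        assert np.linalg.matrix_rank(Jm.weights) <= 5
        # constant within each n x n block
        block = Jm.weights[:20, 20:40]
        assert np.ptp(block) == pytest.approx(0.0, abs=1e-15)

    def test_block_means_recover_structured_draw(self):
        n, P, sigma, sigma_mu = 200, 20, 1.0, 2.0
        Jm = hc.build_two_level(n=n, P=P, sigma=sigma, sigma_mu=sigma_mu, seed=5)
        xi_P = Jm.level_draws[0]
        blocks = Jm.weights.reshape(P, n, P, n).mean(axis=(1, 3))
        expected = sigma_mu * xi_P / n
        # block averages of the bulk term have sd sigma/(N sqrt(n... )): n^2 entries of var sigma^2/N
        se = sigma / np.sqrt(n * P) / n
        assert np.all(np.abs(blocks - expected) < 4 * se)

    def test_seeded_determinism(self):
        A = hc.build_two_level(10, 4, 1.0, 1.0, seed=9)
        B = hc.build_two_level(10, 4, 1.0, 1.0, seed=9)
        assert np.array_equal(A.weights, B.weights)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            hc.build_two_level(10, 4, -1.0, 1.0, seed=0)


class TestBuildMultilevel:
    def test_zero_strengths_give_zero_matrix(self):
        spec = HierarchySpec(sizes=(3, 4, 5), strengths=(0.0, 0.0, 0.0))
        Jm = hc.build_multilevel(spec, seed=0)
        assert np.all(Jm.weights == 0.0)

    def test_single_level_is_plain_random(self):
        spec = HierarchySpec(sizes=(50,), strengths=(2.0,))
        Jm = hc.build_multilevel(spec, seed=1)
        expected = 2.0 * hc.random_bulk(
            50, np.random.default_rng(np.random.SeedSequence(1).spawn(1)[0])
        )
        assert np.allclose(Jm.weights, expected)

    def test_variance_composition_three_levels(self):
        # total entry variance = sum_i sigma_i^2 N_i / N^2 (kron averaging
        # divides each level's draw by the product of later block sizes)
        spec = HierarchySpec(sizes=(4, 5, 10), strengths=(1.5, 1.2, 1.0))
        Jm = hc.build_multilevel(spec, seed=2)
        N = spec.n_units
        sizes = np.array(spec.level_sizes, dtype=float)
        expected = float(np.sum(np.array(spec.strengths) ** 2 * sizes / N**2))
        assert abs(Jm.weights.var() - expected) / expected < 0.15

    def test_matches_two_level_moments(self):
        spec = HierarchySpec.two_level(n=50, P=8, sigma=1.0, sigma_mu=2.0)
        A = hc.build_multilevel(spec, seed=11)
        B = hc.build_two_level(n=50, P=8, sigma=1.0, sigma_mu=2.0, seed=11)
        assert np.array_equal(A.weights, B.weights)  # same construction path
        # and the blockwise mean variance matches the generative description
        blocks = A.weights.reshape(8, 50, 8, 50).mean(axis=(1, 3))
        # block means ~ sigma_mu Xi(P)/n: variance sigma_mu^2/(P n^2)
        expected = 2.0**2 / (8 * 50**2)
        assert abs(blocks.var() / expected - 1.0) < 0.6

    def test_bulk_draw_roundtrip(self):
        spec = HierarchySpec(sizes=(4, 25), strengths=(2.0, 1.0))
        Jm = hc.build_multilevel(spec, seed=3)
        xi = Jm.bulk_draw()
        rebuilt = (
            np.kron(Jm.structured_parent(), hc.mean_projector(25)) + 1.0 * xi
        )
        assert np.allclose(rebuilt, Jm.weights, atol=1e-12)


class TestSpectrum:
    def test_zero_matrix(self):
        spec = HierarchySpec(sizes=(2, 5), strengths=(0.0, 0.0))
        eig = hc.spectrum(hc.build_multilevel(spec, seed=0))
        assert np.allclose(eig, 0.0)

    def test_low_rank_outliers_when_sigma_zero(self):
        n, P, sigma_mu = 100, 8, 3.0
        Jm = hc.build_two_level(n=n, P=P, sigma=0.0, sigma_mu=sigma_mu, seed=6)
        eig = np.sort_complex(hc.spectrum(Jm))
        outliers = sorted(np.abs(eig), reverse=True)[:P]
        expected = sorted(np.abs(np.linalg.eigvals(sigma_mu * Jm.level_draws[0])), reverse=True)
        assert np.allclose(outliers, expected, atol=1e-8)
        # all other eigenvalues vanish (rank <= P)
        rest = sorted(np.abs(eig))[: n * P - P]
        assert max(rest) < 1e-8

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hc.spectrum(np.array([[np.inf, 0.0], [0.0, 1.0]]))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        Jm = hc.build_two_level(n=10, P=4, sigma=1.0, sigma_mu=2.0, seed=12)
        Jm.save(tmp_path / "net")
        back = hc.ConnectivityMatrix.load(tmp_path / "net")
        assert np.array_equal(back.weights, Jm.weights)
        assert back.spec == Jm.spec
        assert back.seed == Jm.seed
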