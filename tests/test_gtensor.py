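import numpy as np
import pytest

from qgclone import gtensor, synth
from qgclone.gfit import GPosterior

from conftest import wishart_posterior

TRAITS = ("AFR", "body_mass", "size_at_birth")


class TestVectorize:
    def test_identity(self):
        np.testing.assert_allclose(
            gtensor.vectorize_g(np.eye(3)), [1, 0, 0, 1, 0, 1]
        )

    def test_frobenius_inner_product_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.standard_normal((4, 4))
            B = rng.standard_normal((4, 4))
            A, B = A + A.T, B + B.T
            assert np.dot(
                gtensor.vectorize_g(A), gtensor.vectorize_g(B)
            ) == pytest.approx(np.sum(A * B), abs=1e-10)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((3, 3))
        G = A @ A.T
        np.testing.assert_allclose(
            gtensor.devectorize_g(gtensor.vectorize_g(G), 3), G, rtol=1e-14
        )

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            gtensor.vectorize_g(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestSTensor:
    def test_identical_matrices_zero(self):
        G = np.diag([1.0, 2.0, 3.0])
        S = gtensor.build_s_tensor([G, G, G])
        assert np.abs(S).max() < 1e-12

    def test_rank_bounded_by_m_minus_one(self):
        rng = np.random.default_rng(2)
        Gs = [(lambda A: A @ A.T)(rng.standard_normal((3, 3))) for _ in range(3)]
        S = gtensor.build_s_tensor(Gs)
        assert np.linalg.matrix_rank(S, tol=1e-10) <= 2

    def test_two_point_closed_form(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 3))
        G1, G2 = A @ A.T, 2 * (A @ A.T) + np.eye(3)
        S = gtensor.build_s_tensor([G1, G2])
        lam = np.linalg.eigvalsh(S)
        expected = 0.5 * np.sum(
            (gtensor.vectorize_g(G1) - gtensor.vectorize_g(G2)) ** 2
        )
        assert lam[-1] == pytest.approx(expected, rel=1e-10)
        assert np.abs(lam[:-1]).max() < 1e-10 * expected

    def test_single_matrix_rejected(self):
        with pytest.raises(ValueError):
            gtensor.build_s_tensor([np.eye(3)])


class TestEigentensors:
    def test_single_trait_family_concentrates(self):
        base = np.diag([0.5, 0.4, 0.3])
        fam = synth.make_g_family(base, "single_trait", m=4, magnitude=0.4, trait=2)
        props, tensors = gtensor.eigentensors(gtensor.build_s_tensor(fam))
        assert props[0] == pytest.approx(1.0, abs=1e-10)
        loadings, v = gtensor._leading_loadings(tensors[0])
        assert abs(v[2]) == pytest.approx(1.0, abs=1e-8)

    def test_at_most_m_minus_one_nonzero(self):
        rng = np.random.default_rng(4)
        Gs = [(lambda A: A @ A.T)(rng.standard_normal((3, 3))) for _ in range(3)]
        props, _ = gtensor.eigentensors(gtensor.build_s_tensor(Gs))
        assert (props[2:] < 1e-10).all()

    def test_orthonormality(self):
        rng = np.random.default_rng(5)
        Gs = [(lambda A: A @ A.T)(rng.standard_normal((3, 3))) for _ in range(4)]
        _, tensors = gtensor.eigentensors(gtensor.build_s_tensor(Gs))
        for a, Ta in enumerate(tensors):
            for b, Tb in enumerate(tensors):
                ip = np.sum(Ta * Tb)
                assert ip == pytest.approx(1.0 if a == b else 0.0, abs=1e-8)

    def test_all_zero_s_flagged(self):
        props, tensors = gtensor.eigentensors(np.zeros((6, 6)))
        assert len(props) == 0 and tensors == []


class TestCoordinatesAndSiteVariance:
    def test_coordinate_of_mean_is_zero(self):
        rng = np.random.default_rng(6)
        Gs = [(lambda A: A @ A.T)(rng.standard_normal((3, 3))) for _ in range(3)]
        mean_G = np.mean(Gs, axis=0)
        _, tensors = gtensor.eigentensors(gtensor.build_s_tensor(Gs))
        assert gtensor.tensor_coordinates(mean_G, tensors[0], mean_G) == pytest.approx(0.0)

    def test_coordinate_recovers_coefficient(self):
        rng = np.random.default_rng(7)
        Gs = [(lambda A: A @ A.T)(rng.standard_normal((3, 3))) for _ in range(3)]
        mean_G = np.mean(Gs, axis=0)
        _, tensors = gtensor.eigentensors(gtensor.build_s_tensor(Gs))
        c = 0.37
        assert gtensor.tensor_coordinates(
            mean_G + c * tensors[1], tensors[1], mean_G
        ) == pytest.approx(c, abs=1e-10)

    def test_reconstruction_completeness(self):
        rng = np.random.default_rng(8)
        Gs = [(lambda A: A @ A.T)(rng.standard_normal((3, 3))) for _ in range(4)]
        mean_G = np.mean(Gs, axis=0)
        _, tensors = gtensor.eigentensors(gtensor.build_s_tensor(Gs))
        for G in Gs:
            recon = sum(
                gtensor.tensor_coordinates(G, Ek, mean_G) * Ek for Ek in tensors
            )
            np.testing.assert_allclose(recon, G - mean_G, atol=1e-8)

    def test_site_variance_basics(self):
        chile_G = np.array([[0.13, 0.0004, 0.02],
                            [0.0004, 0.04, 0.01],
                            [0.02, 0.01, 0.13]])
        e1 = np.array([1.0, 0.0, 0.0])
        assert gtensor.site_variance(e1, chile_G) == pytest.approx(0.13)
        assert gtensor.site_variance(e1 / np.linalg.norm(e1), np.eye(3)) == 1.0
        from qgclone.gcompare import gmax
        v, lam = gmax(chile_G)
        assert gtensor.site_variance(v, chile_G) == pytest.approx(lam, abs=1e-10)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            gtensor.site_variance(np.array([1.0, 1.0, 0.0]), np.eye(3))


def _gradient_posteriors(scales=(0.1, 0.6, 1.5), seed=0, n_samples=200):
    """Posteriors whose G differ only in size-at-birth variance."""
    posts = []
    for j, s in enumerate(scales):
        G = np.diag([0.3, 0.25, s])
        posts.append(
            wishart_posterior(G, n_samples=n_samples, df=600, seed=seed + j,
                              population=f"pop{j + 1}")
        )
    return posts


class TestTensorAnalysis:
    def test_sb_gradient_dominates_first_tensor(self):
        posts = _gradient_posteriors()
        dec = gtensor.tensor_analysis(posts, seed=0)
        assert dec.variance_proportions[0] > 0.9
        assert abs(dec.leading_loadings[2]) > 0.9
        # variance increases along the gradient order, so the oriented
        # tensor (pointing from the gradient end back to the start)
        # reads as loss of size-at-birth variance
        assert dec.leading_loadings[2] < 0

    def test_site_variances_ordered_along_gradient(self):
        dec = gtensor.tensor_analysis(_gradient_posteriors(), seed=0)
        sv = dec.site_variance_T1
        assert sv[0] < sv[1] < sv[2]

    def test_proportions_sum_to_one(self):
        dec = gtensor.tensor_analysis(_gradient_posteriors(), seed=0)
        assert 0 <= dec.variance_proportions.min()
        # per-draw normalization: modes of a simplex need not sum exactly,
        # but must stay near 1
        assert dec.variance_proportions.sum() == pytest.approx(1.0, abs=0.05)

    def test_population_permutation_invariance(self):
        posts = _gradient_posteriors()
        a = gtensor.tensor_analysis(posts, seed=0)
        b = gtensor.tensor_analysis(posts[::-1], seed=0)
        np.testing.assert_allclose(
            np.sort(a.variance_proportions), np.sort(b.variance_proportions), atol=0.02
        )
        np.testing.assert_allclose(
            np.abs(a.leading_loadings), np.abs(b.leading_loadings), atol=0.05
        )
        np.testing.assert_allclose(a.site_variance_T1, b.site_variance_T1[::-1], atol=0.05)

    def test_scaling_equivariance(self):
        posts = _gradient_posteriors()
        c = 4.0
        scaled = [
            GPosterior.from_matrices(p.trait_names, c * p.G, population=p.population)
            for p in posts
        ]
        a = gtensor.tensor_analysis(posts, seed=0)
        b = gtensor.tensor_analysis(scaled, seed=0)
        np.testing.assert_allclose(a.variance_proportions, b.variance_proportions, atol=0.02)
        np.testing.assert_allclose(a.leading_loadings, b.leading_loadings, atol=0.05)
        np.testing.assert_allclose(b.site_variance_T1, c * a.site_variance_T1, rtol=0.1)

    def test_report_mirrors_three_blocks(self, tmp_path):
        dec = gtensor.tensor_analysis(_gradient_posteriors(), seed=0)
        rep = dec.to_dict()
        assert set(rep) == {"gradient", "traits", "A_variance_proportions",
                            "B_delta_va_tensor1", "C_site_variance_T1"}
        assert [r["population"] for r in rep["C_site_variance_T1"]] == list(dec.populations)
        dec.save(tmp_path / "tensor.json")
        assert (tmp_path / "tensor.json").exists()

    def test_trait_mismatch_rejected(self):
        posts = _gradient_posteriors()
        bad = GPosterior.from_matrices(("a", "b", "c"), posts[0].G)
        with pytest.raises(ValueError, match="trait"):
            gtensor.tensor_analysis([posts[0], bad])
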