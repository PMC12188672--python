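"""Flat and constant-curvature embeddings, embeddability, stress, selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentgeo import (
    cmds_embed,
    curvature_gram,
    embeddability_check,
    embedding_stress,
    hyperbolic_embed,
    laplacian_spectral_embed,
    select_geometry,
    spherical_embed,
)
from latentgeo.embedding import EmbeddingResult
from latentgeo.exceptions import EmbeddingError, ValidationError


def sphere_points_distances(n, seed, m=2):
    """Exact geodesic distances of random points on the unit m-sphere."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n, m + 1))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    D = np.arccos(np.clip(v @ v.T, -1, 1))
    np.fill_diagonal(D, 0.0)
    return D


def hyperboloid_points_distances(n, seed, m=2, scale=1.0):
    """Exact distances of random points on the hyperbolic plane (k = -1)."""
    rng = np.random.default_rng(seed)
    w = scale * rng.normal(size=(n, m))
    x0 = np.sqrt(1 + (w**2).sum(axis=1))
    ch = np.outer(x0, x0) - w @ w.T
    D = np.arccosh(np.clip(ch, 1, None))
    np.fill_diagonal(D, 0.0)
    return D


class TestCmds:
    def test_equilateral_triangle_exact(self):
        D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = cmds_embed(D, m=2)
        assert res.stress <= 1e-9

    def test_unit_square_exact(self):
        s2 = np.sqrt(2.0)
        D = np.array(
            [[0, 1, s2, 1], [1, 0, 1, s2], [s2, 1, 0, 1], [1, s2, 1, 0]]
        )
        res = cmds_embed(D, m=2)
        assert res.stress <= 1e-9
        np.testing.assert_allclose(res.hstar, D, atol=1e-9)

    def test_case_study_stress_value(self, individual1_matrix):
        res = cmds_embed(individual1_matrix, m=2)
        assert res.stress == pytest.approx(0.8585134, abs=5e-6)

    def test_matches_pcoa_reference(self, individual1_matrix):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        import skbio

        ref = skbio_ord.pcoa(
            skbio.DistanceMatrix(
                individual1_matrix.D, ids=individual1_matrix.labels
            ),
            number_of_dimensions=2,
        )
        X = ref.samples.to_numpy()
        ref_h = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        mine = cmds_embed(individual1_matrix, m=2)
        np.testing.assert_allclose(mine.hstar, ref_h, atol=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            cmds_embed(np.array([[0, 1.0], [2.0, 0]]))


class TestLaplacianSpectral:
    def test_identical_nodes_coincide(self):
        D = np.array(
            [
                [0, 0, 1, 2, 1.5],
                [0, 0, 1, 2, 1.5],
                [1, 1, 0, 1, 0.8],
                [2, 2, 1, 0, 0.9],
                [1.5, 1.5, 0.8, 0.9, 0],
            ]
        )
        res = laplacian_spectral_embed(D, m=2)
        np.testing.assert_allclose(res.coords[0], res.coords[1], atol=1e-9)

    def test_path_graph_middle_node_between_endpoints(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = laplacian_spectral_embed(D, m=2)
        x = res.coords[:, 0]
        assert abs(x[1]) < 1e-9  # middle node centred by symmetry
        assert x[0] * x[2] < 0  # endpoints on opposite sides

    def test_case_study_stress_positive_finite(self, individual1_matrix):
        res = laplacian_spectral_embed(individual1_matrix, m=2)
        assert np.isfinite(res.stress)
        assert res.stress > 0

    def test_least_squares_scale_helps(self, individual1_matrix):
        scaled = laplacian_spectral_embed(individual1_matrix, m=2)
        # removing the fitted scale can only increase the stress
        unscaled_h = scaled.hstar / scaled.notes["scale"]
        raw_stress = embedding_stress(individual1_matrix.D, unscaled_h, 6)
        assert scaled.stress <= raw_stress + 1e-12


class TestCurvatureGram:
    def test_all_zero_distances(self):
        D = np.zeros((4, 4))
        gram = curvature_gram(D, k=1.0)
        np.testing.assert_array_equal(gram.C, np.ones((4, 4)))
        assert gram.n_pos == 1
        assert gram.n_zero == 3

    def test_small_curvature_series_limit(self):
        D = sphere_points_distances(5, seed=1)
        k = 1e-5
        gram = curvature_gram(D, k)
        approx = 1 - k * D**2 / 2
        assert np.abs(gram.C - approx).max() < k**2 * (D.max() ** 4)

    def test_zero_curvature_rejected(self):
        with pytest.raises(ValueError):
            curvature_gram(np.zeros((3, 3)), k=0.0)

    def test_sphere_sampled_sign_pattern(self):
        D = sphere_points_distances(6, seed=2)
        gram = curvature_gram(D, k=1.0)
        assert gram.n_neg == 0
        assert gram.n_pos <= 3


class TestEmbeddabilityCheck:
    def test_spherical_construction_embeddable(self):
        D = sphere_points_distances(6, seed=3)
        gram = curvature_gram(D, k=1.0)
        ok, p = embeddability_check(gram, m=2)
        assert ok
        assert p <= 3

    def test_hyperbolic_construction_embeddable(self):
        D = hyperboloid_points_distances(6, seed=4)
        gram = curvature_gram(D, k=-1.0)
        ok, p = embeddability_check(gram, m=2)
        assert ok
        assert gram.n_pos == 1
        assert p <= 2

    def test_generic_random_matrix_not_embeddable(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0.5, 2.0, size=(6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        ok_h, _ = embeddability_check(curvature_gram(D, k=-1.0), m=2)
        ok_s, _ = embeddability_check(curvature_gram(D, k=1.0), m=2)
        assert not (ok_h and ok_s)

    def test_verdict_agrees_with_coordinate_fit_oracle(self):
        # brute-force oracle: can coordinates in the model space reproduce
        # the distances?  Check on small instances of both kinds.
        from scipy.optimize import minimize

        def hyp_fit_residual(D, m=2):
            n = D.shape[0]

            def loss(w):
                W = w.reshape(n, m)
                x0 = np.sqrt(1 + (W**2).sum(axis=1))
                ch = np.clip(np.outer(x0, x0) - W @ W.T, 1, None)
                H = np.arccosh(ch)
                return ((H - D)[np.triu_indices(n, 1)] ** 2).sum()

            best = np.inf
            for s in range(3):
                w0 = np.random.default_rng(s).normal(size=n * m) * 0.5
                best = min(best, minimize(loss, w0, method="L-BFGS-B").fun)
            return best

        D_yes = hyperboloid_points_distances(4, seed=6)
        ok, _ = embeddability_check(curvature_gram(D_yes, k=-1.0), m=2)
        assert ok
        assert hyp_fit_residual(D_yes) < 1e-10

        D_no = sphere_points_distances(5, seed=7) * 2.0  # strongly spherical
        ok_no, _ = embeddability_check(curvature_gram(D_no, k=-1.0), m=2)
        assert not ok_no
        assert hyp_fit_residual(D_no) > 1e-4


class TestHyperbolicEmbed:
    def test_recovery_of_sampled_points(self):
        D = hyperboloid_points_distances(6, seed=8)
        res = hyperbolic_embed(D, m=2, k=-1.0)
        assert res.stress <= 1e-6
        np.testing.assert_allclose(res.hstar, D, atol=1e-6)

    def test_two_point_isometry(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = hyperbolic_embed(D, m=2, k=-1.0)
        assert res.hstar[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_poincare_inside_unit_disk(self, individual1_matrix):
        res = hyperbolic_embed(individual1_matrix, m=2, k=-1.0)
        norms = np.linalg.norm(res.poincare, axis=1)
        assert np.all(norms < 1.0)

    def test_curvature_scaling(self):
        D = hyperboloid_points_distances(5, seed=9) / 2.0  # curvature -4
        res = hyperbolic_embed(D, m=2, k=-4.0)
        assert res.stress <= 1e-6

    def test_positive_curvature_rejected(self):
        with pytest.raises(ValueError):
            hyperbolic_embed(np.zeros((3, 3)), k=1.0)


class TestSphericalEmbed:
    def test_recovery_of_sampled_points(self):
        D = sphere_points_distances(6, seed=10)
        res = spherical_embed(D, m=2, k=1.0)
        assert res.stress <= 1e-6
        np.testing.assert_allclose(res.hstar, D, atol=1e-6)

    def test_antipodal_pair(self):
        D = np.array([[0.0, np.pi], [np.pi, 0.0]])
        res = spherical_embed(D, m=2, k=1.0)
        assert res.hstar[0, 1] == pytest.approx(np.pi)
        assert res.coords[0] @ res.coords[1] == pytest.approx(-1.0)

    def test_equilateral_spherical_triangle(self):
        D = np.full((3, 3), 0.5)
        np.fill_diagonal(D, 0.0)
        res = spherical_embed(D, m=2, k=1.0)
        off = res.hstar[np.triu_indices(3, 1)]
        np.testing.assert_allclose(off, off[0])
        np.testing.assert_allclose(off, 0.5, atol=1e-9)

    def test_rows_unit_norm(self):
        D = sphere_points_distances(5, seed=11)
        res = spherical_embed(D, m=2, k=1.0)
        np.testing.assert_allclose(
            np.linalg.norm(res.coords, axis=1), 1.0, atol=1e-9
        )

    def test_distances_beyond_pi_rejected(self):
        D = np.array([[0.0, 4.0], [4.0, 0.0]])
        with pytest.raises(EmbeddingError):
            spherical_embed(D, m=2, k=1.0)


class TestStress:
    def test_perfect_reconstruction_zero(self):
        D = sphere_points_distances(5, seed=12)
        assert embedding_stress(D, D, 5) == 0.0

    def test_two_node_hand_value(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        H = np.zeros((2, 2))
        # ordered pairs: sqrt(2 * 1) / 2
        assert embedding_stress(D, H, 2) == pytest.approx(np.sqrt(2) / 2)

    def test_unordered_convention_halves_sum(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        H = np.zeros((2, 2))
        assert embedding_stress(D, H, 2, convention="unordered") == pytest.approx(
            0.5
        )

    def test_matches_direct_resummation(self, individual1_matrix):
        res = cmds_embed(individual1_matrix, m=2)
        D = individual1_matrix.D
        total = 0.0
        for i in range(6):
            for j in range(6):
                if i != j:
                    total += (D[i, j] - res.hstar[i, j]) ** 2
        assert res.stress == pytest.approx(np.sqrt(total) / 6, abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            embedding_stress(np.zeros((3, 3)), np.zeros((4, 4)))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_stress_permutation_invariance(seed):
    """Relabeling nodes leaves every embedding stress unchanged."""
    rng = np.random.default_rng(seed)
    A = rng.uniform(0.1, 1.0, size=(5, 5))
    D = (A + A.T) / 2
    np.fill_diagonal(D, 0.0)
    perm = rng.permutation(5)
    Dp = D[np.ix_(perm, perm)]
    assert cmds_embed(D).stress == pytest.approx(cmds_embed(Dp).stress, abs=1e-9)
    assert hyperbolic_embed(D).stress == pytest.approx(
        hyperbolic_embed(Dp).stress, abs=1e-9
    )


class TestSelectGeometry:
    def _res(self, space, stress):
        return EmbeddingResult(
            space=space, k=0.0, m=2, labels=[], coords=np.zeros((0, 2)),
            hstar=np.zeros((0, 0)), stress=stress,
        )

    def test_smallest_stress_wins(self):
        picked = select_geometry(
            [
                self._res("hyperbolic", 0.14),
                self._res("euclidean", 0.075),
                self._res("spherical", 0.15),
            ]
        )
        assert picked.space == "euclidean"

    def test_single_result(self):
        r = self._res("spherical", 0.5)
        assert select_geometry([r]) is r

    def test_tie_prefers_euclidean(self):
        picked = select_geometry(
            [self._res("hyperbolic", 0.1), self._res("euclidean", 0.1)]
        )
        assert picked.space == "euclidean"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_geometry([])
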