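"""Procrustes superimposition, shape variables, TPS grids, shape scores."""

import numpy as np
import pytest

import wingshape as ws
from wingshape.exceptions import ValidationError
from wingshape.morphometrics import _shape_basis, tangent_residuals

import oracles


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_unit_square(self):
        sq = np.array([[0.5, 0.5], [-0.5, 0.5], [-0.5, -0.5], [0.5, -0.5]])
        assert ws.centroid_size(sq) == pytest.approx(np.sqrt(2))

    def test_homogeneity_and_rotation_invariance(self, landmark_cloud):
        X = landmark_cloud[0].coords
        cs = ws.centroid_size(X)
        assert ws.centroid_size(3.0 * X) == pytest.approx(3.0 * cs)
        assert ws.centroid_size(X @ _rot(1.1).T) == pytest.approx(cs)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValidationError):
            ws.centroid_size(np.zeros((5, 2)))


class TestGpa:
    def test_rigid_and_scale_copies_align_exactly(self, landmark_cloud):
        A = landmark_cloud[0].coords
        B = (A @ _rot(np.pi / 2).T) * 3.0 + np.array([5.0, -2.0])
        space = ws.gpa([A, B])
        assert np.linalg.norm(space.aligned[0] - space.aligned[1]) < 1e-9
        assert ws.procrustes_distance(A, B) < 1e-9

    def test_single_specimen_consensus_is_itself(self, landmark_cloud):
        X = landmark_cloud[0].coords
        space = ws.gpa([X])
        centered = X - X.mean(axis=0)
        expected = centered / np.sqrt((centered**2).sum())
        np.testing.assert_allclose(space.consensus, expected, atol=1e-12)

    def test_rotation_optimum_matches_grid_search_oracle(self, landmark_cloud):
        A = landmark_cloud[0].coords
        B = landmark_cloud[1].coords
        d = ws.procrustes_distance(A, B)
        d_grid = oracles.grid_search_rotation(
            *(
                (X - X.mean(0)) / np.sqrt(((X - X.mean(0)) ** 2).sum())
                for X in (A, B)
            )
        )
        assert d <= d_grid + 1e-12
        assert abs(d - d_grid) < 1e-6

    def test_procrustes_ss_descends_monotonically(self, landmark_cloud):
        space = ws.gpa(landmark_cloud, slide=True)
        ss = space.ss_history
        assert all(a >= b - 1e-12 for a, b in zip(ss, ss[1:]))

    def test_consensus_is_a_fixed_point(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        again = ws.gpa(list(space.aligned))
        assert (
            np.sqrt(((again.consensus - space.consensus) ** 2).mean()) < 1e-8
        )

    def test_sliding_does_not_increase_distance_to_consensus(self, landmark_cloud):
        free = ws.gpa(landmark_cloud, slide=False)
        slid = ws.gpa(landmark_cloud, slide=True)
        assert slid.ss_history[-1] <= free.ss_history[-1] + 1e-12

    def test_mismatched_landmark_count_rejected(self, landmark_cloud):
        bad = np.vstack([landmark_cloud[0].coords, [0.0, 0.0]])
        with pytest.raises(ValidationError):
            ws.gpa([landmark_cloud[0], bad])


class TestShapeVariables:
    def test_dimension_is_2k_minus_4(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        sv = ws.shape_variables(space)
        k = space.n_landmarks
        assert sv.shape == (len(landmark_cloud), 2 * k - 4)
        assert sv.shape[1] == 20  # k = 12

    def test_pure_affine_deformation_loads_only_on_uniform(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        basis, sim, _ = _shape_basis(space)
        C = space.consensus
        for A in (np.array([[0.0, 1.0], [0.0, 0.0]]), np.array([[1.0, 0.0], [0.0, -1.0]])):
            v = (C @ A).ravel()
            v = v - sim.T @ (sim @ v)
            partial_warp_loadings = basis[:, :-2].T @ v
            uniform_loadings = basis[:, -2:].T @ v
            assert np.abs(partial_warp_loadings).max() < 1e-8
            assert np.abs(uniform_loadings).max() > 0

    def test_scores_reconstruct_tangent_residuals(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        sv = ws.shape_variables(space)
        V = tangent_residuals(space).reshape(len(landmark_cloud), -1)
        rec = sv @ space._tangent_basis.T
        assert np.abs(rec - V).max() < 1e-8

    def test_total_variance_preserved(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        sv = ws.shape_variables(space)
        V = tangent_residuals(space).reshape(len(landmark_cloud), -1)
        assert np.isclose(
            sv.var(axis=0, ddof=1).sum(), V.var(axis=0, ddof=1).sum(), atol=1e-8
        )

    def test_bending_eigenvalues_sorted_descending(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        ws.shape_variables(space)
        ev = space.bending_energy_eigenvalues
        assert len(ev) == space.n_landmarks - 3
        assert np.all(np.diff(ev) <= 1e-12)


class TestTpsGrid:
    def test_identity_map_when_target_equals_consensus(self, landmark_cloud):
        C = ws.gpa(landmark_cloud).consensus
        g = ws.tps_grid(C, C)
        np.testing.assert_allclose(g.mapped_grid, g.source_grid, atol=1e-10)
        assert g.bending_energy < 1e-12

    def test_landmarks_interpolated_exactly(self, landmark_cloud):
        rng = np.random.default_rng(3)
        C = ws.gpa(landmark_cloud).consensus
        T = C + rng.normal(scale=0.05, size=C.shape)
        g = ws.tps_grid(C, T)
        assert np.abs(g.transform(C) - T).max() < 1e-10

    def test_coefficients_match_dense_bordered_solve(self, landmark_cloud):
        rng = np.random.default_rng(4)
        C = ws.gpa(landmark_cloud).consensus
        T = C + rng.normal(scale=0.05, size=C.shape)
        g = ws.tps_grid(C, T)
        W, A = oracles.tps_bordered_solve(C, T)
        np.testing.assert_allclose(g.weights, W, atol=1e-8)
        np.testing.assert_allclose(g.affine, A, atol=1e-8)

    def test_collinear_landmarks_raise_explained_error(self):
        C = np.column_stack([np.linspace(0, 1, 6), np.zeros(6)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            ws.tps_grid(C, C + 0.01)


class TestShapeScores:
    @staticmethod
    def _space_with_known_allometry(n=200, seed=11):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(12, 2))
        C = ws.gpa(
            [base + rng.normal(scale=0.02, size=(12, 2)) for _ in range(3)]
        ).consensus
        x = rng.normal(size=n)
        beta = rng.normal(size=24)
        beta /= np.linalg.norm(beta)
        noise = rng.normal(scale=2e-4, size=(n, 24))
        aligned = (C.ravel() + 2e-3 * np.outer(x, beta) + noise).reshape(n, 12, 2)
        return (
            ws.ShapeSpace(consensus=C, aligned=aligned, centroid_sizes=np.ones(n)),
            x,
        )

    def test_scores_recover_constructed_allometry(self):
        space, x = self._space_with_known_allometry()
        scores = ws.shape_scores(space, x)
        assert abs(np.corrcoef(scores, x)[0, 1]) > 0.99

    def test_identical_specimens_get_equal_scores(self, landmark_cloud):
        X = landmark_cloud[0].coords
        space = ws.gpa([X, X, X])
        scores = ws.shape_scores(space, np.array([1.0, 2.0, 3.0]))
        assert np.allclose(scores, scores[0])

    def test_covariate_rescaling_changes_scores_affinely(self):
        space, x = self._space_with_known_allometry()
        s1 = ws.shape_scores(space, x)
        s2 = ws.shape_scores(space, 5.0 * x + 2.0)
        fit = np.polyfit(s1, s2, 1)
        assert np.abs(np.polyval(fit, s1) - s2).max() < 1e-10

    def test_constant_covariate_rejected(self, landmark_cloud):
        space = ws.gpa(landmark_cloud)
        with pytest.raises(ValidationError):
            ws.shape_scores(space, np.ones(len(landmark_cloud)))
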