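import numpy as np
import pytest

from sparse_xanes import (
    EnergyGrid,
    SamplingPlan,
    SpectralLibrary,
    compute_basis,
    deim_select,
    design_experiment,
    load_plan,
    reconstruct,
    reconstruction_error,
    regional_deim,
    save_plan,
    solve_coefficients,
)
from sparse_xanes.background_augmentation import (
    augment_library,
    default_background_config,
)
from sparse_xanes.reduced_basis import ReducedBasis

from conftest import random_orthonormal

EDGE = 7112.0


def _basis_from_U(U, k=None):
    m, l = U.shape
    s = np.linspace(1.0, 0.5, l)
    return ReducedBasis(grid=EnergyGrid(np.arange(m, dtype=float)), U=U,
                        singular_values=s,
                        explained_variance_ratio=s**2 / np.sum(s**2),
                        k=k or l, n_columns=l)


def naive_deim(U, k):
    """Reference implementation: rebuild the full interpolatory projector
    Pi_j = U_j (P_j^T U_j)^-1 P_j^T from scratch at every step."""
    indices = [int(np.argmax(np.abs(U[:, 0])))]
    for j in range(1, k):
        Uj = U[:, :j]
        P = np.zeros((U.shape[0], j))
        for col, p in enumerate(indices):
            P[p, col] = 1.0
        proj = Uj @ np.linalg.inv(P.T @ Uj) @ P.T
        r = U[:, j] - proj @ U[:, j]
        indices.append(int(np.argmax(np.abs(r))))
    return indices


class TestDeimSelect:
    def test_single_canonical_vector(self):
        U = np.zeros((5, 1))
        U[2, 0] = 1.0
        plan = deim_select(_basis_from_U(U), 1)
        assert plan.indices.tolist() == [2]

    def test_two_canonical_vectors_in_order(self):
        U = np.zeros((6, 2))
        U[0, 0] = 1.0
        U[1, 1] = 1.0
        plan = deim_select(_basis_from_U(U), 2)
        assert plan.indices.tolist() == [0, 1]

    def test_tie_breaks_to_smallest_index(self):
        U = np.zeros((5, 1))
        U[1, 0] = U[3, 0] = 0.5  # exact tie
        plan = deim_select(_basis_from_U(U), 1)
        assert plan.indices.tolist() == [1]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_projector_reference(self, seed):
        U = random_orthonormal(20, 4, seed)
        plan = deim_select(_basis_from_U(U), 4)
        assert plan.indices.tolist() == naive_deim(U, 4)

    def test_indices_distinct_and_residuals_recorded(self):
        U = random_orthonormal(50, 10, 1234)
        plan = deim_select(_basis_from_U(U), 10)
        assert len(set(plan.indices.tolist())) == 10
        assert plan.residual_norms.size == 10
        assert np.all(plan.residual_norms > 0)

    def test_permutation_equivariance(self):
        U = random_orthonormal(30, 5, 77)
        rng = np.random.default_rng(5)
        perm = rng.permutation(30)
        plan = deim_select(_basis_from_U(U), 5)
        plan_p = deim_select(_basis_from_U(U[perm]), 5)
        assert plan_p.indices.tolist() == [
            int(np.nonzero(perm == i)[0][0]) for i in plan.indices]

    def test_standards_basis_points_cluster_near_edge(self, basis13):
        """Greedy selection weights feature changes, which concentrate about
        the absorption edge: most of the 13 points land within +/-30 eV."""
        plan = deim_select(basis13, 13)
        assert plan.s == 13
        near = np.sum(np.abs(plan.energies - EDGE) <= 30.0)
        assert near >= 7


@pytest.fixture(scope="module")
def aug4(standards4, fe_grid):
    cfg = default_background_config(fe_grid, EDGE, n_variants=25, seed=6)
    return augment_library(standards4, cfg, append_originals=False)


@pytest.fixture(scope="module")
def interp_setup():
    U = random_orthonormal(60, 6, 42)
    basis = _basis_from_U(U)
    plan = deim_select(basis, 6)
    return basis, plan


class TestRegionalDeim:
    def test_duplicate_regions_collapse_to_union(self, aug4):
        span = aug4.grid.span
        plan = regional_deim(aug4, [span, span], 5)
        single = regional_deim(aug4, [span], 5)
        assert plan.indices.tolist() == single.indices.tolist()

    def test_disjoint_regions_keep_points_inside(self, aug4):
        regions = [(7000.0, 7100.0), (7150.0, 7300.0)]
        plan = regional_deim(aug4, regions, 3)
        assert plan.s == 6
        for (lo, hi), rec in zip(regions, plan.regions):
            for idx in rec["indices"]:
                assert lo <= aug4.grid.energies[idx] <= hi

    def test_full_plus_edge_window_aggregation(self, aug4):
        span = aug4.grid.span
        plan = regional_deim(aug4, [span, (EDGE - 30.0, EDGE + 30.0)], 7)
        assert 7 <= plan.s <= 14
        assert len(plan.regions) == 2

    def test_too_small_region_rejected(self, aug4):
        from sparse_xanes import ConfigurationError
        with pytest.raises(ConfigurationError):
            regional_deim(aug4, [(EDGE - 1.0, EDGE + 1.0)], 20)


class TestSolveAndReconstruct:
    def test_measuring_the_basis_gives_identity(self, interp_setup):
        basis, plan = interp_setup
        sampled = basis.U[plan.indices, :]
        coeffs = solve_coefficients(basis, plan, sampled)
        np.testing.assert_allclose(coeffs.C, np.eye(6), atol=1e-10)
        assert coeffs.solve_mode == "interpolatory"

    def test_scaled_first_mode(self, interp_setup):
        basis, plan = interp_setup
        sampled = 2.0 * basis.U[plan.indices, 0][:, None]
        coeffs = solve_coefficients(basis, plan, sampled)
        expected = np.zeros((6, 1))
        expected[0, 0] = 2.0
        np.testing.assert_allclose(coeffs.C, expected, atol=1e-10)

    def test_in_span_mixtures_recovered_exactly(self, interp_setup):
        basis, plan = interp_setup
        rng = np.random.default_rng(3)
        W = rng.standard_normal((6, 10))
        A = basis.U @ W
        coeffs = solve_coefficients(basis, plan, A[plan.indices])
        np.testing.assert_allclose(coeffs.C, W, atol=1e-10)
        np.testing.assert_allclose(reconstruct(basis, coeffs), A, atol=1e-10)

    def test_interpolation_exact_even_for_noisy_data(self, interp_setup):
        basis, plan = interp_setup
        rng = np.random.default_rng(4)
        A = rng.standard_normal((60, 5))  # arbitrary, far from the span
        coeffs = solve_coefficients(basis, plan, A[plan.indices])
        approx = reconstruct(basis, coeffs)
        np.testing.assert_allclose(approx[plan.indices], A[plan.indices],
                                   atol=1e-10)

    def test_zero_coefficients_give_zero_matrix(self, interp_setup):
        basis, plan = interp_setup
        coeffs = solve_coefficients(basis, plan,
                                    np.zeros((plan.s, 3)))
        np.testing.assert_array_equal(reconstruct(basis, coeffs), 0.0)

    def test_underdetermined_rejected(self, interp_setup):
        basis, _ = interp_setup
        short = SamplingPlan(indices=np.array([0, 1, 2]),
                             energies=basis.grid.energies[:3], basis_rank=3)
        with pytest.raises(ValueError, match="underdetermined"):
            solve_coefficients(basis, short, np.zeros((3, 1)))

    def test_oversampled_least_squares_still_exact_in_span(self, interp_setup):
        basis, plan = interp_setup
        extra = [i for i in range(60) if i not in plan.indices][:4]
        big = SamplingPlan(
            indices=np.concatenate([plan.indices, extra]),
            energies=basis.grid.energies[
                np.concatenate([plan.indices, extra])],
            basis_rank=6)
        rng = np.random.default_rng(5)
        A = basis.U @ rng.standard_normal((6, 4))
        coeffs = solve_coefficients(basis, big, A[big.indices])
        assert coeffs.solve_mode == "least_squares"
        np.testing.assert_allclose(reconstruct(basis, coeffs), A, atol=1e-10)

    def test_centered_basis_round_trip(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal((40, 7)) + 3.0
        lib = SpectralLibrary(EnergyGrid(np.arange(40.0)), a)
        basis = compute_basis(lib, centering="mean")
        plan = deim_select(basis, basis.l)
        coeffs = solve_coefficients(basis, plan, a[plan.indices])
        np.testing.assert_allclose(reconstruct(basis, coeffs), a, atol=1e-9)

    def test_ill_conditioned_sampling_warns(self):
        U = np.zeros((8, 2))
        U[0, 0] = 1.0
        U[1, 1] = 1e-14
        U[2, 1] = 1.0
        basis = _basis_from_U(np.linalg.qr(U)[0][:, :2])
        bad = SamplingPlan(indices=np.array([0, 1]),
                           energies=basis.grid.energies[:2], basis_rank=2)
        with pytest.warns(RuntimeWarning, match="condition"):
            coeffs = solve_coefficients(basis, bad, np.zeros((2, 1)))
        assert coeffs.ill_conditioned


class TestReconstructionError:
    def test_perfect_match_is_zero(self):
        t = np.random.default_rng(0).standard_normal((10, 3))
        err = reconstruction_error(t, t)
        np.testing.assert_array_equal(err["rel_l2"], 0.0)
        np.testing.assert_array_equal(err["max_abs"], 0.0)

    def test_double_is_unit_relative_error(self):
        t = np.random.default_rng(1).standard_normal((10, 3))
        err = reconstruction_error(t, 2.0 * t)
        np.testing.assert_allclose(err["rel_l2"], 1.0)

    def test_zero_norm_column_flagged(self):
        t = np.zeros((5, 2))
        t[:, 1] = 1.0
        err = reconstruction_error(t, t + 0.1)
        assert err["zero_norm_columns"].tolist() == [0]
        assert np.isnan(err["rel_l2"][0])

    def test_mask_restricts_rows(self):
        t = np.ones((6, 1))
        a = t.copy()
        a[4:] = 5.0
        mask = np.arange(6) < 4
        err = reconstruction_error(t, a, mask=mask)
        np.testing.assert_array_equal(err["rel_l2"], 0.0)


class TestDesignExperiment:
    def test_plain_13_standard_design(self, standards13):
        basis, plan, prov = design_experiment(standards13,
                                              rank_method="count",
                                              rank_param=13)
        assert plan.s == 13
        assert prov["k"] == 13

    def test_fully_augmented_design_selects_18_points(self, standards13,
                                                      fe_grid):
        """13 prior states + 5 background components -> 18 energies."""
        cfg = default_background_config(fe_grid, EDGE, n_variants=100, seed=2)
        basis, plan, prov = design_experiment(standards13, cfg,
                                              rank_method="auto")
        assert plan.s == 18
        assert basis.k == 18

    def test_single_standard_single_point(self, standards4):
        lib = SpectralLibrary(standards4.grid, standards4.matrix[:, :1],
                              labels=[standards4.labels[0]],
                              edge_energy=standards4.edge_energy)
        basis, plan, _ = design_experiment(lib, rank_method="count",
                                           rank_param=1)
        u1 = compute_basis(lib).U[:, 0]
        assert plan.indices[0] == int(np.argmax(np.abs(u1)))


class TestPlanSerialization:
    def test_json_round_trip_preserves_selection_order(self, tmp_path,
                                                       basis13):
        plan = deim_select(basis13, 9)
        path = tmp_path / "plan.json"
        save_plan(plan, path, provenance={"note": "fixture"})
        back = load_plan(path, grid=basis13.grid)
        assert back.indices.tolist() == plan.indices.tolist()
        np.testing.assert_allclose(back.energies, plan.energies, atol=1e-9)
        assert back.basis_rank == plan.basis_rank

    def test_energy_mismatch_rejected(self, tmp_path, basis13, fe_grid):
        plan = deim_select(basis13, 3)
        path = tmp_path / "plan.json"
        save_plan(plan, path)
        other = EnergyGrid(fe_grid.energies + 0.17)
        with pytest.raises(ValueError, match="not on the target grid"):
            load_plan(path, grid=other)
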