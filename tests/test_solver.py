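import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from mcligand.density import calc_density, footprint_mask, grid_for_conformers
from mcligand.ligand import Conformer
from mcligand.solver import (DesignMatrix, build_design_matrix,
                             project_capped_simplex, qp_screen, solve_miqp,
                             solve_qp)


def random_design(rng, n=6, m=40):
    A = rng.normal(size=(n, m))
    b = rng.normal(size=m)
    return DesignMatrix(A, b)


def projected_gradient_oracle(design, iters=200000):
    """Plain projected gradient with small constant step (independent path)."""
    G, c = design.gram, design.atb
    L = 2.0 * np.linalg.eigvalsh(G)[-1]
    w = np.zeros(design.n_candidates)
    for _ in range(iters):
        w_new = project_capped_simplex(w - 2.0 * (G @ w - c) / L)
        if np.max(np.abs(w_new - w)) < 1e-12:
            return w_new
        w = w_new
    return w


def brute_force_miqp(design, cardinality, t_min):
    """Exhaustive oracle built on SLSQP subset solves (independent path)."""
    n = design.n_candidates
    G, c = design.gram, design.atb
    best = (0.0, (), np.zeros(n))          # objective excl. b'b, subset, w
    for size in range(1, cardinality + 1):
        for subset in itertools.combinations(range(n), size):
            idx = list(subset)
            if size * t_min > 1.0:
                continue
            Gs, cs = G[np.ix_(idx, idx)], c[idx]

            def f(x):
                return float(x @ Gs @ x - 2.0 * cs @ x)

            def fprime(x):
                return 2.0 * (Gs @ x) - 2.0 * cs

            x0 = np.full(size, min(1.0 / size, max(t_min, 1.0 / size)))
            res = minimize(f, x0, jac=fprime, method="SLSQP",
                           bounds=[(t_min, 1.0)] * size,
                           constraints=[{"type": "ineq",
                                         "fun": lambda x: 1.0 - x.sum(),
                                         "jac": lambda x: -np.ones(size)}],
                           options={"maxiter": 300, "ftol": 1e-14})
            if res.success and res.fun < best[0] - 1e-12:
                best = (res.fun, subset, None)
                w = np.zeros(n)
                w[idx] = res.x
                best = (res.fun, subset, w)
    return best


class TestSolveQP:
    def test_single_perfect_candidate(self, rng):
        A = rng.random((1, 30)) + 0.5
        sol = solve_qp(DesignMatrix(A, A[0]))
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-8)

    def test_zero_observation_gives_zero_weights(self, rng):
        A = rng.random((4, 30))
        sol = solve_qp(DesignMatrix(A, np.zeros(30)))
        assert np.all(sol.weights == 0)
        assert sol.objective == pytest.approx(0.0)

    def test_noiseless_mixture_recovered(self, rng):
        A = rng.random((2, 60))
        b = 0.6 * A[0] + 0.4 * A[1]
        sol = solve_qp(DesignMatrix(A, b))
        assert np.allclose(sol.weights, [0.6, 0.4], atol=1e-3)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_projected_gradient_oracle(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng, n=5, m=30)
        sol = solve_qp(design)
        w_ref = projected_gradient_oracle(design)
        assert design.rss(sol.weights) <= design.rss(w_ref) + 1e-8
        assert np.allclose(sol.weights, w_ref, atol=1e-5)

    def test_feasibility_always_holds(self, rng):
        for _ in range(20):
            design = random_design(rng)
            w = solve_qp(design).weights
            assert np.all(w >= 0)
            assert w.sum() <= 1.0 + 1e-9

    def test_scale_covariance(self, rng):
        design = random_design(rng)
        scaled = DesignMatrix(3.7 * design.A, 3.7 * design.b)
        assert np.allclose(solve_qp(design).weights,
                           solve_qp(scaled).weights, atol=1e-7)


class TestSolveMIQP:
    def test_single_perfect_candidate(self, rng):
        A = rng.random((1, 30)) + 0.5
        sol = solve_miqp(DesignMatrix(A, A[0]), cardinality=1)
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-8)
        assert sol.objective == pytest.approx(0.0, abs=1e-10)

    def test_t_min_enforced(self, rng):
        for seed in range(10):
            design = random_design(np.random.default_rng(seed), n=7)
            sol = solve_miqp(design, cardinality=3, t_min=0.20)
            nz = sol.weights[sol.weights > 0]
            assert np.all(nz >= 0.20 - 1e-9)
            assert len(nz) <= 3
            assert sol.weights.sum() <= 1.0 + 1e-9

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        design = random_design(rng, n=6)
        sol = solve_miqp(design, cardinality=3, t_min=0.20)
        obj_ref, subset_ref, w_ref = brute_force_miqp(design, 3, 0.20)
        assert tuple(sol.selected) == subset_ref
        assert np.allclose(sol.weights, w_ref, atol=1e-6)

    def test_objective_monotone_in_cardinality(self, rng):
        for seed in range(8):
            design = random_design(np.random.default_rng(seed + 100), n=6)
            objs = [solve_miqp(design, cardinality=k, t_min=0.2).objective
                    for k in (1, 2, 3)]
            assert objs[1] <= objs[0] + 1e-10
            assert objs[2] <= objs[1] + 1e-10

    def test_invalid_arguments(self, rng):
        design = random_design(rng)
        with pytest.raises(ValueError):
            solve_miqp(design, cardinality=0)
        with pytest.raises(ValueError):
            solve_miqp(design, cardinality=2, t_min=1.5)


class TestQPScreen:
    def _candidates(self, rng, n_decoys=50):
        truth = Conformer(coords=[[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                                  [2.2, 1.2, 0.0]], b_factors=[15.0] * 3)
        decoys = [truth.with_coords(truth.coords
                                    + rng.normal(2.0, 1.0, (3, 3)))
                  for _ in range(n_decoys)]
        return truth, decoys

    def test_decoys_eliminated_against_noiseless_truth(self, rng):
        truth, decoys = self._candidates(rng)
        copies = [truth.with_coords(truth.coords.copy()) for _ in range(3)]
        grid = grid_for_conformers([truth] + decoys, 1.0)
        obs = calc_density([truth], [1.0], grid, 1.0)
        mask = footprint_mask([truth], grid, radius=1.5)
        pool = copies + decoys
        survivors, weights, _ = qp_screen(pool, obs, mask, resolution=1.0)
        assert all(s in copies for s in survivors)
        assert weights.sum() == pytest.approx(1.0, abs=1e-3)

    def test_single_candidate_survives(self, rng):
        truth, _ = self._candidates(rng, n_decoys=0)
        grid = grid_for_conformers([truth], 1.0)
        obs = calc_density([truth], [0.7], grid, 1.0)
        mask = footprint_mask([truth], grid, radius=1.5)
        survivors, weights, _ = qp_screen([truth], obs, mask, resolution=1.0)
        assert survivors == [truth]
        assert weights[0] <= 1.0 + 1e-9

    def test_batching_is_a_no_op_when_batch_covers_pool(self, rng):
        truth, decoys = self._candidates(rng, n_decoys=10)
        grid = grid_for_conformers([truth] + decoys, 1.0)
        obs = calc_density([truth], [1.0], grid, 1.0)
        mask = footprint_mask([truth] + decoys, grid, radius=1.5)
        pool = [truth] + decoys
        s1, w1, _ = qp_screen(pool, obs, mask, batch_size=len(pool),
                              resolution=1.0)
        s2, w2, _ = qp_screen(pool, obs, mask, batch_size=10**6,
                              resolution=1.0)
        assert s1 == s2
        assert np.allclose(w1, w2, atol=1e-10)


def test_design_matrix_from_density_is_consistent(rng):
    """Design-matrix rows agree with full-grid density restricted to mask."""
    c = Conformer(coords=[[0.0, 0.0, 0.0], [1.4, 0.3, -0.2]],
                  b_factors=[18.0, 22.0])
    grid = grid_for_conformers([c], 1.2)
    obs = calc_density([c], [1.0], grid, 1.2, atomic_numbers=[6, 8])
    mask = footprint_mask([c], grid, radius=1.5)
    design = build_design_matrix([c], obs, mask, resolution=1.2,
                                 atomic_numbers=[6, 8], scale=False)
    assert np.allclose(design.A[0], mask.extract(obs), rtol=1e-6, atol=1e-9)
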