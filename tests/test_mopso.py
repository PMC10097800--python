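import math

import numpy as np
import pytest

from hemoswarm.mopso import (
    MOPSOConfig,
    ParetoRepository,
    combine_repositories,
    constriction,
    dominates,
    literature_domain_bounds,
    mathematical_domain_bounds,
    mopso_run,
    pbest_update,
    velocity_position_update,
)


class TestConstriction:
    def test_reference_phi(self):
        omega, c = constriction(2.01)
        assert omega == pytest.approx(0.86823, abs=1e-5)
        assert c == pytest.approx(1.74514, abs=1e-5)

    def test_phi_2_5(self):
        omega, c = constriction(2.5)
        assert omega == pytest.approx(0.38197, abs=1e-5)
        assert c == pytest.approx(0.95491, abs=1e-5)

    def test_limit_phi_to_two(self):
        omega, _ = constriction(2.0 + 1e-12)
        assert omega == pytest.approx(1.0, abs=1e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            constriction(2.0)
        with pytest.raises(ValueError):
            constriction(1.5)


class TestDominates:
    def test_strict(self):
        assert dominates((0.1, 0.1), (0.2, 0.2))

    def test_mutual_nondominance(self):
        assert not dominates((0.1, 0.3), (0.3, 0.1))
        assert not dominates((0.3, 0.1), (0.1, 0.3))

    def test_equal_pairs(self):
        assert not dominates((0.2, 0.2), (0.2, 0.2))

    def test_partial_tie(self):
        assert dominates((0.1, 0.2), (0.1, 0.3))

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            dominates((0.1,), (0.1, 0.2))


class TestVelocityPositionUpdate:
    LB = np.array([-1.0, -1.0])
    UB = np.array([1.0, 1.0])

    def test_pure_inertial_decay(self):
        rng = np.random.default_rng(0)
        x = np.array([0.2, -0.3])
        v = np.array([0.1, 0.05])
        omega, c = constriction(2.01)
        x2, v2 = velocity_position_update(x, v, x, x, omega, c, self.LB, self.UB, rng)
        np.testing.assert_allclose(v2, omega * v)
        np.testing.assert_allclose(x2, x + omega * v)

    def test_motion_toward_leader(self):
        rng = np.random.default_rng(1)
        x = np.array([0.0, 0.0])
        g = np.array([0.5, 0.5])
        omega, c = constriction(2.01)
        x2, v2 = velocity_position_update(
            x, np.zeros(2), x, g, omega, c, self.LB, self.UB, rng
        )
        assert np.all(v2 >= 0)  # step is toward the leader
        np.testing.assert_allclose(x2, np.clip(x + v2, self.LB, self.UB))

    def test_boundary_clamp_keeps_velocity(self):
        rng = np.random.default_rng(2)
        x = np.array([0.9, 0.0])
        v = np.array([5.0, 0.0])  # will push past UB
        omega, c = constriction(2.01)
        x2, v2 = velocity_position_update(x, v, x, x, omega, c, self.LB, self.UB, rng)
        assert x2[0] == self.UB[0]
        assert v2[0] == pytest.approx(omega * 5.0)  # velocity maintained


class TestParetoRepository:
    def test_dominated_candidate_rejected(self):
        repo = ParetoRepository(capacity=10, n_grid=5)
        rng = np.random.default_rng(0)
        repo.insert(np.array([0.0]), (0.1, 0.1), rng)
        assert not repo.insert(np.array([1.0]), (0.2, 0.2), rng)
        assert len(repo) == 1

    def test_dominating_candidate_evicts(self):
        repo = ParetoRepository(capacity=10, n_grid=5)
        rng = np.random.default_rng(0)
        repo.insert(np.array([0.0]), (0.3, 0.1), rng)
        repo.insert(np.array([1.0]), (0.1, 0.3), rng)
        assert repo.insert(np.array([2.0]), (0.05, 0.05), rng)
        assert len(repo) == 1
        np.testing.assert_allclose(repo.positions[0], [2.0])

    def test_equal_objectives_coexist(self):
        repo = ParetoRepository(capacity=10, n_grid=5)
        rng = np.random.default_rng(0)
        assert repo.insert(np.array([0.0]), (0.0, 0.0), rng)
        assert repo.insert(np.array([1.0]), (0.0, 0.0), rng)
        assert len(repo) == 2

    def test_stored_entries_are_copies(self):
        repo = ParetoRepository(capacity=10, n_grid=5)
        rng = np.random.default_rng(0)
        pos = np.array([0.5])
        objs = np.array([0.2, 0.2])
        repo.insert(pos, objs, rng)
        pos[0] = 99.0
        objs[0] = 99.0
        np.testing.assert_allclose(repo.positions[0], [0.5])
        np.testing.assert_allclose(repo.objectives[0], [0.2, 0.2])

    def test_capacity_enforced(self):
        repo = ParetoRepository(capacity=5, n_grid=4)
        rng = np.random.default_rng(1)
        # mutually non-dominated points along a front
        for i in range(12):
            f1 = i / 11
            repo.insert(np.array([float(i)]), (f1, 1.0 - f1), rng)
        assert len(repo) == 5
        assert repo.is_mutually_nondominated()

    def test_grid_single_entry(self):
        repo = ParetoRepository(capacity=10, n_grid=50)
        rng = np.random.default_rng(0)
        repo.insert(np.array([0.0]), (0.5, 0.5), rng)
        grid = repo.update_grid()
        assert grid.shape == (1, 2)
        assert np.all((grid >= 0) & (grid < 50))

    def test_grid_opposite_corners(self):
        repo = ParetoRepository(capacity=10, n_grid=50)
        rng = np.random.default_rng(0)
        repo.insert(np.array([0.0]), (0.0, 1.0), rng)
        repo.insert(np.array([1.0]), (1.0, 0.0), rng)
        grid = repo.update_grid()
        # 1% padding keeps extremes inside the first and last bins
        assert grid[0, 0] == 0 and grid[0, 1] == 49
        assert grid[1, 0] == 49 and grid[1, 1] == 0

    def test_select_leader_single_entry(self):
        repo = ParetoRepository(capacity=10, n_grid=5)
        rng = np.random.default_rng(0)
        repo.insert(np.array([3.0]), (0.5, 0.5), rng)
        np.testing.assert_allclose(repo.select_leader(rng), [3.0])

    def test_select_leader_empty(self):
        repo = ParetoRepository(capacity=10, n_grid=5)
        with pytest.raises(ValueError):
            repo.select_leader(np.random.default_rng(0))

    def test_leader_roulette_prefers_sparse_cells(self):
        # one entry in a sparse cell, nine clustered in a dense cell;
        # weights 1 and 1/9 give P(sparse) = 0.9
        repo = ParetoRepository(capacity=100, n_grid=2)
        repo.positions = [np.array([0.0])] + [np.array([float(i)]) for i in range(1, 10)]
        repo.objectives = [np.array([0.0, 1.0])] + [
            np.array([1.0, 0.0001 * i]) for i in range(9)
        ]
        repo.update_grid()
        rng = np.random.default_rng(42)
        hits = sum(
            1 for _ in range(10_000) if repo.select_leader(rng)[0] == 0.0
        )
        assert hits / 10_000 == pytest.approx(0.9, abs=0.02)


class TestPbestUpdate:
    def test_current_dominates(self):
        rng = np.random.default_rng(0)
        p, po, replaced = pbest_update(
            np.array([0.0]), np.array([0.5, 0.5]), np.array([1.0]), np.array([0.1, 0.1]), rng
        )
        assert replaced and p[0] == 1.0

    def test_pbest_dominates(self):
        rng = np.random.default_rng(0)
        p, po, replaced = pbest_update(
            np.array([0.0]), np.array([0.1, 0.1]), np.array([1.0]), np.array([0.5, 0.5]), rng
        )
        assert not replaced and p[0] == 0.0

    def test_tie_is_fair_coin(self):
        rng = np.random.default_rng(7)
        n = 10_000
        replaced = 0
        for _ in range(n):
            _, _, r = pbest_update(
                np.array([0.0]),
                np.array([0.1, 0.9]),
                np.array([1.0]),
                np.array([0.9, 0.1]),
                rng,
            )
            replaced += r
        assert replaced / n == pytest.approx(0.5, abs=0.05)


class TestDomainBounds:
    def test_mathematical(self):
        lb, ub = mathematical_domain_bounds()
        assert lb[0] == pytest.approx(math.log(1e-30))
        assert ub[0] == pytest.approx(math.log(1e-5))
        np.testing.assert_allclose(lb[1:], [0.1, 0.1])
        np.testing.assert_allclose(ub[1:], [20.0, 20.0])

    def test_literature(self):
        lb, ub = literature_domain_bounds()
        assert lb[0] == pytest.approx(math.log(1e-9))
        assert ub[0] == pytest.approx(math.log(1e-7))
        np.testing.assert_allclose(lb[1:], [1.5, 0.5])
        np.testing.assert_allclose(ub[1:], [2.5, 1.0])

    def test_config_validation(self):
        lb, ub = literature_domain_bounds()
        with pytest.raises(ValueError):
            MOPSOConfig(lb=ub, ub=lb)
        with pytest.raises(ValueError):
            MOPSOConfig(lb=lb, ub=ub, phi=2.0)
        with pytest.raises(ValueError):
            MOPSOConfig(lb=lb, ub=ub, n_particles=0)


def _bowl_config(seed=3):
    return MOPSOConfig(
        lb=np.array([-5.0, -5.0]),
        ub=np.array([5.0, 5.0]),
        n_particles=50,
        t_max=200,
        capacity=50,
        n_grid=10,
        seed=seed,
    )


class TestMopsoRun:
    def test_convex_bowl_degenerate_case(self):
        x0 = np.array([0.3, -0.7])

        def bowl(x):
            f = float(np.sum((x - x0) ** 2))
            return f, f

        repo = mopso_run(bowl, _bowl_config())
        best = min(repo.positions, key=lambda p: np.sum((p - x0) ** 2))
        assert np.linalg.norm(best - x0) < 1e-3

    def test_repository_invariants_and_bounds(self):
        def schaffer(x):
            return float(x[0] ** 2), float((x[0] - 2.0) ** 2)

        cfg = MOPSOConfig(
            lb=np.array([-5.0]), ub=np.array([10.0]),
            n_particles=20, t_max=50, capacity=30, n_grid=10, seed=3,
        )
        repo = mopso_run(schaffer, cfg)
        assert repo.is_mutually_nondominated()
        pos = repo.position_array()
        assert np.all(pos >= cfg.lb) and np.all(pos <= cfg.ub)

    def test_seed_reproducibility_bit_equal(self):
        def schaffer(x):
            return float(x[0] ** 2), float((x[0] - 2.0) ** 2)

        cfg = dict(
            lb=np.array([-5.0]), ub=np.array([10.0]),
            n_particles=20, t_max=50, capacity=30, n_grid=10, seed=11,
        )
        r1 = mopso_run(schaffer, MOPSOConfig(**cfg))
        r2 = mopso_run(schaffer, MOPSOConfig(**cfg))
        assert len(r1) == len(r2)
        np.testing.assert_array_equal(r1.position_array(), r2.position_array())
        np.testing.assert_array_equal(r1.objective_array(), r2.objective_array())

    def test_nonfinite_objective_raises(self):
        def bad(x):
            return float("nan"), 0.0

        with pytest.raises(RuntimeError, match="non-finite"):
            mopso_run(bad, _bowl_config())


class TestCombineRepositories:
    def test_union_refilters_dominance(self):
        rng = np.random.default_rng(0)
        r1 = ParetoRepository(capacity=10, n_grid=5)
        r1.insert(np.array([0.0]), (0.5, 0.5), rng)
        r2 = ParetoRepository(capacity=10, n_grid=5)
        r2.insert(np.array([1.0]), (0.1, 0.1), rng)
        merged = combine_repositories([r1, r2], seed=0)
        assert len(merged) == 1
        np.testing.assert_allclose(merged.positions[0], [1.0])

    def test_empty_list(self):
        with pytest.raises(ValueError):
            combine_repositories([])
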