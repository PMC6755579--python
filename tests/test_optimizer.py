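"""PSO velocity/position updates, BFGS, two-stage gating, swarm search."""

import numpy as np
import pytest
from scipy.optimize import minimize

from chaosdock.optimizer import (
    BoxObjective,
    Particle,
    SwarmConfig,
    bfgs_local_search,
    one_stage_local_search,
    position_update,
    pso_search,
    two_stage_local_search,
    velocity_update_chaotic,
    velocity_update_standard,
)
from chaosdock.synthetic import make_test_objective


class _StubStream:
    def __init__(self, values):
        self.values = list(values)

    def next_unit(self):
        return self.values.pop(0)


def _particle(x, v, pbest, pbest_score=np.inf, streams=None):
    w, r = streams or (None, None)
    return Particle(
        X=np.atleast_1d(np.asarray(x, float)),
        V=np.atleast_1d(np.asarray(v, float)),
        pbest_X=np.atleast_1d(np.asarray(pbest, float)),
        pbest_score=pbest_score,
        w_stream=w,
        r_stream=r,
    )


class _Counting(BoxObjective):
    """Objective wrapper logging every evaluation."""

    def __init__(self, inner):
        super().__init__(inner.dim, inner.lower, inner.upper)
        self.inner = inner
        self.log = []

    def value(self, x):
        v = self.inner.value(x)
        self.log.append(v)
        return v

    def gradient(self, x):
        return self.inner.gradient(x)


CFG = SwarmConfig(seed=0)


class TestVelocityUpdates:
    def test_equilibrium_is_stationary(self):
        p = _particle(1.0, 0.0, 1.0)
        v = velocity_update_standard(p, np.array([1.0]), CFG, 0.7, 0.2)
        assert np.allclose(v, 0.0)
        p = _particle(1.0, 0.0, 1.0, streams=(_StubStream([0.8]), _StubStream([0.3])))
        assert np.allclose(velocity_update_chaotic(p, np.array([1.0]), CFG), 0.0)

    def test_standard_hand_computed_1d(self):
        # w=0.36, c1=c2=0.99, V=1, X=0, pbest=1, gbest=2, r1=r2=1
        p = _particle(0.0, 1.0, 1.0)
        v = velocity_update_standard(p, np.array([2.0]), CFG, 1.0, 1.0)
        assert v[0] == pytest.approx(0.36 + 0.99 + 1.98, rel=1e-12)

    def test_standard_zero_randomness_keeps_inertia_only(self):
        p = _particle(0.0, 1.0, 1.0)
        v = velocity_update_standard(p, np.array([2.0]), CFG, 0.0, 0.0)
        assert v[0] == pytest.approx(0.36, rel=1e-12)

    def test_chaotic_hand_computed_1d(self):
        # injected w_cm=0.5, r_cm=0.25 -> 0.5*1 + 0.99*0.25*1 + 0.99*0.75*2
        p = _particle(0.0, 1.0, 1.0,
                      streams=(_StubStream([0.5]), _StubStream([0.25])))
        v = velocity_update_chaotic(p, np.array([2.0]), CFG)
        assert v[0] == pytest.approx(0.5 + 0.2475 + 1.485, rel=1e-12)

    def test_chaotic_draws_once_per_particle(self):
        w, r = _StubStream([0.5, 0.9]), _StubStream([0.25, 0.9])
        p = Particle(X=np.zeros(5), V=np.ones(5), pbest_X=np.ones(5),
                     pbest_score=0.0, w_stream=w, r_stream=r)
        velocity_update_chaotic(p, np.full(5, 2.0), CFG)
        assert len(w.values) == 1 and len(r.values) == 1  # one draw for 5 dims

    def test_position_update_clamps_and_wraps(self):
        obj = make_test_objective("sphere", dim=2, bounds=(-1.0, 1.0))
        p = _particle([0.9, 0.0], [0.0, 0.0], [0.0, 0.0])
        x = position_update(p, np.array([5.0, -0.25]), obj)
        assert x[0] == 1.0 and x[1] == -0.25


class TestBFGS:
    def test_starts_at_minimum_takes_no_steps(self):
        fun = lambda x: float((x[0] - 1) ** 2 + (x[1] - 2) ** 2)
        grad = lambda x: np.array([2 * (x[0] - 1), 2 * (x[1] - 2)])
        x, f, steps = bfgs_local_search(fun, grad, np.array([1.0, 2.0]), 100)
        assert steps == 0 and f == 0.0

    def test_quadratic_bowl(self):
        fun = lambda x: float((x[0] - 1) ** 2 + (x[1] - 2) ** 2)
        grad = lambda x: np.array([2 * (x[0] - 1), 2 * (x[1] - 2)])
        x, f, _ = bfgs_local_search(fun, grad, np.zeros(2), 100)
        assert np.allclose(x, [1.0, 2.0], atol=1e-6)

    def test_rosenbrock_matches_scipy_oracle(self):
        obj = make_test_objective("rosenbrock", dim=2)
        x0 = np.array([-1.2, 1.0])
        x, f, _ = bfgs_local_search(obj.value, obj.gradient, x0, 200)
        assert f < 1e-6
        ref = minimize(obj.value, x0, jac=obj.gradient, method="BFGS")
        assert np.allclose(x, ref.x, atol=1e-3)

    def test_nonfinite_objective_aborts(self):
        fun = lambda x: float("nan")
        grad = lambda x: np.zeros(1)
        x, f, steps = bfgs_local_search(fun, grad, np.array([3.0]), 50)
        assert steps == 0 and x[0] == 3.0


class TestTwoStageLocalSearch:
    def _cfg(self, **kw):
        return SwarmConfig(seed=0, **kw)

    def test_gating_blocks_stage_two(self):
        # Rosenbrock is slow enough that the stage-1 probe cannot converge
        inner = make_test_objective("rosenbrock", dim=2)
        obj = _Counting(inner)
        # pbest is already better than anything stage 1 can reach
        p = _particle([-1.2, 1.0], [0, 0], [1.0, 1.0], pbest_score=-1.0)
        improved = two_stage_local_search(p, obj, self._cfg(), full_steps=200)
        assert not improved
        n_gated = len(obj.log)
        # un-gated comparison: same start, hopeless pbest -> stage 2 runs
        obj2 = _Counting(inner)
        p2 = _particle([-1.2, 1.0], [0, 0], [1.0, 1.0], pbest_score=np.inf)
        assert two_stage_local_search(p2, obj2, self._cfg(), full_steps=200)
        assert len(obj2.log) > n_gated
        assert p2.pbest_score < 1e-6

    def test_improvement_updates_pbest(self):
        obj = make_test_objective("sphere", dim=2, bounds=(-5, 5), center=[1, 1])
        p = _particle([3.0, 3.0], [0, 0], [3.0, 3.0], pbest_score=8.0)
        assert two_stage_local_search(p, obj, self._cfg(), full_steps=60)
        assert p.pbest_score < 1e-8
        assert np.allclose(p.pbest_X, [1.0, 1.0], atol=1e-3)

    def test_ratio_one_equals_single_full_search(self):
        inner = make_test_objective("rosenbrock", dim=2)
        p0 = _particle([-1.2, 1.0], [0, 0], [-1.2, 1.0], pbest_score=np.inf)
        p1 = _particle([-1.2, 1.0], [0, 0], [-1.2, 1.0], pbest_score=np.inf)
        o0, o1 = _Counting(inner), _Counting(inner)
        two_stage_local_search(p0, o0, self._cfg(ls_ratio=1.0), full_steps=150)
        one_stage_local_search(p1, o1, self._cfg(), full_steps=150)
        assert p0.pbest_score == pytest.approx(p1.pbest_score, abs=1e-10)
        assert len(o0.log) == len(o1.log)

    def test_budget_never_exceeds_one_stage(self):
        """On a smooth bowl, 2LS costs at most the one-stage evaluations."""
        inner = make_test_objective("sphere", dim=4, bounds=(-5, 5), center=[0.5] * 4)
        for pbest_score in (np.inf, 1e-9):
            o2, o1 = _Counting(inner), _Counting(inner)
            p2 = _particle([4.0] * 4, [0] * 4, [4.0] * 4, pbest_score=pbest_score)
            p1 = _particle([4.0] * 4, [0] * 4, [4.0] * 4, pbest_score=pbest_score)
            two_stage_local_search(p2, o2, self._cfg(), full_steps=80)
            one_stage_local_search(p1, o1, self._cfg(), full_steps=80)
            assert len(o2.log) <= len(o1.log)


class TestPsoSearch:
    def test_sphere_recovered_over_seeds(self):
        obj = make_test_objective("sphere", dim=3, bounds=(-5, 5), center=[1.0, -2.0, 0.5])
        for seed in range(20):
            x, f, _ = pso_search(obj, SwarmConfig(seed=seed, max_generations=60))
            assert f < 1e-6
            assert np.abs(x - obj.minimum_x).max() < 1e-3

    def test_constant_objective_stalls_at_generation_two(self):
        class Flat(BoxObjective):
            def value(self, x):
                return 1.0

            def gradient(self, x):
                return np.zeros(self.dim)

        obj = Flat(2, -1.0, 1.0)
        _, f, gens = pso_search(obj, SwarmConfig(seed=1, stall_generations=1))
        assert gens == 2
        assert f == 1.0

    def test_reproducible_with_fixed_seed(self):
        for chaos in (None, "singer"):
            obj = make_test_objective("rastrigin", dim=2)
            cfg = SwarmConfig(seed=42, chaos_map=chaos, max_generations=25)
            r1 = pso_search(obj, cfg)
            r2 = pso_search(obj, cfg)
            assert np.array_equal(r1[0], r2[0])
            assert r1[1] == r2[1] and r1[2] == r2[2]

    def test_gbest_equals_minimum_evaluation_seen(self):
        inner = make_test_objective("rastrigin", dim=2)
        obj = _Counting(inner)
        _, f, _ = pso_search(obj, SwarmConfig(seed=3, max_generations=20))
        assert f == pytest.approx(min(obj.log), abs=1e-12)

    def test_gbest_history_monotone(self):
        obj = make_test_objective("rastrigin", dim=2)
        history = []
        pso_search(obj, SwarmConfig(seed=5, max_generations=30), history=history)
        scores = [h[1] for h in history]
        assert all(b <= a + 1e-15 for a, b in zip(scores, scores[1:]))
        assert len(scores) >= 2


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SwarmConfig(n_particles=0)
        with pytest.raises(ValueError):
            SwarmConfig(ls_ratio=0.0)
        with pytest.raises(ValueError):
            SwarmConfig(stall_generations=0)

    def test_none_string_normalized(self):
        assert SwarmConfig(chaos_map="none").chaos_map is None

    def test_baseline_mode(self):
        base = SwarmConfig().baseline()
        assert base.chaos_map is None and base.two_stage is False
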