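import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import reactopt as r
from reactopt.errors import ConfigurationError, DomainError
from reactopt.moo import BatchSelector, ObjectivePoint, ReferencePoint

# ---------------------------------------------------------------- oracles


def oracle_front(points):
    """O(n^2) double-loop dominance oracle (independent of the sweep)."""
    out = set()
    for i, p in enumerate(points):
        dominated = any(
            r.dominates(q, p) for j, q in enumerate(points) if j != i
        )
        duplicate = any(
            q.yield_pct == p.yield_pct and q.cost == p.cost
            for q in (points[j] for j in range(i))
        )
        if not dominated and not duplicate:
            out.add(i)
    return out


def oracle_hv_mc(points, ref, n=1_000_000, seed=0):
    """Monte-Carlo box-fraction hypervolume estimate."""
    rng = np.random.default_rng(seed)
    ys = rng.uniform(ref.yield_ref, max(p.yield_pct for p in points), size=n)
    cs = rng.uniform(min(p.cost for p in points), ref.cost_ref, size=n)
    box = (max(p.yield_pct for p in points) - ref.yield_ref) * (
        ref.cost_ref - min(p.cost for p in points)
    )
    dominated = np.zeros(n, dtype=bool)
    for p in points:
        dominated |= (ys <= p.yield_pct) & (cs >= p.cost)
    return box * dominated.mean()


def oracle_hv_gain(y, c, front, ref):
    """Independent HV gain of adding one point: strip integration over cost."""
    pts = [p for p in front] + [ObjectivePoint(y, c)]
    # integrate height over cost strips delimited by all cost breakpoints
    breaks = sorted({p.cost for p in pts} | {ref.cost_ref})
    breaks = [b for b in breaks if b <= ref.cost_ref]
    total = 0.0
    for lo, hi in zip(breaks, breaks[1:]):
        height = max(
            [p.yield_pct - ref.yield_ref for p in pts if p.cost <= lo] + [0.0]
        )
        total += height * (hi - lo)
    base_breaks = sorted({p.cost for p in front} | {ref.cost_ref})
    base = 0.0
    for lo, hi in zip(base_breaks, base_breaks[1:]):
        height = max(
            [p.yield_pct - ref.yield_ref for p in front if p.cost <= lo] + [0.0]
        )
        base += height * (hi - lo)
    return total - base


def oracle_ehvi_quadrature(mu, sd, c, front, ref, n_grid=20_001):
    """1-D quadrature EHVI oracle for a single Gaussian-yield candidate."""
    ys = np.linspace(mu - 8 * sd, mu + 8 * sd, n_grid)
    gains = np.array([oracle_hv_gain(y, c, front, ref) for y in ys])
    pdf = norm.pdf(ys, mu, sd)
    return np.trapezoid(gains * pdf, ys)


# ---------------------------------------------------------------- dominance


class TestDominates:
    def test_tradeoff_neither_dominates(self):
        a, b = ObjectivePoint(71, 2.19), ObjectivePoint(26, 1.40)
        assert not r.dominates(a, b) and not r.dominates(b, a)

    def test_equal_cost_higher_yield(self):
        assert r.dominates(ObjectivePoint(10, 1.25), ObjectivePoint(3, 1.25))

    def test_irreflexive(self):
        a = ObjectivePoint(50, 1.0)
        assert not r.dominates(a, a)

    def test_equal_both_neither_dominates(self):
        a, b = ObjectivePoint(5, 1.0), ObjectivePoint(5, 1.0)
        assert not r.dominates(a, b) and not r.dominates(b, a)


class TestParetoFront:
    def test_fixture_front_rows(self):
        from reactopt.io import load_training_fixture

        df = load_training_fixture()
        pts = [
            ObjectivePoint(y, c) for y, c in zip(df["yield_pct"], df["cost"])
        ]
        front = r.pareto_front(pts)
        assert sorted(i + 1 for i in front.indices) == [1, 9, 10, 14]
        assert oracle_front(pts) == set(front.indices)

    def test_single_point(self):
        front = r.pareto_front([ObjectivePoint(10, 1.0)])
        assert front.indices == [0]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_clouds_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = [
            ObjectivePoint(float(y), float(c))
            for y, c in zip(rng.uniform(0, 100, 200), rng.uniform(0.5, 3, 200))
        ]
        assert set(r.pareto_front(pts).indices) == oracle_front(pts)

    def test_order_by_cost_ascending(self):
        rng = np.random.default_rng(9)
        pts = [
            ObjectivePoint(float(y), float(c))
            for y, c in zip(rng.uniform(0, 100, 50), rng.uniform(0.5, 3, 50))
        ]
        front = r.pareto_front(pts)
        costs = [p.cost for p in front.points]
        assert costs == sorted(costs)

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        pts = [
            ObjectivePoint(float(y), float(c))
            for y, c in zip(rng.uniform(0, 100, 80), rng.uniform(0.5, 3, 80))
        ]
        once = r.pareto_front(pts)
        twice = r.pareto_front(once.points)
        assert twice.points == once.points


# ---------------------------------------------------------------- hypervolume


class TestHypervolume:
    REF = ReferencePoint(0.0, 3.0)

    def test_empty_front(self):
        assert r.hypervolume([], self.REF) == 0.0

    def test_single_rectangle(self):
        assert r.hypervolume([ObjectivePoint(50, 1.0)], self.REF) == 100.0

    def test_ref_not_dominated_rejected(self):
        with pytest.raises(DomainError):
            r.hypervolume([ObjectivePoint(50, 3.5)], self.REF)
        with pytest.raises(DomainError):
            r.hypervolume([ObjectivePoint(0.0, 1.0)], self.REF)

    @pytest.mark.parametrize("seed", range(3))
    def test_three_point_fronts_vs_mc(self, seed):
        rng = np.random.default_rng(seed)
        pts = [
            ObjectivePoint(float(y), float(c))
            for y, c in zip(rng.uniform(10, 90, 3), rng.uniform(0.5, 2.5, 3))
        ]
        hv = r.hypervolume(pts, self.REF)
        mc = oracle_hv_mc(pts, self.REF, seed=seed)
        assert hv == pytest.approx(mc, rel=0.005)

    def test_monotone_adding_nondominated_point(self):
        pts = [ObjectivePoint(50, 1.5)]
        hv0 = r.hypervolume(pts, self.REF)
        hv1 = r.hypervolume(pts + [ObjectivePoint(70, 2.0)], self.REF)
        assert hv1 > hv0

    def test_dominated_point_adds_nothing(self):
        pts = [ObjectivePoint(50, 1.5)]
        hv0 = r.hypervolume(pts, self.REF)
        hv1 = r.hypervolume(pts + [ObjectivePoint(30, 2.0)], self.REF)
        assert hv1 == pytest.approx(hv0)


# ---------------------------------------------------------------- EHVI


class TestJointEhvi:
    REF = ReferencePoint(0.0, 3.0)
    FRONT = [ObjectivePoint(60, 1.0), ObjectivePoint(80, 2.0)]

    def test_dominated_deterministic_candidates_zero(self):
        val = r.joint_ehvi(
            mu=[40.0, 50.0], sd=[0.0, 0.0], costs=[1.5, 2.5],
            front=self.FRONT, ref=self.REF, seed=0,
        )
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_nondominated_equals_hv_increment(self):
        cand = ObjectivePoint(90.0, 2.5)
        val = r.joint_ehvi(
            mu=[cand.yield_pct], sd=[0.0], costs=[cand.cost],
            front=self.FRONT, ref=self.REF, seed=0,
        )
        inc = r.hypervolume(self.FRONT + [cand], self.REF) - r.hypervolume(
            self.FRONT, self.REF
        )
        assert val == pytest.approx(inc)

    @pytest.mark.parametrize(
        "mu,sd,cost", [(70.0, 10.0, 1.5), (85.0, 5.0, 2.4), (55.0, 15.0, 0.8)]
    )
    def test_gaussian_case_vs_quadrature(self, mu, sd, cost):
        est = r.joint_ehvi(
            mu=[mu], sd=[sd], costs=[cost], front=self.FRONT, ref=self.REF,
            n_draws=4096, seed=3,
        )
        oracle = oracle_ehvi_quadrature(mu, sd, cost, self.FRONT, self.REF)
        assert est == pytest.approx(oracle, rel=0.01, abs=0.01)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            val = r.joint_ehvi(
                mu=rng.uniform(0, 100, 3), sd=rng.uniform(0, 10, 3),
                costs=rng.uniform(0.5, 2.9, 3), front=self.FRONT,
                ref=self.REF, n_draws=256, seed=int(rng.integers(1e6)),
            )
            assert val >= 0.0

    def test_mc_error_halves_from_1024_to_4096(self):
        mu, sd, cost = 75.0, 12.0, 1.5

        def spread(n_draws):
            vals = [
                r.joint_ehvi([mu], [sd], [cost], self.FRONT, self.REF,
                             n_draws=n_draws, seed=s)
                for s in range(40)
            ]
            return np.std(vals)

        ratio = spread(4096) / spread(1024)
        assert 0.3 < ratio < 0.75  # ~0.5 expected (1/sqrt(4))

    def test_empty_batch_rejected(self):
        with pytest.raises(ConfigurationError):
            r.joint_ehvi([], [], [], self.FRONT, self.REF)


# ---------------------------------------------------------------- batch select


def make_selector(mu, sd, costs, front, ref, n_draws=2048, seed=0):
    return BatchSelector(
        np.array(mu), np.array(sd), np.array(costs), front, ref,
        n_draws=n_draws, seed=seed,
    )


class TestSelectBatch:
    REF = ReferencePoint(0.0, 3.3)
    FRONT = [ObjectivePoint(50, 2.0)]

    def test_exhaustive_pool8_q2(self):
        rng = np.random.default_rng(2)
        sel = make_selector(
            rng.uniform(30, 90, 8), rng.uniform(2, 12, 8),
            rng.uniform(0.5, 3.0, 8), self.FRONT, self.REF,
        )
        idx, val, _ = sel.select(2)
        best = max(
            itertools.combinations(range(8), 2), key=lambda c: sel.joint(c)
        )
        assert set(idx) == set(best)
        assert val == pytest.approx(sel.joint(tuple(best)))

    def test_dominating_candidate_always_in_batch(self):
        mu = [95.0, 40.0, 45.0, 42.0]
        sd = [0.5, 0.5, 0.5, 0.5]
        costs = [0.5, 2.5, 2.6, 2.7]  # candidate 0 dominates everything
        sel = make_selector(mu, sd, costs, self.FRONT, self.REF)
        idx, _, _ = sel.select(2)
        assert 0 in idx

    def test_near_duplicates_avoided_for_diverse_pair(self):
        # two near-duplicate high-EHVI candidates + one diverse moderate one
        mu = [80.0, 80.0, 60.0]
        sd = [1.0, 1.0, 1.0]
        costs = [2.5, 2.5, 1.0]
        sel = make_selector(mu, sd, costs, self.FRONT, self.REF)
        idx, _, _ = sel.select(2)
        assert set(idx) in ({0, 2}, {1, 2})
        # verify against exhaustion that the diverse pair really wins
        vals = {c: sel.joint(c) for c in itertools.combinations(range(3), 2)}
        assert max(vals, key=vals.get) in ((0, 2), (1, 2))

    def test_greedy_beats_top_q_individual(self):
        rng = np.random.default_rng(7)
        n = 30
        sel = make_selector(
            rng.uniform(30, 95, n), rng.uniform(1, 15, n),
            rng.uniform(0.5, 3.2, n), self.FRONT, self.REF, n_draws=512,
        )
        idx, val, indiv = sel.select(3)
        topq = tuple(int(j) for j in np.argsort(-indiv)[:3])
        assert val >= sel.joint(topq) - 1e-12

    def test_pool_too_small(self):
        with pytest.raises(ConfigurationError):
            r.select_batch([1.0], [0.1], [1.0], self.FRONT, self.REF, q=2)


# ---------------------------------------------------------------- refinement


class QuadraticModel:
    """Deterministic toy surrogate peaking at x*: range-scaled quadratic, sd=0."""

    def __init__(self, space, target):
        self.target = np.asarray(target)
        self.ranges = np.array([v.upper - v.lower for v in space.continuous])

    def predict(self, X):
        X = np.asarray(X)[:, : len(self.target)]
        z = (X - self.target) / self.ranges
        return 100.0 - 100.0 * (z**2).sum(axis=1), np.zeros(len(X))


@pytest.fixture
def simple_space():
    disc = r.DiscreteVariable(
        "solvent", ("S0",), np.array([[0.1, 0.2, 0.3, 0.4, 0.5]]),
        ("sig0", "sig2", "sig3", "sig4", "sig5"),
    )
    return r.DesignSpace(continuous=r.default_bounds(), discrete=disc)


class TestRefineBatch:
    REF = ReferencePoint(0.0, 3.0)

    def test_quadratic_toy_reaches_known_maximizer(self, simple_space):
        from reactopt.space import ConditionEncoder

        enc = ConditionEncoder(simple_space)
        target = np.array([1.5, 1.5, 3.0, 0.5, 30.0, 30.0])
        model = QuadraticModel(simple_space, target)
        start = r.Condition(
            values=dict(zip(simple_space.variable_names,
                            [1.2, 1.8, 2.0, 0.8, 20.0, 45.0])),
            choice="S0",
        )
        refined = r.refine_batch(
            [start], model, enc, simple_space, [], self.REF,
            cost_fn=lambda c: 1.0, seed=0, n_draws=64, maxiter=200,
        )
        got = refined[0].as_array(simple_space.variable_names)
        # tolerance scaled per-variable by its range
        ranges = np.array([v.upper - v.lower for v in simple_space.continuous])
        assert np.all(np.abs(got - target) / ranges < 1e-3)

    def test_feasibility_always(self, simple_space):
        from reactopt.space import ConditionEncoder

        enc = ConditionEncoder(simple_space)
        model = QuadraticModel(simple_space, np.array([2.0, 2.0, 5.0, 1.0, 50.0, 60.0]))
        start = r.Condition(
            values=dict(zip(simple_space.variable_names,
                            [1.9, 1.9, 4.9, 0.95, 49.0, 59.0])),
            choice="S0",
        )
        refined = r.refine_batch(
            [start], model, enc, simple_space, [], self.REF,
            cost_fn=lambda c: 1.0, seed=0, n_draws=64, maxiter=50,
        )
        simple_space.validate_condition(refined[0])

    def test_fixed_point_unchanged(self, simple_space):
        from reactopt.space import ConditionEncoder

        enc = ConditionEncoder(simple_space)
        target = np.array([1.5, 1.5, 3.0, 0.5, 30.0, 30.0])
        model = QuadraticModel(simple_space, target)
        start = r.Condition(
            values=dict(zip(simple_space.variable_names, target)), choice="S0"
        )
        refined = r.refine_batch(
            [start], model, enc, simple_space, [], self.REF,
            cost_fn=lambda c: 1.0, seed=0, n_draws=64, maxiter=50,
        )
        got = refined[0].as_array(simple_space.variable_names)
        assert np.allclose(got, target, atol=1e-6)


@settings(max_examples=30, deadline=None)
@given(st.lists(
    st.tuples(st.floats(0.1, 100), st.floats(0.1, 3)), min_size=1, max_size=40,
))
def test_front_matches_oracle_property(pairs):
    pts = [ObjectivePoint(y, c) for y, c in pairs]
    assert set(r.pareto_front(pts).indices) == oracle_front(pts)
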