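"""Pareto dominance, 2-D hypervolume, joint batch EHVI and batch refinement.

Objectives are fixed-orientation throughout: yield (%) is maximized and
cost is minimized.  Yield is the stochastic black-box objective — inside
the acquisition it is sampled from each candidate's predictive normal
distribution — while cost is an analytic, noiseless function of the
condition.  Hypervolume is exact (sorted sweep); expected hypervolume
improvement of a batch is a Monte-Carlo estimate under common random
numbers so batches compared under the same seed share draws.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .errors import ConfigurationError, DomainError
from .space import Condition, DesignSpace

__all__ = [
    "ObjectivePoint",
    "ParetoFront",
    "ReferencePoint",
    "dominates",
    "pareto_front",
    "hypervolume",
    "joint_ehvi",
    "BatchSelector",
    "select_batch",
    "refine_batch",
]

logger = logging.getLogger(__name__)

#: Exhaustive batch enumeration is used when C(pool, q) is at most this.
EXHAUSTIVE_LIMIT = 100_000


@dataclass(frozen=True)
class ObjectivePoint:
    yield_pct: float  # maximize
    cost: float  # minimize


@dataclass(frozen=True)
class ReferencePoint:
    yield_ref: float  # strictly below every yield of interest
    cost_ref: float  # strictly above every cost of interest


@dataclass
class ParetoFront:
    """Nondominated subset, ordered by cost ascending, with source indices."""

    points: list[ObjectivePoint]
    indices: list[int]

    def __len__(self) -> int:
        return len(self.points)


def dominates(a: ObjectivePoint, b: ObjectivePoint) -> bool:
    """True iff ``a`` is at least as good in both objectives and better in one."""
    return (
        a.yield_pct >= b.yield_pct
        and a.cost <= b.cost
        and (a.yield_pct > b.yield_pct or a.cost < b.cost)
    )


def pareto_front(points: list[ObjectivePoint]) -> ParetoFront:
    """Exact nondominated subset via a cost-sorted sweep (ties collapse)."""
    if not points:
        raise ConfigurationError("need at least one point")
    order = sorted(
        range(len(points)), key=lambda i: (points[i].cost, -points[i].yield_pct)
    )
    front_idx: list[int] = []
    best_yield = -math.inf
    for i in order:
        p = points[i]
        if p.yield_pct > best_yield:
            front_idx.append(i)
            best_yield = p.yield_pct
        # equal-yield/equal-cost duplicates collapse onto the first occurrence
    return ParetoFront([points[i] for i in front_idx], front_idx)


def _hv_arrays(
    yields: np.ndarray, costs: np.ndarray, ref: ReferencePoint
) -> np.ndarray:
    """Vectorized 2-D hypervolume for (..., m) yield realizations.

    ``costs`` has shape (m,) and is shared across realizations (cost is
    deterministic).  Points outside the reference box contribute nothing.
    """
    if costs.size == 0:
        return np.zeros(yields.shape[:-1])
    order = np.argsort(costs, kind="stable")
    cs = np.minimum(costs[order], ref.cost_ref)
    heights = np.maximum(
        np.maximum.accumulate(yields[..., order], axis=-1) - ref.yield_ref, 0.0
    )
    widths = np.diff(np.append(cs, ref.cost_ref))
    return (heights * widths).sum(axis=-1)


def hypervolume(points: list[ObjectivePoint], ref: ReferencePoint) -> float:
    """Exact area dominated by the front of ``points`` and bounded by ``ref``.

    ``ref`` must be strictly worse than every point (below in yield, above
    in cost) or a :class:`DomainError` is raised.  Empty input yields 0.
    """
    if not points:
        return 0.0
    ys = np.array([p.yield_pct for p in points], dtype=float)
    cs = np.array([p.cost for p in points], dtype=float)
    if np.any(ys <= ref.yield_ref) or np.any(cs >= ref.cost_ref):
        raise DomainError("reference point must be strictly worse than all points")
    return float(_hv_arrays(ys, cs, ref))


def joint_ehvi(
    mu: np.ndarray,
    sd: np.ndarray,
    costs: np.ndarray,
    front: list[ObjectivePoint],
    ref: ReferencePoint,
    n_draws: int = 1024,
    seed: int | None = None,
    z: np.ndarray | None = None,
) -> float:
    """Monte-Carlo joint EHVI of a candidate batch.

    Yields are drawn independently per candidate from N(mu_i, sd_i); costs
    are deterministic.  Pass ``z`` (standard-normal draws, shape
    ``(n_draws, q)``) to reuse common random numbers across comparisons.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sd = np.atleast_1d(np.asarray(sd, dtype=float))
    costs = np.atleast_1d(np.asarray(costs, dtype=float))
    q = mu.size
    if q == 0:
        raise ConfigurationError("batch must contain at least one candidate")
    if z is None:
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((n_draws, q))
    samples = mu + sd * z  # (n_draws, q)
    front_y = np.array([p.yield_pct for p in front], dtype=float)
    front_c = np.array([p.cost for p in front], dtype=float)
    all_c = np.concatenate([front_c, costs])
    all_y = np.concatenate(
        [np.broadcast_to(front_y, (samples.shape[0], front_y.size)), samples], axis=1
    )
    hv_base = float(_hv_arrays(front_y, front_c, ref)) if front else 0.0
    hv_aug = _hv_arrays(all_y, all_c, ref)
    return float(np.mean(hv_aug) - hv_base)


class BatchSelector:
    """Joint-EHVI batch selection over a fixed candidate pool with CRN.

    One matrix of standard-normal draws (``n_draws`` × pool size) is drawn
    up front; every batch evaluated during the search reuses the columns of
    its members, so joint-EHVI comparisons are under common random numbers.
    """

    def __init__(
        self,
        mu: np.ndarray,
        sd: np.ndarray,
        costs: np.ndarray,
        front: list[ObjectivePoint],
        ref: ReferencePoint,
        n_draws: int = 1024,
        seed: int | None = None,
    ) -> None:
        self.mu = np.asarray(mu, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.costs = np.asarray(costs, dtype=float)
        self.ref = ref
        self.front_y = np.array([p.yield_pct for p in front], dtype=float)
        self.front_c = np.array([p.cost for p in front], dtype=float)
        rng = np.random.default_rng(seed)
        self.samples = self.mu + self.sd * rng.standard_normal(
            (n_draws, self.mu.size)
        )
        self.hv_base = (
            float(_hv_arrays(self.front_y, self.front_c, ref)) if front else 0.0
        )
        self.n_draws = n_draws

    def joint(self, idx: tuple[int, ...]) -> float:
        """Joint EHVI of the batch given by pool indices (CRN)."""
        ii = np.asarray(idx, dtype=int)
        all_c = np.concatenate([self.front_c, self.costs[ii]])
        all_y = np.concatenate(
            [
                np.broadcast_to(self.front_y, (self.n_draws, self.front_y.size)),
                self.samples[:, ii],
            ],
            axis=1,
        )
        return float(np.mean(_hv_arrays(all_y, all_c, self.ref)) - self.hv_base)

    def individual(self) -> np.ndarray:
        """Single-candidate EHVI for every pool member (diagnostics)."""
        return np.array([self.joint((j,)) for j in range(self.mu.size)])

    def select(self, q: int) -> tuple[list[int], float, np.ndarray]:
        """Pick a batch of ``q`` pool indices maximizing joint EHVI.

        Exhaustive when C(pool, q) <= :data:`EXHAUSTIVE_LIMIT`; otherwise
        greedy construction followed by pairwise swap hill-climbing.  The
        top-q individual-EHVI batch is always evaluated too, and the best
        batch visited anywhere in the search is returned.
        """
        n = self.mu.size
        if q < 1 or q > n:
            raise ConfigurationError(f"batch size q={q} invalid for pool of {n}")
        indiv = self.individual()
        best_idx: tuple[int, ...] | None = None
        best_val = -math.inf

        def consider(idx: tuple[int, ...]) -> float:
            nonlocal best_idx, best_val
            val = self.joint(idx)
            if val > best_val:
                best_val, best_idx = val, tuple(idx)
            return val

        if math.comb(n, q) <= EXHAUSTIVE_LIMIT:
            for combo in itertools.combinations(range(n), q):
                consider(combo)
            return list(best_idx), best_val, indiv

        # top-q individual candidates as a baseline batch
        consider(tuple(int(j) for j in np.argsort(-indiv)[:q]))

        # greedy construction (partial batches scored with the same CRN draws)
        chosen: list[int] = []
        for _ in range(q):
            j_best, v_best = -1, -math.inf
            for j in range(n):
                if j in chosen:
                    continue
                v = self.joint(tuple(chosen + [j]))
                if v > v_best:
                    v_best, j_best = v, j
            chosen.append(j_best)
        consider(tuple(chosen))

        # pairwise swap hill-climbing from the best full batch so far
        batch = list(best_idx)
        cur = best_val
        improved, passes = True, 0
        while improved and passes < 3:
            improved = False
            passes += 1
            for pos in range(q):
                for j in range(n):
                    if j in batch:
                        continue
                    trial = batch.copy()
                    trial[pos] = j
                    v = consider(tuple(trial))
                    if v > cur + 1e-15:
                        batch, cur = trial, v
                        improved = True
        return list(best_idx), best_val, indiv


def select_batch(
    mu: np.ndarray,
    sd: np.ndarray,
    costs: np.ndarray,
    front: list[ObjectivePoint],
    ref: ReferencePoint,
    q: int = 5,
    n_draws: int = 1024,
    seed: int | None = None,
) -> list[int]:
    """Convenience wrapper: joint-EHVI batch of pool indices."""
    if len(np.atleast_1d(mu)) < q:
        raise ConfigurationError("candidate pool smaller than batch size")
    sel = BatchSelector(mu, sd, costs, front, ref, n_draws=n_draws, seed=seed)
    idx, _, _ = sel.select(q)
    return idx


def refine_batch(
    batch: list[Condition],
    model,
    encoder,
    space: DesignSpace,
    front: list[ObjectivePoint],
    ref: ReferencePoint,
    cost_fn,
    seed: int | None = None,
    n_draws: int = 512,
    maxiter: int = 30,
) -> list[Condition]:
    """Local joint-EHVI refinement of the continuous coordinates.

    Solvent choices stay fixed per point; continuous coordinates move within
    the (override-aware) bounds via L-BFGS-B on the negative joint EHVI
    under a fixed draw matrix (common random numbers).  Falls back to the
    input batch if the optimizer does not improve the joint EHVI.
    """
    q = len(batch)
    var_names = [v.name for v in space.continuous]
    d = len(var_names)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, q))

    bounds01 = []
    lohi = []
    for cond in batch:
        b = space.bounds_for(cond.choice)
        lohi.append(b)
        bounds01.extend([(0.0, 1.0)] * d)

    def to_conditions(x: np.ndarray) -> list[Condition]:
        out = []
        for i, cond in enumerate(batch):
            vals = {}
            for j, name in enumerate(var_names):
                lo, hi = lohi[i][j]
                vals[name] = lo + float(np.clip(x[i * d + j], 0.0, 1.0)) * (hi - lo)
            out.append(Condition(values=vals, choice=cond.choice))
        return out

    def ehvi_of(conds: list[Condition]) -> float:
        X = encoder.transform(conds)
        mu, sd = model.predict(X)
        costs = np.array([cost_fn(c) for c in conds])
        return joint_ehvi(mu, sd, costs, front, ref, z=z)

    x0 = np.empty(q * d)
    for i, cond in enumerate(batch):
        for j, name in enumerate(var_names):
            lo, hi = lohi[i][j]
            x0[i * d + j] = (cond.values[name] - lo) / (hi - lo)

    base_val = ehvi_of(batch)
    try:
        res = minimize(
            lambda x: -ehvi_of(to_conditions(x)),
            x0,
            method="L-BFGS-B",
            bounds=bounds01,
            options={"maxiter": maxiter},
        )
        refined = to_conditions(res.x)
        refined_val = ehvi_of(refined)
    except Exception:  # pragma: no cover - defensive fallback
        logger.exception("refinement failed; returning input batch")
        return batch
    if refined_val >= base_val:
        return refined
    logger.debug("refinement did not improve joint EHVI (%.4g < %.4g)",
                 refined_val, base_val)
    return batch
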