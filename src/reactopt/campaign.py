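"""Closed-loop optimization campaign and the pool-based benchmark harness.

One iteration of the loop: select the best surrogate family by seeded CV,
sample a fresh stratified-LHS candidate pool, pick a batch by joint EHVI,
refine it locally, hand the batch out for evaluation, and fold measured
results back in.  A master seed fans out deterministically to every source
of randomness (LHS, CV folds, MC draws, search), so the whole loop is
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BoundsError, ConfigurationError
from .moo import (
    BatchSelector,
    ObjectivePoint,
    ReferencePoint,
    _hv_arrays,
    joint_ehvi,
    pareto_front,
    refine_batch,
)
from .solvents import PriceTable, reaction_cost
from .space import Condition, ConditionEncoder, DesignSpace, lhs_sample
from .surrogates import FAMILIES, ModelReport, TrainingSet, select_best

__all__ = [
    "CampaignConfig",
    "CampaignState",
    "StoppingDecision",
    "derive_seed",
    "initialize",
    "propose",
    "update",
    "check_stopping",
    "pool_benchmark",
    "run_simulated_campaign",
]


def derive_seed(master: int, *tags: int) -> int:
    """Deterministic sub-seed derivation from the master seed."""
    return int(np.random.SeedSequence([master, *tags]).generate_state(1)[0])


@dataclass(frozen=True)
class CampaignConfig:
    featurization: str = "raw_descriptors"
    n_components: int = 3
    families: tuple[str, ...] = ("gaussian_process", "gbdt_ensemble")
    q: int = 5
    pool_per_solvent: int = 200
    n_draws: int = 512
    n_hyper: int = 0
    folds: int = 5
    refine_maxiter: int = 20
    ref_yield: float = 0.0
    ref_cost_factor: float = 1.1
    noise_sd: float = 1.8
    limiting_mmol: float = 0.2
    solvent_volume_L: float = 0.005
    base_concentration_mM: float = 40.0


@dataclass
class StoppingDecision:
    stop: bool
    reasons: set[str]


@dataclass
class CampaignState:
    space: DesignSpace
    prices: PriceTable
    config: CampaignConfig
    master_seed: int
    conditions: list[Condition] = field(default_factory=list)
    objectives: list[ObjectivePoint] = field(default_factory=list)
    pending: list[Condition] = field(default_factory=list)
    iteration: int = 0
    hv_history: list[float] = field(default_factory=list)
    front_history: list[tuple[int, ...]] = field(default_factory=list)
    model_reports: list[list[ModelReport]] = field(default_factory=list)
    #: catalyst solubility (mmol/L) per solvent, for proposal clamping
    catalyst_solubility: dict[str, float] = field(default_factory=dict)
    last_diagnostics: dict = field(default_factory=dict)

    @property
    def front(self):
        return pareto_front(self.objectives) if self.objectives else None

    def reference_point(self) -> ReferencePoint:
        """Data-driven reference: yield 0, cost 1.1x the max observed cost."""
        if not self.objectives:
            raise ConfigurationError("no evaluated points yet")
        max_cost = max(p.cost for p in self.objectives)
        return ReferencePoint(
            self.config.ref_yield, self.config.ref_cost_factor * max_cost
        )

    def cost_of(self, condition: Condition) -> float:
        return reaction_cost(
            condition, self.prices, self.config.limiting_mmol,
            self.config.solvent_volume_L,
        )


def _hv_box(points: list[ObjectivePoint], ref: ReferencePoint) -> float:
    """Hypervolume clipped to the reference box (no domination precondition)."""
    if not points:
        return 0.0
    ys = np.array([p.yield_pct for p in points])
    cs = np.array([p.cost for p in points])
    return float(_hv_arrays(ys, cs, ref))


def initialize(
    space: DesignSpace,
    prices: PriceTable,
    config: CampaignConfig,
    n_init: int,
    seed: int,
    catalyst_solubility: dict[str, float] | None = None,
) -> CampaignState:
    """New campaign with a stratified LHS design awaiting evaluation."""
    n_vars = len(space.continuous)
    if n_init < 2 * n_vars:
        warnings.warn(
            f"n_init={n_init} below 2x the number of variables ({2 * n_vars})",
            stacklevel=2,
        )
    state = CampaignState(
        space=space, prices=prices, config=config, master_seed=seed,
        catalyst_solubility=dict(catalyst_solubility or {}),
    )
    state.pending = lhs_sample(space, n_init, derive_seed(seed, 0, 0))
    return state


def _clamp_catalyst(state: CampaignState, cond: Condition) -> tuple[Condition, bool]:
    """Clamp catalyst mol% to the solubility-implied cap for its solvent."""
    sol = state.catalyst_solubility.get(cond.choice)
    if sol is None:
        return cond, False
    cap = 100.0 * sol / state.config.base_concentration_mM
    lo = state.space._var("catalyst_molpct").lower
    cap = max(cap, lo)
    if cond.values["catalyst_molpct"] <= cap:
        return cond, False
    vals = dict(cond.values)
    vals["catalyst_molpct"] = cap
    return Condition(values=vals, choice=cond.choice), True


def propose(state: CampaignState, q: int | None = None,
            seed: int | None = None) -> list[Condition]:
    """Next batch: model selection -> LHS pool -> joint EHVI -> refinement."""
    cfg = state.config
    q = q if q is not None else cfg.q
    if len(state.conditions) < 5:
        raise ConfigurationError("need at least 5 evaluated points to propose")
    base = seed if seed is not None else derive_seed(
        state.master_seed, 1, state.iteration
    )

    encoder = ConditionEncoder(state.space, cfg.featurization, cfg.n_components)
    data = TrainingSet(
        encoder.transform(state.conditions),
        np.array([p.yield_pct for p in state.objectives]),
        meta={"featurization": cfg.featurization,
              "variables": list(state.space.variable_names)},
    )
    model, best_report, reports = select_best(
        data, cfg.families, seed=derive_seed(base, 1), folds=cfg.folds,
        n_hyper=cfg.n_hyper,
    )
    state.model_reports.append(reports)

    front_pts = state.front.points
    ref = state.reference_point()

    n_choices = len(state.space.discrete.choices)
    pool = lhs_sample(
        state.space, cfg.pool_per_solvent * n_choices, derive_seed(base, 2)
    )
    if q > len(pool):
        raise ConfigurationError(
            f"batch size q={q} exceeds candidate pool of {len(pool)}"
        )
    mu, sd = model.predict(encoder.transform(pool))
    costs = np.array([state.cost_of(c) for c in pool])
    selector = BatchSelector(
        mu, sd, costs, front_pts, ref, n_draws=cfg.n_draws,
        seed=derive_seed(base, 3),
    )
    idx, joint_before, indiv = selector.select(q)
    batch = [pool[i] for i in idx]

    refined = refine_batch(
        batch, model, encoder, state.space, front_pts, ref, state.cost_of,
        seed=derive_seed(base, 4), n_draws=cfg.n_draws,
        maxiter=cfg.refine_maxiter,
    )
    mu_r, sd_r = model.predict(encoder.transform(refined))
    joint_after = joint_ehvi(
        mu_r, sd_r, np.array([state.cost_of(c) for c in refined]), front_pts,
        ref, n_draws=cfg.n_draws, seed=derive_seed(base, 4),
    )

    proposals, clamped_flags = [], []
    for cond in refined:
        cond, clamped = _clamp_catalyst(state, cond)
        proposals.append(cond)
        clamped_flags.append(clamped)
        state.space.validate_condition(cond)

    state.pending = proposals
    state.last_diagnostics = {
        "iteration": state.iteration,
        "selected_family": best_report.family,
        "cv_rmse": best_report.cv_rmse,
        "cv_r2": best_report.cv_r2,
        "pool_size": len(pool),
        "joint_ehvi_selected": joint_before,
        "joint_ehvi_refined": joint_after,
        "individual_ehvi": [float(v) for v in indiv],
        "individual_ehvi_top": float(np.max(indiv)),
        "batch_indices": list(map(int, idx)),
        "catalyst_clamped": clamped_flags,
        "reference_point": (ref.yield_ref, ref.cost_ref),
    }
    return proposals


def update(
    state: CampaignState,
    conditions: list[Condition],
    measured: list[ObjectivePoint],
) -> CampaignState:
    """Append measured results, recompute front and HV, advance iteration."""
    if len(conditions) != len(measured):
        raise ConfigurationError("conditions and objectives must align")
    for cond in conditions:
        if any(cond == prev for prev in state.conditions):
            warnings.warn(f"duplicate condition for {cond.choice}; kept as replicate",
                          stacklevel=2)
        try:
            state.space.validate_condition(cond)
        except BoundsError as exc:
            # measured facts are kept even when outside the declared bounds
            warnings.warn(f"evaluated condition outside bounds: {exc}", stacklevel=2)
    state.conditions.extend(conditions)
    state.objectives.extend(measured)
    pending_left = [p for p in state.pending if p not in conditions]
    state.pending = pending_left
    ref = state.reference_point()
    front = pareto_front(state.objectives)
    state.hv_history.append(_hv_box(front.points, ref))
    state.front_history.append(tuple(sorted(front.indices)))
    state.iteration += 1
    return state


def check_stopping(
    state: CampaignState,
    hv_rel_tol: float = 0.01,
    patience: int = 2,
    rmse_factor: float = 2.0,
) -> StoppingDecision:
    """Three-criterion stopping rule.

    ``hv_converged``: relative HV improvement below ``hv_rel_tol`` for
    ``patience`` consecutive iterations.  ``model_accurate``: latest selected
    model's CV RMSE at or below ``rmse_factor`` times the configured noise
    sd.  ``front_stable`` (advisory): front membership unchanged over
    ``patience`` iterations.  Stop iff converged AND accurate.
    """
    if state.iteration < 2 or len(state.hv_history) < 2:
        raise ConfigurationError("need at least 2 iterations of history")
    reasons: set[str] = set()

    hv = state.hv_history
    n_checks = min(patience, len(hv) - 1)
    rels = []
    for t in range(len(hv) - n_checks, len(hv)):
        prev = hv[t - 1]
        rels.append((hv[t] - prev) / prev if prev > 0 else np.inf)
    if n_checks >= patience and all(r < hv_rel_tol for r in rels):
        reasons.add("hv_converged")

    if state.model_reports:
        order = {f: i for i, f in enumerate(state.config.families)}
        latest = min(
            state.model_reports[-1],
            key=lambda r: (r.cv_rmse, -r.cv_r2, order.get(r.family, 99)),
        )
        if latest.cv_rmse <= rmse_factor * state.config.noise_sd:
            reasons.add("model_accurate")

    if len(state.front_history) > patience and len(
        set(state.front_history[-(patience + 1):])
    ) == 1:
        reasons.add("front_stable")

    stop = "hv_converged" in reasons and "model_accurate" in reasons
    return StoppingDecision(stop=stop, reasons=reasons)


def pool_benchmark(
    conditions: list[Condition],
    objectives: list[ObjectivePoint],
    space: DesignSpace,
    init_indices: list[int],
    acquisition: str = "ehvi",
    seeds: tuple[int, ...] = (0,),
    family: str = "gaussian_process",
    featurization: str = "raw_descriptors",
    n_draws: int = 256,
    ref_cost_factor: float = 1.1,
) -> pd.DataFrame:
    """Replay an acquisition strategy against a fixed evaluated pool.

    One point is sampled per iteration (q=1) without replacement until the
    pool is exhausted; the surrogate is refit after every sample.  Returns a
    tidy frame with columns (seed, step, hv, acquisition), where ``step`` is
    the total number of sampled points and ``hv`` is measured against a
    fixed reference derived from the full pool.
    """
    if acquisition not in ("ehvi", "random"):
        raise ConfigurationError(f"unknown acquisition {acquisition!r}")
    n = len(conditions)
    if len(objectives) != n:
        raise ConfigurationError("pool conditions/objectives must align")
    init = sorted(set(int(i) for i in init_indices))
    if not init or init[0] < 0 or init[-1] >= n:
        raise ConfigurationError("init subset must be valid pool indices")

    ref = ReferencePoint(0.0, ref_cost_factor * max(p.cost for p in objectives))
    encoder = ConditionEncoder(space, featurization)
    X_all = encoder.transform(conditions)
    y_all = np.array([p.yield_pct for p in objectives])
    costs_all = np.array([p.cost for p in objectives])

    records = []
    for seed in seeds:
        rng = np.random.default_rng(derive_seed(seed, 11))
        sampled = list(init)
        remaining = [i for i in range(n) if i not in set(init)]
        records.append(
            {"seed": seed, "step": len(sampled), "acquisition": acquisition,
             "hv": _hv_box([objectives[i] for i in sampled], ref)}
        )
        step = len(sampled)
        while remaining:
            if acquisition == "ehvi":
                from .surrogates import TrainingSet, fit as fit_family

                model = fit_family(
                    family, TrainingSet(X_all[sampled], y_all[sampled]),
                    seed=derive_seed(seed, 12, step),
                )
                mu, sd = model.predict(X_all[remaining])
                front = pareto_front([objectives[i] for i in sampled])
                sel = BatchSelector(
                    mu, sd, costs_all[remaining], front.points, ref,
                    n_draws=n_draws, seed=derive_seed(seed, 13, step),
                )
                pick = remaining[int(np.argmax(sel.individual()))]
            else:
                pick = remaining[int(rng.integers(len(remaining)))]
            sampled.append(pick)
            remaining.remove(pick)
            step += 1
            records.append(
                {"seed": seed, "step": step, "acquisition": acquisition,
                 "hv": _hv_box([objectives[i] for i in sampled], ref)}
            )
    return pd.DataFrame.from_records(records)


def run_simulated_campaign(
    space: DesignSpace,
    simulator,
    prices: PriceTable,
    config: CampaignConfig,
    n_init: int,
    n_iterations: int,
    seed: int,
    proposer: str = "ehvi",
    catalyst_solubility: dict[str, float] | None = None,
) -> CampaignState:
    """Convenience closed loop against a simulator (ehvi or uniform-random)."""
    state = initialize(space, prices, config, n_init, seed,
                       catalyst_solubility=catalyst_solubility)
    counter = 0

    def evaluate(conds: list[Condition]) -> list[ObjectivePoint]:
        nonlocal counter
        out = []
        for c in conds:
            out.append(ObjectivePoint(
                yield_pct=simulator.observe_yield(
                    c, derive_seed(seed, 5, counter)),
                cost=state.cost_of(c),
            ))
            counter += 1
        return out

    update(state, state.pending, evaluate(state.pending))
    for _ in range(n_iterations):
        if proposer == "ehvi":
            batch = propose(state)
        else:
            rng = np.random.default_rng(derive_seed(seed, 6, state.iteration))
            batch = []
            for _j in range(config.q):
                choice = space.discrete.choices[
                    int(rng.integers(len(space.discrete.choices)))
                ]
                vals = {
                    v.name: float(rng.uniform(lo, hi))
                    for v, (lo, hi) in zip(space.continuous,
                                           space.bounds_for(choice))
                }
                batch.append(Condition(values=vals, choice=choice))
        update(state, batch, evaluate(batch))
    return state
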