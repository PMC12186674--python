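"""Synthetic ground truth standing in for the flow reactor.

The yield surface is a response-surface stand-in, not a mechanistic model:
yield is driven by the absorbed photon dose — the *product* of catalyst
loading and residence time — saturating toward a plateau, rises with
alkene and hydride-donor equivalents with diminishing returns, carries
mild positive acid/temperature effects, and falls with the solvent's
s-profile asymmetry descriptor (sig3).  Observations add homoscedastic
Gaussian replicate noise (default sd 1.8%) and clip to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .moo import ObjectivePoint
from .solvents import (
    DEFAULT_DESCRIPTOR_NAMES,
    PriceTable,
    SolventRecord,
    reaction_cost,
)
from .space import Condition, DesignSpace, lhs_sample

__all__ = [
    "GroundTruthParams",
    "SyntheticPool",
    "ReactionSimulator",
    "make_library",
    "make_pool",
    "default_price_table",
]


@dataclass(frozen=True)
class GroundTruthParams:
    y_max: float = 85.0  # plateau yield, %
    dose_scale: float = 30.0  # saturation constant for catalyst_molpct * time_min
    sig3_slope: float = 0.25  # yield penalty per unit standardized sig3
    sig3_offset: float = 2.0  # shifts the penalty so low-sig3 solvents stay < 1
    alkene_exp: float = 0.35
    he_exp: float = 0.45
    acid_slope: float = 0.05
    temp_slope: float = 0.05
    noise_sd: float = 1.8  # replicate noise, %

    def __post_init__(self) -> None:
        if not 0 < self.y_max <= 100:
            raise ConfigurationError("y_max must be in (0, 100]")
        if self.noise_sd < 0 or self.dose_scale <= 0:
            raise ConfigurationError("noise_sd >= 0 and dose_scale > 0 required")


@dataclass
class SyntheticPool:
    conditions: list[Condition]
    objectives: list[ObjectivePoint]
    params: GroundTruthParams
    seed: int

    def __len__(self) -> int:
        return len(self.conditions)


def yield_surface(
    alkene_eq: float,
    he_eq: float,
    catalyst_molpct: float,
    acid_eq: float,
    temp_C: float,
    time_min: float,
    sig3_z: float,
    params: GroundTruthParams,
) -> float:
    """Noiseless yield (%) at explicit coordinates; ``sig3_z`` standardized."""
    dose = catalyst_molpct * time_min
    sat = dose / (dose + params.dose_scale)
    phi_alkene = (alkene_eq / 2.0) ** params.alkene_exp
    phi_he = (he_eq / 2.0) ** params.he_exp
    phi_acid_t = min(
        1.0,
        0.9
        + params.acid_slope * (acid_eq - 0.1) / 0.9
        + params.temp_slope * (temp_C - 10.0) / 40.0,
    )
    psi = float(
        np.clip(1.0 - params.sig3_slope * (sig3_z + params.sig3_offset), 0.0, 1.0)
    )
    y = params.y_max * sat * phi_alkene * phi_he * phi_acid_t * psi
    return float(np.clip(y, 0.0, 100.0))


class ReactionSimulator:
    """Evaluates conditions of a design space against the synthetic surface.

    The sig3 descriptor is standardized over the space's own solvent set so
    the penalty term is scale-free with respect to the library generator.
    """

    def __init__(
        self,
        space: DesignSpace,
        params: GroundTruthParams | None = None,
        sig3_name: str = "sig3",
    ) -> None:
        self.space = space
        self.params = params or GroundTruthParams()
        names = space.discrete.descriptor_names
        if sig3_name not in names:
            raise ConfigurationError(f"descriptor {sig3_name!r} not in space")
        col = names.index(sig3_name)
        sig3 = space.discrete.descriptors[:, col]
        loc, scale = float(sig3.mean()), float(sig3.std())
        if scale == 0:
            scale = 1.0
        self._sig3_z = {
            lab: (float(sig3[i]) - loc) / scale
            for i, lab in enumerate(space.discrete.choices)
        }

    def sig3_z(self, choice: str) -> float:
        return self._sig3_z[choice]

    def true_yield(self, condition: Condition) -> float:
        """Noiseless yield (%) for a condition."""
        v = condition.values
        return yield_surface(
            v["alkene_eq"], v["he_eq"], v["catalyst_molpct"], v["acid_eq"],
            v["temp_C"], v["time_min"], self._sig3_z[condition.choice], self.params,
        )

    def observe_yield(self, condition: Condition, seed: int) -> float:
        """Seeded noisy observation: true yield + N(0, noise_sd), clipped."""
        rng = np.random.default_rng(seed)
        y = self.true_yield(condition) + rng.normal(0.0, self.params.noise_sd)
        return float(np.clip(y, 0.0, 100.0))


def make_library(n_solvents: int = 20, seed: int = 0) -> list[SolventRecord]:
    """Seeded synthetic solvent library with correlated sigma moments.

    Solubilities span the clamping threshold, so filtering always produces
    at least one upper-bound override and at least two unclamped solvents.
    """
    if n_solvents < 2:
        raise ConfigurationError("need at least 2 solvents")
    rng = np.random.default_rng(seed)
    d = len(DEFAULT_DESCRIPTOR_NAMES)
    corr = np.full((d, d), 0.2)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_solvents, d)) @ chol.T
    means = np.array([60.0, 8.0, 0.5, 2.0, 5.0])
    scales = np.array([15.0, 3.0, 0.8, 1.0, 2.0])
    descriptors = means + scales * z

    prices = np.exp(rng.normal(3.5, 0.5, size=n_solvents))
    he_sol = rng.uniform(25.0, 220.0, size=n_solvents)
    cat_sol = rng.uniform(0.8, 6.0, size=n_solvents)
    basic = rng.random(n_solvents) < 0.15

    # constructed guarantees: threshold exercised on both sides
    if not np.any((he_sol >= 40.0) & (he_sol < 80.0)):
        he_sol[0] = 60.47
        basic[0] = False
    if np.count_nonzero(he_sol >= 80.0) < 2:
        he_sol[-2:] = [120.0, 150.0]
        basic[-2:] = False

    return [
        SolventRecord(
            name=f"SOL{i:02d}",
            descriptors=descriptors[i],
            price_per_L=float(prices[i]),
            he_solubility=float(he_sol[i]),
            catalyst_solubility=float(cat_sol[i]),
            is_basic=bool(basic[i]),
        )
        for i in range(n_solvents)
    ]


def default_price_table(records: list[SolventRecord]) -> PriceTable:
    """Toy reagent prices sized so per-experiment costs land near 1–3 units."""
    return PriceTable(
        alkene=1.2,
        he=1.5,
        catalyst=120.0,
        acid=0.3,
        solvent_price_per_L={r.name: r.price_per_L for r in records},
    )


def make_pool(
    space: DesignSpace,
    n: int,
    params: GroundTruthParams,
    seed: int,
    prices: PriceTable,
    limiting_mmol: float = 0.2,
    solvent_volume_L: float = 0.005,
) -> SyntheticPool:
    """LHS-sampled pool of evaluated (condition, objective) pairs."""
    if n < 10:
        raise ConfigurationError("pool size must be >= 10")
    sim = ReactionSimulator(space, params)
    conditions = lhs_sample(space, n, seed)
    objectives = [
        ObjectivePoint(
            yield_pct=sim.observe_yield(c, seed=int(np.random.SeedSequence(
                [seed, 7, i]).generate_state(1)[0])),
            cost=reaction_cost(c, prices, limiting_mmol, solvent_volume_L),
        )
        for i, c in enumerate(conditions)
    ]
    return SyntheticPool(conditions, objectives, params, seed)
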