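"""Shared fixtures.

Heavy artifacts (the 20-seed campaign replicates and the 73-point pool
benchmark) are session-scoped and shared between the module tests and the
acceptance suite so they are computed once per run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import reactopt as r
from reactopt.campaign import (
    CampaignConfig,
    derive_seed,
    pool_benchmark,
    run_simulated_campaign,
)
from reactopt.simulate import GroundTruthParams, default_price_table

N_SEEDS = 20

FAST_CONFIG = CampaignConfig(
    families=("gaussian_process", "gbdt_ensemble"),
    pool_per_solvent=40,
    n_draws=192,
    refine_maxiter=8,
)


@pytest.fixture(scope="session")
def library():
    return r.make_library(20, seed=1)


@pytest.fixture(scope="session")
def shortlist(library):
    res = r.filter_solvents(library)
    return res.shortlist[:8], {
        k: v for k, v in res.he_eq_overrides.items()
        if k in {s.name for s in res.shortlist[:8]}
    }


@pytest.fixture(scope="session")
def space8(shortlist):
    records, overrides = shortlist
    return r.build_design_space(records, overrides)


@pytest.fixture(scope="session")
def prices8(shortlist):
    return default_price_table(shortlist[0])


@pytest.fixture(scope="session")
def sim8(space8):
    return r.ReactionSimulator(space8)


@pytest.fixture(scope="session")
def lowest_sig3_solvent(space8):
    col = space8.discrete.descriptor_names.index("sig3")
    return space8.discrete.choices[
        int(np.argmin(space8.discrete.descriptors[:, col]))
    ]


def _run(space, sim, prices, seed, proposer):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_simulated_campaign(
            space, sim, prices, FAST_CONFIG, n_init=48, n_iterations=5,
            seed=seed, proposer=proposer,
        )


@pytest.fixture(scope="session")
def campaign_runs(space8, sim8, prices8):
    """Twenty seeded full campaigns (48 init + 5x5 EHVI proposals)."""
    return [_run(space8, sim8, prices8, seed, "ehvi") for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def random_campaign_runs(space8, sim8, prices8):
    """Matched uniform-random-proposer campaigns for the paired comparison."""
    return [_run(space8, sim8, prices8, seed, "random") for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def pool73(space8, prices8):
    return r.make_pool(space8, 73, GroundTruthParams(), seed=11, prices=prices8)


@pytest.fixture(scope="session")
def pool73_init(pool73):
    """Two conditions per solvent (16 points), mirroring the first benchmark."""
    per: dict[str, list[int]] = {}
    for i, c in enumerate(pool73.conditions):
        per.setdefault(c.choice, []).append(i)
    return sorted(i for idxs in per.values() for i in idxs[:2])


@pytest.fixture(scope="session")
def benchmark_curves(pool73, pool73_init, space8):
    """EHVI and random pool-benchmark learning curves over 20 paired seeds."""
    seeds = tuple(derive_seed(99, k) for k in range(N_SEEDS))
    ehvi = pool_benchmark(
        pool73.conditions, pool73.objectives, space8, pool73_init,
        acquisition="ehvi", seeds=seeds, n_draws=192,
    )
    rand = pool_benchmark(
        pool73.conditions, pool73.objectives, space8, pool73_init,
        acquisition="random", seeds=seeds,
    )
    return ehvi, rand
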