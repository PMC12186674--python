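"""File formats, run configuration, fixtures and state persistence.

Campaign data travels as comma-separated UTF-8 CSV with dot decimals and a
fixed, case-insensitive header; solvent libraries as CSV/TSV.  Campaign
state round-trips through a JSON document plus the campaign CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .campaign import CampaignConfig, CampaignState
from .errors import ConfigurationError
from .moo import ObjectivePoint
from .solvents import DEFAULT_DESCRIPTOR_NAMES, PriceTable, SolventRecord
from .space import (
    Condition,
    ContinuousVariable,
    DesignSpace,
    DiscreteVariable,
)

__all__ = [
    "CAMPAIGN_COLUMNS",
    "read_campaign_csv",
    "write_campaign_csv",
    "frame_to_conditions",
    "state_to_frame",
    "load_training_fixture",
    "read_solvent_library",
    "write_solvent_library",
    "RunConfig",
    "load_config",
    "save_state",
    "load_state",
]

CAMPAIGN_COLUMNS = (
    "alkene_eq",
    "catalyst_molpct",
    "he_eq",
    "acid_eq",
    "temp_C",
    "time_min",
    "solvent",
    "cost",
    "yield_pct",
)
_NUMERIC = tuple(c for c in CAMPAIGN_COLUMNS if c != "solvent")


def read_campaign_csv(path) -> pd.DataFrame:
    """Read a campaign table, validating header order and numeric cells."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    got = [c.strip().lower() for c in df.columns]
    want = [c.lower() for c in CAMPAIGN_COLUMNS]
    if got != want:
        missing = [c for c in want if c not in got]
        if missing:
            raise ConfigurationError(
                f"campaign CSV missing column(s): {', '.join(missing)}"
            )
        raise ConfigurationError(
            f"campaign CSV columns out of order: expected {want}, got {got}"
        )
    df.columns = CAMPAIGN_COLUMNS
    for col in _NUMERIC:
        for i, cell in enumerate(df[col]):
            if cell == "":
                continue
            try:
                float(cell)
            except ValueError:
                raise ConfigurationError(
                    f"non-numeric cell at row {i + 2}, column {col!r}: {cell!r}"
                ) from None
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    return df


def write_campaign_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(CAMPAIGN_COLUMNS))


def frame_to_conditions(
    df: pd.DataFrame,
) -> tuple[list[Condition], list[ObjectivePoint]]:
    """Split a campaign frame into conditions and measured objectives."""
    conditions, objectives = [], []
    for _, row in df.iterrows():
        values = {
            c: float(row[c]) for c in _NUMERIC if c not in ("cost", "yield_pct")
        }
        conditions.append(Condition(values=values, choice=str(row["solvent"])))
        objectives.append(
            ObjectivePoint(yield_pct=float(row["yield_pct"]),
                           cost=float(row["cost"]))
        )
    return conditions, objectives


def state_to_frame(state: CampaignState) -> pd.DataFrame:
    rows = []
    for cond, obj in zip(state.conditions, state.objectives):
        row = {c: cond.values[c] for c in _NUMERIC if c in cond.values}
        row["solvent"] = cond.choice
        row["cost"] = obj.cost
        row["yield_pct"] = obj.yield_pct
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CAMPAIGN_COLUMNS))


def conditions_to_frame(conditions: list[Condition]) -> pd.DataFrame:
    """Conditions-only frame (cost/yield left blank) for pending designs."""
    rows = []
    for cond in conditions:
        row = {k: cond.values.get(k, np.nan) for k in _NUMERIC}
        row["solvent"] = cond.choice
        row["cost"] = np.nan
        row["yield_pct"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CAMPAIGN_COLUMNS))


def load_training_fixture() -> pd.DataFrame:
    """The packaged 16-row seed campaign table."""
    with resources.files("reactopt.data").joinpath("training_table.csv").open() as fh:
        return read_campaign_csv(fh)


_LIB_COLUMNS = ("name", *DEFAULT_DESCRIPTOR_NAMES, "price_per_L",
                "he_solubility_mM", "cat_solubility_mM", "is_basic")


def read_solvent_library(path) -> list[SolventRecord]:
    """Solvent library from CSV (or TSV, by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _LIB_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"solvent library missing column(s): {', '.join(missing)}"
        )
    return [
        SolventRecord(
            name=str(r["name"]),
            descriptors=np.array([r[c] for c in DEFAULT_DESCRIPTOR_NAMES]),
            price_per_L=float(r["price_per_L"]),
            he_solubility=float(r["he_solubility_mM"]),
            catalyst_solubility=float(r["cat_solubility_mM"]),
            is_basic=bool(r["is_basic"]),
        )
        for _, r in df.iterrows()
    ]


def write_solvent_library(records: list[SolventRecord], path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    rows = []
    for r in records:
        row = {"name": r.name}
        row.update(dict(zip(DEFAULT_DESCRIPTOR_NAMES, r.descriptors)))
        row.update({"price_per_L": r.price_per_L,
                    "he_solubility_mM": r.he_solubility,
                    "cat_solubility_mM": r.catalyst_solubility,
                    "is_basic": r.is_basic})
        rows.append(row)
    pd.DataFrame(rows, columns=list(_LIB_COLUMNS)).to_csv(path, index=False, sep=sep)


class OpticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epsilon_470: float = 1413.5  # (mol/L)^-1 cm^-1
    path_length_cm: float = 0.1
    a_max: float = 2.0


class StoppingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hv_rel_tol: float = 0.01
    patience: int = 2
    rmse_factor: float = 2.0


class PriceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alkene: float = 1.2
    he: float = 1.5
    catalyst: float = 120.0
    acid: float = 0.3
    internal_standard: float = 0.0


class RunConfig(BaseModel):
    """Schema-validated JSON run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    solvent_library: str | None = None
    prices: PriceConfig = Field(default_factory=PriceConfig)
    optics: OpticsConfig = Field(default_factory=OpticsConfig)
    stopping: StoppingConfig = Field(default_factory=StoppingConfig)
    featurization: str = "raw_descriptors"
    n_components: int = 3
    families: tuple[str, ...] = ("gaussian_process", "gbdt_ensemble")
    q: int = 5
    pool_per_solvent: int = 200
    n_draws: int = 512
    n_hyper: int = 0
    n_init: int = 48
    refine_maxiter: int = 20
    noise_sd: float = 1.8
    reaction_conc_mM: float = 40.0
    limiting_mmol: float = 0.2
    solvent_volume_L: float = 0.005
    master_seed: int = 0

    def campaign_config(self) -> CampaignConfig:
        return CampaignConfig(
            featurization=self.featurization,
            n_components=self.n_components,
            families=tuple(self.families),
            q=self.q,
            pool_per_solvent=self.pool_per_solvent,
            n_draws=self.n_draws,
            n_hyper=self.n_hyper,
            refine_maxiter=self.refine_maxiter,
            noise_sd=self.noise_sd,
            limiting_mmol=self.limiting_mmol,
            solvent_volume_L=self.solvent_volume_L,
            base_concentration_mM=self.reaction_conc_mM,
        )

    def price_table(self, records: list[SolventRecord]) -> PriceTable:
        return PriceTable(
            alkene=self.prices.alkene, he=self.prices.he,
            catalyst=self.prices.catalyst, acid=self.prices.acid,
            internal_standard=self.prices.internal_standard,
            solvent_price_per_L={r.name: r.price_per_L for r in records},
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def _space_to_dict(space: DesignSpace) -> dict:
    return {
        "continuous": [
            {"name": v.name, "lower": v.lower, "upper": v.upper, "units": v.units}
            for v in space.continuous
        ],
        "discrete": {
            "name": space.discrete.name,
            "choices": list(space.discrete.choices),
            "descriptor_names": list(space.discrete.descriptor_names),
            "descriptors": space.discrete.descriptors.tolist(),
        },
        "per_choice_overrides": space.per_choice_overrides,
    }


def _space_from_dict(d: dict) -> DesignSpace:
    return DesignSpace(
        continuous=tuple(
            ContinuousVariable(v["name"], v["lower"], v["upper"], v.get("units", ""))
            for v in d["continuous"]
        ),
        discrete=DiscreteVariable(
            name=d["discrete"]["name"],
            choices=tuple(d["discrete"]["choices"]),
            descriptors=np.array(d["discrete"]["descriptors"]),
            descriptor_names=tuple(d["discrete"]["descriptor_names"]),
        ),
        per_choice_overrides={
            k: dict(v) for k, v in d["per_choice_overrides"].items()
        },
    )


def _condition_to_dict(cond: Condition) -> dict:
    return {"values": cond.values, "choice": cond.choice}


def save_state(state: CampaignState, json_path, csv_path) -> None:
    """Persist a campaign as JSON (audit trail) + campaign CSV (data)."""
    doc = {
        "master_seed": state.master_seed,
        "iteration": state.iteration,
        "hv_history": state.hv_history,
        "front_history": [list(t) for t in state.front_history],
        "model_reports": [
            [r.to_dict() for r in reports] for reports in state.model_reports
        ],
        "pending": [_condition_to_dict(c) for c in state.pending],
        "space": _space_to_dict(state.space),
        "config": asdict(state.config),
        "prices": asdict(state.prices),
        "catalyst_solubility": state.catalyst_solubility,
        "campaign_csv": str(Path(csv_path).name),
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
    write_campaign_csv(state_to_frame(state), csv_path)


def load_state(json_path, csv_path) -> CampaignState:
    from .surrogates import ModelReport

    with open(json_path) as fh:
        doc = json.load(fh)
    cfg = doc["config"]
    cfg["families"] = tuple(cfg["families"])
    state = CampaignState(
        space=_space_from_dict(doc["space"]),
        prices=PriceTable(**{
            **doc["prices"],
            "solvent_price_per_L": dict(doc["prices"]["solvent_price_per_L"]),
        }),
        config=CampaignConfig(**cfg),
        master_seed=doc["master_seed"],
        catalyst_solubility=dict(doc.get("catalyst_solubility", {})),
    )
    df = read_campaign_csv(csv_path)
    if len(df):
        conds, objs = frame_to_conditions(df)
        state.conditions, state.objectives = conds, objs
    state.pending = [
        Condition(values={k: float(v) for k, v in c["values"].items()},
                  choice=c["choice"])
        for c in doc["pending"]
    ]
    state.iteration = doc["iteration"]
    state.hv_history = [float(h) for h in doc["hv_history"]]
    state.front_history = [tuple(t) for t in doc["front_history"]]
    state.model_reports = [
        [ModelReport(family=r["family"], cv_rmse=r["cv_rmse"], cv_r2=r["cv_r2"],
                     hyperparameters=r["hyperparameters"], seed=r["seed"])
         for r in reports]
        for reports in doc["model_reports"]
    ]
    return state
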