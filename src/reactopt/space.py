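"""Mixed continuous/discrete design spaces, condition encoding, and LHS.

A design space couples six (or any number of) bounded continuous reaction
variables with one discrete solvent variable whose choices carry numeric
descriptor vectors.  Per-solvent upper-bound overrides express solubility
caps (e.g. the usable Hantzsch-ester equivalents in a poorly solvating
solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, ConfigurationError, SolventLookupError

__all__ = [
    "ContinuousVariable",
    "DiscreteVariable",
    "DesignSpace",
    "Condition",
    "ConditionEncoder",
    "VARIABLE_ORDER",
    "lhs_sample",
    "clamp_upper_equivalents",
    "encode",
    "default_bounds",
]

#: Canonical variable order used in all numeric encodings.
VARIABLE_ORDER = (
    "alkene_eq",
    "he_eq",
    "catalyst_molpct",
    "acid_eq",
    "temp_C",
    "time_min",
)


@dataclass(frozen=True)
class ContinuousVariable:
    name: str
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ConfigurationError(f"{self.name}: bounds must be finite")
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
            )


@dataclass(frozen=True)
class DiscreteVariable:
    name: str
    choices: tuple[str, ...]
    descriptors: np.ndarray  # (n_choices, n_descriptors)
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "choices", tuple(self.choices))
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))
        object.__setattr__(
            self, "descriptors", np.asarray(self.descriptors, dtype=float)
        )
        if len(self.choices) < 1:
            raise ConfigurationError(f"{self.name}: needs at least one choice")
        if len(set(self.choices)) != len(self.choices):
            raise ConfigurationError(f"{self.name}: choice labels must be unique")
        if self.descriptors.ndim != 2 or self.descriptors.shape != (
            len(self.choices),
            len(self.descriptor_names),
        ):
            raise ConfigurationError(
                f"{self.name}: descriptor matrix must be "
                f"(n_choices, n_descriptors) = ({len(self.choices)}, "
                f"{len(self.descriptor_names)})"
            )

    def index_of(self, label: str) -> int:
        try:
            return self.choices.index(label)
        except ValueError:
            raise SolventLookupError(label) from None

    def descriptor_vector(self, label: str) -> np.ndarray:
        return self.descriptors[self.index_of(label)]


@dataclass(frozen=True)
class DesignSpace:
    continuous: tuple[ContinuousVariable, ...]
    discrete: DiscreteVariable
    #: choice label -> {variable name -> overriding upper bound}
    per_choice_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "continuous", tuple(self.continuous))
        names = [v.name for v in self.continuous]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate continuous variable names")
        for choice, ov in self.per_choice_overrides.items():
            if choice not in self.discrete.choices:
                raise ConfigurationError(f"override for unknown choice {choice!r}")
            for var, upper in ov.items():
                cv = self._var(var)
                if not (cv.lower <= upper <= cv.upper):
                    raise ConfigurationError(
                        f"override {choice}/{var}={upper} outside global bounds "
                        f"[{cv.lower}, {cv.upper}]"
                    )

    def _var(self, name: str) -> ContinuousVariable:
        for v in self.continuous:
            if v.name == name:
                return v
        raise ConfigurationError(f"unknown continuous variable {name!r}")

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.continuous)

    def bounds_for(self, choice: str) -> list[tuple[float, float]]:
        """(lower, upper) per continuous variable with overrides applied."""
        if choice not in self.discrete.choices:
            raise SolventLookupError(choice)
        ov = self.per_choice_overrides.get(choice, {})
        return [(v.lower, ov.get(v.name, v.upper)) for v in self.continuous]

    def validate_condition(self, condition: "Condition") -> None:
        """Raise :class:`BoundsError` unless the condition lies in the space."""
        if condition.choice not in self.discrete.choices:
            raise SolventLookupError(condition.choice)
        for var, (lo, hi) in zip(self.continuous, self.bounds_for(condition.choice)):
            if var.name not in condition.values:
                raise BoundsError(f"condition missing value for {var.name!r}")
            x = condition.values[var.name]
            if not (lo <= x <= hi) or not np.isfinite(x):
                raise BoundsError(
                    f"{var.name}={x} outside [{lo}, {hi}] for solvent "
                    f"{condition.choice!r}"
                )

    def contains(self, condition: "Condition") -> bool:
        try:
            self.validate_condition(condition)
        except (BoundsError, SolventLookupError):
            return False
        return True


@dataclass(frozen=True)
class Condition:
    """One experiment's settings: continuous values plus a solvent choice."""

    values: dict[str, float]
    choice: str

    def as_array(self, order: tuple[str, ...] = VARIABLE_ORDER) -> np.ndarray:
        return np.array([self.values[n] for n in order], dtype=float)


def default_bounds() -> tuple[ContinuousVariable, ...]:
    """The six default continuous reaction variables and their global bounds."""
    return (
        ContinuousVariable("alkene_eq", 1.0, 2.0, "eq"),
        ContinuousVariable("he_eq", 1.0, 2.0, "eq"),
        ContinuousVariable("catalyst_molpct", 0.5, 5.0, "mol %"),
        ContinuousVariable("acid_eq", 0.1, 1.0, "eq"),
        ContinuousVariable("temp_C", 10.0, 50.0, "°C"),
        ContinuousVariable("time_min", 4.0, 60.0, "min"),
    )


def clamp_upper_equivalents(
    solubility: float, base_concentration: float, max_eq: float
) -> float:
    """Solubility-capped upper bound in equivalents, rounded to 2 decimals.

    ``min(max_eq, solubility / base_concentration)`` — the usable equivalents
    of a reagent whose dissolved concentration cannot exceed ``solubility``
    at a given limiting-reactant concentration.
    """
    from .errors import DomainError

    if solubility <= 0 or base_concentration <= 0 or max_eq <= 0:
        raise DomainError("solubility, base concentration and max_eq must be > 0")
    return round(min(max_eq, solubility / base_concentration), 2)


def _stratum_counts(n: int, k: int) -> list[int]:
    """Divide n as evenly as possible over k strata (earlier strata larger)."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def lhs_sample(
    space: DesignSpace,
    n: int,
    seed: int,
    choices: tuple[str, ...] | None = None,
) -> list[Condition]:
    """Stratified Latin hypercube sample of ``n`` conditions.

    ``n`` is split as evenly as possible across the allowed solvent choices
    (declared order); a separate continuous LHS (one sample per equal-width
    bin per variable, uniform jitter within the bin) is run per stratum,
    rescaled to that solvent's (possibly overridden) bounds.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    labels = tuple(choices) if choices is not None else space.discrete.choices
    if not labels:
        raise ConfigurationError("design space has no solvent choices")
    for lab in labels:
        if lab not in space.discrete.choices:
            raise SolventLookupError(lab)

    counts = _stratum_counts(n, len(labels))
    out: list[Condition] = []
    for stratum, (label, n_s) in enumerate(zip(labels, counts)):
        if n_s == 0:
            continue
        rng = np.random.default_rng([seed, stratum])
        bounds = space.bounds_for(label)
        d = len(bounds)
        # one point per bin per dimension, independently permuted
        u = (rng.permuted(np.tile(np.arange(n_s), (d, 1)), axis=1).T
             + rng.uniform(size=(n_s, d))) / n_s
        for row in u:
            values = {
                v.name: lo + x * (hi - lo)
                for v, (lo, hi), x in zip(space.continuous, bounds, row)
            }
            out.append(Condition(values=values, choice=label))
    return out


class ConditionEncoder:
    """Maps conditions to numeric feature vectors.

    ``raw_descriptors``: the continuous values in :data:`VARIABLE_ORDER`
    followed by the solvent's raw descriptor vector.  ``pca_components``:
    descriptors are standardized over the space's solvent set and projected
    onto the first ``n_components`` principal components.
    """

    def __init__(
        self,
        space: DesignSpace,
        featurization: str = "raw_descriptors",
        n_components: int = 3,
    ) -> None:
        if featurization not in ("raw_descriptors", "pca_components"):
            raise ConfigurationError(f"unknown featurization {featurization!r}")
        self.space = space
        self.featurization = featurization
        self.n_components = n_components
        if featurization == "pca_components":
            from .solvents import pca_reduce, standardize

            Z, self._means, self._sds = standardize(space.discrete.descriptors)
            scores, self._loadings, self._evr = pca_reduce(Z, n_components)
            self._choice_features = {
                lab: scores[i] for i, lab in enumerate(space.discrete.choices)
            }
        else:
            self._choice_features = {
                lab: space.discrete.descriptors[i]
                for i, lab in enumerate(space.discrete.choices)
            }

    @property
    def feature_names(self) -> list[str]:
        cont = [v.name for v in self.space.continuous]
        if self.featurization == "pca_components":
            return cont + [f"pc{i + 1}" for i in range(self.n_components)]
        return cont + list(self.space.discrete.descriptor_names)

    @property
    def n_continuous(self) -> int:
        return len(self.space.continuous)

    @property
    def descriptor_indices(self) -> list[int]:
        """Column indices of the solvent-descriptor block."""
        n = self.n_continuous
        return list(range(n, len(self.feature_names)))

    def encode_one(self, condition: Condition) -> np.ndarray:
        if condition.choice not in self._choice_features:
            raise SolventLookupError(condition.choice)
        order = tuple(v.name for v in self.space.continuous)
        return np.concatenate(
            [condition.as_array(order), self._choice_features[condition.choice]]
        )

    def transform(self, conditions: list[Condition]) -> np.ndarray:
        return np.vstack([self.encode_one(c) for c in conditions])


def encode(
    condition: Condition,
    space: DesignSpace,
    featurization: str = "raw_descriptors",
    n_components: int = 3,
) -> np.ndarray:
    """Convenience single-condition encoding (see :class:`ConditionEncoder`)."""
    return ConditionEncoder(space, featurization, n_components).encode_one(condition)
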