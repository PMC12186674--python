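"""Solvent library handling, descriptor PCA, cost objective and photophysics.

Solvents are parametrized by five sigma-moment descriptors (screening-charge
density summaries; the third moment is the asymmetry of the s-profile) and
carry measured solubilities that constrain the usable design space: the
library is filtered so every retained solvent supports a clear solution at
the reaction concentration, and solvents that cannot dissolve the full
reagent excess get a per-solvent upper-bound override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateDescriptorError, DomainError
from .space import Condition, clamp_upper_equivalents

__all__ = [
    "SolventRecord",
    "PriceTable",
    "OpticalSetup",
    "FilterResult",
    "filter_solvents",
    "standardize",
    "destandardize",
    "pca_reduce",
    "reaction_cost",
    "absorbance",
    "max_transparent_concentration",
    "DEFAULT_DESCRIPTOR_NAMES",
]

#: Default descriptor column labels for five sigma moments.
DEFAULT_DESCRIPTOR_NAMES = ("sig0", "sig2", "sig3", "sig4", "sig5")

#: Index of the s-profile asymmetry moment within the default descriptors.
SIG3_INDEX = DEFAULT_DESCRIPTOR_NAMES.index("sig3")


@dataclass(frozen=True)
class SolventRecord:
    name: str
    descriptors: np.ndarray  # five sigma moments
    price_per_L: float
    he_solubility: float  # mmol/L
    catalyst_solubility: float  # mmol/L
    is_basic: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "descriptors", np.asarray(self.descriptors, dtype=float)
        )
        if not np.all(np.isfinite(self.descriptors)):
            raise ConfigurationError(f"{self.name}: descriptors must be finite")
        if self.price_per_L < 0:
            raise ConfigurationError(f"{self.name}: price must be >= 0")
        if self.he_solubility < 0 or self.catalyst_solubility < 0:
            raise ConfigurationError(f"{self.name}: solubilities must be >= 0")


@dataclass(frozen=True)
class PriceTable:
    """Per-reagent unit prices (cost units per mmol) plus per-solvent prices."""

    alkene: float
    he: float
    catalyst: float
    acid: float
    internal_standard: float = 0.0
    solvent_price_per_L: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alkene", "he", "catalyst", "acid", "internal_standard"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"price for {name} must be >= 0")
        if any(p < 0 for p in self.solvent_price_per_L.values()):
            raise ConfigurationError("solvent prices must be >= 0")


@dataclass(frozen=True)
class OpticalSetup:
    epsilon: float  # (mol/L)^-1 cm^-1
    concentration: float  # mol/L
    path_length: float  # cm


@dataclass
class FilterResult:
    shortlist: list[SolventRecord]
    #: name -> machine-readable rejection reason
    rejections: dict[str, str]
    #: name -> clamped upper bound in equivalents (only for retained solvents)
    he_eq_overrides: dict[str, float]


def filter_solvents(
    library: list[SolventRecord],
    reaction_conc: float = 40.0,
    require_clear: bool = True,
    max_eq: float = 2.0,
) -> FilterResult:
    """Shortlist solvents and record per-solvent rejection reasons.

    Removes basic-flagged solvents (acid-catalyzed chemistry) and, when
    ``require_clear``, solvents whose reagent solubility cannot support even
    1.0 eq at ``reaction_conc``.  Retained solvents whose solubility is below
    ``max_eq * reaction_conc`` get an upper-bound override in equivalents.
    Library order is preserved.
    """
    if not library:
        raise ConfigurationError("empty solvent library")
    shortlist: list[SolventRecord] = []
    rejections: dict[str, str] = {}
    overrides: dict[str, float] = {}
    for rec in library:
        if rec.is_basic:
            rejections[rec.name] = "basic"
            continue
        if require_clear and rec.he_solubility < reaction_conc:
            rejections[rec.name] = "insoluble at 1.0 eq"
            continue
        shortlist.append(rec)
        if rec.he_solubility < max_eq * reaction_conc:
            overrides[rec.name] = clamp_upper_equivalents(
                rec.he_solubility, reaction_conc, max_eq
            )
    return FilterResult(shortlist, rejections, overrides)


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise standardization; returns (Z, means, sds).

    Raises :class:`DegenerateDescriptorError` naming the first zero-variance
    column.  Population (ddof=0) standard deviations are used so the round
    trip through :func:`destandardize` is exact.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need a 2-D matrix with >= 2 rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DegenerateDescriptorError(
            f"descriptor column {int(bad[0])} has zero variance"
        )
    return (X - means) / sds, means, sds


def destandardize(Z: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return np.asarray(Z, dtype=float) * sds + means


def pca_reduce(
    standardized: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA on a standardized matrix.

    Returns ``(scores (n, k), loadings (k, d), explained_fractions (d,))``
    where the fractions cover *all* components (nonincreasing, summing to 1).
    Each loading vector is scaled so its largest-magnitude element is
    positive, for cross-platform determinism.
    """
    Z = np.asarray(standardized, dtype=float)
    d = Z.shape[1]
    if not 1 <= k <= d:
        raise ConfigurationError(f"k={k} out of range [1, {d}]")
    _, s, vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    # fix sign: largest-|.| element of each loading positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    var = s**2
    fractions = var / var.sum()
    loadings = vt[:k]
    scores = (Z - Z.mean(axis=0)) @ loadings.T
    return scores, loadings, fractions


def reaction_cost(
    condition: Condition,
    prices: PriceTable,
    limiting_amount: float,
    solvent_volume: float,
) -> float:
    """Analytic per-experiment cost in cost units.

    ``limiting_amount`` (mmol) scales the reagent terms; the catalyst enters
    at ``catalyst_molpct / 100`` equivalents.  The solvent term is
    ``solvent_volume * price_per_L`` and is independent of the scale.
    """
    if limiting_amount <= 0 or solvent_volume <= 0:
        raise DomainError("amounts must be > 0")
    if condition.choice not in prices.solvent_price_per_L:
        raise ConfigurationError(
            f"no solvent price for {condition.choice!r} in the price table"
        )
    v = condition.values
    reagents = (
        v["alkene_eq"] * prices.alkene
        + v["he_eq"] * prices.he
        + v["acid_eq"] * prices.acid
        + (v["catalyst_molpct"] / 100.0) * prices.catalyst
    )
    return (
        limiting_amount * reagents
        + solvent_volume * prices.solvent_price_per_L[condition.choice]
    )


def absorbance(setup: OpticalSetup) -> float:
    """Beer–Lambert absorbance ``A = epsilon * c * l`` (A = log10(I0/I))."""
    if setup.epsilon < 0 or setup.concentration < 0 or setup.path_length < 0:
        raise DomainError("optical inputs must be >= 0")
    return setup.epsilon * setup.concentration * setup.path_length


def max_transparent_concentration(
    epsilon: float, path_length: float, a_max: float
) -> float:
    """Largest concentration (mol/L) keeping absorbance at or below ``a_max``."""
    if epsilon <= 0 or path_length <= 0:
        raise DomainError("epsilon and path length must be > 0")
    if a_max < 0:
        raise DomainError("a_max must be >= 0")
    return a_max / (epsilon * path_length)


def build_design_space(
    records: list[SolventRecord],
    he_eq_overrides: dict[str, float] | None = None,
    continuous=None,
    descriptor_names: tuple[str, ...] = DEFAULT_DESCRIPTOR_NAMES,
):
    """Assemble a :class:`~reactopt.space.DesignSpace` from solvent records.

    ``he_eq_overrides`` (e.g. from :func:`filter_solvents`) become per-solvent
    upper bounds on the ``he_eq`` variable.
    """
    from .space import DesignSpace, DiscreteVariable, default_bounds

    if continuous is None:
        continuous = default_bounds()
    discrete = DiscreteVariable(
        name="solvent",
        choices=tuple(r.name for r in records),
        descriptors=np.vstack([r.descriptors for r in records]),
        descriptor_names=descriptor_names,
    )
    overrides = {
        name: {"he_eq": eq} for name, eq in (he_eq_overrides or {}).items()
    }
    return DesignSpace(continuous=continuous, discrete=discrete,
                       per_choice_overrides=overrides)


def transmittance(setup: OpticalSetup) -> float:
    """Fraction of light transmitted, ``I/I0 = 10**(-A)``."""
    return math.pow(10.0, -absorbance(setup))
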