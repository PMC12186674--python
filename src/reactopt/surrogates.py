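"""Surrogate model zoo: fit, cross-validate, and select the best family.

Every family exposes the same contract — ``fit(X, y)`` then
``predict(X) -> (mean, sd)`` with a nonnegative predictive uncertainty:
the Gaussian process reports its posterior standard deviation, the tree
and neural-network families the spread across a bootstrap ensemble.
Model selection is a pure function of (data, families, seed): each family
is scored by seeded k-fold cross-validation and the lowest held-out RMSE
wins (ties broken by higher R^2, then declared family order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .errors import ConfigurationError

__all__ = [
    "TrainingSet",
    "ModelReport",
    "FAMILIES",
    "fit",
    "cross_validate",
    "select_best",
    "tune",
]

#: Declared family order (also the tie-break order in selection).
FAMILIES = ("gaussian_process", "gbdt_ensemble", "rf_ensemble", "nn_ensemble")

MIN_TRAIN_ROWS = 5


@dataclass
class TrainingSet:
    X: np.ndarray
    y: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ConfigurationError("X and y must be aligned (n rows each)")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ConfigurationError("NaN in training data")

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class ModelReport:
    family: str
    cv_rmse: float
    cv_r2: float
    hyperparameters: dict
    seed: int
    fold_predictions: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "cv_rmse": self.cv_rmse,
            "cv_r2": self.cv_r2,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
        }


class GPSurrogate:
    """Anisotropic Matern-5/2 GP with a fitted white-noise term."""

    family = "gaussian_process"

    def __init__(self, seed: int = 0, nu: float = 2.5, n_restarts: int = 0):
        self.seed = seed
        self.nu = nu
        self.n_restarts = n_restarts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPSurrogate":
        X = np.asarray(X, dtype=float)
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        d = Xs.shape[1]
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=np.ones(d), length_scale_bounds=(1e-2, 1e3), nu=self.nu
        ) + WhiteKernel(1e-4, (1e-8, 1e2))
        self._gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=self.n_restarts,
            random_state=self.seed,
        )
        import warnings

        from sklearn.exceptions import ConvergenceWarning

        with warnings.catch_warnings():
            # hyperparameters pinned at a bound are fine for irrelevant inputs
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gp.fit(Xs, np.asarray(y, dtype=float))
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean, sd = self._gp.predict(self._scaler.transform(np.asarray(X)), return_std=True)
        return mean, np.maximum(sd, 0.0)


class _BootstrapEnsemble:
    """Mean/sd across base learners fitted on bootstrap resamples."""

    n_members = 20

    def __init__(self, seed: int = 0, n_members: int | None = None, **params):
        self.seed = seed
        if n_members is not None:
            self.n_members = n_members
        self.params = params

    def _make_member(self, rs: int):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self._members = []
        for m in range(self.n_members):
            idx = rng.integers(0, n, size=n)
            member = self._make_member(self.seed * 1000 + m)
            member.fit(X[idx], y[idx])
            self._members.append(member)
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        preds = np.stack([m.predict(np.asarray(X)) for m in self._members])
        return preds.mean(axis=0), preds.std(axis=0)


class GBDTEnsemble(_BootstrapEnsemble):
    """Bootstrap ensemble of gradient-boosted regression trees."""

    family = "gbdt_ensemble"

    def _make_member(self, rs: int):
        defaults = dict(n_estimators=120, max_depth=3, learning_rate=0.08,
                        subsample=0.9)
        defaults.update(self.params)
        return GradientBoostingRegressor(random_state=rs, **defaults)


class RFEnsemble:
    """Random forest; uncertainty from the spread across its trees."""

    family = "rf_ensemble"

    def __init__(self, seed: int = 0, n_estimators: int = 200, **params):
        self.seed = seed
        self.params = dict(n_estimators=max(n_estimators, 20), **params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RFEnsemble":
        self._rf = RandomForestRegressor(random_state=self.seed, **self.params)
        self._rf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        per_tree = np.stack([t.predict(X) for t in self._rf.estimators_])
        return per_tree.mean(axis=0), per_tree.std(axis=0)


class NNEnsemble(_BootstrapEnsemble):
    """Bootstrap ensemble of small multilayer perceptrons (scaled inputs)."""

    family = "nn_ensemble"

    def fit(self, X: np.ndarray, y: np.ndarray):
        self._scaler = StandardScaler().fit(np.asarray(X, dtype=float))
        return super().fit(self._scaler.transform(X), y)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return super().predict(self._scaler.transform(np.asarray(X, dtype=float)))

    def _make_member(self, rs: int):
        defaults = dict(hidden_layer_sizes=(32, 16), max_iter=600, alpha=1e-3,
                        solver="lbfgs")
        defaults.update(self.params)
        return MLPRegressor(random_state=rs, **defaults)


_REGISTRY = {
    "gaussian_process": GPSurrogate,
    "gbdt_ensemble": GBDTEnsemble,
    "rf_ensemble": RFEnsemble,
    "nn_ensemble": NNEnsemble,
}

#: Per-family hyperparameter search ranges for the seeded random search.
_TUNE_SPACE = {
    "gaussian_process": {"nu": [1.5, 2.5]},
    "gbdt_ensemble": {
        "n_estimators": (50, 300),
        "max_depth": (2, 4),
        "learning_rate": (0.03, 0.3),
    },
    "rf_ensemble": {"n_estimators": (100, 400), "max_features": (0.3, 1.0)},
    "nn_ensemble": {"alpha": (1e-5, 1e-1)},
}


def fit(family: str, train: TrainingSet, seed: int, hyperparameters: dict | None = None):
    """Fit one surrogate family; bit-reproducible under the same seed."""
    if family not in _REGISTRY:
        raise ConfigurationError(f"unknown surrogate family {family!r}")
    if len(train) < MIN_TRAIN_ROWS:
        raise ConfigurationError(
            f"need >= {MIN_TRAIN_ROWS} training rows, got {len(train)}"
        )
    model = _REGISTRY[family](seed=seed, **(hyperparameters or {}))
    return model.fit(train.X, train.y)


def cross_validate(
    family: str,
    data: TrainingSet,
    folds: int = 5,
    holdout: float = 0.2,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> ModelReport:
    """Seeded k-fold CV; RMSE and R^2 on the pooled held-out predictions.

    ``holdout`` documents the held-out fraction per fold and must equal
    ``1 / folds`` (an 80/20 split five times is 5-fold CV).
    """
    if len(data) < folds + MIN_TRAIN_ROWS:
        raise ConfigurationError("not enough rows for the requested split")
    if abs(holdout - 1.0 / folds) > 1e-9:
        raise ConfigurationError("holdout fraction must equal 1/folds")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(kf.split(data.X)):
        model = fit(
            family, TrainingSet(data.X[tr], data.y[tr]), seed=seed,
            hyperparameters=hyperparameters,
        )
        mean, _ = model.predict(data.X[te])
        for i, m in zip(te, mean):
            rows.append({"fold": fold, "row": int(i), "y_true": float(data.y[i]),
                         "y_pred": float(m)})
    preds = pd.DataFrame(rows)
    rmse = float(np.sqrt(mean_squared_error(preds["y_true"], preds["y_pred"])))
    r2 = float(r2_score(preds["y_true"], preds["y_pred"]))
    return ModelReport(
        family=family, cv_rmse=rmse, cv_r2=r2,
        hyperparameters=dict(hyperparameters or {}), seed=seed,
        fold_predictions=preds,
    )


def tune(family: str, data: TrainingSet, n_draws: int, seed: int,
         folds: int = 5, base: dict | None = None) -> dict:
    """Small seeded random search; returns the best hyperparameter draw.

    ``base`` hyperparameters (e.g. a smaller ensemble) are merged into every
    draw and into the returned value.
    """
    if n_draws <= 0:
        return dict(base or {})
    rng = np.random.default_rng(seed)
    space = _TUNE_SPACE.get(family, {})
    best_hp = dict(base or {})
    best_rmse = cross_validate(family, data, folds=folds, holdout=1.0 / folds,
                               seed=seed, hyperparameters=best_hp).cv_rmse
    for _ in range(min(n_draws, 25)):
        hp = dict(base or {})
        for name, rng_spec in space.items():
            if isinstance(rng_spec, list):
                hp[name] = rng_spec[rng.integers(len(rng_spec))]
            else:
                lo, hi = rng_spec
                if isinstance(lo, int) and isinstance(hi, int):
                    hp[name] = int(rng.integers(lo, hi + 1))
                else:
                    hp[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) \
                        if lo > 0 else float(rng.uniform(lo, hi))
        rmse = cross_validate(family, data, folds=folds, holdout=1.0 / folds,
                              seed=seed, hyperparameters=hp).cv_rmse
        if rmse < best_rmse:
            best_rmse, best_hp = rmse, hp
    return best_hp


def select_best(
    data: TrainingSet,
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
    folds: int = 5,
    n_hyper: int = 0,
):
    """CV-score every family and fit the winner on all data.

    Returns ``(fitted model, winning ModelReport, all reports)``.  Winner =
    lowest cv_rmse; ties break by higher cv_r2, then declared order.
    """
    if len(families) < 2:
        raise ConfigurationError("need at least 2 candidate families")
    reports: list[ModelReport] = []
    errors: list[str] = []
    for family in families:
        try:
            hp = tune(family, data, n_hyper, seed, folds=folds) if n_hyper else {}
            reports.append(
                cross_validate(family, data, folds=folds, holdout=1.0 / folds,
                               seed=seed, hyperparameters=hp)
            )
        except Exception as exc:  # noqa: BLE001 - aggregate per-family failures
            errors.append(f"{family}: {exc}")
    if not reports:
        raise ConfigurationError("all surrogate families failed: " + "; ".join(errors))
    order = {f: i for i, f in enumerate(families)}
    best = min(reports, key=lambda r: (r.cv_rmse, -r.cv_r2, order[r.family]))
    model = fit(best.family, data, seed=seed, hyperparameters=best.hyperparameters)
    return model, best, reports
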