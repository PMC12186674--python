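"""Post-hoc model interrogation: permutation importance and partial dependence.

Importances are reported in metric units (held-constant-model RMSE increase,
in yield %), not normalized, so they are directly comparable with the
replicate-noise floor.  Feature groups allow shuffling the whole
solvent-descriptor block as one feature alongside the individual
descriptors, guarding against correlated-descriptor masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "permutation_importance",
    "partial_dependence",
    "DependenceCurve",
    "descriptor_groups",
]


def _predict_mean(model, X: np.ndarray) -> np.ndarray:
    out = model.predict(X)
    return out[0] if isinstance(out, tuple) else out


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    groups: dict[str, list[int]] | None = None,
    n_repeats: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance under the RMSE metric.

    ``importance = mean over repeats of rmse(shuffled) - rmse(baseline)``;
    the baseline is computed once.  ``groups`` maps an importance entry to
    the column indices shuffled jointly (defaults to one entry per column).
    Returns a frame with columns (feature, importance_mean, importance_sd,
    rank), rank 1 = most important.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_repeats < 2:
        raise ConfigurationError("n_repeats must be >= 2")
    if groups is None:
        groups = {name: [j] for j, name in enumerate(feature_names)}
    for name, cols in groups.items():
        if any(j < 0 or j >= X.shape[1] for j in cols):
            raise ConfigurationError(f"unknown feature columns for {name!r}")

    rng = np.random.default_rng(seed)
    baseline = _rmse(y, _predict_mean(model, X))
    rows = []
    for name, cols in groups.items():
        deltas = np.empty(n_repeats)
        for r in range(n_repeats):
            perm = rng.permutation(X.shape[0])
            Xs = X.copy()
            Xs[:, cols] = X[perm][:, cols]  # joint shuffle keeps the block intact
            deltas[r] = _rmse(y, _predict_mean(model, Xs)) - baseline
        rows.append({"feature": name, "importance_mean": float(deltas.mean()),
                     "importance_sd": float(deltas.std(ddof=1))})
    table = pd.DataFrame(rows)
    order = table["importance_mean"].rank(ascending=False, method="first")
    table["rank"] = order.astype(int)
    return table


def descriptor_groups(encoder) -> dict[str, list[int]]:
    """PFI groups: every individual feature plus the solvent block as one."""
    names = encoder.feature_names
    groups = {name: [j] for j, name in enumerate(names)}
    groups["solvent(block)"] = list(encoder.descriptor_indices)
    return groups


@dataclass
class DependenceCurve:
    features: tuple[str, ...]
    grid: tuple[np.ndarray, ...]
    response: np.ndarray  # (g,) for one feature, (g1, g2) for two


def partial_dependence(
    model,
    X: np.ndarray,
    features: list[int],
    feature_names: list[str] | None = None,
    grid_size: int = 20,
) -> DependenceCurve:
    """Mean-response partial dependence over a grid within the observed range."""
    X = np.asarray(X, dtype=float)
    if not 1 <= len(features) <= 2:
        raise ConfigurationError("partial dependence supports 1 or 2 features")
    names = tuple(
        (feature_names[j] if feature_names else f"x{j}") for j in features
    )
    grids = tuple(
        np.linspace(X[:, j].min(), X[:, j].max(), grid_size) for j in features
    )
    if len(features) == 1:
        j = features[0]
        resp = np.empty(grid_size)
        for gi, g in enumerate(grids[0]):
            Xg = X.copy()
            Xg[:, j] = g
            resp[gi] = float(np.mean(_predict_mean(model, Xg)))
    else:
        j1, j2 = features
        resp = np.empty((grid_size, grid_size))
        for a, g1 in enumerate(grids[0]):
            for b, g2 in enumerate(grids[1]):
                Xg = X.copy()
                Xg[:, j1] = g1
                Xg[:, j2] = g2
                resp[a, b] = float(np.mean(_predict_mean(model, Xg)))
    if not np.all(np.isfinite(resp)):
        raise ConfigurationError("non-finite partial-dependence response")
    return DependenceCurve(features=names, grid=grids, response=resp)
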