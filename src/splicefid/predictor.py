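"""Random-forest regression of log2 SEF from sequence features.

Threefold cross-validation with target-quantile stratified folds;
performance is the Pearson correlation between observed and pooled
out-of-fold predicted log2 SEF (per-fold correlations are reported too,
since either pooling convention is defensible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = ["ModelReport", "fit_cv", "pearson_r", "importances"]


@dataclass
class ModelReport:
    n_events: int
    folds: int
    seed: int
    hyperparams: dict
    fold_assignment: np.ndarray  # fold index per event
    predictions: pd.DataFrame  # index event, columns observed/predicted/fold
    pearson_pooled: float
    pearson_per_fold: list[float]
    feature_importances: pd.Series  # normalized, sums to 1

    def importances_ranked(self) -> pd.Series:
        return self.feature_importances.sort_values(ascending=False)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Product-moment correlation; None for constant or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def _stratified_folds(targets: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels balanced across the target distribution.

    Events are sorted by target; each consecutive block of ``folds``
    events is dealt one per fold in a seed-shuffled order, so every fold
    spans the full target range.
    """
    n = targets.size
    order = np.argsort(targets, kind="mergesort")
    assignment = np.empty(n, dtype=int)
    for block_start in range(0, n, folds):
        block = order[block_start: block_start + folds]
        labels = rng.permutation(folds)[: block.size]
        assignment[block] = labels
    return assignment


def fit_cv(
    features: pd.DataFrame,
    targets: Sequence[float],
    folds: int = 3,
    seed: int = 0,
    n_estimators: int = 500,
    max_features: str = "sqrt",
) -> ModelReport:
    """Out-of-fold random-forest regression with a pooled Pearson R.

    Missing feature values are imputed with the training fold's
    per-column median (test-fold leakage avoided).  Targets must be
    finite; raises on constant targets or n < folds.
    """
    y = np.asarray(targets, dtype=float)
    X = features.to_numpy(dtype=float)
    if y.size != X.shape[0]:
        raise ValueError("feature rows and targets differ in length")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite (filter zero-SEF events upstream)")
    if y.size < folds:
        raise ValueError(f"need at least {folds} events for {folds}-fold CV")
    if np.std(y) == 0:
        raise ValueError("constant target: correlation undefined")

    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(y, folds, rng)

    pred = np.full(y.size, np.nan)
    per_fold_r: list[float] = []
    hyper = {
        "n_estimators": n_estimators,
        "max_features": max_features,
        "folds": folds,
        "seed": seed,
    }
    for fold in range(folds):
        test = assignment == fold
        train = ~test
        med = np.nanmedian(X[train], axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        Xtr = np.where(np.isfinite(X[train]), X[train], med)
        Xte = np.where(np.isfinite(X[test]), X[test], med)
        model = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=seed + fold,
            n_jobs=1,
        )
        model.fit(Xtr, y[train])
        pred[test] = model.predict(Xte)
        r = pearson_r(y[test], pred[test])
        per_fold_r.append(float("nan") if r is None else r)

    pooled = pearson_r(y, pred)

    # full-data fit for impurity importances
    med = np.nanmedian(X, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    Xfull = np.where(np.isfinite(X), X, med)
    full = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    full.fit(Xfull, y)
    imp = pd.Series(full.feature_importances_, index=features.columns)
    total = imp.sum()
    if total > 0:
        imp = imp / total

    return ModelReport(
        n_events=int(y.size),
        folds=folds,
        seed=seed,
        hyperparams=hyper,
        fold_assignment=assignment,
        predictions=pd.DataFrame(
            {"observed": y, "predicted": pred, "fold": assignment},
            index=features.index,
        ),
        pearson_pooled=float("nan") if pooled is None else pooled,
        pearson_per_fold=per_fold_r,
        feature_importances=imp,
    )


def importances(report: ModelReport) -> pd.Series:
    """Ranked, normalized impurity importances from the full-data fit."""
    return report.importances_ranked()
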