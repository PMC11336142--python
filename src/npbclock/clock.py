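"""Random-forest age clock.

Trains one regression forest per (split, imputation) pair on the completed
training tables, predicts each record in its own test fold once per
imputation, and averages the per-imputation predictions into the record's
final predicted age.  Downstream quantities:

* delta age      — predicted minus known chronological age;
* relative age   — residual of a pooled OLS of predicted on known age
  (positive = old-for-age), plus per-individual lifetime means;
* repeatability  — random-intercept ICC of relative age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor

from ._seeds import seed_for

from .impute import ImputedSet

__all__ = [
    "ClockModel",
    "ClockMetrics",
    "ClockError",
    "tune_mtry",
    "train_clock",
    "predict_panel",
    "clock_metrics",
    "relative_age",
    "repeatability",
    "run_clock",
    "standardize_set",
]

DEFAULT_NTREE = 2000


class ClockError(RuntimeError):
    pass


@dataclass
class ClockModel:
    split_index: int
    imputation_index: int
    forest: RandomForestRegressor
    mtry: int
    ntree: int
    features: tuple[str, ...]


@dataclass
class ClockMetrics:
    r_squared: float
    median_abs_error: float
    slope_pred_vs_known: float
    repeatability: float = np.nan
    #: R^2 here is the squared Pearson correlation between predicted and known
    #: age, not 1 - SSE/SST (the two differ under calibration slope != 1).
    r_squared_definition: str = "squared-pearson"


def _forest_seed(seed: int, split: int, imp: int) -> int:
    return int(seed_for(seed, "forest", split, imp).generate_state(1)[0] % (2**31))


def standardize_set(s: ImputedSet, features) -> ImputedSet:
    """Center/scale continuous features using *training* statistics, applied to
    both partitions (leakage-safe default)."""
    train, test = s.train_table.copy(), s.test_table.copy()
    for f in features:
        mu = float(train[f].mean())
        sd = float(train[f].std(ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            sd = 1.0
        train[f] = (train[f] - mu) / sd
        test[f] = (test[f] - mu) / sd
    return ImputedSet(s.split_index, s.imputation_index, train, test)


def tune_mtry(
    train_sets: list[ImputedSet],
    grid: list[int],
    features,
    ntree: int = 500,
    seed: int = 0,
) -> int:
    """Grid value maximizing the mean out-of-bag R^2 (squared Pearson between
    OOB predictions and known age) across the supplied training tables."""
    if not grid:
        raise ClockError("empty mtry grid")
    features = list(features)
    bad = [v for v in grid if not 1 <= v <= len(features)]
    if bad:
        raise ClockError(f"mtry values out of range 1..{len(features)}: {bad}")
    if len(grid) == 1:
        return int(grid[0])
    scores = {}
    for v in grid:
        r2s = []
        for k, s in enumerate(train_sets):
            X = s.train_table[features].to_numpy()
            y = s.train_table["age_start"].to_numpy()
            rf = RandomForestRegressor(
                n_estimators=ntree,
                max_features=v,
                oob_score=True,
                bootstrap=True,
                random_state=_forest_seed(seed, 99, k) ^ v,
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rf.fit(X, y)
            oob = rf.oob_prediction_
            ok = np.isfinite(oob)
            r2s.append(float(np.corrcoef(oob[ok], y[ok])[0, 1] ** 2))
        scores[v] = float(np.mean(r2s))
    best = max(scores, key=lambda v: (scores[v], -v))
    return int(best)


def train_clock(
    train_set: ImputedSet,
    features,
    mtry: int,
    ntree: int = DEFAULT_NTREE,
    seed: int = 0,
) -> ClockModel:
    features = tuple(features)
    X = train_set.train_table[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ClockError(
            f"split {train_set.split_index} imputation {train_set.imputation_index}: "
            "missing cells in a completed training table"
        )
    y = train_set.train_table["age_start"].to_numpy(dtype=float)
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        random_state=_forest_seed(seed, train_set.split_index, train_set.imputation_index),
        n_jobs=1,
    )
    rf.fit(X, y)
    return ClockModel(
        split_index=train_set.split_index,
        imputation_index=train_set.imputation_index,
        forest=rf,
        mtry=mtry,
        ntree=ntree,
        features=features,
    )


def predict_panel(models: list[ClockModel], sets: list[ImputedSet]) -> pd.DataFrame:
    """Predict every record in its test fold, once per imputation, and average.

    Returns one row per (individual_id, year_index) with known_age,
    predicted_age and delta_age.
    """
    by_key = {(m.split_index, m.imputation_index): m for m in models}
    frames = []
    for s in sets:
        key = (s.split_index, s.imputation_index)
        if key not in by_key:
            raise ClockError(f"no model for split/imputation {key}")
        m = by_key[key]
        X = s.test_table[list(m.features)].to_numpy(dtype=float)
        pred = m.forest.predict(X)
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": s.test_table["individual_id"],
                    "year_index": s.test_table["year_index"],
                    "known_age": s.test_table["age_start"],
                    "prediction": pred,
                }
            )
        )
    allp = pd.concat(frames, ignore_index=True)
    out = (
        allp.groupby(["individual_id", "year_index"], as_index=False)
        .agg(known_age=("known_age", "first"), predicted_age=("prediction", "mean"))
        .sort_values(["individual_id", "year_index"])
        .reset_index(drop=True)
    )
    out["delta_age"] = out["predicted_age"] - out["known_age"]
    return out


def clock_metrics(preds: pd.DataFrame) -> ClockMetrics:
    if len(preds) < 3:
        raise ClockError("need at least 3 predictions for metrics")
    known = preds["known_age"].to_numpy(dtype=float)
    pred = preds["predicted_age"].to_numpy(dtype=float)
    if np.var(known) == 0:
        raise ClockError("known age has zero variance")
    r = float(np.corrcoef(pred, known)[0, 1])
    slope = float(np.cov(pred, known, ddof=1)[0, 1] / np.var(known, ddof=1))
    return ClockMetrics(
        r_squared=r**2,
        median_abs_error=float(np.median(np.abs(pred - known))),
        slope_pred_vs_known=slope,
    )


def relative_age(preds: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Residuals of pooled OLS of predicted on known age, plus per-individual
    lifetime means of those residuals."""
    if len(preds) < 3:
        raise ClockError("need at least 3 predictions")
    known = preds["known_age"].to_numpy(dtype=float)
    pred = preds["predicted_age"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(known, pred, 1)
    out = preds.copy()
    out["relative_age"] = pred - (intercept + slope * known)
    lifetime = out.groupby("individual_id")["relative_age"].mean()
    lifetime.name = "lifetime_relative_age"
    return out, lifetime


def repeatability(preds: pd.DataFrame, column: str = "relative_age") -> float:
    """Random-intercept ICC: between-individual variance over total variance."""
    counts = preds.groupby("individual_id").size()
    if len(counts) < 2 or (counts < 2).all():
        raise ClockError("repeatability needs >=2 individuals, one with >=2 records")
    y = preds[column].to_numpy(dtype=float)
    groups = pd.factorize(preds["individual_id"])[0]
    X = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # Powell profiles the single variance ratio to high precision
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="powell")
        except (np.linalg.LinAlgError, ValueError):
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    sigma_b = float(np.asarray(res.cov_re)[0, 0])
    sigma_w = float(res.scale)
    icc = sigma_b / (sigma_b + sigma_w)
    return float(np.clip(icc, 0.0, 1.0))


def permutation_importance_frame(
    models: list[ClockModel], sets: list[ImputedSet], seed: int = 0, n_repeats: int = 3
) -> pd.DataFrame:
    """Mean permutation importance (test-fold R^2 drop) across all models."""
    from sklearn.inspection import permutation_importance

    features = list(models[0].features)
    by_key = {(m.split_index, m.imputation_index): m for m in models}
    acc = np.zeros(len(features))
    for s in sets:
        m = by_key[(s.split_index, s.imputation_index)]
        X = s.test_table[features].to_numpy(dtype=float)
        y = s.test_table["age_start"].to_numpy(dtype=float)
        imp = permutation_importance(
            m.forest, X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
        )
        acc += imp.importances_mean
    acc /= len(sets)
    return (
        pd.DataFrame({"trait": features, "importance": acc})
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )


def run_clock(
    sets: list[ImputedSet],
    features,
    ntree: int = DEFAULT_NTREE,
    mtry_grid: list[int] | None = None,
    seed: int = 0,
    standardize: bool = True,
    tune_ntree: int = 300,
) -> tuple[list[ClockModel], pd.DataFrame, int]:
    """End-to-end clock: standardize, tune mtry on split-0 training tables,
    train all (split, imputation) forests, predict and average.

    Returns (models, predictions frame, selected mtry).
    """
    features = list(features)
    if standardize:
        sets = [standardize_set(s, features) for s in sets]
    if mtry_grid is None:
        p = len(features)
        mtry_grid = sorted(
            {max(1, p // 6), max(1, p // 3), max(1, int(np.sqrt(p))), max(1, p // 2)}
        )
    split0 = [s for s in sets if s.split_index == 0]
    mtry = tune_mtry(split0, mtry_grid, features, ntree=tune_ntree, seed=seed)
    models = [
        train_clock(s, features, mtry=mtry, ntree=ntree, seed=seed) for s in sets
    ]
    preds = predict_panel(models, sets)
    return models, preds, mtry
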