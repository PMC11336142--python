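"""Two-phase missing-data handling and the 5-split x 5-imputation structure.

Phase 1 (:func:`neighbor_fill`) propagates values from the adjacent year of
life: the mean of the two flanking observed values for continuous traits, a
seeded random pick between them for binary/categorical traits, a straight
carry when only one neighbor is observed.  Only originally-observed values
ever act as donors, so fills never chain across runs of missing years.

Phase 2 is chained predictive mean matching (:func:`pmm_impute`): each
incomplete column is regressed (linearly, with categorical columns one-hot
encoded on the predictor side) on all other trait columns, and each missing
cell receives the *observed* value of a donor row drawn from the ``k`` rows
with the closest predictions, with probability proportional to 1/(rank+1).
Chronological age is never part of the predictor matrix.

:func:`build_imputed_sets` runs PMM separately on the training and test rows
of each train/test split (no cross-partition information flow), ``m`` times
per split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import rng_for
from .datamodel import CohortPanel

__all__ = [
    "SplitPlan",
    "ImputedSet",
    "ImputationError",
    "neighbor_fill",
    "make_splits",
    "pmm_impute",
    "build_imputed_sets",
]


class ImputationError(RuntimeError):
    pass


@dataclass
class SplitPlan:
    """Assignment of every (individual_id, year_index) record to one test fold."""

    n_splits: int
    assignment: pd.Series  # MultiIndex (individual_id, year_index) -> fold

    def test_mask(self, df: pd.DataFrame, fold: int) -> np.ndarray:
        keys = pd.MultiIndex.from_frame(df[["individual_id", "year_index"]])
        return self.assignment.reindex(keys).to_numpy() == fold


@dataclass
class ImputedSet:
    split_index: int
    imputation_index: int
    train_table: pd.DataFrame  # id columns + age + completed traits
    test_table: pd.DataFrame


# -- phase 1: neighbor filling -------------------------------------------------


def neighbor_fill(panel: CohortPanel, seed: int = 0) -> tuple[CohortPanel, pd.DataFrame]:
    """One pass of adjacent-year filling over originally missing cells.

    Returns the filled panel and a log frame with one row per filled cell
    (individual_id, year_index, trait, source in {mean, carry-back,
    carry-forward, random-pick}, value).
    """
    rng = rng_for(seed, "neighbor_fill")
    df = panel.df.copy()
    traits = panel.trait_names
    kinds = {t.name: t.kind for t in panel.registry}
    log_rows = []
    for ind, grp in df.groupby("individual_id", sort=False):
        g = grp.sort_values("year_index")
        idx = g.index.to_numpy()
        years = g["year_index"].to_numpy()
        year_pos = {y: i for i, y in enumerate(years)}
        for trait in traits:
            orig = g[trait].to_numpy(dtype=float)  # snapshot: donors only
            miss = np.isnan(orig)
            if not miss.any():
                continue
            for i in np.flatnonzero(miss):
                y = years[i]
                before = year_pos.get(y - 1)
                after = year_pos.get(y + 1)
                v_before = orig[before] if before is not None else np.nan
                v_after = orig[after] if after is not None else np.nan
                has_b, has_a = not np.isnan(v_before), not np.isnan(v_after)
                if not has_b and not has_a:
                    continue
                if has_b and has_a:
                    if kinds[trait] == "continuous":
                        value, source = 0.5 * (v_before + v_after), "mean"
                    else:
                        value = v_before if rng.random() < 0.5 else v_after
                        source = "random-pick"
                elif has_b:
                    value, source = v_before, "carry-forward"
                else:
                    value, source = v_after, "carry-back"
                df.at[idx[i], trait] = value
                log_rows.append((ind, y, trait, source, value))
    log = pd.DataFrame(
        log_rows, columns=["individual_id", "year_index", "trait", "source", "value"]
    )
    return CohortPanel(df, panel.registry, provenance=panel.provenance), log


# -- splits --------------------------------------------------------------------


def make_splits(panel: CohortPanel, n_splits: int = 5, seed: int = 0) -> SplitPlan:
    """Per-individual round-robin assignment of years to test folds.

    Each individual's years are dealt cyclically into a seeded random
    permutation of the folds, so per-individual fold counts differ by at most
    one and an individual with exactly ``n_splits`` years lands once in every
    fold.
    """
    if n_splits < 2:
        raise ImputationError("n_splits must be >= 2")
    rng = rng_for(seed, "splits")
    keys, folds = [], []
    for ind, grp in panel.df.groupby("individual_id", sort=True):
        years = np.sort(grp["year_index"].to_numpy())
        order = rng.permutation(n_splits)
        for j, y in enumerate(years):
            keys.append((ind, y))
            folds.append(int(order[j % n_splits]))
    assignment = pd.Series(
        folds,
        index=pd.MultiIndex.from_tuples(keys, names=["individual_id", "year_index"]),
        name="fold",
    )
    return SplitPlan(n_splits=n_splits, assignment=assignment)


# -- phase 2: chained predictive mean matching --------------------------------


def _onehot_predictors(table: pd.DataFrame, columns, kinds, exclude: str) -> np.ndarray:
    """Predictor matrix from all columns but ``exclude``; categorical3 columns
    expand to two indicator columns (level 0 is the reference)."""
    parts = [np.ones(len(table))]
    for c in columns:
        if c == exclude:
            continue
        v = table[c].to_numpy(dtype=float)
        if kinds[c] == "categorical3":
            parts.append((v == 1.0).astype(float))
            parts.append((v == 2.0).astype(float))
        else:
            parts.append(v)
    return np.column_stack(parts)


def _initial_fill(table: pd.DataFrame, columns, kinds) -> pd.DataFrame:
    out = table.copy()
    for c in columns:
        col = out[c]
        if not col.isna().any():
            continue
        if col.dropna().empty:
            raise ImputationError(f"column {c!r} entirely missing; no donors exist")
        if kinds[c] == "continuous":
            out[c] = col.fillna(col.median())
        else:
            out[c] = col.fillna(col.mode().iloc[0])
    return out


def _draw_donors(
    pred_obs: np.ndarray,
    obs_values: np.ndarray,
    pred_mis: np.ndarray,
    k_donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each missing-cell prediction, draw a donor among the k observed rows
    with closest predictions; weight 1/(rank+1); ties broken by row order."""
    n_obs = len(pred_obs)
    k = min(k_donors, n_obs)
    # stable sort ensures deterministic tie-breaking by row order
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    weights = 1.0 / (np.arange(k) + 1.0)  # rank 0 = closest -> weight 1/(rank+1)
    weights = weights / weights.sum()
    # candidate window of 2k sorted neighbors around each query, vectorized
    pos = np.searchsorted(sorted_pred, pred_mis)
    lo = np.clip(pos - k, 0, max(n_obs - 2 * k, 0))
    width = min(2 * k, n_obs)
    window = lo[:, None] + np.arange(width)[None, :]  # (n_mis, width)
    dist = np.abs(sorted_pred[window] - pred_mis[:, None])
    nearest = np.take_along_axis(
        window, np.argsort(dist, axis=1, kind="stable")[:, :k], axis=1
    )  # (n_mis, k), rank 0 = closest
    rank_draw = rng.choice(k, size=len(pred_mis), p=weights)
    donor_sorted_pos = nearest[np.arange(len(pred_mis)), rank_draw]
    return obs_values[order[donor_sorted_pos]]


def pmm_impute(
    table: pd.DataFrame,
    kinds: dict[str, str],
    m: int = 5,
    k_donors: int = 5,
    n_burn: int = 3,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Chained PMM producing ``m`` independently-seeded completed tables.

    ``table`` holds trait columns only (no age, no identifiers); ``kinds``
    maps each column to its trait kind.  Every imputed value is an observed
    value of its own column (the PMM donor property).
    """
    columns = list(table.columns)
    for c in columns:
        n_obs = table[c].notna().sum()
        if n_obs == 0:
            raise ImputationError(f"column {c!r} entirely missing; no donors exist")
    miss_mask = table.isna()
    if not miss_mask.to_numpy().any():
        return [table.copy() for _ in range(m)]
    results = []
    for chain in range(m):
        rng = rng_for(seed, "pmm", chain)
        work = _initial_fill(table, columns, kinds)
        for sweep in range(n_burn):
            for c in columns:
                mis = miss_mask[c].to_numpy()
                if not mis.any():
                    continue
                X = _onehot_predictors(work, columns, kinds, exclude=c)
                y = table[c].to_numpy(dtype=float)  # observed targets only
                obs = ~mis
                beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
                pred = X @ beta
                drawn = _draw_donors(
                    pred[obs], y[obs], pred[mis], k_donors, rng
                )
                col = work[c].to_numpy(dtype=float)
                col[mis] = drawn
                work[c] = col
        results.append(work)
    return results


# -- split-aware imputation ----------------------------------------------------


def build_imputed_sets(
    panel: CohortPanel,
    plan: SplitPlan,
    m: int = 5,
    k_donors: int = 5,
    n_burn: int = 3,
    seed: int = 0,
) -> list[ImputedSet]:
    """PMM each split's training rows and test rows in isolation, ``m`` times.

    Returns ``n_splits * m`` :class:`ImputedSet` objects whose tables carry
    the identifier columns and ``age_start`` alongside the completed traits
    (age is excluded from the imputation itself).
    """
    traits = panel.trait_names
    kinds = {t.name: t.kind for t in panel.registry}
    id_cols = ["individual_id", "year_index", "age_start"]
    out: list[ImputedSet] = []
    for split in range(plan.n_splits):
        test_mask = plan.test_mask(panel.df, split)
        parts = {}
        for role, mask in (("train", ~test_mask), ("test", test_mask)):
            rows = panel.df.loc[mask].reset_index(drop=True)
            try:
                completed = pmm_impute(
                    rows[traits],
                    kinds,
                    m=m,
                    k_donors=k_donors,
                    n_burn=n_burn,
                    seed=int(
                        np.random.SeedSequence(
                            [seed, split, 0 if role == "train" else 1]
                        ).generate_state(1)[0]
                    ),
                )
            except ImputationError as exc:
                raise ImputationError(f"split {split}, {role} rows: {exc}") from exc
            parts[role] = [
                pd.concat([rows[id_cols].reset_index(drop=True), tab], axis=1)
                for tab in completed
            ]
        for j in range(m):
            out.append(
                ImputedSet(
                    split_index=split,
                    imputation_index=j,
                    train_table=parts["train"][j],
                    test_table=parts["test"][j],
                )
            )
    return out
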