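"""Survival and early-adversity models on clock outputs.

Survival records use counting-process (start, stop] intervals with delayed
entry, so both the lifetime model (one interval per individual, covariate =
lifetime mean relative age) and the time-varying annual model (one interval
per female-year, covariate = that year's relative age, individual-clustered
robust SEs) share one fitting routine.  Cox fits are delegated to lifelines
(Efron tie handling); an independent partial-likelihood oracle lives in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

__all__ = [
    "CoxResult",
    "DeltaAgeModelResult",
    "SurvivalError",
    "ADVERSITY_BINARY",
    "ADVERSITY_CONTINUOUS",
    "build_lifetime_records",
    "build_annual_records",
    "fit_cox",
    "cumulative_adversity",
    "fit_delta_age_lmm",
    "fit_cox_with_adversity",
]

ADVERSITY_BINARY = ("maternal_death", "close_sibling", "drought")
#: (column, adverse side): low connectedness / low rank / large group
ADVERSITY_CONTINUOUS = (
    ("maternal_sci", "low"),
    ("maternal_rank", "low"),
    ("group_size", "high"),
)


class SurvivalError(RuntimeError):
    pass


@dataclass
class CoxResult:
    covariate: str
    coefficient: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    se_type: str  # "model" | "cluster-robust"
    n_events: int
    n_records: int


@dataclass
class DeltaAgeModelResult:
    coefficients: pd.DataFrame  # term, coef, se, p
    random_intercept_var: float
    fallback_ols: bool = False

    def coef(self, term: str) -> float:
        return float(
            self.coefficients.set_index("term").at[term, "coef"]
        )

    def se(self, term: str) -> float:
        return float(self.coefficients.set_index("term").at[term, "se"])


# -- record construction -------------------------------------------------------


def build_lifetime_records(
    lifetime_relative_age: pd.Series,
    vitals: pd.DataFrame,
    first_observed_age: pd.Series | None = None,
) -> pd.DataFrame:
    """One interval per individual with the lifetime mean relative age.

    Entry honors left truncation: the interval starts at the vital table's
    entry age or, if supplied, the first observed adult age.
    """
    vit = vitals.set_index("individual_id")
    missing = [i for i in lifetime_relative_age.index if i not in vit.index]
    if missing:
        raise SurvivalError(f"individuals lacking vital records: {missing[:5]}")
    ids = list(lifetime_relative_age.index)
    start = vit.loc[ids, "entry_age"].to_numpy(dtype=float)
    if first_observed_age is not None:
        start = np.maximum(start, first_observed_age.reindex(ids).to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "individual_id": ids,
            "start_age": start,
            "stop_age": vit.loc[ids, "end_age"].to_numpy(dtype=float),
            "event": vit.loc[ids, "event"].to_numpy(dtype=int),
            "lifetime_relative_age": lifetime_relative_age.to_numpy(dtype=float),
        }
    )
    bad = out["stop_age"] <= out["start_age"]
    if bad.any():
        raise SurvivalError(
            f"non-positive intervals for {out.loc[bad, 'individual_id'].tolist()[:5]}"
        )
    return out


def build_annual_records(
    preds: pd.DataFrame, vitals: pd.DataFrame, covariate: str = "relative_age"
) -> pd.DataFrame:
    """One (start, stop] interval per predicted female-year.

    A death is assigned to the interval containing it; if the death-year
    record was dropped by the inclusion filters (so it has no prediction),
    the individual contributes no event — mirroring how short final years
    fall out of the annual analysis.
    """
    vit = vitals.set_index("individual_id")
    rows = []
    for _, r in preds.iterrows():
        ind = r["individual_id"]
        if ind not in vit.index:
            raise SurvivalError(f"individual {ind!r} has predictions but no vitals")
        end_age = float(vit.at[ind, "end_age"])
        event_flag = int(vit.at[ind, "event"])
        start = float(r["known_age"])
        if end_age <= start:
            continue  # record beyond the vital window; defensive
        stop = min(start + 1.0, end_age)
        event = int(event_flag == 1 and start < end_age <= start + 1.0)
        rows.append((ind, r["year_index"], start, stop, event, float(r[covariate])))
    out = pd.DataFrame(
        rows,
        columns=["individual_id", "year_index", "start_age", "stop_age", "event", covariate],
    )
    # overlapping intervals within an individual violate the counting process
    for ind, grp in out.groupby("individual_id"):
        g = grp.sort_values("start_age")
        if (g["start_age"].to_numpy()[1:] < g["stop_age"].to_numpy()[:-1] - 1e-9).any():
            raise SurvivalError(f"overlapping intervals for individual {ind!r}")
    return out


# -- Cox fitting ---------------------------------------------------------------


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    cluster: str | None = None,
) -> dict[str, CoxResult]:
    """Efron-tie Cox partial likelihood on (start, stop] records.

    ``cluster`` names a grouping column (typically ``individual_id``) for
    grouped-sandwich robust standard errors.  Returns one CoxResult per
    covariate.
    """
    n_events = int(records["event"].sum())
    if n_events < 1:
        raise SurvivalError("no events in the survival records")
    for c in covariates:
        if records[c].nunique() <= 1:
            raise SurvivalError(f"covariate {c!r} is constant; not identifiable")
    cols = ["start_age", "stop_age", "event", *covariates]
    if cluster:
        cols.append(cluster)
    df = records[cols].copy()
    cph = CoxPHFitter()
    kwargs = dict(
        duration_col="stop_age",
        entry_col="start_age",
        event_col="event",
        show_progress=False,
    )
    if cluster:
        kwargs.update(cluster_col=cluster, robust=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, **kwargs)
    summ = cph.summary
    out = {}
    for c in covariates:
        row = summ.loc[c]
        out[c] = CoxResult(
            covariate=c,
            coefficient=float(row["coef"]),
            hazard_ratio=float(np.exp(row["coef"])),
            ci_low=float(np.exp(row["coef lower 95%"])),
            ci_high=float(np.exp(row["coef upper 95%"])),
            p_value=float(row["p"]),
            se=float(row["se(coef)"]),
            se_type="cluster-robust" if cluster else "model",
            n_events=n_events,
            n_records=len(df),
        )
    return out


# -- adversity -----------------------------------------------------------------


def cumulative_adversity(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, list]:
    """Quartile-score the six adversity sources and sum them into an index.

    Binary sources copy through; continuous sources are flagged when the
    individual falls in the most adverse population quartile (boundaries
    inclusive on the adverse side).  Individuals missing any source are
    excluded and returned in the second element.
    """
    sources = list(ADVERSITY_BINARY) + [c for c, _ in ADVERSITY_CONTINUOUS]
    missing = [c for c in sources if c not in profiles.columns]
    if missing:
        raise SurvivalError(f"profiles lack adversity columns {missing}")
    complete = profiles.dropna(subset=sources).copy()
    excluded = sorted(
        set(profiles["individual_id"]) - set(complete["individual_id"])
    )
    for c in ADVERSITY_BINARY:
        complete[f"flag_{c}"] = complete[c].astype(int)
    for c, side in ADVERSITY_CONTINUOUS:
        if side == "low":
            thr = complete[c].quantile(0.25)
            complete[f"flag_{c}"] = (complete[c] <= thr).astype(int)
        else:
            thr = complete[c].quantile(0.75)
            complete[f"flag_{c}"] = (complete[c] >= thr).astype(int)
    flag_cols = [f"flag_{c}" for c in sources]
    complete["cumulative_index"] = complete[flag_cols].sum(axis=1)
    return complete.reset_index(drop=True), excluded


def fit_delta_age_lmm(
    preds: pd.DataFrame,
    profiles: pd.DataFrame,
    current_conditions: list[str] = ("proportional_rank", "group_size_year", "rainfall_anomaly"),
    mode: str = "cumulative",
) -> DeltaAgeModelResult:
    """Linear mixed model of per-year delta age on early adversity.

    ``mode='cumulative'`` uses the 0..6 index as a continuous covariate;
    ``mode='multivariable'`` enters the six sources separately (continuous
    sources unbinned).  Known chronological age and the current-condition
    covariates are always included; individual identity is a random
    intercept.  Singular mixed fits fall back to OLS with individual-
    clustered robust SEs (flagged on the result).
    """
    if mode == "cumulative":
        adv_terms = ["cumulative_index"]
    elif mode == "multivariable":
        adv_terms = list(ADVERSITY_BINARY) + [c for c, _ in ADVERSITY_CONTINUOUS]
    else:
        raise SurvivalError(f"unknown mode {mode!r}")
    keep = ["individual_id", *adv_terms]
    df = preds.merge(profiles[keep], on="individual_id", how="inner")
    terms = adv_terms + ["known_age"] + [c for c in current_conditions if c in df.columns]
    cols = ["delta_age", "individual_id", *terms]
    df = df[cols].dropna().reset_index(drop=True)
    if df.empty:
        raise SurvivalError("no complete rows for the delta-age model")
    y = df["delta_age"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms]
    )
    names = ["const", *terms]
    groups = pd.factorize(df["individual_id"])[0]
    if np.allclose(np.var(y), 0.0):
        coefs = pd.DataFrame(
            {"term": names, "coef": 0.0, "se": 0.0, "p": 1.0}
        )
        coefs.loc[coefs["term"] == "const", "coef"] = float(y.mean())
        return DeltaAgeModelResult(coefs, 0.0)
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
            if not np.all(np.isfinite(res.bse_fe)):
                raise np.linalg.LinAlgError("singular fit")
            coefs = pd.DataFrame(
                {
                    "term": names,
                    "coef": np.asarray(res.fe_params, dtype=float),
                    "se": np.asarray(res.bse_fe, dtype=float),
                    "p": np.asarray(res.pvalues)[: len(names)],
                }
            )
            re_var = float(np.asarray(res.cov_re)[0, 0])
        except (np.linalg.LinAlgError, ValueError):
            fallback = True
            res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
            coefs = pd.DataFrame(
                {"term": names, "coef": res.params, "se": res.bse, "p": res.pvalues}
            )
            re_var = np.nan
    return DeltaAgeModelResult(coefs, re_var, fallback_ols=fallback)


def fit_cox_with_adversity(
    records: pd.DataFrame,
    relative_age_col: str,
    adversity_col: str = "cumulative_index",
    cluster: str | None = None,
) -> tuple[dict[str, CoxResult], float]:
    """Joint Cox fit of relative age and the adversity index, plus the
    attenuation diagnostic: ratio of the relative-age coefficient with vs
    without adversity in the model."""
    joint = fit_cox(records, [relative_age_col, adversity_col], cluster=cluster)
    alone = fit_cox(records, [relative_age_col], cluster=cluster)
    denom = alone[relative_age_col].coefficient
    attenuation = (
        joint[relative_age_col].coefficient / denom if denom != 0 else np.nan
    )
    return joint, float(attenuation)
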