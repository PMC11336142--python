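"""Two-stage trait screening.

Stage 1 picks a per-trait base covariate model by exhaustive AIC search over
fixed-effect subsets (random-intercept structure held fixed).  Stage 2 adds
linear and quadratic age terms to the selected base model and tests them; a
trait enters the clock feature set if either term is significant at alpha.

Model families by trait kind:

* continuous   — linear mixed model with an individual random intercept,
  fitted by ML (Wald z tests on the age terms);
* binary       — binomial GLM with individual-clustered robust SEs (a
  working-independence stand-in for a logistic GLMM);
* categorical3 — multinomial logit without a random effect; age terms are
  assessed by likelihood-ratio tests (linear added first, then quadratic).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .datamodel import CohortPanel, standardize_traits

__all__ = [
    "CandidateModelSpec",
    "AgeScreenResult",
    "ScreeningError",
    "select_base_model",
    "test_age_terms",
    "screen_traits",
    "ALPHA",
]

ALPHA = 0.05


class ScreeningError(RuntimeError):
    pass


@dataclass(frozen=True)
class CandidateModelSpec:
    trait: str
    fixed_effects: tuple[str, ...]
    random_effects: tuple[str, ...] = ("individual_id",)
    family: str = "gaussian-lmm"  # gaussian-lmm | binomial-glmm | multinomial


@dataclass
class AgeScreenResult:
    trait: str
    linear_coef: float = np.nan
    quadratic_coef: float = np.nan
    p_linear: float = np.nan
    p_quadratic: float = np.nan
    aic_base: float = np.nan
    df_base: int = 0
    significant: bool = False
    fit_ok: bool = True
    note: str = ""


def _family_for(kind: str) -> str:
    return {
        "continuous": "gaussian-lmm",
        "binary": "binomial-glmm",
        "categorical3": "multinomial",
    }[kind]


def _design(df: pd.DataFrame, fixed: tuple[str, ...], age_cols: bool, age_center: float):
    X = [np.ones(len(df))]
    names = ["const"]
    for c in fixed:
        X.append(df[c].to_numpy(dtype=float))
        names.append(c)
    if age_cols:
        a = df["age_start"].to_numpy(dtype=float) - age_center
        X.extend([a, a**2])
        names.extend(["age_c", "age_c2"])
    return np.column_stack(X), names


def _fit_gaussian(df, trait, fixed, age_cols, age_center):
    """ML mixed model with individual random intercept; OLS+cluster fallback."""
    X, names = _design(df, fixed, age_cols, age_center)
    y = df[trait].to_numpy(dtype=float)
    groups = pd.factorize(df["individual_id"])[0]
    k = X.shape[1] + 2  # fixed effects + RE variance + residual variance
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = None
            for method in ("bfgs", "lbfgs", "powell"):
                cand = sm.MixedLM(y, X, groups=groups).fit(reml=False, method=method)
                if np.isfinite(cand.llf) and np.all(np.isfinite(cand.bse_fe)):
                    res = cand
                    break
            if res is None:
                raise np.linalg.LinAlgError("no converged mixed fit")
            params = dict(zip(names, res.fe_params))
            pvals = dict(zip(names, res.pvalues[: len(names)]))
            aic = -2.0 * res.llf + 2.0 * k
            return params, pvals, aic, k, ""
        except (np.linalg.LinAlgError, ValueError):
            res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
            params = dict(zip(names, res.params))
            pvals = dict(zip(names, res.pvalues))
            aic = res.aic
            return params, pvals, aic, X.shape[1] + 1, "ols-cluster-fallback"


def _fit_binomial(df, trait, fixed, age_cols, age_center):
    X, names = _design(df, fixed, age_cols, age_center)
    y = df[trait].to_numpy(dtype=float)
    groups = pd.factorize(df["individual_id"])[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
    params = dict(zip(names, res.params))
    pvals = dict(zip(names, res.pvalues))
    return params, pvals, res.aic, X.shape[1], ""


def _fit_multinomial_ll(df, trait, fixed, age_cols, age_center):
    """Returns (result, loglike, n_params). Age terms tested by LRT upstream."""
    X, names = _design(df, fixed, age_cols, age_center)
    y = df[trait].to_numpy(dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
    k = X.shape[1] * (len(np.unique(y)) - 1)
    return res, float(res.llf), k, names


def _rows_for(panel: CohortPanel, trait: str, fixed: tuple[str, ...]) -> pd.DataFrame:
    cols = ["individual_id", "age_start", trait, *fixed]
    return panel.df[cols].dropna().reset_index(drop=True)


def select_base_model(
    trait: str, panel: CohortPanel, candidates: list[str] | tuple[str, ...] = ()
) -> CandidateModelSpec:
    """Exhaustive AIC search over fixed-effect subsets of ``candidates``.

    Among models within two AIC units of the minimum, the one with the fewest
    estimated parameters wins; further ties break on subset enumeration order
    (candidates sorted by name, then subsets by size), so the result does not
    depend on the caller's candidate ordering.
    """
    candidates = tuple(sorted(candidates))
    if len(candidates) > 10:
        raise ScreeningError(f"{trait}: >10 candidate covariates (exhaustive bound)")
    family = _family_for(panel.spec(trait).kind)
    fitted = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            df = _rows_for(panel, trait, subset)
            try:
                if family == "gaussian-lmm":
                    *_, aic, k, _note = _fit_gaussian(df, trait, subset, False, 0.0)
                elif family == "binomial-glmm":
                    *_, aic, k, _note = _fit_binomial(df, trait, subset, False, 0.0)
                else:
                    _, llf, k, _names = _fit_multinomial_ll(df, trait, subset, False, 0.0)
                    aic = -2.0 * llf + 2.0 * k
            except Exception:
                continue
            fitted.append((subset, float(aic), int(k)))
    if not fitted:
        raise ScreeningError(f"{trait}: no fittable base model")
    subset = choose_by_aic(fitted)
    return CandidateModelSpec(trait=trait, fixed_effects=subset, family=family)


def choose_by_aic(entries: list[tuple[tuple, float, int]]):
    """AIC selection rule: minimum AIC wins, but among entries within two AIC
    units of the minimum, the one with the fewest degrees of freedom is chosen
    (ties break on subset size then lexical order).  ``entries`` are
    (key, aic, df) triples."""
    best_aic = min(a for _, a, _k in entries)
    within = [e for e in entries if e[1] <= best_aic + 2.0]
    key, _aic, _df = min(within, key=lambda e: (e[2], len(e[0]), e[0]))
    return key


def test_age_terms(
    trait: str,
    base: CandidateModelSpec,
    panel: CohortPanel,
    alpha: float = ALPHA,
    with_base_aic: bool = True,
) -> AgeScreenResult:
    """Refit the base model with linear + quadratic age (centered at the mean
    age of the fitted rows) and report per-term p-values.

    ``with_base_aic=False`` skips the extra base-model refit that only feeds
    the ``aic_base``/``df_base`` diagnostics (p-values are unaffected).
    """
    df = _rows_for(panel, trait, base.fixed_effects)
    out = AgeScreenResult(trait=trait)
    if len(df) < 10 or df[trait].nunique() < 2:
        out.fit_ok = False
        out.note = "degenerate trait (too few rows or zero variance)"
        return out
    age_center = float(df["age_start"].mean())
    try:
        if base.family == "gaussian-lmm":
            params, pvals, aic, k, note = _fit_gaussian(
                df, trait, base.fixed_effects, True, age_center
            )
            if with_base_aic:
                base_fit = _fit_gaussian(df, trait, base.fixed_effects, False, age_center)
                out.aic_base, out.df_base = base_fit[2], base_fit[3]
            out.linear_coef = params["age_c"]
            out.quadratic_coef = params["age_c2"]
            out.p_linear = pvals["age_c"]
            out.p_quadratic = pvals["age_c2"]
            out.note = note
        elif base.family == "binomial-glmm":
            params, pvals, aic, k, note = _fit_binomial(
                df, trait, base.fixed_effects, True, age_center
            )
            if with_base_aic:
                base_fit = _fit_binomial(df, trait, base.fixed_effects, False, age_center)
                out.aic_base, out.df_base = base_fit[2], base_fit[3]
            out.linear_coef = params["age_c"]
            out.quadratic_coef = params["age_c2"]
            out.p_linear = pvals["age_c"]
            out.p_quadratic = pvals["age_c2"]
        else:
            out = _test_age_terms_multinomial(df, trait, base, age_center, out)
    except Exception as exc:  # pragma: no cover - safety net
        out.fit_ok = False
        out.note = f"fit failed: {exc}"
        return out
    if out.fit_ok:
        out.significant = bool(
            (np.isfinite(out.p_linear) and out.p_linear <= alpha)
            or (np.isfinite(out.p_quadratic) and out.p_quadratic <= alpha)
        )
    return out


def _lrt(ll_small, k_small, ll_big, k_big) -> float:
    dof = k_big - k_small
    if dof <= 0:
        return np.nan
    stat = max(0.0, 2.0 * (ll_big - ll_small))
    return float(sps.chi2.sf(stat, dof))


def _test_age_terms_multinomial(df, trait, base, age_center, out):
    fixed = base.fixed_effects
    a = df["age_start"].to_numpy(dtype=float) - age_center
    work = df.copy()
    work["_age_c"] = a
    work["_age_c2"] = a**2
    _, ll0, k0, _ = _fit_multinomial_ll(work, trait, fixed, False, age_center)
    _, ll1, k1, _ = _fit_multinomial_ll(work, trait, fixed + ("_age_c",), False, age_center)
    res2, ll2, k2, names = _fit_multinomial_ll(
        work, trait, fixed + ("_age_c", "_age_c2"), False, age_center
    )
    out.aic_base = -2.0 * ll0 + 2.0 * k0
    out.df_base = k0
    out.p_linear = _lrt(ll0, k0, ll1, k1)
    out.p_quadratic = _lrt(ll1, k1, ll2, k2)
    # report the first-contrast coefficients (log-odds vs reference level)
    i_lin = names.index("_age_c")
    i_quad = names.index("_age_c2")
    par = np.asarray(res2.params)
    out.linear_coef = float(par[i_lin, 0])
    out.quadratic_coef = float(par[i_quad, 0])
    return out


def screen_traits(
    panel: CohortPanel,
    registry=None,
    candidates: dict[str, list[str]] | None = None,
    alpha: float = ALPHA,
    standardize: bool = True,
) -> tuple[list[AgeScreenResult], list[str]]:
    """Screen every registered trait; return per-trait results plus the
    selected feature list (significant traits, in registry order).

    Continuous traits are standardized (pooled) before fitting so linear
    coefficients read as SD per year.  Per-trait candidate covariates default
    to each TraitSpec's ``candidate_covariates``.
    """
    registry = tuple(registry) if registry is not None else panel.registry
    if standardize:
        panel, _ = standardize_traits(panel)
    results: list[AgeScreenResult] = []
    selected: list[str] = []
    for spec in registry:
        cand = (
            candidates.get(spec.name, list(spec.candidate_covariates))
            if candidates is not None
            else list(spec.candidate_covariates)
        )
        try:
            base = select_base_model(spec.name, panel, cand)
            res = test_age_terms(spec.name, base, panel, alpha=alpha)
        except ScreeningError as exc:
            res = AgeScreenResult(trait=spec.name, fit_ok=False, note=str(exc))
        results.append(res)
        if res.fit_ok and res.significant:
            selected.append(spec.name)
    return results, selected


def results_frame(results: list[AgeScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
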