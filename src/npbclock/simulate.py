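"""Synthetic cohort generator with known ground truth.

Produces long-format individual-year panels whose traits follow one of six
age-trajectory shape classes, with individual random intercepts, a latent
per-individual frailty offset (an individual "looks" ``f_i`` years older than
their chronological age), adversity-dependent frailty, frailty-dependent
mortality, staggered censoring and configurable missingness — so that every
downstream stage (screening, imputation, clock, survival models) can be tested
against recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, softmax

from ._seeds import rng_for
from .datamodel import ADULT_ONSET_AGE, CohortPanel, TraitSpec

__all__ = [
    "SimConfig",
    "SimTruth",
    "SHAPE_CLASSES",
    "ADVERSITY_SOURCES",
    "simulate_cohort",
    "impose_missingness",
    "simulate_survival",
]

SHAPE_CLASSES = (
    "convex",
    "linear-decreasing",
    "linear-increasing",
    "plateauing",
    "ascending",
    "concave",
)

#: binary sources first; the last three are continuous and quartile-scored
ADVERSITY_SOURCES = (
    "maternal_death",
    "close_sibling",
    "drought",
    "maternal_sci",
    "maternal_rank",
    "group_size",
)

_QUARTILE_Z = 0.6744897501960817  # 75th percentile of the standard normal


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings.  Defaults mirror the scale of the study cohort:
    319 adult females, ~7.5 adult years each, 49 traits (38 continuous,
    7 binary, 4 three-level categorical), 26% missing cells."""

    n_individuals: int = 319
    max_age: float = 27.0
    n_continuous: int = 38
    n_binary: int = 7
    n_categorical3: int = 4
    shape_mix: dict = field(
        default_factory=lambda: {s: 1.0 / len(SHAPE_CLASSES) for s in SHAPE_CLASSES}
    )
    effect_size: float = 0.08  # SD per year for linear shapes
    individual_sd: float = 0.5
    residual_sd: float = 0.7
    frailty_sd: float = 1.0  # years
    frailty_trait_loading: float = 1.0
    missing_rate: float = 0.26
    missing_mechanism: str = "blocked-MCAR"
    baseline_hazard: float = 0.093  # per year past adult onset
    frailty_log_hazard: float = 0.3  # log-hazard per frailty-year
    adversity_prevalences: tuple[float, ...] = (0.2, 0.3, 0.25, 0.25, 0.25, 0.25)
    adversity_frailty_effect: float = 0.25  # frailty-years per adverse source
    censor_horizon: tuple[float, float] = (6.0, 40.0)  # uniform study-exit age
    binary_link_gain: float = 3.0  # log-odds multiplier on shape coefficients
    obs_days_range: tuple[int, int] = (80, 340)
    seed: int = 0

    def validate(self) -> None:
        for name in ("individual_sd", "residual_sd", "frailty_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimConfigError("missing_rate must be in [0, 1)")
        if abs(sum(self.shape_mix.values()) - 1.0) > 1e-8:
            raise SimConfigError("shape_mix must sum to 1")
        if any(s not in SHAPE_CLASSES for s in self.shape_mix):
            raise SimConfigError(f"shape_mix keys must be among {SHAPE_CLASSES}")
        if len(self.adversity_prevalences) != 6:
            raise SimConfigError("adversity_prevalences needs six entries")
        if any(not 0 <= p <= 1 for p in self.adversity_prevalences):
            raise SimConfigError("adversity prevalences must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise SimConfigError("baseline_hazard must be > 0")

    @property
    def n_traits(self) -> int:
        return self.n_continuous + self.n_binary + self.n_categorical3

    @property
    def age_ref(self) -> float:
        """Center of the adult age range; quadratic terms bend around it."""
        return 0.5 * (ADULT_ONSET_AGE + self.max_age)


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort."""

    individuals: pd.DataFrame  # frailty, adversity sources/flags/index, survival
    trait_coefficients: pd.DataFrame  # trait, kind, shape, b0_sd, b1, b2


def _shape_coefficients(shape: str, effect: float, config: SimConfig) -> tuple[float, float]:
    """(linear, quadratic) coefficients realizing a trajectory shape.

    The linear term applies to raw effective age; the quadratic term to age
    centered at ``config.age_ref``, so shapes are controlled by where the
    parabola's vertex falls relative to the adult age range.
    """
    half = config.max_age - config.age_ref  # half-width of the adult range
    if shape == "linear-increasing":
        return effect, 0.0
    if shape == "linear-decreasing":
        return -effect, 0.0
    if shape == "convex":
        return 0.0, effect / half
    if shape == "concave":
        return 0.0, -effect / half
    if shape == "plateauing":  # rising, vertex at max_age
        q = effect / (2.0 * half)
        return effect, -q
    if shape == "ascending":  # rising and accelerating, vertex at adult onset
        q = effect / (2.0 * half)
        return effect, q
    raise SimConfigError(f"unknown shape {shape!r}")


def _assign_shapes(config: SimConfig, n: int) -> list[str]:
    """Deterministic largest-remainder allocation of shapes to n traits."""
    quotas = {s: config.shape_mix.get(s, 0.0) * n for s in SHAPE_CLASSES}
    counts = {s: int(np.floor(q)) for s, q in quotas.items()}
    short = n - sum(counts.values())
    remainders = sorted(
        SHAPE_CLASSES, key=lambda s: quotas[s] - counts[s], reverse=True
    )
    for s in remainders[:short]:
        counts[s] += 1
    out: list[str] = []
    for s in SHAPE_CLASSES:
        out.extend([s] * counts[s])
    return out[:n]


def _draw_individuals(config: SimConfig, seed: int) -> pd.DataFrame:
    """Adversity sources, quartile flags, and frailty for every individual."""
    rng = rng_for(seed, "individuals")
    n = config.n_individuals
    ids = [f"F{i:04d}" for i in range(n)]
    p = config.adversity_prevalences
    tab = pd.DataFrame({"individual_id": ids})
    tab["maternal_death"] = (rng.random(n) < p[0]).astype(int)
    tab["close_sibling"] = (rng.random(n) < p[1]).astype(int)
    tab["drought"] = (rng.random(n) < p[2]).astype(int)
    # continuous sources; adverse quartile by the generating distribution
    tab["maternal_sci"] = rng.normal(size=n)
    tab["maternal_rank"] = rng.normal(size=n)
    tab["group_size"] = rng.normal(size=n)
    tab["flag_maternal_death"] = tab["maternal_death"]
    tab["flag_close_sibling"] = tab["close_sibling"]
    tab["flag_drought"] = tab["drought"]
    tab["flag_maternal_sci"] = (tab["maternal_sci"] <= -_QUARTILE_Z).astype(int)
    tab["flag_maternal_rank"] = (tab["maternal_rank"] <= -_QUARTILE_Z).astype(int)
    tab["flag_group_size"] = (tab["group_size"] >= _QUARTILE_Z).astype(int)
    flags = [f"flag_{s}" for s in ADVERSITY_SOURCES]
    tab["adversity_index"] = tab[flags].sum(axis=1)
    tab["frailty"] = (
        config.adversity_frailty_effect * tab["adversity_index"].to_numpy()
        + rng.normal(scale=config.frailty_sd, size=n)
    )
    return tab


def _draw_survival(
    frailty: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Exponential death times past adult onset with log-linear frailty effect,
    uniform study-exit censoring, administrative censoring at max_age."""
    n = len(frailty)
    hazard = config.baseline_hazard * np.exp(config.frailty_log_hazard * frailty)
    death_age = ADULT_ONSET_AGE + rng.exponential(1.0 / hazard)
    lo, hi = config.censor_horizon
    exit_age = np.minimum(rng.uniform(lo, hi, size=n), config.max_age)
    end_age = np.minimum(death_age, exit_age)
    event = (death_age <= exit_age).astype(int)
    return pd.DataFrame(
        {
            "entry_age": ADULT_ONSET_AGE,
            "death_age": death_age,
            "end_age": end_age,
            "event": event,
        }
    )


def simulate_survival(truth, config: SimConfig, seed: int) -> pd.DataFrame:
    """Vital-status table (individual_id, entry_age, end_age, event) drawn from
    per-individual frailty.  ``truth`` may be a SimTruth or a frailty Series
    indexed by individual id."""
    if isinstance(truth, SimTruth):
        frailty = truth.individuals.set_index("individual_id")["frailty"]
    else:
        frailty = pd.Series(truth)
    rng = rng_for(seed, "survival")
    tab = _draw_survival(frailty.to_numpy(dtype=float), config, rng)
    tab.insert(0, "individual_id", frailty.index.to_numpy())
    return tab[["individual_id", "entry_age", "end_age", "event"]]


def build_registry(config: SimConfig) -> tuple[TraitSpec, ...]:
    """Trait registry matching the generator's columns.  Roughly a third of
    the continuous traits are flagged mortality_linked (restricted-clock
    exclusion set)."""
    specs: list[TraitSpec] = []
    # 17 of 38 continuous traits at default scale; proportional when smaller
    n_linked = min(17, int(round(config.n_continuous * 17.0 / 38.0)))
    for i in range(config.n_continuous):
        specs.append(
            TraitSpec(
                name=f"trait_c{i:02d}",
                kind="continuous",
                category="synthetic-continuous",
                mortality_linked=i < n_linked,
            )
        )
    for i in range(config.n_binary):
        specs.append(
            TraitSpec(
                name=f"trait_b{i:02d}", kind="binary", category="synthetic-binary"
            )
        )
    for i in range(config.n_categorical3):
        specs.append(
            TraitSpec(
                name=f"trait_m{i:02d}",
                kind="categorical3",
                category="synthetic-categorical",
            )
        )
    return tuple(specs)


def simulate_cohort(config: SimConfig, seed: int) -> tuple[CohortPanel, SimTruth]:
    """Generate a complete (no missingness) panel plus ground truth.

    Continuous traits for individual i at chronological age a:

        b0_i + b1 * a_eff + b2 * (a_eff - age_ref)^2 + eps,
        a_eff = a + frailty_trait_loading * f_i

    Binary and categorical traits run the same age trajectory through a
    logistic / softmax link scaled by ``binary_link_gain``.
    """
    config.validate()
    indiv = _draw_individuals(config, seed)
    surv = _draw_survival(
        indiv["frailty"].to_numpy(), config, rng_for(seed, "survival")
    )
    indiv = pd.concat([indiv, surv], axis=1)

    registry = build_registry(config)
    shapes = _assign_shapes(config, config.n_traits)
    rng_tr = rng_for(seed, "traits")
    coef_rows = []
    for spec, shape in zip(registry, shapes):
        effect = config.effect_size * rng_tr.uniform(0.75, 1.25)
        b1, b2 = _shape_coefficients(shape, effect, config)
        coef_rows.append((spec.name, spec.kind, shape, config.individual_sd, b1, b2))
    coefs = pd.DataFrame(
        coef_rows, columns=["trait", "kind", "shape", "b0_sd", "b1", "b2"]
    )

    rng_rec = rng_for(seed, "records")
    rows = []
    lo, hi = config.obs_days_range
    for _, ind in indiv.iterrows():
        age = ADULT_ONSET_AGE
        year = 0
        while age < ind["end_age"]:
            fraction = min(1.0, ind["end_age"] - age)
            days = int(round(fraction * rng_rec.integers(lo, hi + 1)))
            dies_this_year = bool(ind["event"]) and ind["end_age"] < age + 1.0
            rows.append(
                (
                    ind["individual_id"],
                    year,
                    age,
                    days,
                    not dies_this_year,
                    rng_rec.uniform(0.0, 1.0),  # proportional_rank
                    rng_rec.normal(25.0, 5.0),  # group_size_year
                    rng_rec.normal(0.0, 1.0),  # rainfall_anomaly
                )
            )
            age += 1.0
            year += 1
    df = pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "year_index",
            "age_start",
            "observation_days",
            "alive_at_year_end",
            "proportional_rank",
            "group_size_year",
            "rainfall_anomaly",
        ],
    )

    frailty = indiv.set_index("individual_id")["frailty"]
    a_eff = (
        df["age_start"].to_numpy()
        + config.frailty_trait_loading
        * frailty.loc[df["individual_id"]].to_numpy()
    )
    a_ctr = a_eff - config.age_ref
    n_rec = len(df)
    n_ind = config.n_individuals
    id_codes = (
        df["individual_id"].map({v: k for k, v in enumerate(indiv["individual_id"])})
    ).to_numpy()

    rng_val = rng_for(seed, "values")
    for spec, (_, c) in zip(registry, coefs.iterrows()):
        b0 = rng_val.normal(scale=config.individual_sd, size=n_ind)[id_codes]
        if spec.kind == "continuous":
            vals = (
                b0
                + c["b1"] * a_eff
                + c["b2"] * a_ctr**2
                + rng_val.normal(scale=config.residual_sd, size=n_rec)
            )
            df[spec.name] = vals
        elif spec.kind == "binary":
            eta = config.binary_link_gain * (
                b0 + c["b1"] * (a_eff - config.age_ref) + c["b2"] * a_ctr**2
            )
            df[spec.name] = (rng_val.random(n_rec) < expit(eta)).astype(float)
        else:  # categorical3: level-specific trajectories, softmax link
            g = config.binary_link_gain
            eta0 = np.zeros(n_rec)
            eta1 = g * (b0 + c["b1"] * (a_eff - config.age_ref))
            eta2 = g * (b0 + c["b1"] * (a_eff - config.age_ref) + c["b2"] * a_ctr**2)
            probs = softmax(np.column_stack([eta0, eta1, eta2]), axis=1)
            u = rng_val.random(n_rec)
            df[spec.name] = (
                (u > probs[:, 0]).astype(float) + (u > probs[:, 0] + probs[:, 1])
            ).astype(float)

    panel = CohortPanel(df, registry, provenance=f"simulated seed={seed}")
    truth = SimTruth(individuals=indiv, trait_coefficients=coefs)
    return panel, truth


def impose_missingness(
    panel: CohortPanel,
    rate: float,
    mechanism: str = "blocked-MCAR",
    seed: int = 0,
    block_share: float = 0.55,
) -> CohortPanel:
    """Blank out an expected fraction ``rate`` of trait cells.

    ``MCAR`` masks cells uniformly.  ``blocked-MCAR`` (the default) spends
    ``block_share`` of the target rate on whole individual-by-trait blocks —
    a data stream absent for an individual — and scatters the rest uniformly;
    scattered holes usually have an observed adjacent year (so adjacent-year
    filling can reach them) while blocked holes do not, giving roughly a
    10%/16% split between fill phases at the default 26% rate.
    ``MAR-on-observation-days`` makes the per-record probability decrease
    with observation_days while keeping the overall expected rate.
    """
    if not 0.0 <= rate < 1.0:
        raise SimConfigError("rate must be in [0, 1)")
    if rate == 0.0:
        return panel.copy()
    rng = rng_for(seed, "missingness", mechanism)
    df = panel.df.copy()
    traits = panel.trait_names
    n = len(df)
    if mechanism == "MCAR":
        mask = rng.random((n, len(traits))) < rate
    elif mechanism == "blocked-MCAR":
        ind_codes = pd.factorize(df["individual_id"])[0]
        n_ind = ind_codes.max() + 1
        p_block = block_share * rate
        blocked_pairs = rng.random((n_ind, len(traits))) < p_block
        mask = blocked_pairs[ind_codes]
        p_scatter = (rate - p_block) / max(1.0 - p_block, 1e-12)
        mask |= rng.random((n, len(traits))) < p_scatter
    elif mechanism == "MAR-on-observation-days":
        pct = df["observation_days"].rank(pct=True, method="average").to_numpy()
        p_rec = np.clip(rate * (1.6 - 1.2 * pct), 0.0, 0.95)
        p_rec *= rate / p_rec.mean()  # renormalize to the target rate
        p_rec = np.clip(p_rec, 0.0, 0.95)
        mask = rng.random((n, len(traits))) < p_rec[:, None]
    else:
        raise SimConfigError(f"unknown mechanism {mechanism!r}")
    block = df[traits].to_numpy(dtype=float)
    block[mask] = np.nan
    df[traits] = block
    return CohortPanel(df, panel.registry, provenance=panel.provenance)
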