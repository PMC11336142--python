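"""Domain types, panel I/O, inclusion filters, annualization and standardization.

The central container is :class:`CohortPanel`: a long-format table with one row
per individual-year of adult life, carrying chronological age at the start of
the year, observation effort, and a registry-described set of trait columns.
Trait kinds are ``continuous``, ``binary`` (coded 0/1) and ``categorical3``
(coded 0/1/2).  Missing values are represented internally as NaN and in CSV as
an empty field or ``NA``.
"""

from __future__ import annotations

import io
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TraitSpec",
    "CohortPanel",
    "FilterReport",
    "PanelSchemaError",
    "PanelIntegrityError",
    "CovariateModelError",
    "ADULT_ONSET_AGE",
    "ID_COLUMNS",
    "MISSING_MARKERS",
    "read_panel",
    "write_panel",
    "apply_inclusion_filters",
    "annualize_sample_residuals",
    "standardize_traits",
]

ADULT_ONSET_AGE = 4.0
ID_COLUMNS = ("individual_id", "year_index", "age_start", "observation_days")
OPTIONAL_COLUMNS = ("alive_at_year_end",)
MISSING_MARKERS = ("", "NA")

TRAIT_KINDS = ("continuous", "binary", "categorical3")
CATEGORICAL3_LEVELS = (0.0, 1.0, 2.0)
BINARY_LEVELS = (0.0, 1.0)


class PanelSchemaError(ValueError):
    """A column or value violates the declared trait schema."""


class PanelIntegrityError(ValueError):
    """Structural invariants of the panel are violated (e.g. duplicate keys)."""


class CovariateModelError(ValueError):
    """The residualization covariate model cannot be fitted."""


@dataclass(frozen=True)
class TraitSpec:
    """Metadata for a single trait column.

    Parameters
    ----------
    name : str
        Column name in the panel.
    kind : str
        One of ``continuous``, ``binary``, ``categorical3``.  Determines the
        screening model family and how imputation treats the column.
    category : str
        Free-text trait grouping label.
    candidate_covariates : tuple of str
        Covariate columns considered during base-model selection.
    mortality_linked : bool
        Flags traits excluded from the restricted clock variant.
    """

    name: str
    kind: str
    category: str = "unspecified"
    candidate_covariates: tuple[str, ...] = ()
    mortality_linked: bool = False

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise PanelSchemaError(
                f"trait {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {TRAIT_KINDS}"
            )
        object.__setattr__(
            self, "candidate_covariates", tuple(self.candidate_covariates)
        )


@dataclass
class CohortPanel:
    """Long-format individual-year trait panel plus its trait registry.

    ``df`` holds one row per (individual_id, year_index) with the identifier
    columns of :data:`ID_COLUMNS`, optional extra covariate columns, and one
    column per registered trait.
    """

    df: pd.DataFrame
    registry: tuple[TraitSpec, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.registry = tuple(self.registry)
        self.df = self.df.reset_index(drop=True)
        validate_panel(self)

    # -- convenience accessors -------------------------------------------------

    @property
    def trait_names(self) -> list[str]:
        return [t.name for t in self.registry]

    @property
    def n_records(self) -> int:
        return len(self.df)

    def traits_of_kind(self, kind: str) -> list[str]:
        return [t.name for t in self.registry if t.kind == kind]

    def spec(self, name: str) -> TraitSpec:
        for t in self.registry:
            if t.name == name:
                return t
        raise KeyError(name)

    def subset_traits(self, names: Sequence[str]) -> "CohortPanel":
        """Panel restricted to a subset of registered traits (order preserved)."""
        keep = [t for t in self.registry if t.name in set(names)]
        drop = [t.name for t in self.registry if t.name not in set(names)]
        return CohortPanel(
            self.df.drop(columns=drop), keep, provenance=self.provenance
        )

    def copy(self) -> "CohortPanel":
        return CohortPanel(self.df.copy(), self.registry, self.provenance)


def validate_panel(panel: CohortPanel) -> None:
    df = panel.df
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise PanelSchemaError(f"missing required column {col!r}")
    dup = df.duplicated(subset=["individual_id", "year_index"])
    if dup.any():
        keys = df.loc[dup, ["individual_id", "year_index"]].values.tolist()
        raise PanelIntegrityError(f"duplicate (individual_id, year_index): {keys}")
    if (df["age_start"] < ADULT_ONSET_AGE - 1e-9).any():
        bad = df.loc[df["age_start"] < ADULT_ONSET_AGE - 1e-9, "individual_id"]
        raise PanelIntegrityError(
            f"age_start < {ADULT_ONSET_AGE} for individuals {sorted(set(bad))}"
        )
    if (df["observation_days"] < 0).any():
        raise PanelIntegrityError("negative observation_days")
    # consecutive adult years must advance age by exactly one year
    for ind, grp in df.groupby("individual_id", sort=False):
        g = grp.sort_values("year_index")
        years = g["year_index"].to_numpy()
        ages = g["age_start"].to_numpy(dtype=float)
        consec = np.diff(years) == 1
        if consec.any() and not np.allclose(np.diff(ages)[consec], 1.0, atol=1e-6):
            raise PanelIntegrityError(
                f"individual {ind!r}: consecutive years do not advance age by 1.0"
            )
    for t in panel.registry:
        if t.name not in df.columns:
            raise PanelSchemaError(f"registered trait {t.name!r} absent from panel")
        vals = df[t.name]
        observed = vals.dropna()
        if t.kind == "binary":
            bad = ~observed.isin(BINARY_LEVELS)
            if bad.any():
                raise PanelSchemaError(
                    f"binary trait {t.name!r} has values outside {{0,1}}: "
                    f"{sorted(set(observed[bad]))}"
                )
        elif t.kind == "categorical3":
            bad = ~observed.isin(CATEGORICAL3_LEVELS)
            if bad.any():
                raise PanelSchemaError(
                    f"categorical3 trait {t.name!r} has values outside {{0,1,2}}: "
                    f"{sorted(set(observed[bad]))}"
                )


# -- I/O ----------------------------------------------------------------------


def read_panel(
    source, registry: Sequence[TraitSpec], provenance: str = ""
) -> CohortPanel:
    """Read a panel CSV and validate it against ``registry``.

    The header must contain :data:`ID_COLUMNS`; every trait in the registry
    must be present; any column that is neither an identifier, an optional
    column, nor a registered trait is treated as a covariate and passed
    through untouched.  Missing values are empty fields or ``NA``.
    """
    registry = tuple(registry)
    df = pd.read_csv(
        source, na_values=list(MISSING_MARKERS), keep_default_na=False
    )
    missing_ids = [c for c in ID_COLUMNS if c not in df.columns]
    if missing_ids:
        raise PanelSchemaError(f"missing identifier columns: {missing_ids}")
    known = set(ID_COLUMNS) | set(OPTIONAL_COLUMNS) | {t.name for t in registry}
    extra_traits = [
        c
        for c in df.columns
        if c not in known and c.startswith("trait_")
    ]
    if extra_traits:
        raise PanelSchemaError(f"unknown trait columns: {extra_traits}")
    for t in registry:
        if t.name in df.columns:
            df[t.name] = pd.to_numeric(df[t.name], errors="raise")
    return CohortPanel(df, registry, provenance=provenance)


def write_panel(panel: CohortPanel, dest) -> None:
    """Write the panel as CSV with ``NA`` missing markers (round-trips)."""
    panel.df.to_csv(dest, index=False, na_rep="NA", lineterminator="\n")


def panel_roundtrip(panel: CohortPanel) -> CohortPanel:
    buf = io.StringIO()
    write_panel(panel, buf)
    buf.seek(0)
    return read_panel(buf, panel.registry, provenance=panel.provenance)


# -- inclusion filters --------------------------------------------------------


@dataclass
class FilterReport:
    """Row-level record of which individual-years were dropped and why."""

    dropped: pd.DataFrame  # columns: individual_id, year_index, reason
    n_input: int = 0
    n_retained: int = 0

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def apply_inclusion_filters(
    panel: CohortPanel,
    min_days: int = 60,
    max_missing: int = 32,
    n_traits: int | None = None,
) -> tuple[CohortPanel, FilterReport]:
    """Drop female-years observed for fewer than ``min_days`` days or with at
    least ``max_missing`` of the clock traits missing.

    ``n_traits`` is a guard: if given, the registry must contain exactly that
    many traits (the missingness threshold is stated relative to it).
    """
    traits = panel.trait_names
    if n_traits is not None and len(traits) != n_traits:
        raise PanelSchemaError(
            f"panel carries {len(traits)} traits; expected {n_traits}"
        )
    df = panel.df
    n_miss = df[traits].isna().sum(axis=1)
    too_few_days = df["observation_days"] < min_days
    too_missing = n_miss >= max_missing
    drop_mask = too_few_days | too_missing

    reasons = []
    for i in df.index[drop_mask]:
        why = []
        if too_few_days.loc[i]:
            why.append(f"observation_days<{min_days}")
        if too_missing.loc[i]:
            why.append(f"missing_traits>={max_missing}")
        reasons.append(
            (df.at[i, "individual_id"], df.at[i, "year_index"], "+".join(why))
        )
    report = FilterReport(
        dropped=pd.DataFrame(
            reasons, columns=["individual_id", "year_index", "reason"]
        ),
        n_input=len(df),
        n_retained=int((~drop_mask).sum()),
    )
    filtered = CohortPanel(
        df.loc[~drop_mask].reset_index(drop=True),
        panel.registry,
        provenance=panel.provenance,
    )
    return filtered, report


# -- annualization of sample-level measures -----------------------------------


def annualize_sample_residuals(
    measures: pd.DataFrame,
    covariates: Sequence[str] = (),
    value_col: str = "value",
) -> pd.DataFrame:
    """Residualize sample-level measurements and average within individual-years.

    ``measures`` has one row per sample with columns ``individual_id``,
    ``year_index``, ``value_col`` and any covariate columns.  A single linear
    model (with intercept) of value on ``covariates`` is fitted across all
    samples; residuals are averaged per (individual_id, year_index).
    Individual-years with no samples simply do not appear in the output.
    """
    required = ["individual_id", "year_index", value_col, *covariates]
    missing = [c for c in required if c not in measures.columns]
    if missing:
        raise CovariateModelError(f"measures table lacks columns {missing}")
    y = measures[value_col].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(measures))]
        + [measures[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CovariateModelError(
            f"rank-deficient covariate model with covariates {list(covariates)}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = measures[["individual_id", "year_index"]].copy()
    out["residual"] = resid
    return (
        out.groupby(["individual_id", "year_index"], as_index=False)["residual"]
        .mean()
    )


# -- standardization ----------------------------------------------------------


def standardize_traits(
    panel: CohortPanel, stats: pd.DataFrame | None = None
) -> tuple[CohortPanel, pd.DataFrame]:
    """Center and scale continuous traits; binary/categorical pass through.

    Uses the sample standard deviation (``ddof=1``).  If ``stats`` is supplied
    (a frame indexed by trait with columns ``location`` and ``scale``) it is
    applied as-is — this is how test partitions reuse training statistics.
    Zero-variance traits are centered only (``scale`` recorded as 1.0 and
    flagged in the ``zero_variance`` column).
    """
    df = panel.df.copy()
    cont = panel.traits_of_kind("continuous")
    if stats is None:
        rows = []
        for name in cont:
            loc = float(df[name].mean())
            sd = float(df[name].std(ddof=1))
            zero = not np.isfinite(sd) or sd <= 0.0
            rows.append((name, loc, 1.0 if zero else sd, zero))
        stats = pd.DataFrame(
            rows, columns=["trait", "location", "scale", "zero_variance"]
        ).set_index("trait")
    for name in cont:
        if name not in stats.index:
            raise PanelSchemaError(f"supplied stats lack trait {name!r}")
        loc = stats.at[name, "location"]
        scale = stats.at[name, "scale"]
        df[name] = (df[name] - loc) / scale
    return CohortPanel(df, panel.registry, provenance=panel.provenance), stats


def destandardize_traits(panel: CohortPanel, stats: pd.DataFrame) -> CohortPanel:
    """Invert :func:`standardize_traits` given its returned stats."""
    df = panel.df.copy()
    for name in panel.traits_of_kind("continuous"):
        df[name] = df[name] * stats.at[name, "scale"] + stats.at[name, "location"]
    return CohortPanel(df, panel.registry, provenance=panel.provenance)
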