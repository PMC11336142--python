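"""End-to-end orchestration: simulate/load -> filter -> screen -> fill ->
split -> impute -> clock -> relative age -> survival -> adversity."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clock import clock_metrics, relative_age, repeatability, run_clock
from .datamodel import apply_inclusion_filters, write_panel
from .impute import build_imputed_sets, make_splits, neighbor_fill
from .screen import results_frame, screen_traits
from .simulate import SimConfig, impose_missingness, simulate_cohort
from .survival import (
    build_annual_records,
    build_lifetime_records,
    cumulative_adversity,
    fit_cox,
    fit_cox_with_adversity,
    fit_delta_age_lmm,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_simulation_study"]


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Flat declarative settings for one pipeline run."""

    seed: int
    out_dir: str = "npbclock_run"
    # input: either a simulation config or paths to panel/vitals/adversity CSVs
    simulation: dict = field(default_factory=dict)
    panel_path: str | None = None
    vitals_path: str | None = None
    adversity_path: str | None = None
    # filters
    min_days: int = 60
    max_missing_fraction: float = 0.65
    # screening
    run_screen: bool = True
    # splits / imputation
    n_splits: int = 5
    m_imputations: int = 5
    k_donors: int = 5
    n_burn: int = 3
    # forest
    ntree: int = 2000
    tune_ntree: int = 300
    mtry_grid: list | None = None
    # variants
    restricted_clock: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise PipelineError("config must set a seed")
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cox_result_dict(res) -> dict:
    return {
        "covariate": res.covariate,
        "coefficient": res.coefficient,
        "hazard_ratio": res.hazard_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
        "se": res.se,
        "se_type": res.se_type,
        "n_events": res.n_events,
        "n_records": res.n_records,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write artifacts under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        files.append(name)

    # --- stage: input ---------------------------------------------------------
    if config.panel_path:
        raise PipelineError(
            "external panel input requires a trait registry loader; "
            "use the library API (read_panel) directly"
        )
    sim = SimConfig(**config.simulation) if config.simulation else SimConfig()
    panel, truth = simulate_cohort(sim, seed=config.seed)
    vitals = truth.individuals[["individual_id", "entry_age", "end_age", "event"]].copy()
    adversity = truth.individuals[
        ["individual_id", "maternal_death", "close_sibling", "drought",
         "maternal_sci", "maternal_rank", "group_size"]
    ].copy()
    panel = impose_missingness(
        panel, sim.missing_rate, sim.missing_mechanism, seed=config.seed
    )
    emit("panel.csv", lambda p: write_panel(panel, p))
    emit("vitals.csv", lambda p: vitals.to_csv(p, index=False))
    emit("adversity.csv", lambda p: adversity.to_csv(p, index=False))
    truth_tab = truth.individuals
    emit("truth.csv", lambda p: truth_tab.to_csv(p, index=False))
    manifest["stages"]["input"] = {"n_records": panel.n_records, "n_traits": len(panel.registry)}

    # --- stage: screening -----------------------------------------------------
    if config.run_screen:
        screen_results, features = screen_traits(panel)
        frame = results_frame(screen_results)
        emit("screen_results.csv", lambda p: frame.to_csv(p, index=False))
        emit("features.txt", lambda p: p.write_text("\n".join(features) + "\n"))
    else:
        features = panel.trait_names
    if not features:
        raise PipelineError("screening selected no traits; clock cannot be built")
    manifest["stages"]["screen"] = {"n_selected": len(features)}

    # --- stage: filters -------------------------------------------------------
    clock_panel = panel.subset_traits(features)
    max_missing = int(np.ceil(config.max_missing_fraction * len(features)))
    filtered, report = apply_inclusion_filters(
        clock_panel, min_days=config.min_days, max_missing=max_missing
    )
    emit("filter_report.csv", lambda p: report.dropped.to_csv(p, index=False))
    manifest["stages"]["filter"] = {
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "max_missing": max_missing,
    }

    # --- stage: fill + splits + imputation ------------------------------------
    filled, fill_log = neighbor_fill(filtered, seed=config.seed)
    emit("fill_log.csv", lambda p: fill_log.to_csv(p, index=False))
    plan = make_splits(filled, n_splits=config.n_splits, seed=config.seed)
    sets = build_imputed_sets(
        filled,
        plan,
        m=config.m_imputations,
        k_donors=config.k_donors,
        n_burn=config.n_burn,
        seed=config.seed,
    )
    manifest["stages"]["impute"] = {"n_sets": len(sets)}

    # --- stage: clock ---------------------------------------------------------
    def _clock_pass(feature_list, tag: str):
        models, preds, mtry = run_clock(
            sets,
            feature_list,
            ntree=config.ntree,
            mtry_grid=config.mtry_grid,
            tune_ntree=config.tune_ntree,
            seed=config.seed,
        )
        preds, lifetime = relative_age(preds)
        metrics = clock_metrics(preds)
        try:
            rpt = repeatability(preds)
        except Exception:
            rpt = float("nan")
        emit(f"predictions{tag}.csv",
             lambda p: preds.to_csv(p, index=False, float_format="%.6f"))
        emit(f"lifetime_relative_age{tag}.csv",
             lambda p: lifetime.to_csv(p, float_format="%.6f"))
        manifest["stages"][f"clock{tag}"] = {
            "mtry": mtry,
            "ntree": config.ntree,
            "n_features": len(feature_list),
            "r_squared": metrics.r_squared,
            "median_abs_error": metrics.median_abs_error,
            "slope": metrics.slope_pred_vs_known,
            "repeatability": rpt,
        }
        return preds, lifetime

    preds, lifetime = _clock_pass(features, "")

    # --- stage: survival ------------------------------------------------------
    surv_out: dict = {}
    life_records = build_lifetime_records(lifetime, vitals)
    life_fit = fit_cox(life_records, ["lifetime_relative_age"])
    surv_out["lifetime"] = _cox_result_dict(life_fit["lifetime_relative_age"])
    annual_records = build_annual_records(preds, vitals)
    if annual_records["event"].sum() > 0:
        annual_fit = fit_cox(annual_records, ["relative_age"], cluster="individual_id")
        surv_out["annual"] = _cox_result_dict(annual_fit["relative_age"])

    # --- stage: adversity -----------------------------------------------------
    profiles, excluded = cumulative_adversity(adversity)
    lmm = fit_delta_age_lmm(
        preds.merge(
            panel.df[["individual_id", "year_index", "proportional_rank",
                      "group_size_year", "rainfall_anomaly"]],
            on=["individual_id", "year_index"], how="left",
        ),
        profiles,
        mode="cumulative",
    )
    emit("lmm_results.csv", lambda p: lmm.coefficients.to_csv(p, index=False))
    adv_records = life_records.merge(
        profiles[["individual_id", "cumulative_index"]], on="individual_id"
    )
    if adv_records["cumulative_index"].nunique() > 1:
        joint, attenuation = fit_cox_with_adversity(
            adv_records, "lifetime_relative_age"
        )
        surv_out["lifetime_with_adversity"] = {
            k: _cox_result_dict(v) for k, v in joint.items()
        }
        surv_out["attenuation_ratio"] = attenuation
    emit("cox_results.json", lambda p: p.write_text(json.dumps(surv_out, indent=2)))
    manifest["stages"]["survival"] = {
        "n_excluded_adversity": len(excluded),
        "lifetime_hr": surv_out["lifetime"]["hazard_ratio"],
    }

    # --- stage: restricted clock ----------------------------------------------
    if config.restricted_clock:
        linked = {t.name for t in panel.registry if t.mortality_linked}
        restricted_features = [f for f in features if f not in linked]
        if not restricted_features:
            raise PipelineError("restricted clock excludes every selected trait")
        rpreds, rlife = _clock_pass(restricted_features, "_restricted")
        r_records = build_lifetime_records(rlife, vitals)
        rfit = fit_cox(r_records, ["lifetime_relative_age"])
        manifest["stages"]["survival_restricted"] = {
            "lifetime_hr": rfit["lifetime_relative_age"].hazard_ratio
        }
        both = preds.merge(
            rpreds[["individual_id", "year_index", "predicted_age"]],
            on=["individual_id", "year_index"],
            suffixes=("", "_restricted"),
        )
        manifest["stages"]["restricted_correlation"] = float(
            np.corrcoef(both["predicted_age"], both["predicted_age_restricted"])[0, 1]
        )

    manifest["files"] = files
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def run_simulation_study(config: PipelineConfig, n_replicates: int = 1) -> dict:
    """Replicate simulate->pipeline and summarize recovery of the generating
    truth: frailty correlation, lifetime HR, adversity coefficient."""
    if n_replicates < 1:
        raise PipelineError("n_replicates must be >= 1")
    rows = []
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(
            config,
            seed=config.seed + rep,
            out_dir=str(Path(config.out_dir) / f"rep{rep:03d}"),
        )
        manifest = run_pipeline(rep_cfg)
        out = Path(rep_cfg.out_dir)
        truth = pd.read_csv(out / "truth.csv")
        lifetime = pd.read_csv(out / "lifetime_relative_age.csv", index_col=0)
        merged = truth.set_index("individual_id").join(lifetime, how="inner")
        corr = float(
            np.corrcoef(merged["frailty"], merged["lifetime_relative_age"])[0, 1]
        )
        rows.append(
            {
                "replicate": rep,
                "frailty_recovery_corr": corr,
                "clock_r_squared": manifest["stages"]["clock"]["r_squared"],
                "lifetime_hr": manifest["stages"]["survival"]["lifetime_hr"],
            }
        )
    frame = pd.DataFrame(rows)
    report = {"n_replicates": n_replicates, "replicates": rows}
    if n_replicates > 1:
        for col in ("frailty_recovery_corr", "clock_r_squared", "lifetime_hr"):
            vals = frame[col].to_numpy()
            half = 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
            report[col] = {
                "mean": float(vals.mean()),
                "ci_low": float(vals.mean() - half),
                "ci_high": float(vals.mean() + half),
            }
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "study_report.json").write_text(json.dumps(report, indent=2))
    return report
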