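import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from npbclock.survival import (
    SurvivalError,
    build_annual_records,
    build_lifetime_records,
    cumulative_adversity,
    fit_cox,
    fit_cox_with_adversity,
    fit_delta_age_lmm,
)


# -- independent oracle: Efron partial likelihood on counting-process data ----


def efron_loglik(beta, start, stop, event, x):
    """Counting-process Efron partial log-likelihood for a single covariate."""
    ll = 0.0
    for t in np.unique(stop[event == 1]):
        dead = (stop == t) & (event == 1)
        at_risk = (start < t) & (t <= stop)
        d = int(dead.sum())
        theta_risk = np.exp(beta * x[at_risk]).sum()
        theta_dead = np.exp(beta * x[dead]).sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= np.log(theta_risk - (l / d) * theta_dead)
    return ll


def oracle_coef(start, stop, event, x):
    res = minimize_scalar(
        lambda b: -efron_loglik(b, start, stop, event, x),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return res.x


def _records(start, stop, event, x, name="x"):
    return pd.DataFrame(
        {
            "individual_id": [f"F{i}" for i in range(len(start))],
            "start_age": start,
            "stop_age": stop,
            "event": event,
            name: x,
        }
    )


class TestFitCoxOracle:
    def test_eight_observation_binary_fixture(self):
        start = np.zeros(8)
        stop = np.array([2.0, 3.0, 3.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0])
        rec = _records(start, stop, event, x)
        fit = fit_cox(rec, ["x"])["x"]
        expected = oracle_coef(start, stop, event, x)
        assert fit.coefficient == pytest.approx(expected, abs=1e-4)
        assert fit.hazard_ratio == pytest.approx(np.exp(expected), rel=1e-3)
        assert fit.n_events == 6

    def test_delayed_entry_fixture(self):
        start = np.array([0.0, 1.0, 2.0, 0.0, 3.0, 1.0])
        stop = np.array([4.0, 5.0, 6.0, 3.0, 7.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([0.5, -0.5, 1.5, 0.0, -1.0, 1.0])
        rec = _records(start, stop, event, x)
        fit = fit_cox(rec, ["x"])["x"]
        expected = oracle_coef(start, stop, event, x)
        assert fit.coefficient == pytest.approx(expected, abs=1e-4)

    def test_tied_event_times_match_efron(self):
        start = np.zeros(10)
        stop = np.array([2.0, 2.0, 2.0, 4.0, 4.0, 5.0, 6.0, 6.0, 7.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 1, 1, 1, 0, 1])
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        rec = _records(start, stop, event, x)
        fit = fit_cox(rec, ["x"])["x"]
        expected = oracle_coef(start, stop, event, x)
        assert fit.coefficient == pytest.approx(expected, abs=1e-4)


class TestFitCoxProperties:
    @staticmethod
    def _sim_records(n=300, beta=0.5, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        h = 0.1 * np.exp(beta * x)
        death = rng.exponential(1.0 / h)
        censor = rng.uniform(2, 25, size=n)
        stop = np.minimum(death, censor)
        event = (death <= censor).astype(int)
        return _records(np.zeros(n), stop, event, x)

    def test_centering_invariance(self):
        rec = self._sim_records()
        f1 = fit_cox(rec, ["x"])["x"]
        rec2 = rec.copy()
        rec2["x"] = rec2["x"] + 100.0
        f2 = fit_cox(rec2, ["x"])["x"]
        assert f2.coefficient == pytest.approx(f1.coefficient, abs=1e-6)

    def test_rescaling_transforms_hazard_ratio(self):
        rec = self._sim_records(seed=1)
        f1 = fit_cox(rec, ["x"])["x"]
        rec2 = rec.copy()
        rec2["x"] = rec2["x"] / 2.0
        f2 = fit_cox(rec2, ["x"])["x"]
        assert f2.coefficient == pytest.approx(2.0 * f1.coefficient, rel=1e-4)

    def test_interval_splitting_invariance(self):
        # splitting any interval at an event-free time leaves the counting-
        # process likelihood, hence the coefficient, unchanged
        rec = self._sim_records(n=120, seed=2)
        f1 = fit_cox(rec, ["x"])["x"]
        rows = []
        for _, r in rec.iterrows():
            mid = 0.5 * (r["start_age"] + r["stop_age"])
            rows.append({**r, "stop_age": mid, "event": 0})
            rows.append({**r, "start_age": mid})
        split = pd.DataFrame(rows)
        f2 = fit_cox(split, ["x"])["x"]
        assert f2.coefficient == pytest.approx(f1.coefficient, abs=1e-6)

    def test_cluster_duplication_sandwich_property(self):
        rec = self._sim_records(n=150, seed=3)
        rec["individual_id"] = [f"F{i}" for i in range(len(rec))]
        base_naive = fit_cox(rec, ["x"])["x"]
        dup = pd.concat([rec, rec], ignore_index=True)
        dup_naive = fit_cox(dup, ["x"])["x"]
        dup_robust = fit_cox(dup, ["x"], cluster="individual_id")["x"]
        # duplication creates tied events; Efron's tie correction is only
        # approximately duplication-invariant (Breslow's would be exact)
        assert dup_naive.coefficient == pytest.approx(base_naive.coefficient, rel=0.01)
        # naive SE shrinks by sqrt(2) under duplication...
        assert dup_naive.se == pytest.approx(base_naive.se / np.sqrt(2), rel=0.01)
        # ...while the grouped sandwich recovers the original uncertainty
        assert dup_robust.se == pytest.approx(base_naive.se, rel=0.05)

    def test_no_events_rejected(self):
        rec = _records(np.zeros(3), np.ones(3), np.zeros(3, int), np.arange(3.0))
        with pytest.raises(SurvivalError, match="no events"):
            fit_cox(rec, ["x"])

    def test_constant_covariate_rejected(self):
        rec = _records(np.zeros(3), np.ones(3), np.ones(3, int), np.ones(3))
        with pytest.raises(SurvivalError, match="constant"):
            fit_cox(rec, ["x"])


class TestBuildLifetimeRecords:
    @staticmethod
    def _vitals(n, n_events):
        return pd.DataFrame(
            {
                "individual_id": [f"F{i}" for i in range(n)],
                "entry_age": 4.0,
                "end_age": np.linspace(6, 20, n),
                "event": [1] * n_events + [0] * (n - n_events),
            }
        )

    def test_one_interval_per_individual_with_events(self):
        vit = self._vitals(20, 12)
        lifetime = pd.Series(
            np.linspace(-1, 1, 20), index=vit["individual_id"],
            name="lifetime_relative_age",
        )
        rec = build_lifetime_records(lifetime, vit)
        assert len(rec) == 20
        assert rec["event"].sum() == 12

    def test_all_censored(self):
        vit = self._vitals(5, 0)
        lifetime = pd.Series(np.zeros(5), index=vit["individual_id"])
        rec = build_lifetime_records(lifetime, vit)
        assert (rec["event"] == 0).all()

    def test_delayed_entry_from_first_observation(self):
        vit = self._vitals(3, 1)  # end ages 6, 13, 20
        lifetime = pd.Series([0.1, 0.2, 0.3], index=vit["individual_id"])
        first_obs = pd.Series([5.5, 4.0, 6.0], index=vit["individual_id"])
        rec = build_lifetime_records(lifetime, vit, first_observed_age=first_obs)
        assert rec.loc[0, "start_age"] == 5.5
        assert rec.loc[1, "start_age"] == 4.0
        assert rec.loc[2, "start_age"] == 6.0

    def test_missing_vital_record_rejected(self):
        vit = self._vitals(2, 1)
        lifetime = pd.Series([0.1, 0.2, 0.3], index=["F0", "F1", "FX"])
        with pytest.raises(SurvivalError, match="lacking vital"):
            build_lifetime_records(lifetime, vit)


class TestBuildAnnualRecords:
    @staticmethod
    def _preds(ids_years_ages, rel):
        return pd.DataFrame(
            {
                "individual_id": [r[0] for r in ids_years_ages],
                "year_index": [r[1] for r in ids_years_ages],
                "known_age": [r[2] for r in ids_years_ages],
                "relative_age": rel,
            }
        )

    def test_death_in_final_interval_only(self):
        preds = self._preds([("A", y, 4.0 + y) for y in range(7)], np.zeros(7))
        vitals = pd.DataFrame(
            {"individual_id": ["A"], "entry_age": [4.0], "end_age": [10.6], "event": [1]}
        )
        rec = build_annual_records(preds, vitals)
        assert len(rec) == 7
        assert rec["event"].tolist() == [0, 0, 0, 0, 0, 0, 1]
        assert rec.iloc[-1]["stop_age"] == pytest.approx(10.6)

    def test_filtered_death_year_contributes_no_event(self):
        # death at 10.6 but the year-6 record (age 10) was filtered out
        preds = self._preds([("A", y, 4.0 + y) for y in range(6)], np.zeros(6))
        vitals = pd.DataFrame(
            {"individual_id": ["A"], "entry_age": [4.0], "end_age": [10.6], "event": [1]}
        )
        rec = build_annual_records(preds, vitals)
        assert rec["event"].sum() == 0

    def test_interval_length_at_most_one(self):
        preds = self._preds(
            [("A", y, 4.0 + y) for y in range(5)] + [("B", y, 4.0 + y) for y in range(3)],
            np.zeros(8),
        )
        vitals = pd.DataFrame(
            {
                "individual_id": ["A", "B"],
                "entry_age": [4.0, 4.0],
                "end_age": [9.0, 6.4],
                "event": [1, 0],
            }
        )
        rec = build_annual_records(preds, vitals)
        assert ((rec["stop_age"] - rec["start_age"]) <= 1.0 + 1e-12).all()
        assert rec["stop_age"].max() <= 9.0

    def test_missing_vitals_rejected(self):
        preds = self._preds([("A", 0, 4.0)], [0.0])
        vitals = pd.DataFrame(
            {"individual_id": ["B"], "entry_age": [4.0], "end_age": [9.0], "event": [0]}
        )
        with pytest.raises(SurvivalError, match="no vitals"):
            build_annual_records(preds, vitals)


class TestCumulativeAdversity:
    @staticmethod
    def _profiles(n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "individual_id": [f"F{i}" for i in range(n)],
                "maternal_death": rng.integers(0, 2, n),
                "close_sibling": rng.integers(0, 2, n),
                "drought": rng.integers(0, 2, n),
                "maternal_sci": rng.normal(size=n),
                "maternal_rank": rng.normal(size=n),
                "group_size": rng.normal(size=n),
            }
        )

    def test_sum_of_flags(self):
        prof = self._profiles()
        prof.loc[0, ["maternal_death", "close_sibling", "drought"]] = [1, 0, 1]
        prof.loc[0, ["maternal_sci", "maternal_rank"]] = 10.0  # benign side
        prof.loc[0, "group_size"] = -10.0  # benign side
        out, _ = cumulative_adversity(prof)
        row = out[out["individual_id"] == "F0"].iloc[0]
        assert row["cumulative_index"] == 2

    def test_quartile_boundary_inclusive(self):
        prof = self._profiles(5)
        prof["group_size"] = [1.0, 2.0, 3.0, 4.0, 5.0]  # 75th percentile = 4.0
        out, _ = cumulative_adversity(prof)
        flags = out.set_index("individual_id")["flag_group_size"]
        assert flags.tolist() == [0, 0, 0, 1, 1]

    def test_all_benign_index_zero(self):
        prof = self._profiles()
        prof.loc[0, ["maternal_death", "close_sibling", "drought"]] = 0
        prof.loc[0, ["maternal_sci", "maternal_rank"]] = 10.0
        prof.loc[0, "group_size"] = -10.0
        out, _ = cumulative_adversity(prof)
        assert out[out["individual_id"] == "F0"].iloc[0]["cumulative_index"] == 0

    def test_missing_source_excluded(self):
        prof = self._profiles()
        prof.loc[3, "maternal_sci"] = np.nan
        out, excluded = cumulative_adversity(prof)
        assert excluded == ["F3"]
        assert "F3" not in set(out["individual_id"])

    def test_quarter_flagged_per_continuous_source(self):
        prof = self._profiles(400, seed=1)
        out, _ = cumulative_adversity(prof)
        for src in ("maternal_sci", "maternal_rank", "group_size"):
            assert abs(out[f"flag_{src}"].mean() - 0.25) < 0.02


class TestDeltaAgeLmm:
    @staticmethod
    def _data(effect=0.3, n_ind=80, seed=0):
        rng = np.random.default_rng(seed)
        profiles = pd.DataFrame(
            {
                "individual_id": [f"F{i}" for i in range(n_ind)],
                "cumulative_index": rng.integers(0, 5, n_ind),
            }
        )
        rows = []
        for _, p in profiles.iterrows():
            base = effect * p["cumulative_index"] + rng.normal(scale=0.3)
            for y in range(rng.integers(3, 8)):
                rows.append(
                    {
                        "individual_id": p["individual_id"],
                        "known_age": 4.0 + y,
                        "delta_age": base + rng.normal(scale=0.5),
                        "proportional_rank": rng.uniform(),
                        "group_size_year": rng.normal(25, 5),
                        "rainfall_anomaly": rng.normal(),
                    }
                )
        return pd.DataFrame(rows), profiles

    def test_recovers_adversity_effect(self):
        preds, profiles = self._data(effect=0.3, seed=1)
        res = fit_delta_age_lmm(preds, profiles, mode="cumulative")
        coef = res.coef("cumulative_index")
        se = res.se("cumulative_index")
        assert abs(coef - 0.3) < 2.5 * se

    def test_constant_delta_age_zero_coefficients(self):
        preds, profiles = self._data(seed=2)
        preds["delta_age"] = 1.5
        res = fit_delta_age_lmm(preds, profiles, mode="cumulative")
        assert res.coef("cumulative_index") == pytest.approx(0.0, abs=1e-8)

    def test_multivariable_mode_uses_six_sources(self):
        preds, profiles = self._data(seed=3)
        rng = np.random.default_rng(3)
        for c in ("maternal_death", "close_sibling", "drought"):
            profiles[c] = rng.integers(0, 2, len(profiles))
        for c in ("maternal_sci", "maternal_rank", "group_size"):
            profiles[c] = rng.normal(size=len(profiles))
        res = fit_delta_age_lmm(preds, profiles, mode="multivariable")
        terms = set(res.coefficients["term"])
        assert {"maternal_death", "maternal_sci", "group_size", "known_age"} <= terms


class TestCoxWithAdversity:
    def test_full_confounding_attenuates(self):
        # adversity drives frailty entirely; relative age is a noisy frailty
        # readout; conditioning on the index must pull the relative-age
        # coefficient toward zero
        rng = np.random.default_rng(4)
        n = 400
        index = rng.integers(0, 4, n).astype(float)
        frailty = 0.8 * index
        rel_age = frailty + rng.normal(scale=0.4, size=n)
        h = 0.08 * np.exp(0.5 * frailty)
        death = rng.exponential(1.0 / h)
        censor = rng.uniform(5, 30, n)
        rec = pd.DataFrame(
            {
                "individual_id": [f"F{i}" for i in range(n)],
                "start_age": 0.0,
                "stop_age": np.minimum(death, censor),
                "event": (death <= censor).astype(int),
                "rel": rel_age,
                "cumulative_index": index,
            }
        )
        joint, attenuation = fit_cox_with_adversity(rec, "rel")
        assert attenuation < 0.8

    def test_independent_adversity_no_attenuation(self):
        rng = np.random.default_rng(5)
        n = 400
        index = rng.integers(0, 4, n).astype(float)
        rel_age = rng.normal(size=n)
        h = 0.08 * np.exp(0.5 * rel_age)
        death = rng.exponential(1.0 / h)
        censor = rng.uniform(5, 30, n)
        rec = pd.DataFrame(
            {
                "individual_id": [f"F{i}" for i in range(n)],
                "start_age": 0.0,
                "stop_age": np.minimum(death, censor),
                "event": (death <= censor).astype(int),
                "rel": rel_age,
                "cumulative_index": index,
            }
        )
        joint, attenuation = fit_cox_with_adversity(rec, "rel")
        assert attenuation == pytest.approx(1.0, abs=0.15)

    def test_constant_index_rejected(self):
        rec = pd.DataFrame(
            {
                "individual_id": ["A", "B", "C"],
                "start_age": 0.0,
                "stop_age": [1.0, 2.0, 3.0],
                "event": [1, 1, 0],
                "rel": [0.1, 0.5, -0.2],
                "cumulative_index": 2.0,
            }
        )
        with pytest.raises(SurvivalError, match="constant"):
            fit_cox_with_adversity(rec, "rel")
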