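"""Cox feature models, eligibility filtering and Kaplan-Meier splits."""

import numpy as np
import pandas as pd
import pytest

from repnet.survival import (
    cox_feature_model,
    eligible_tumor_types,
    km_median_split,
    survival_scan,
)
from repnet.synthetic import simulate_feature_cohort, simulate_survival_outcomes

from .oracles import km_product_limit


def survival_frame(rng, n, beta=0.0, censoring=0.3, sex=None):
    f = rng.normal(0, 1, n)
    t, e = simulate_survival_outcomes(f, beta, 1 / 1500, censoring, rng)
    return pd.DataFrame(
        {
            "feat": f,
            "os_time": t,
            "os_event": e,
            "age_at_diagnosis": np.clip(rng.normal(62, 11, n), 25, 90),
            "sex": sex if sex is not None else rng.choice(["female", "male"], n),
            "stage_group": rng.choice(["early", "late"], n),
        }
    )


class TestEligibility:
    def make_clinical(self, events_by_type):
        rows = []
        for tt, n_events in events_by_type.items():
            for i in range(n_events + 20):
                rows.append(
                    {"tumor_type": tt, "os_event": 1 if i < n_events else 0}
                )
        return pd.DataFrame(rows)

    def test_threshold_is_at_least(self):
        clinical = self.make_clinical({"LOW": 39, "EDGE": 40, "HIGH": 90})
        assert eligible_tumor_types(clinical) == {"EDGE", "HIGH"}

    def test_empty_cohort(self):
        assert eligible_tumor_types(pd.DataFrame(columns=["tumor_type", "os_event"])) == set()


class TestCoxFeatureModel:
    def test_null_feature_hazard_near_one(self):
        rng = np.random.default_rng(0)
        fit = cox_feature_model(survival_frame(rng, 500, beta=0.0), "feat")
        assert 0.85 <= fit.hazard_ratio <= 1.18

    def test_planted_log2_effect_recovered(self):
        rng = np.random.default_rng(1)
        fit = cox_feature_model(survival_frame(rng, 500, beta=np.log(2)), "feat")
        assert 1.7 <= fit.hazard_ratio <= 2.35

    def test_single_sex_cohort_drops_covariate_and_fits(self):
        rng = np.random.default_rng(2)
        df = survival_frame(rng, 120, sex=np.repeat("female", 120))
        fit = cox_feature_model(df, "feat")
        assert fit.converged
        assert "is_male" not in fit.covariates_used
        assert "age" in fit.covariates_used

    def test_constant_feature_is_missing(self):
        rng = np.random.default_rng(3)
        df = survival_frame(rng, 60)
        df["feat"] = 1.0
        fit = cox_feature_model(df, "feat")
        assert fit.missing

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        df = survival_frame(rng, 300, beta=0.5)
        fit1 = cox_feature_model(df, "feat")
        df10 = df.copy()
        df10["feat"] = df10["feat"] * 10
        fit10 = cox_feature_model(df10, "feat")
        assert fit10.coef == pytest.approx(fit1.coef / 10, rel=1e-4)
        assert fit10.p_value == pytest.approx(fit1.p_value, rel=1e-3)


class TestSurvivalScan:
    def test_protective_entropy_effect_recovered(self):
        rng = np.random.default_rng(5)
        df = simulate_feature_cohort(250, rng, survival_beta=-np.log(2))
        res = survival_scan(df, min_events=40)
        row = res[(res["chain"] == "IGH") & (res["feature"] == "entropy_H")]
        assert len(row) == 1
        assert row["hazard_ratio"].iloc[0] < 1

    def test_group_below_event_threshold_omitted(self):
        rng = np.random.default_rng(6)
        df = simulate_feature_cohort(20, rng)
        res = survival_scan(df, min_events=40)
        assert res.empty

    def test_subtype_grouping_is_parametric(self):
        rng = np.random.default_rng(7)
        df = simulate_feature_cohort(150, rng)
        df["subtype"] = np.where(
            df["sample_id"].rank(method="dense") % 2 == 0, "LUMA", "BASAL"
        )
        res = survival_scan(df, group_col="subtype", min_events=20)
        assert set(res["subtype"]) <= {"LUMA", "BASAL"}
        assert (res.groupby("subtype").size() == 15).all()


class TestKaplanMeier:
    def clinical(self, times, events, values=None):
        n = len(times)
        return pd.DataFrame(
            {
                "os_time": times,
                "os_event": events,
                "feat": values if values is not None else np.arange(n, dtype=float),
            }
        )

    def test_distinct_event_times_drop_one_over_n(self):
        n = 8
        df = self.clinical(np.arange(1, n + 1, dtype=float), np.ones(n, dtype=int))
        split = km_median_split(df, "feat")
        # each side: all events at distinct times -> steps of 1/n_side
        for side, n_side in ((split.low, split.n_low), (split.high, split.n_high)):
            surv = side["survival"].to_numpy()
            steps = np.diff(surv[surv < 1.0], prepend=1.0)
            assert np.allclose(steps, -1.0 / n_side)

    def test_all_censored_curve_stays_at_one(self):
        df = self.clinical([5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0])
        split = km_median_split(df, "feat")
        assert (split.low["survival"] == 1.0).all()
        assert (split.high["survival"] == 1.0).all()

    def test_curves_non_increasing_and_start_at_one(self):
        rng = np.random.default_rng(8)
        df = self.clinical(
            rng.exponential(100, 30), rng.integers(0, 2, 30), rng.normal(size=30)
        )
        split = km_median_split(df, "feat")
        for side in (split.low, split.high):
            s = side["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)

    def test_median_ties_go_to_low_group(self):
        values = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        df = self.clinical(np.arange(1.0, 7.0), np.ones(6, dtype=int), values)
        split = km_median_split(df, "feat")
        # median is 2.5; values <= 2.5 -> low
        assert split.n_low == 3
        assert split.n_high == 3

    def test_degenerate_split_rejected(self):
        df = self.clinical([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], np.ones(4))
        with pytest.raises(ValueError):
            km_median_split(df, "feat")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_product_limit_oracle(self, seed):
        rng = np.random.default_rng(seed)
        times = np.round(rng.exponential(50, 10), 0) + 1
        events = rng.integers(0, 2, 10)
        if events.sum() == 0:
            events[0] = 1
        df = self.clinical(times, events, rng.normal(size=10))
        split = km_median_split(df, "feat")
        for side_df, mask in (
            (split.low, df["feat"] <= split.threshold),
            (split.high, df["feat"] > split.threshold),
        ):
            oracle = km_product_limit(times[mask.to_numpy()], events[mask.to_numpy()])
            got = dict(zip(side_df["time"], side_df["survival"]))
            for t, s in oracle.items():
                assert got[t] == pytest.approx(s, abs=1e-9)


class TestRecoveryCalibration:
    def test_beta_recovery_bias_and_coverage(self):
        """Over repeated cohorts with a known log-2 hazard coefficient the
        estimator should be nearly unbiased with near-nominal CI coverage."""
        beta = np.log(2)
        rng = np.random.default_rng(2024)
        coefs, covered = [], 0
        n_cohorts = 40
        for _ in range(n_cohorts):
            fit = cox_feature_model(survival_frame(rng, 300, beta=beta), "feat")
            coefs.append(fit.coef)
            covered += fit.ci_lower <= beta <= fit.ci_upper
        assert abs(np.mean(coefs) / beta - 1) <= 0.15
        assert 0.90 - 0.08 <= covered / n_cohorts <= 1.0
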