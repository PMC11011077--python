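import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from gbmsize import (
    apply_censoring,
    generate_cohort,
    lognormal_from_quartiles,
    null_config,
    paper_like_config,
    sample_covariates,
    sample_survival_times,
    summarize_cohort,
    truncnorm_from_quartiles,
)
from gbmsize.cohort import linear_predictor


class TestQuartileMatching:
    def test_lognormal_from_published_core_volume_summary(self):
        dist = lognormal_from_quartiles(28.1, 12.6, 50.3)
        assert dist.mu == pytest.approx(3.3357, abs=1e-4)
        assert dist.sigma == pytest.approx(1.0263, abs=1e-3)

    def test_lognormal_symmetric_on_log_scale(self):
        dist = lognormal_from_quartiles(np.e, 1.0, np.e**2)
        assert dist.mu == pytest.approx(1.0)
        assert dist.sigma == pytest.approx(2.0 / (2 * 0.6744897501960817))

    def test_zero_spread_flagged_degenerate(self):
        dist = lognormal_from_quartiles(5.0, 5.0, 5.0)
        assert dist.degenerate
        np.testing.assert_allclose(dist.ppf(np.array([0.1, 0.9])), 5.0, rtol=1e-12)

    @pytest.mark.parametrize("args", [(0.0, 1.0, 2.0), (5.0, 6.0, 4.0), (-1.0, 0.5, 2.0)])
    def test_invalid_quartiles_rejected(self, args):
        median, q1, q3 = args
        with pytest.raises(ValueError):
            lognormal_from_quartiles(median, q1, q3)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        mu=st.floats(-1.0, 4.0),
        sigma=st.floats(0.05, 1.5),
    )
    def test_lognormal_quartiles_recovered_exactly(self, mu, sigma):
        # theoretical quartiles of the fitted distribution equal the inputs
        z = 0.6744897501960817
        median, q1, q3 = np.exp([mu, mu - z * sigma, mu + z * sigma])
        dist = lognormal_from_quartiles(median, q1, q3)
        assert dist.quantile(0.5) == pytest.approx(median, rel=1e-9)
        assert dist.quantile(0.75) - dist.quantile(0.25) == pytest.approx(q3 - q1, rel=1e-7)

    def test_truncnorm_quartiles_recovered_after_truncation(self):
        dist = truncnorm_from_quartiles(4.4, 3.3, 5.4, lo=0.5)
        assert dist.quantile(0.5) == pytest.approx(4.4, abs=1e-8)
        assert dist.quantile(0.75) - dist.quantile(0.25) == pytest.approx(2.1, abs=1e-8)

    def test_truncnorm_strong_truncation_still_matches(self):
        # contract: the truncated distribution matches the median and IQR
        dist = truncnorm_from_quartiles(1.0, 0.6, 1.5, lo=0.0, hi=2.0)
        assert dist.quantile(0.5) == pytest.approx(1.0, abs=1e-8)
        assert dist.quantile(0.75) - dist.quantile(0.25) == pytest.approx(0.9, abs=1e-6)

    def test_truncnorm_unachievable_iqr_rejected(self):
        # IQR equal to half the window width is the uniform limit
        with pytest.raises(ValueError, match="not achievable"):
            truncnorm_from_quartiles(1.0, 0.5, 1.6, lo=0.0, hi=2.0)


class TestSurvivalSampling:
    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(0)
        t = sample_survival_times(np.zeros(200_000), 1.0, 12 / np.log(2), rng)
        assert np.median(t) == pytest.approx(12.0, rel=0.02)

    def test_doubling_hazard_halves_median(self):
        rng = np.random.default_rng(1)
        t = sample_survival_times(np.full(200_000, np.log(2)), 1.0, 12 / np.log(2), rng)
        assert np.median(t) == pytest.approx(6.0, rel=0.02)

    def test_weibull_median_closed_form(self):
        shape, scale = 1.2, 20.0
        rng = np.random.default_rng(2)
        t = sample_survival_times(np.zeros(100_000), shape, scale, rng)
        assert np.median(t) == pytest.approx(scale * np.log(2) ** (1 / shape), rel=0.02)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(ValueError):
            sample_survival_times(np.zeros(3), -1.0, 10.0, np.random.default_rng(0))


class TestCensoring:
    def test_no_censoring_when_all_events_before_window(self):
        rng = np.random.default_rng(0)
        t = np.array([1.0, 2.0, 3.0])
        time, event = apply_censoring(t, 100.0, 200.0, rng)
        assert np.all(event == 1)
        assert np.all(time == t)

    def test_censoring_forced_by_definition(self):
        # T=50 against a degenerate-ish window far below it
        rng = np.random.default_rng(0)
        time, event = apply_censoring(np.array([50.0]), 19.9999, 20.0001, rng)
        assert event[0] == 0
        assert time[0] == pytest.approx(20.0, abs=1e-3)

    def test_censored_fraction_matches_numeric_integral(self):
        # exponential T (median 12), C ~ U(10, 70):
        # P(censored) = (1/60) * int_10^70 S(t) dt, computed independently
        lam = np.log(2) / 12
        expected, _ = integrate.quad(lambda t: np.exp(-lam * t) / 60.0, 10, 70)
        rng = np.random.default_rng(3)
        t = sample_survival_times(np.zeros(400_000), 1.0, 1 / lam, rng)
        _, event = apply_censoring(t, 10.0, 70.0, rng)
        assert 1 - event.mean() == pytest.approx(expected, abs=0.004)

    def test_bound_and_validation(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            apply_censoring(np.ones(2), 5.0, 5.0, rng)
        time, _ = apply_censoring(rng.exponential(40, 5000), 10.0, 70.0, rng)
        assert time.max() <= 70.0


class TestGenerateCohort:
    def test_determinism_bit_identical(self):
        cfg = paper_like_config(seed=42)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_cohort(paper_like_config(seed=1))
        b = generate_cohort(paper_like_config(seed=2))
        assert not a["time_months"].equals(b["time_months"])

    def test_single_patient_cohort(self):
        cfg = paper_like_config(seed=0, n_patients=1)
        table = generate_cohort(cfg)
        assert len(table) == 1
        s = summarize_cohort(table)
        assert s["age"]["median"] == pytest.approx(table["age"].iloc[0])
        if table["event"].iloc[0] == 1:
            assert s["km_median_os_months"] == pytest.approx(table["time_months"].iloc[0])

    def test_schema_and_positivity(self, paper_cohort):
        assert list(paper_cohort.columns) == [
            "age", "sex", "surgery", "oncology", "mgmt",
            "diameter_cm", "cv_cm3", "wv_cm3", "time_months", "event",
        ]
        assert (paper_cohort["time_months"] > 0).all()
        assert paper_cohort["event"].isin((0, 1)).all()
        assert (paper_cohort[["diameter_cm", "cv_cm3", "wv_cm3"]] > 0).all().all()
        assert paper_cohort["time_months"].max() <= 70.0

    def test_null_betas_make_outcome_independent_of_covariates(self):
        # Spearman correlation between ln(WV) and event time among deaths
        # averages to ~0 across replicate null cohorts
        rhos = []
        for seed in range(30):
            c = generate_cohort(null_config(seed=seed, censor_lo=60.0, censor_hi=70.0))
            d = c[c["event"] == 1]
            rhos.append(stats.spearmanr(np.log(d["wv_cm3"]), d["time_months"]).statistic)
        assert abs(np.mean(rhos)) < 0.035  # ~3 x MC standard error

    def test_copula_monotonicity(self):
        def mean_rho(r):
            corr = ((1.0, r, 0.5), (r, 1.0, 0.5), (0.5, 0.5, 1.0))
            vals = []
            for seed in range(5):
                c = generate_cohort(null_config(seed=seed, size_copula_corr=corr))
                vals.append(stats.spearmanr(c["diameter_cm"], c["cv_cm3"]).statistic)
            return np.mean(vals)

        assert mean_rho(0.9) > mean_rho(0.5) > mean_rho(0.1)

    def test_surgery_independent_of_size_when_slope_zero(self):
        completeness = {"biopsy": 0, "resection_lt90": 1, "resection_ge90": 2, "resection_100": 3}
        rhos, freqs = [], []
        for seed in range(10):
            c = generate_cohort(null_config(seed=seed))
            rhos.append(
                stats.spearmanr(
                    c["surgery"].map(completeness), np.log(c["wv_cm3"])
                ).statistic
            )
            freqs.append((c["surgery"] == "biopsy").mean())
        assert abs(np.mean(rhos)) < 0.05
        assert np.mean(freqs) == pytest.approx(71 / 279, abs=0.02)

    def test_surgery_size_association_shifts_large_tumours(self):
        cfg = paper_like_config(seed=0, n_patients=4000)
        c = sample_covariates(cfg, np.random.default_rng(0))
        big = c["wv_cm3"] > c["wv_cm3"].median()
        # positive slope: less-complete resection (biopsy) more likely for big tumours
        assert (c.loc[big, "surgery"] == "biopsy").mean() > (
            c.loc[~big, "surgery"] == "biopsy"
        ).mean()

    def test_mgmt_missingness_rate(self):
        fracs = [
            (generate_cohort(paper_like_config(seed=s))["mgmt"] == "unknown").mean()
            for s in range(20)
        ]
        assert np.mean(fracs) == pytest.approx(21 / 279, abs=0.015)

    def test_enforce_nesting_forces_wv_above_cv(self):
        cfg = null_config(seed=0, n_patients=3000, enforce_nesting=True)
        c = generate_cohort(cfg)
        assert (c["wv_cm3"] > c["cv_cm3"]).all()

    def test_linear_predictor_centred_near_zero(self):
        cfg = paper_like_config(seed=0, n_patients=20000)
        cov = sample_covariates(cfg, np.random.default_rng(1))
        lp = linear_predictor(cfg, cov)
        assert abs(lp.mean()) < 0.02


class TestSummarize:
    def test_counts_sum_to_n(self, paper_cohort):
        s = summarize_cohort(paper_cohort)
        for field in ("sex", "surgery", "oncology", "mgmt"):
            assert sum(v["count"] for v in s[field].values()) == s["n"]

    def test_empty_table_rejected(self, paper_cohort):
        with pytest.raises(ValueError):
            summarize_cohort(paper_cohort.iloc[0:0])

    def test_event_count_and_km_fields(self, paper_cohort):
        s = summarize_cohort(paper_cohort)
        assert s["n_events"] == int(paper_cohort["event"].sum())
        assert s["km_median_os_ci95"][0] <= s["km_median_os_months"] <= s["km_median_os_ci95"][1]
        assert s["max_followup_months"] <= 70.0
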