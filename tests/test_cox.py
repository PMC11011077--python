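import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gbmsize import (
    ModelSpec,
    build_model_suite,
    concordance_index,
    fit_cox,
    partial_log_likelihood,
    wald_p,
)
from gbmsize.cox import design_matrix


class TestModelSpec:
    def test_labels(self):
        assert ModelSpec("wv", "log", ("surgery",)).label == "log(wv) + surgery"
        assert ModelSpec("cv").label == "cv"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"size_variable": "volume"},
            {"size_variable": "wv", "transform": "sqrt"},
            {"size_variable": "wv", "adjustment": ("age", "age")},
            {"size_variable": "wv", "adjustment": ("height",)},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            ModelSpec(**kwargs)


class TestPartialLikelihood:
    def test_null_loglik_closed_form_three_subjects(self, tiny_cohort_factory):
        # no ties, beta=0: ll = -sum ln(risk set sizes) = -ln3 -ln2 -ln1
        t = tiny_cohort_factory([1, 2, 3], [1, 1, 1], [1.0, 2.0, 3.0])
        ll = partial_log_likelihood([0.0], t, ModelSpec("cv"))
        assert ll == pytest.approx(-np.log(6.0))

    def test_efron_equals_breslow_without_ties(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3, 4, 5], [1, 0, 1, 1, 1], [3.0, 1.0, 4.0, 1.5, 2.0])
        spec = ModelSpec("cv")
        for beta in (-0.5, 0.0, 0.7):
            assert partial_log_likelihood([beta], t, spec, "efron") == pytest.approx(
                partial_log_likelihood([beta], t, spec, "breslow")
            )

    def test_efron_below_breslow_with_ties(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 1, 2, 3], [1, 1, 1, 0], [2.0, 1.0, 3.0, 1.0])
        spec = ModelSpec("cv")
        # Efron's within-tie averaging shrinks the denominators, so ll is larger
        assert partial_log_likelihood([0.5], t, spec, "efron") > partial_log_likelihood(
            [0.5], t, spec, "breslow"
        )

    def test_dimension_mismatch_rejected(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2], [1, 1], [1.0, 2.0])
        with pytest.raises(ValueError):
            partial_log_likelihood([0.0, 0.0], t, ModelSpec("cv"))

    def test_fitted_beta_is_local_maximum(self, paper_cohort):
        spec = ModelSpec("wv", "log")
        fit = fit_cox(paper_cohort, spec)
        best = partial_log_likelihood(fit.beta, paper_cohort, spec)
        for eps in (-0.1, 0.1):
            assert best >= partial_log_likelihood(fit.beta + eps, paper_cohort, spec)


class TestFitCox:
    def test_matches_grid_search_oracle_four_subjects(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3, 4], [1, 1, 1, 1], [1.0, 0.0, 1.0, 0.0])
        spec = ModelSpec("cv")
        fit = fit_cox(t, spec)
        grid = np.arange(-10, 10, 1e-3)
        lls = [partial_log_likelihood([b], t, spec) for b in grid]
        assert abs(fit.beta[0] - grid[int(np.argmax(lls))]) < 1e-3

    def test_matches_lifelines_on_cohort(self, paper_cohort):
        from lifelines import CoxPHFitter

        spec = ModelSpec("cv", "log", ("age", "sex", "surgery", "oncology", "mgmt"))
        fit = fit_cox(paper_cohort, spec)
        X, names, df = design_matrix(paper_cohort, spec)
        frame = pd.DataFrame(X, columns=names)
        frame["T"], frame["E"] = df["time_months"].values, df["event"].values
        ll = CoxPHFitter().fit(frame, "T", "E")
        np.testing.assert_allclose(fit.beta, ll.params_.values, atol=1e-4)
        np.testing.assert_allclose(fit.se, ll.standard_errors_.values, atol=1e-5)
        assert fit.concordance == pytest.approx(ll.concordance_index_, abs=1e-9)

    def test_constant_size_refused(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            fit_cox(t, ModelSpec("cv"))

    def test_too_few_events_refused(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3], [1, 0, 0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="events"):
            fit_cox(t, ModelSpec("cv"))

    def test_constant_adjustment_dropped_and_reported(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3, 4], [1, 1, 1, 1], [1.0, 3.0, 2.0, 4.0])
        fit = fit_cox(t, ModelSpec("cv", adjustment=("sex",)))
        assert "sex_female" in fit.dropped_terms
        assert fit.terms == ["cv"]

    def test_mgmt_adjustment_filters_unknown_rows(self, paper_cohort):
        fit = fit_cox(paper_cohort, ModelSpec("wv", "log", ("mgmt",)))
        n_known = int((paper_cohort["mgmt"] != "unknown").sum())
        assert fit.n_used == n_known < len(paper_cohort)

    def test_scale_equivariance(self, paper_cohort):
        spec = ModelSpec("cv")
        fit1 = fit_cox(paper_cohort, spec)
        scaled = paper_cohort.copy()
        scaled["cv_cm3"] = scaled["cv_cm3"] * 10.0  # cm3 -> "mm-ish" units
        fit2 = fit_cox(scaled, spec)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0] / 10.0, rel=1e-6)
        assert fit2.wald_pvalues[0] == pytest.approx(fit1.wald_pvalues[0], rel=1e-6)
        assert fit2.concordance == pytest.approx(fit1.concordance, abs=1e-12)

    def test_log_transform_invariant_to_unit_change(self, paper_cohort):
        spec = ModelSpec("wv", "log")
        fit1 = fit_cox(paper_cohort, spec)
        scaled = paper_cohort.copy()
        scaled["wv_cm3"] = scaled["wv_cm3"] * 1000.0  # cm3 -> mm3
        fit2 = fit_cox(scaled, spec)
        assert fit2.beta[0] == pytest.approx(fit1.beta[0], rel=1e-6)
        assert fit2.wald_pvalues[0] == pytest.approx(fit1.wald_pvalues[0], rel=1e-6)
        assert fit2.concordance == pytest.approx(fit1.concordance, abs=1e-12)

    def test_univariable_overall_p_equals_coefficient_p(self, paper_cohort):
        fit = fit_cox(paper_cohort, ModelSpec("diameter"))
        assert fit.overall_wald_p == pytest.approx(fit.wald_pvalues[0], rel=1e-9)


class TestWaldP:
    def test_zero_coefficient_gives_one(self):
        assert wald_p(0.0, 1.0) == pytest.approx(1.0)

    def test_critical_value(self):
        assert wald_p(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(beta=st.floats(-5, 5), se=st.floats(0.01, 10))
    def test_symmetry_and_range(self, beta, se):
        p = wald_p(beta, se)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(wald_p(-beta, se))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_p(1.0, 0.0)


class TestConcordance:
    def test_perfect_concordance(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3, 4], [1, 1, 1, 1], [1.0] * 4)
        assert concordance_index(t, -t["time_months"].values) == pytest.approx(1.0)

    def test_all_ties_give_half(self, tiny_cohort_factory):
        t = tiny_cohort_factory([1, 2, 3, 4], [1, 1, 1, 1], [1.0] * 4)
        assert concordance_index(t, np.zeros(4)) == pytest.approx(0.5)

    def test_hand_enumerated_pairs(self, tiny_cohort_factory):
        # times (1,2,3), risks (3,1,2): concordant (1,2),(1,3); discordant (2,3)
        t = tiny_cohort_factory([1, 2, 3], [1, 1, 1], [1.0] * 3)
        assert concordance_index(t, np.array([3.0, 1.0, 2.0])) == pytest.approx(2 / 3)


class TestModelSuite:
    def test_suite_has_42_fits(self, paper_cohort):
        fits = build_model_suite(paper_cohort)
        assert len(fits) == 42
        assert sum(spec.univariable for spec in fits) == 6
        for spec, fit in fits.items():
            assert fit.converged
            if "mgmt" in spec.adjustment:
                assert fit.n_used == int((paper_cohort["mgmt"] != "unknown").sum())
            else:
                assert fit.n_used == len(paper_cohort)
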