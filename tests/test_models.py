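"""Logistic / auto-logistic fitting against closed forms and statsmodels."""

import warnings

import numpy as np
import pandas as pd
import pytest

import autologit as al
from autologit.exceptions import SingularDesignError, ValidationError
from autologit.models import AUTOCOV_TERM, LogisticGLM


def _counts_cohort(n_event: int, n_total: int) -> pd.DataFrame:
    death = np.concatenate([np.ones(n_event), np.zeros(n_total - n_event)])
    return pd.DataFrame({"death": death})


class TestLogisticClosedForms:
    def test_intercept_only_log_odds(self):
        # 167 deaths in 1170 -> intercept = ln(167/1003)
        cohort = _counts_cohort(167, 1170)
        fit = al.fit_logistic(al.DesignSpec([], outcome="death"), cohort)
        assert fit.table.loc["intercept", "estimate"] == pytest.approx(
            np.log(167 / 1003), abs=1e-8
        )
        assert fit.converged

    def test_two_by_two_odds_ratio_cross_product(self):
        # triage levels 1&2: 143 dead / 666 alive; levels 3&4: 24 / 338
        rows = (
            [("levels12", 1)] * 143
            + [("levels12", 0)] * 666
            + [("levels34", 1)] * 24
            + [("levels34", 0)] * 338
        )
        cohort = pd.DataFrame(rows, columns=["triage", "death"])
        design = al.DesignSpec(
            [al.Covariate("triage", "binary", reference="levels12")]
        )
        fit = al.fit_logistic(design, cohort)
        expected_or = (24 * 666) / (143 * 338)  # odds(34)/odds(12)
        assert fit.table.loc["triage_levels34", "OR"] == pytest.approx(
            expected_or, rel=1e-8
        )
        # the cross-product the other way round is its reciprocal
        assert 1.0 / fit.table.loc["triage_levels34", "OR"] == pytest.approx(
            (143 * 338) / (24 * 666), rel=1e-8
        )

    def test_fitted_probabilities_sum_to_event_count(self, small_fit):
        flog, fauto, _, _ = small_fit
        for fit in (flog, fauto):
            assert fit.fitted.sum() == pytest.approx(fit.y.sum(), abs=1e-6)
            assert np.all((fit.fitted > 0) & (fit.fitted < 1))

    def test_aic_identity(self, small_fit):
        flog, fauto, _, _ = small_fit
        for fit in (flog, fauto):
            assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_ci_brackets_or(self, small_fit):
        flog, _, _, _ = small_fit
        t = flog.table
        assert (t["ci_low"] < t["OR"]).all() and (t["OR"] < t["ci_high"]).all()

    def test_degenerate_outcomes_rejected(self):
        with pytest.raises(ValidationError, match="no events"):
            al.fit_logistic(al.DesignSpec([]), _counts_cohort(0, 20))
        with pytest.raises(ValidationError, match="no non-events"):
            al.fit_logistic(al.DesignSpec([]), _counts_cohort(20, 20))


class TestAgainstStatsmodels:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coefficients_and_ses_match(self, seed):
        """Independent maximum-likelihood oracle on random designs."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 400
        X = pd.DataFrame(
            {
                "a": rng.normal(size=n),
                "b": rng.integers(0, 2, n).astype(float),
                "c": rng.normal(2, 1, n),
            }
        )
        eta = -1.0 + 0.8 * X["a"] - 0.5 * X["b"] + 0.3 * X["c"]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
        est = LogisticGLM().fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X.to_numpy())).fit(disp=0)
        np.testing.assert_allclose(est.coef_, ref.params, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(est.se_, ref.bse, rtol=1e-5, atol=1e-8)
        assert est.loglik_ == pytest.approx(ref.llf, abs=1e-6)

    def test_sklearn_estimator_protocol(self):
        est = LogisticGLM(max_iter=25)
        assert est.get_params()["max_iter"] == 25
        est.set_params(max_iter=60)
        assert est.max_iter == 60
        clone_params = LogisticGLM(**est.get_params()).get_params()
        assert clone_params == est.get_params()


class TestPathologies:
    def test_complete_separation_flagged_with_term(self):
        rng = np.random.default_rng(0)
        n = 60
        x = rng.normal(size=n)
        y = (x > 0).astype(float)
        X = pd.DataFrame({"sep": x})
        with pytest.warns(UserWarning, match="separation|diverge"):
            est = LogisticGLM().fit(X, y)
        assert not est.converged_
        assert est.result_.diverging_term == "sep"

    def test_singular_design_names_collinear_column(self):
        rng = np.random.default_rng(1)
        n = 80
        a = rng.normal(size=n)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a})
        y = (rng.uniform(size=n) < 0.4).astype(float)
        with pytest.raises(SingularDesignError, match="a|twice_a"):
            LogisticGLM().fit(X, y)

    def test_missing_values_in_design_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0, 0.5]})
        with pytest.raises(ValidationError, match="missing|non-finite"):
            LogisticGLM().fit(X, np.array([0, 1, 0, 1.0]))


class TestDesignSpec:
    def test_reference_level_must_exist(self):
        cohort = pd.DataFrame(
            {"death": [0, 1, 0, 1], "g": ["a", "b", "a", "b"]}
        )
        design = al.DesignSpec([al.Covariate("g", "binary", reference="zzz")])
        with pytest.raises(ValidationError, match="zzz"):
            design.build(cohort)

    def test_complete_case_drop_warns_with_count(self):
        cohort = pd.DataFrame(
            {"death": [0, 1, 0, 1, 0], "a": [1.0, 2.0, np.nan, 0.5, 1.5]}
        )
        with pytest.warns(UserWarning, match="dropped 1"):
            X, y, idx = al.DesignSpec([al.Covariate("a")]).build(cohort)
        assert len(X) == 4 and len(idx) == 4

    def test_categorical_dummies_against_reference(self):
        cohort = pd.DataFrame(
            {
                "death": [0, 1, 0, 1, 0, 1],
                "g": ["a", "b", "c", "a", "b", "c"],
            }
        )
        design = al.DesignSpec([al.Covariate("g", "categorical", reference="b")])
        X, _, _ = design.build(cohort)
        assert sorted(X.columns) == ["g_a", "g_c"]


class TestAutoLogistic:
    def test_equals_logistic_on_manually_augmented_design(self, small_fit):
        """Pseudolikelihood = ordinary logistic with the autocov column."""
        _, fauto, weights, cohort = small_fit
        design = al.DesignSpec(
            [
                al.Covariate("age"),
                al.Covariate("triage", "binary", reference="levels12"),
                al.Covariate("los"),
            ]
        )
        X, y, _ = design.build(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X[AUTOCOV_TERM] = al.autocovariate(weights, y)
        manual = LogisticGLM().fit(X, y)
        np.testing.assert_allclose(
            fauto.table["estimate"], manual.result_.table["estimate"], rtol=1e-10
        )
        assert fauto.has_autocovariate
        assert AUTOCOV_TERM in fauto.table.index

    def test_constant_autocovariate_names_it(self):
        """All units isolated -> autocov equals prevalence everywhere."""
        rng = np.random.default_rng(0)
        cohort = pd.DataFrame(
            {
                "unit_id": range(20),
                "x": np.arange(20) * 1000.0,
                "y": np.zeros(20),
                "a": rng.normal(size=20),
                "death": rng.integers(0, 2, 20).astype(float),
            }
        )
        with pytest.warns(UserWarning):
            w = al.build_weights(cohort[["unit_id", "x", "y"]], radius=1.0)
        with pytest.raises(SingularDesignError, match="autocovariate"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            al.fit_autologistic(al.DesignSpec([al.Covariate("a")]), cohort, w)

    def test_gamma_centred_at_zero_without_spatial_signal(self):
        """With gamma_true = 0 the autocovariate coefficient is unbiased."""
        gs = []
        design = al.DesignSpec(
            [al.Covariate("age"), al.Covariate("los")]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(20):
                cohort, prov = al.generate_dataset(
                    al.SimConfig(n=500, gamma=0.0, seed=100 + s)
                )
                w = al.build_weights(
                    cohort[["unit_id", "x", "y"]], prov["config"]["radius"]
                )
                fit = al.fit_autologistic(design, cohort, w)
                gs.append(fit.table.loc[AUTOCOV_TERM, "estimate"])
        gs = np.asarray(gs)
        mc_se = gs.std(ddof=1) / np.sqrt(len(gs))
        assert abs(gs.mean()) < 2.5 * mc_se + 0.05
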