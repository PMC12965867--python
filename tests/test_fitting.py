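import numpy as np
import pandas as pd
import pytest

from proteintrial.cohort import apply_eligibility
from proteintrial.fitting import (
    LinearModel,
    ModelSpec,
    ModelSpecSet,
    RankDeficiencyError,
    SaturatedModel,
    UnseenLevelError,
    default_model_specs,
    fit_all,
    predict_outcome,
)
from proteintrial.synthetic import compact_config, discrete_toy_cohort, generate_cohort


class TestSaturated:
    def test_two_by_two_logistic_reproduces_proportions(self):
        # cells: (a=1,y=1)=30, (1,0)=70, (0,1)=10, (0,0)=90
        a = np.repeat(["1", "0"], [100, 100])
        y = np.concatenate([np.repeat([1, 0], [30, 70]), np.repeat([1, 0], [10, 90])])
        df = pd.DataFrame({"a": a, "y": y})
        model = SaturatedModel.fit(
            df, ModelSpec(target="y", family="logistic", predictors=("a",), saturated=True)
        )
        pred = model.predict_mean(pd.DataFrame({"a": ["1", "0"]}))
        np.testing.assert_allclose(pred, [0.30, 0.10])

    def test_unseen_stratum_errors(self):
        df = pd.DataFrame({"a": ["0", "1"], "y": [1.0, 2.0]})
        model = SaturatedModel.fit(
            df, ModelSpec(target="y", family="linear", predictors=("a",), saturated=True)
        )
        with pytest.raises(UnseenLevelError):
            model.predict_mean(pd.DataFrame({"a": ["2"]}))


class TestLinear:
    def test_noise_free_interpolation(self):
        a = np.array([0.6, 0.9, 1.2, 1.5, 1.8] * 10)
        df = pd.DataFrame({"protein_1": a, "y_2": 100.0 - 10.0 * a})
        fit = LinearModel.fit(
            df, ModelSpec(target="y_2", family="linear", predictors=("protein_1",))
        )
        np.testing.assert_allclose(fit.coef, [100.0, -10.0], atol=1e-9)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-9)

    def test_intercept_only_predicts_mean(self):
        df = pd.DataFrame({"y_2": [154.0] * 20, "x": np.arange(20.0)})
        fit = LinearModel.fit(df, ModelSpec(target="y_2", family="linear", predictors=()))
        np.testing.assert_allclose(
            fit.linear_predictor(pd.DataFrame({"x": [1.0]})), [154.0]
        )

    def test_rank_deficiency_names_terms(self):
        df = pd.DataFrame({"x1": [1.0, 2, 3, 4], "x2": [2.0, 4, 6, 8], "y": [1.0, 2, 3, 4]})
        with pytest.raises(RankDeficiencyError) as exc:
            LinearModel.fit(
                df, ModelSpec(target="y", family="linear", predictors=("x1", "x2"))
            )
        assert exc.value.columns

    def test_unseen_level_raises(self):
        df = pd.DataFrame({"g": ["a", "b"] * 10, "y": np.arange(20.0)})
        fit = LinearModel.fit(df, ModelSpec(target="y", family="linear", predictors=("g",)))
        with pytest.raises(UnseenLevelError, match="'g'"):
            fit.linear_predictor(pd.DataFrame({"g": ["c"]}))

    def test_log_transform_requires_positive(self):
        df = pd.DataFrame({"y": [1.0, -1.0], "x": [0.0, 1.0]})
        with pytest.raises(Exception, match="positive"):
            LinearModel.fit(
                df, ModelSpec(target="y", family="linear", predictors=("x",), transform="log")
            )


class TestFitAll:
    def test_deterministic(self, compact_cohort):
        m1 = fit_all(compact_cohort)
        m2 = fit_all(compact_cohort)
        np.testing.assert_array_equal(
            m1.outcome_models["vat"].coef, m2.outcome_models["vat"].coef
        )

    def test_outcome_models_use_uncensored_only(self, compact_cohort, compact_models):
        n_unc = int((compact_cohort.df["censor"] == "none").sum())
        assert compact_models.outcome_models["vat"].n == n_unc
        assert compact_models.exposure_model.n == len(compact_cohort)

    def test_diagnostics_cover_every_model(self, compact_models):
        assert all(d["converged"] for d in compact_models.diagnostics.values())
        assert "vat_2" in compact_models.diagnostics
        assert "protein_1" in compact_models.diagnostics

    def test_fitted_mean_matches_observed_mean(self, compact_cohort, compact_models):
        # normal-equation identity for linear models with intercept
        unc = compact_models.source[compact_models.source["censor"] == "none"]
        pred = compact_models.outcome_models["vat"].predict_mean(unc)
        assert pred.mean() == pytest.approx(unc["vat_2"].mean(), rel=1e-9)

    def test_default_specs_cover_everything(self, compact_cohort):
        specs = default_model_specs(compact_cohort.schema)
        targets = [ms.target for ms in specs.all_specs()]
        assert "protein_1" in targets
        assert "vat_2" in targets
        assert "censor_death" in targets and "censor_ltfu" in targets
        # temporal ordering: no baseline outcome predicts a baseline covariate
        for ms in specs.covariate:
            assert not any(p.endswith("_2") for p in ms.predictors)

    def test_specs_yaml_round_trip(self, tmp_path, compact_cohort):
        specs = default_model_specs(compact_cohort.schema)
        path = tmp_path / "specs.yaml"
        specs.to_yaml(path)
        assert ModelSpecSet.from_yaml(path) == specs


class TestCoefficientRecovery:
    @pytest.mark.parametrize("n,factor", [(1000, 1.0), (10_000, 1.0)])
    def test_outcome_slope_recovered(self, n, factor):
        cfg = compact_config(n=n)
        cohort, _ = apply_eligibility(generate_cohort(cfg, seed=n))
        models = fit_all(cohort)
        tab = models.outcome_models["vat"].coef_table()
        row = tab[tab.term == "protein_1"]
        slope, se = float(row.coef.iloc[0]), float(row.se.iloc[0])
        assert slope == pytest.approx(cfg.effect_protein["vat"], abs=3 * se * factor)

    def test_se_shrinks_with_n(self):
        ses = []
        for n in (1000, 10_000):
            cohort, _ = apply_eligibility(generate_cohort(compact_config(n=n), seed=n))
            tab = fit_all(cohort).outcome_models["vat"].coef_table()
            ses.append(float(tab[tab.term == "protein_1"].se.iloc[0]))
        assert ses[1] < 0.5 * ses[0]

    def test_exposure_carryover_recovered(self):
        cfg = compact_config(n=10_000)
        cohort, _ = apply_eligibility(generate_cohort(cfg, seed=77))
        tab = fit_all(cohort).exposure_model.coef_table()
        row = tab[tab.term == "log_protein_0"]
        assert float(row.coef.iloc[0]) == pytest.approx(
            cfg.exposure.carryover, abs=3 * float(row.se.iloc[0])
        )


class TestPredictOutcome:
    def test_linear_evaluation(self):
        a = np.array([0.6, 0.9, 1.2, 1.5, 1.8] * 20)
        df = pd.DataFrame({"protein_1": a, "y": 100.0 - 10.0 * a})
        fit = LinearModel.fit(df, ModelSpec(target="y", family="linear", predictors=("protein_1",)))
        out = fit.predict_mean(pd.DataFrame({"protein_1": [1.5]}))
        np.testing.assert_allclose(out, [85.0], atol=1e-9)

    def test_purity(self, compact_models):
        history = compact_models.source.head(50)
        p1 = predict_outcome(compact_models, 1.1, history)
        p2 = predict_outcome(compact_models, 1.1, history)
        pd.testing.assert_frame_equal(p1, p2)

    def test_exposure_argument_used(self, compact_models):
        history = compact_models.source.head(50)
        low = predict_outcome(compact_models, 0.6, history)["vat"]
        high = predict_outcome(compact_models, 1.6, history)["vat"]
        assert (high < low).all()  # negative slope on VAT


class TestMultinomialAndLogistic:
    def test_multinomial_covariate_simulates_valid_levels(self):
        from proteintrial.synthetic import default_config

        cohort, _ = apply_eligibility(generate_cohort(default_config(n=1200), seed=5))
        models = fit_all(cohort)
        smoking = models.covariate_models["smoking"]
        rng = np.random.default_rng(0)
        draws = smoking.sample(models.source.head(200), rng)
        assert set(draws) <= {"never", "former", "current"}

    def test_constant_censor_target_falls_back(self):
        cohort, specs, _ = discrete_toy_cohort(n=200, seed=3)
        models = fit_all(cohort, specs)
        p = models.censoring_models["death"].predict_proba(cohort.df.head(5))
        np.testing.assert_allclose(p, 0.0)
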