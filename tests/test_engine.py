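import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from proteintrial.engine import (
    crude_contrast,
    estimate,
    plugin_standardization_oracle,
    run_all_strategies,
    simulate_covariates,
)
from proteintrial.fitting import UnseenLevelError, fit_all
from proteintrial.strategies import (
    InterventionStrategy as S,
    apply_intervention,
    parse_strategies,
)
from proteintrial.synthetic import discrete_toy_cohort

from conftest import make_manual_cohort


class TestApplyIntervention:
    def test_lifted_to_threshold(self):
        assert apply_intervention(0.9, S.threshold(1.2)) == 1.2

    def test_adherent_unchanged(self):
        assert apply_intervention(1.4, S.threshold(1.2)) == 1.4

    def test_natural_identity(self):
        assert apply_intervention(0.9, S.natural()) == 0.9

    @given(
        a=st.floats(0.05, 4.0),
        t1=st.floats(0.1, 2.0),
        t2=st.floats(0.1, 2.0),
    )
    def test_nesting(self, a, t1, t2):
        lo, hi = sorted([t1, t2])
        assert apply_intervention(a, S.threshold(hi)) >= apply_intervention(
            a, S.threshold(lo)
        )

    def test_strategy_validation(self):
        with pytest.raises(ValueError):
            S.threshold(-1.0)
        with pytest.raises(ValueError):
            S(kind="natural_course", t=1.0)

    def test_parse(self):
        grid = parse_strategies("nc,0.8,1.5")
        assert grid[0] == S.natural()
        assert grid[2] == S.threshold(1.5)


class TestRunAll:
    def test_natural_first_and_zero_ate(self, compact_models):
        ests = run_all_strategies(compact_models, mc_size=2000, seed=1)
        assert ests[0].strategy == S.natural()
        assert all(v == 0.0 for v in ests[0].ate_vs_natural.values())
        assert len(ests) == 5

    def test_duplicate_strategies_rejected(self, compact_models):
        with pytest.raises(ValueError, match="duplicate"):
            run_all_strategies(
                compact_models, [S.natural(), S.threshold(1.0), S.threshold(1.0)]
            )

    def test_natural_course_required(self, compact_models):
        with pytest.raises(ValueError, match="reference strategy"):
            run_all_strategies(compact_models, [S.threshold(1.0)])

    def test_determinism(self, compact_models):
        a = run_all_strategies(compact_models, mc_size=3000, seed=9)
        b = run_all_strategies(compact_models, mc_size=3000, seed=9)
        for ga, gb in zip(a, b):
            assert ga.standardized_mean == gb.standardized_mean
            assert ga.ate_vs_natural == gb.ate_vs_natural

    def test_threshold_below_floor_is_noop(self, compact_models):
        # observed/simulated intakes are truncated to the fitted range,
        # so a tiny threshold never binds
        ests = run_all_strategies(
            compact_models, [S.natural(), S.threshold(1e-4)], mc_size=3000, seed=2
        )
        assert ests[1].standardized_mean == ests[0].standardized_mean
        assert all(v == 0.0 for v in ests[1].ate_vs_natural.values())

    def test_small_mc_warns(self, compact_models, caplog):
        with caplog.at_level(logging.WARNING, logger="proteintrial.engine"):
            estimate(compact_models, S.threshold(1.2), mc_size=50, seed=0)
        assert any("mc_size" in rec.message for rec in caplog.records)

    def test_monotone_dose_response(self, compact_models):
        ests = run_all_strategies(compact_models, mc_size=20_000, seed=4)
        vat = [g.standardized_mean["vat"] for g in ests]
        assert all(a >= b for a, b in zip(vat, vat[1:]))


class TestSimulateCovariates:
    def test_same_seed_identical(self, compact_models):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        base = compact_models.source.head(500)
        s1 = simulate_covariates(compact_models, base, rng1)
        s2 = simulate_covariates(compact_models, base, rng2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_calibrated_against_observed(self, compact_cohort, compact_models):
        rng = np.random.default_rng(11)
        idx = rng.integers(0, len(compact_models.source), size=50_000)
        base = compact_models.source.iloc[idx].reset_index(drop=True)
        sim = simulate_covariates(compact_models, base, rng)
        for col in ("hei_1", "met_1", "vat_1", "protein_1"):
            obs = compact_cohort.df[col].astype(float)
            mc_se = sim[col].std() / np.sqrt(len(sim))
            # 3 MC SEs plus the sampling error of the observed mean itself
            tol = 3 * (mc_se + obs.std() / np.sqrt(len(obs)))
            assert sim[col].mean() == pytest.approx(obs.mean(), abs=tol)

    def test_truncation_to_observed_range(self, compact_cohort, compact_models):
        rng = np.random.default_rng(3)
        base = compact_models.source.head(20_000)
        sim = simulate_covariates(compact_models, base, rng)
        for col in ("hei_1", "vat_1", "protein_1"):
            obs = compact_cohort.df[col].astype(float)
            assert sim[col].min() >= obs.min() - 1e-9
            assert sim[col].max() <= obs.max() + 1e-9

    def test_degenerate_models_simulate_constants(self):
        cohort, specs, _ = discrete_toy_cohort(n=300, seed=2)
        models = fit_all(cohort, specs)
        # y_1 is identically zero in the toy cohort: zero residual variance
        rng = np.random.default_rng(0)
        sim = simulate_covariates(models, models.source.head(100), rng)
        np.testing.assert_allclose(sim["y_1"], 0.0, atol=1e-12)

    def test_unknown_mode_rejected(self, compact_models):
        with pytest.raises(ValueError, match="mode"):
            simulate_covariates(
                compact_models, compact_models.source.head(5), np.random.default_rng(0), mode="x"
            )


class TestPluginOracle:
    def test_exposure_independent_outcome(self):
        df = make_manual_cohort(
            {
                "l_0": np.array(["0", "1"] * 10, dtype=object),
                "protein_1": np.array([0.6, 1.4] * 10),
                "y_2": np.zeros(20),
            }
        )
        for strat in (S.natural(), S.threshold(1.2)):
            val = plugin_standardization_oracle(
                df, ["l_0"], strat, outcome_fn=lambda a, l: float(l)
            )
            assert val == pytest.approx(0.5)

    def test_mean_of_lifted_exposure(self):
        # E[Y|a,l] = a, exposures {0.6, 1.4} equally likely:
        # threshold(1.2) -> (1.2 + 1.4)/2
        df = make_manual_cohort(
            {
                "l_0": np.array(["0", "0", "1", "1"], dtype=object),
                "protein_1": np.array([0.6, 1.4, 0.6, 1.4]),
                "y_2": np.array([0.6, 1.4, 0.6, 1.4]),
            }
        )
        val = plugin_standardization_oracle(
            df, ["l_0"], S.threshold(1.2), outcome_fn=lambda a, l: a
        )
        assert val == pytest.approx(1.3)

    def test_empty_stratum_error_names_stratum(self):
        df = make_manual_cohort(
            {
                "l_0": np.array(["0", "0", "1", "1"], dtype=object),
                "protein_1": np.array([0.6, 1.4, 0.6, 1.4]),
                "y_2": np.array([1.0, 2.0, 3.0, 4.0]),
            }
        )
        with pytest.raises(UnseenLevelError):
            plugin_standardization_oracle(df, ["l_0"], S.threshold(1.2))

    def test_natural_course_equals_crude_mean(self):
        cohort, _, _ = discrete_toy_cohort(n=500, seed=8)
        val = plugin_standardization_oracle(cohort, ["l_0"], S.natural())
        assert val == pytest.approx(cohort.df["y_2"].mean())


class TestOracleEquivalence:
    def test_mc_matches_plugin_single_cohort(self):
        cohort, specs, _ = discrete_toy_cohort(n=2000, seed=0)
        models = fit_all(cohort, specs)
        for strat in (S.natural(), S.threshold(1.0), S.threshold(1.4)):
            g = estimate(models, strat, mc_size=200_000, seed=0, mode="empirical")
            oracle = plugin_standardization_oracle(cohort, ["l_0"], strat)
            assert abs(g.standardized_mean["y"] - oracle) <= 3 * max(
                g.mean_se["y"], 1e-9
            )


class TestModes:
    def test_empirical_and_parametric_agree(self, compact_models):
        gp = estimate(compact_models, S.threshold(1.5), mc_size=30_000, seed=1)
        ge = estimate(compact_models, S.threshold(1.5), mc_size=30_000, seed=1, mode="empirical")
        assert gp.ate_vs_natural["vat"] == pytest.approx(
            ge.ate_vs_natural["vat"], abs=0.5
        )


class TestCrudeContrast:
    def test_confounded_crude_is_biased(self, compact_cfg):
        from proteintrial.cohort import apply_eligibility
        from proteintrial.synthetic import generate_cohort, true_ate

        cohort, _ = apply_eligibility(
            generate_cohort(compact_cfg.replace(n=20_000), seed=9)
        )
        ate_c, se_c = crude_contrast(cohort, S.threshold(1.5), "vat")
        truth = true_ate(compact_cfg, S.threshold(1.5))["vat"]
        assert abs(ate_c - truth) > 3 * se_c
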