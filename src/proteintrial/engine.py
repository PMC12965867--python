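"""Monte Carlo parametric g-formula.

Pseudo-individuals are seeded from a with-replacement draw of observed
pre-baseline rows; baseline covariates, baseline outcomes and the natural
exposure are then either simulated from the fitted conditional models
("parametric" mode) or taken from the resampled rows ("empirical" mode,
which reduces to regression standardization).  Each strategy transforms the
same natural exposure draws (common random numbers), outcomes are predicted
for every pseudo-individual (censoring abolished), and strategy contrasts
are paired differences against the natural course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import EXPOSURE, Cohort
from .fitting import FittedModelSet, LinearModel, ModelSpec, UnseenLevelError, predict_outcome
from .strategies import InterventionStrategy, apply_intervention, study_grid

__all__ = [
    "GEstimate",
    "simulate_covariates",
    "apply_intervention",
    "estimate",
    "run_all_strategies",
    "plugin_standardization_oracle",
    "crude_contrast",
    "study_grid",
]

logger = logging.getLogger(__name__)

DEFAULT_MC_SIZE = 20_000


@dataclass(frozen=True)
class GEstimate:
    """Standardized outcome means for one strategy, plus the paired contrast."""

    strategy: InterventionStrategy
    standardized_mean: dict[str, float]
    ate_vs_natural: dict[str, float]
    mc_size: int
    seed: int
    mean_se: dict[str, float]  # MC standard error of the standardized mean
    ate_se: dict[str, float]  # MC standard error of the paired ATE (0 for reference)

    @property
    def is_reference(self) -> bool:
        return self.strategy.kind == "natural_course"


def _base_draw(models: FittedModelSet, mc_size: int, rng: np.random.Generator) -> pd.DataFrame:
    src = models.source
    idx = rng.integers(0, len(src), size=mc_size)
    return src.iloc[idx].reset_index(drop=True)


def simulate_covariates(
    models: FittedModelSet,
    base_sample: pd.DataFrame,
    rng: np.random.Generator,
    mode: str = "parametric",
) -> pd.DataFrame:
    """Simulate baseline history and the natural-course exposure.

    ``base_sample`` supplies the pre-baseline block.  In parametric mode the
    baseline covariates are drawn sequentially from their fitted conditional
    models (continuous draws truncated to the observed range), baseline
    outcomes from theirs, and the natural exposure from the exposure model.
    Empirical mode keeps the resampled observed rows as-is.
    """
    if mode not in ("parametric", "empirical"):
        raise ValueError(f"unknown simulation mode {mode!r}")
    sim = base_sample.reset_index(drop=True).copy()
    if mode == "empirical":
        return sim

    schema = models.schema
    for cov in schema.covariates:
        if not cov.time_varying:
            sim[f"{cov.name}_1"] = sim[f"{cov.name}_0"]
    for name in models.sim_order:
        model = models.covariate_models[name]
        drawn = model.sample(sim, rng)
        if schema.covariate(name).kind == "binary":
            drawn = np.asarray(drawn, dtype=int).astype(str)
        sim[f"{name}_1"] = drawn
    for name, model in models.y1_models.items():
        sim[f"{name}_1"] = model.sample(sim, rng)
    a_nat = models.exposure_model.sample(sim, rng)
    sim[f"{EXPOSURE}_1"] = a_nat
    sim[f"log_{EXPOSURE}_1"] = np.log(a_nat)
    return sim


def _validate_strategies(strategies: Sequence[InterventionStrategy], require_natural: bool) -> None:
    if len(set(strategies)) != len(strategies):
        raise ValueError("duplicate strategies")
    if require_natural and not any(s.kind == "natural_course" for s in strategies):
        raise ValueError("reference strategy required: include the natural course")


def _mc_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((0x6F0, seed)))


def _estimates_for(
    models: FittedModelSet,
    strategies: Sequence[InterventionStrategy],
    mc_size: int,
    seed: int,
    mode: str,
) -> list[GEstimate]:
    if mc_size < 100:
        logger.warning("mc_size=%d is very small; estimates will be noisy", mc_size)
    rng = _mc_rng(seed)
    base = _base_draw(models, mc_size, rng)
    sim = simulate_covariates(models, base, rng, mode=mode)
    a_nat = sim[f"{EXPOSURE}_1"].to_numpy(dtype=float)

    natural = InterventionStrategy.natural()
    pred_nat = predict_outcome(models, a_nat, sim)
    results: list[GEstimate] = []
    ordered = [s for s in strategies if s.kind == "natural_course"]
    ordered += [s for s in strategies if s.kind != "natural_course"]
    for strat in ordered:
        if strat == natural:
            pred = pred_nat
        else:
            pred = predict_outcome(models, apply_intervention(a_nat, strat), sim)
        diff = pred - pred_nat
        root_n = np.sqrt(mc_size)
        results.append(
            GEstimate(
                strategy=strat,
                standardized_mean={k: float(v) for k, v in pred.mean().items()},
                ate_vs_natural={k: float(v) for k, v in diff.mean().items()},
                mc_size=mc_size,
                seed=seed,
                mean_se={k: float(pred[k].std(ddof=1) / root_n) for k in pred.columns},
                ate_se={
                    k: (0.0 if strat == natural else float(diff[k].std(ddof=1) / root_n))
                    for k in pred.columns
                },
            )
        )
    return results


def estimate(
    models: FittedModelSet,
    strategy: InterventionStrategy,
    mc_size: int = DEFAULT_MC_SIZE,
    seed: int = 0,
    mode: str = "parametric",
) -> GEstimate:
    """Standardized mean and ATE versus the natural course for one strategy."""
    strategies = [InterventionStrategy.natural()]
    if strategy.kind != "natural_course":
        strategies.append(strategy)
    results = _estimates_for(models, strategies, mc_size, seed, mode)
    return results[-1]


def run_all_strategies(
    models: FittedModelSet,
    strategies: Sequence[InterventionStrategy] | None = None,
    mc_size: int = DEFAULT_MC_SIZE,
    seed: int = 0,
    mode: str = "parametric",
) -> list[GEstimate]:
    """One estimate per strategy on shared draws; natural course first."""
    if strategies is None:
        strategies = study_grid()
    _validate_strategies(strategies, require_natural=True)
    return _estimates_for(models, strategies, mc_size, seed, mode)


def plugin_standardization_oracle(
    data: Cohort | pd.DataFrame,
    confounders: Sequence[str],
    strategy: InterventionStrategy,
    exposure_col: str = f"{EXPOSURE}_1",
    outcome_col: str = "y_2",
    outcome_fn: Callable | None = None,
) -> float:
    """Exact plug-in standardization for fully discrete cohorts.

    Enumerates confounder strata: sum_l P(l) * sum_a P(a|l) * E[Y | g(a), l],
    with conditional outcome means taken from the empirical table (or from
    ``outcome_fn(a, l)`` when a known structural mean is supplied).  No
    randomness.  An intervened exposure value never observed within a
    stratum raises an error naming the stratum.
    """
    df = data.uncensored() if isinstance(data, Cohort) else data
    confounders = list(confounders)
    n = len(df)
    total = 0.0
    for l_key, stratum in df.groupby(confounders, sort=True):
        if len(confounders) == 1 and isinstance(l_key, tuple):
            l_key = l_key[0]
        p_l = len(stratum) / n
        inner = 0.0
        for a_val, cell in stratum.groupby(exposure_col, sort=True):
            p_a = len(cell) / len(stratum)
            g_a = apply_intervention(float(a_val), strategy)
            if outcome_fn is not None:
                ey = outcome_fn(g_a, l_key)
            else:
                target = stratum[np.isclose(stratum[exposure_col].astype(float), g_a)]
                if target.empty:
                    raise UnseenLevelError(
                        "x".join([exposure_col] + confounders), (g_a,) + tuple(np.atleast_1d(l_key))
                    )
                ey = float(target[outcome_col].mean())
            inner += p_a * ey
        total += p_l * inner
    return float(total)


def crude_contrast(
    cohort: Cohort, strategy: InterventionStrategy, outcome: str
) -> tuple[float, float]:
    """Unadjusted analogue of the threshold ATE, with its standard error.

    Regresses the end-of-follow-up outcome on the exposure alone (uncensored
    records) and scales the slope by the average exposure lift the strategy
    would induce.  Used to demonstrate confounding control, not as an
    estimator.
    """
    df = cohort.uncensored()
    spec = ModelSpec(
        target=f"{outcome}_2", family="linear", predictors=(f"{EXPOSURE}_1",)
    )
    fit = LinearModel.fit(df, spec, name=f"crude_{outcome}")
    slope, slope_se = fit.coef[1], fit.coef_se[1]
    a = df[f"{EXPOSURE}_1"].to_numpy(dtype=float)
    lift = float(np.mean(apply_intervention(a, strategy) - a))
    return float(slope * lift), float(abs(lift) * slope_se)
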