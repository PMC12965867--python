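"""Pipeline driver, effects table, and natural-course diagnostics."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CovariateSchema, apply_eligibility, censoring_summary
from .engine import _base_draw, _mc_rng, simulate_covariates
from .fitting import FittedModelSet, ModelSpecSet, fit_all, predict_outcome
from .inference import BootstrapResult, bootstrap
from .strategies import InterventionStrategy
from .synthetic import DGPConfig, generate_cohort


@dataclass
class EffectsTable:
    """Strategy-by-outcome estimates with bootstrap CIs, ready for export."""

    df: pd.DataFrame  # strategy, outcome, mean, mean_lo, mean_hi, ate, ate_lo, ate_hi
    metadata: dict

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        out = self.df.copy()
        num = out.select_dtypes(include=[np.number]).columns
        out[num] = out[num].round(decimals)
        return out

    def to_csv(self, path, decimals: int = 1) -> None:
        self.rounded(decimals).to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "rows": self.df.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def effects_table(boot: BootstrapResult, metadata: Mapping | None = None) -> EffectsTable:
    """Assemble the Table-3-style layout from a bootstrap result.

    The natural-course row is the reference: its ATE is identically zero and
    carries no contrast CI.
    """
    rows = []
    for g in boot.point:
        label = g.strategy.label
        for out, mean in g.standardized_mean.items():
            m_lo, m_hi = boot.mean_ci[(label, out)]
            if g.is_reference:
                a_lo = a_hi = np.nan
            else:
                a_lo, a_hi = boot.ate_ci[(label, out)]
            rows.append(
                {
                    "strategy": label,
                    "outcome": out,
                    "mean": mean,
                    "mean_lo": m_lo,
                    "mean_hi": m_hi,
                    "ate": g.ate_vs_natural[out],
                    "ate_lo": a_lo,
                    "ate_hi": a_hi,
                }
            )
    meta = dict(metadata or {})
    meta.setdefault("ci_method", boot.method)
    meta.setdefault("n_resamples", boot.n_resamples)
    meta.setdefault("n_failed_replicates", boot.n_failed)
    meta.setdefault("seed", boot.seed)
    return EffectsTable(df=pd.DataFrame(rows), metadata=meta)


def rebuild_effects_table(
    point_table: EffectsTable, replicate_store: pd.DataFrame
) -> EffectsTable:
    """Recompute CI columns from a stored replicate table, without refitting."""
    df = point_table.df.drop(columns=["mean_lo", "mean_hi", "ate_lo", "ate_hi"]).copy()
    mean_lo, mean_hi, ate_lo, ate_hi = [], [], [], []
    for _, row in df.iterrows():
        grp = replicate_store[
            (replicate_store["strategy"] == row["strategy"])
            & (replicate_store["outcome"] == row["outcome"])
        ]
        lo, hi = np.percentile(grp["mean"].to_numpy(), [2.5, 97.5])
        mean_lo.append(lo)
        mean_hi.append(hi)
        if row["strategy"] == "natural_course":
            ate_lo.append(np.nan)
            ate_hi.append(np.nan)
        else:
            lo, hi = np.percentile(grp["ate"].to_numpy(), [2.5, 97.5])
            ate_lo.append(lo)
            ate_hi.append(hi)
    df["mean_lo"], df["mean_hi"] = mean_lo, mean_hi
    df["ate_lo"], df["ate_hi"] = ate_lo, ate_hi
    df = df[point_table.df.columns]
    return EffectsTable(df=df, metadata=dict(point_table.metadata))


def natural_course_diagnostic(
    models: FittedModelSet,
    cohort: Cohort,
    mc_size: int = 20_000,
    seed: int = 0,
    mode: str = "parametric",
    flag_fraction: float = 0.05,
) -> pd.DataFrame:
    """Compare simulated natural-course outcome means with observed means.

    Flags any outcome whose absolute difference exceeds ``flag_fraction`` of
    the observed (uncensored) outcome SD — the standard no-gross-
    misspecification check.
    """
    rng = _mc_rng(seed)
    base = _base_draw(models, mc_size, rng)
    sim = simulate_covariates(models, base, rng, mode=mode)
    pred = predict_outcome(models, sim["protein_1"].to_numpy(dtype=float), sim)
    obs = cohort.uncensored()
    rows = []
    for out in cohort.schema.outcomes:
        observed = float(obs[f"{out}_2"].mean())
        observed_sd = float(obs[f"{out}_2"].std(ddof=1))
        simulated = float(pred[out].mean())
        diff = simulated - observed
        rows.append(
            {
                "outcome": out,
                "observed_mean": observed,
                "simulated_mean": simulated,
                "difference": diff,
                "observed_sd": observed_sd,
                "flag": bool(abs(diff) > flag_fraction * observed_sd),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic or file-backed cohort)."""

    strategies: tuple[str, ...] = ("nc", "0.8", "1.0", "1.2", "1.5")
    mc_size: int = 20_000
    n_resamples: int = 500
    seed: int = 0
    mode: str = "parametric"
    n_jobs: int = 1
    dgp: DGPConfig | None = None
    cohort_csv: str | None = None
    schema_yaml: str | None = None
    outdir: str | None = None
    model_specs: ModelSpecSet | None = None

    def parsed_strategies(self) -> tuple[InterventionStrategy, ...]:
        return tuple(InterventionStrategy.parse(s) for s in self.strategies)

    def digest(self) -> str:
        payload = {
            "strategies": list(self.strategies),
            "mc_size": self.mc_size,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "mode": self.mode,
            "dgp": self.dgp.to_dict() if self.dgp else None,
            "cohort_csv": self.cohort_csv,
            "model_specs": self.model_specs.to_dict() if self.model_specs else None,
        }
        raw = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(raw).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> tuple[EffectsTable, dict]:
    """Eligibility -> fitting -> g-formula -> bootstrap -> effects table.

    Returns the table and an artifacts dict (cohort counts, exclusion log,
    diagnostic frame, bootstrap result, run log).  If ``config.outdir`` is
    set, CSV/JSON artifacts and a run log capturing every seed and count are
    written there.
    """
    strategies = config.parsed_strategies()
    if not any(s.kind == "natural_course" for s in strategies):
        raise ValueError("reference strategy required: include the natural course")

    if config.dgp is not None:
        raw = generate_cohort(config.dgp, seed=config.seed)
    elif config.cohort_csv and config.schema_yaml:
        schema = CovariateSchema.from_yaml(config.schema_yaml)
        raw = Cohort.from_csv(config.cohort_csv, schema)
    else:
        raise ValueError("pipeline config needs either a DGP or a cohort CSV + schema")

    eligible, exclusions = apply_eligibility(raw)
    models = fit_all(eligible, config.model_specs)
    boot = bootstrap(
        eligible,
        specs=config.model_specs,
        strategies=strategies,
        n_resamples=config.n_resamples,
        mc_size=config.mc_size,
        seed=config.seed,
        mode=config.mode,
        n_jobs=config.n_jobs,
    )
    diagnostic = natural_course_diagnostic(
        models, eligible, mc_size=config.mc_size, seed=config.seed, mode=config.mode
    )
    run_log = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "mc_size": config.mc_size,
        "n_resamples": config.n_resamples,
        "n_failed_replicates": boot.n_failed,
        "mode": config.mode,
        "strategies": [s.label for s in strategies],
        "n_input": len(raw),
        "n_eligible": len(eligible),
        "exclusions": exclusions.counts,
        "censoring": censoring_summary(eligible),
    }
    table = effects_table(
        boot,
        metadata={
            "mc_size": config.mc_size,
            "mode": config.mode,
            "config_digest": config.digest(),
            "n_eligible": len(eligible),
        },
    )
    artifacts = {
        "eligible_cohort": eligible,
        "exclusions": exclusions,
        "bootstrap": boot,
        "diagnostic": diagnostic,
        "run_log": run_log,
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "effects.csv")
        table.to_json(outdir / "effects.json")
        exclusions.to_frame().to_csv(outdir / "exclusions.csv", index=False)
        diagnostic.to_csv(outdir / "natural_course_diagnostic.csv", index=False)
        if boot.replicate_store is not None:
            boot.replicate_store.to_csv(outdir / "bootstrap_replicates.csv", index=False)
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
    return table, artifacts
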