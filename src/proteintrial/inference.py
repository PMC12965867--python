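"""Nonparametric bootstrap confidence intervals (percentile method).

Each replicate resamples participants with replacement, refits every model,
and reruns every strategy; 95% intervals are the 2.5th/97.5th percentiles
of the replicate estimates.  Replicate seeds are derived deterministically
from (master seed, replicate index), so results do not depend on worker
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .cohort import ID_COL, Cohort
from .engine import GEstimate, run_all_strategies
from .fitting import FitError, ModelSpecSet, fit_all
from .strategies import InterventionStrategy, study_grid

DEFAULT_RESAMPLES = 500


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapResult:
    n_resamples: int
    n_failed: int
    point: list[GEstimate]
    mean_ci: dict[tuple[str, str], tuple[float, float]]
    ate_ci: dict[tuple[str, str], tuple[float, float]]
    seed: int
    method: str = "percentile"
    flagged: list[tuple[str, str]] = field(default_factory=list)
    replicate_store: pd.DataFrame | None = None

    @property
    def failure_rate(self) -> float:
        return self.n_failed / self.n_resamples

    def point_for(self, label: str) -> GEstimate:
        for g in self.point:
            if g.strategy.label == label:
                return g
        raise KeyError(label)


def _replicate_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence((0xB007, seed, rep)).generate_state(1)[0])


def _one_replicate(
    cohort: Cohort,
    specs: ModelSpecSet | None,
    strategies: Sequence[InterventionStrategy],
    mc_size: int,
    mode: str,
    rep_seed: int,
) -> list[tuple[str, str, float, float]] | None:
    rng = np.random.default_rng(rep_seed)
    n = len(cohort)
    idx = rng.integers(0, n, size=n)
    df = cohort.df.iloc[idx].reset_index(drop=True).copy()
    df[ID_COL] = np.arange(1, n + 1)
    resampled = Cohort(df=df, schema=cohort.schema)
    try:
        models = fit_all(resampled, specs, drop_aliased=True)
        ests = run_all_strategies(models, strategies, mc_size=mc_size, seed=rep_seed, mode=mode)
    except FitError:
        return None
    rows = []
    for g in ests:
        for out, mean in g.standardized_mean.items():
            rows.append((g.strategy.label, out, mean, g.ate_vs_natural[out]))
    return rows


def bootstrap(
    cohort: Cohort,
    specs: ModelSpecSet | None = None,
    strategies: Sequence[InterventionStrategy] | None = None,
    n_resamples: int = DEFAULT_RESAMPLES,
    mc_size: int = 20_000,
    seed: int = 0,
    mode: str = "parametric",
    n_jobs: int = 1,
    keep_replicates: bool = True,
) -> BootstrapResult:
    """Percentile bootstrap over the full fit-and-standardize pipeline.

    Replicates whose model fits fail are dropped and counted; more than 10%
    failures aborts with diagnostics.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if strategies is None:
        strategies = study_grid()
    strategies = tuple(strategies)

    point = run_all_strategies(
        fit_all(cohort, specs), strategies, mc_size=mc_size, seed=seed, mode=mode
    )

    rep_seeds = [_replicate_seed(seed, r) for r in range(n_resamples)]
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_replicate)(cohort, specs, strategies, mc_size, mode, rs)
        for rs in rep_seeds
    )
    rows = []
    n_failed = 0
    for rep, res in enumerate(results):
        if res is None:
            n_failed += 1
            continue
        rows.extend((rep, *r) for r in res)
    if n_failed > 0.10 * n_resamples:
        raise BootstrapError(
            f"{n_failed}/{n_resamples} bootstrap replicates failed model fitting"
        )
    store = pd.DataFrame(
        rows, columns=["replicate", "strategy", "outcome", "mean", "ate"]
    )

    mean_ci: dict[tuple[str, str], tuple[float, float]] = {}
    ate_ci: dict[tuple[str, str], tuple[float, float]] = {}
    flagged: list[tuple[str, str]] = []
    point_by = {
        (g.strategy.label, out): (g.standardized_mean[out], g.ate_vs_natural[out])
        for g in point
        for out in g.standardized_mean
    }
    for (label, out), grp in store.groupby(["strategy", "outcome"], sort=True):
        lo_m, hi_m = np.percentile(grp["mean"].to_numpy(), [2.5, 97.5])
        mean_ci[(label, out)] = (float(lo_m), float(hi_m))
        if label != "natural_course":
            lo_a, hi_a = np.percentile(grp["ate"].to_numpy(), [2.5, 97.5])
            ate_ci[(label, out)] = (float(lo_a), float(hi_a))
        pm, pa = point_by[(label, out)]
        outside = not (lo_m <= pm <= hi_m)
        if label != "natural_course":
            outside |= not (ate_ci[(label, out)][0] <= pa <= ate_ci[(label, out)][1])
        if outside:
            flagged.append((label, out))
    return BootstrapResult(
        n_resamples=n_resamples,
        n_failed=n_failed,
        point=point,
        mean_ci=mean_ci,
        ate_ci=ate_ci,
        seed=seed,
        flagged=flagged,
        replicate_store=store if keep_replicates else None,
    )
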