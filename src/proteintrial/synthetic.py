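"""Synthetic cohort generator with known counterfactual truth.

The data-generating process (DGP) mirrors the analysis's causal ordering:
pre-baseline covariates and outcomes -> baseline covariates, outcomes and
exposure -> end-of-follow-up outcomes, with censoring by death and loss to
follow-up generated from baseline history.

Structure, in generation order (all structural equations linear; continuous
noise Gaussian; the exposure log-normal):

1. ``L0``: covariates drawn from their marginals.
2. ``U``: a latent adiposity factor inducing cross-outcome correlation
   through the pre-baseline outcomes ``Y0`` (downstream equations condition
   only on observables, so fitted parametric models remain correctly
   specified).
3. ``log A0``: linear in covariate scores plus noise.
4. ``L1``: AR(1) for continuous covariates; sticky redraw for categorical.
5. ``Y1``: linear in ``Y0``, covariate scores, ``log A0``.
6. ``log A1``: linear in ``log A0``, covariate scores, standardized baseline
   weight (heavier women have lower g/kg intake), plus noise.
7. ``Y2``: linear in ``Y1``, covariate scores and — crucially — *linear in
   A1 on the natural scale* with per-outcome slope ``effect_protein``; a
   shared residual factor correlates outcomes without biasing means.
8. Censoring: logistic in baseline history; censored rows lose ``Y2``.

Because ``Y2`` is linear in ``A1`` and everything upstream of ``A1`` is
unaffected by the intervention, the true effect of a threshold rule ``t`` is
``effect_protein * E[(t - A1)+]``, which :func:`true_intervention_mean` can
evaluate either by brute-force simulation or in closed form by propagating
the linear-Gaussian system (enumerating categorical profiles).

Covariate "scores" are standardized codings: ``(x - mean)/sd`` for
continuous, ``(x - p)/sqrt(p(1-p))`` for binary, standardized level index
for categorical covariates.  All stated coefficients are per score unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import norm

from .cohort import (
    CENSOR_LEVELS,
    Cohort,
    CovariateDef,
    CovariateSchema,
)
from .strategies import InterventionStrategy, apply_intervention


class ConfigError(ValueError):
    """Raised for structurally invalid DGP configurations."""


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ContinuousParams:
    mean: float
    sd: float
    rho: float = 0.0  # L1 = mean + rho*(L0-mean) + sd*sqrt(1-rho^2)*eps

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigError("continuous covariate sd must be > 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigError("autocorrelation must lie in [-1, 1]")


@dataclass(frozen=True)
class BinaryParams:
    p: float
    kappa: float = 1.0  # P(keep L0 value); else redraw from marginal

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ConfigError("binary prevalence must lie in (0, 1)")
        if not 0.0 <= self.kappa <= 1.0:
            raise ConfigError("persistence must lie in [0, 1]")


@dataclass(frozen=True)
class CategoricalParams:
    probs: tuple[float, ...]
    kappa: float = 1.0

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ConfigError("categorical probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SyntheticCovariate:
    definition: CovariateDef
    params: ContinuousParams | BinaryParams | CategoricalParams

    @property
    def name(self) -> str:
        return self.definition.name


@dataclass(frozen=True)
class ExposureParams:
    """Log-normal protein intake model for A0 and A1 (g/kg/day)."""

    log_mean: float
    log_sd0: float  # residual sd of log A0
    carryover: float  # coef of (log A0 - log_mean) in log A1
    log_sd1: float  # residual sd of log A1
    effects0: Mapping[str, float] = field(default_factory=dict)
    effects1: Mapping[str, float] = field(default_factory=dict)
    weight_effect: float = 0.0  # per SD of baseline body weight
    log_mean1: float | None = None

    @property
    def center1(self) -> float:
        return self.log_mean if self.log_mean1 is None else self.log_mean1


@dataclass(frozen=True)
class OutcomeParams:
    name: str
    mean0: float
    sd0: float  # total pre-baseline SD (latent + residual)
    latent_load: float
    ar1: float
    drift1: float
    sd1: float  # residual sd of Y1
    ar2: float
    drift2: float
    effect_protein: float  # slope of Y2 on A1, per g/kg/day
    sd2: float  # independent residual sd of Y2
    effects1: Mapping[str, float] = field(default_factory=dict)
    effects2: Mapping[str, float] = field(default_factory=dict)
    a0_effect: float = 0.0  # coef of (log A0 - log_mean) in Y1
    shared2: float = 0.0  # loading on the shared Y2 residual factor

    def __post_init__(self):
        if abs(self.latent_load) >= self.sd0:
            raise ConfigError(f"{self.name}: |latent_load| must be < sd0")

    @property
    def resid_sd0(self) -> float:
        return float(np.sqrt(self.sd0**2 - self.latent_load**2))


@dataclass(frozen=True)
class CensoringParams:
    intercept: float
    effects: Mapping[str, float] = field(default_factory=dict)
    a1_effect: float = 0.0  # per (A1 - a_ref)
    weight_effect: float = 0.0  # per SD of baseline weight


@dataclass(frozen=True)
class DGPConfig:
    """Full structural specification of the synthetic cohort."""

    n: int
    covariates: tuple[SyntheticCovariate, ...]
    exposure: ExposureParams
    outcomes: tuple[OutcomeParams, ...]
    censoring: Mapping[str, CensoringParams]
    a_ref: float = 0.97  # centering constant for A1 in outcome/censoring models
    energy_mean: float = 1575.7
    energy_sd: float = 729.0
    missing_protein_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ConfigError("cohort size must be positive")
        names = {c.name for c in self.covariates}
        referenced = set()
        referenced |= set(self.exposure.effects0) | set(self.exposure.effects1)
        for o in self.outcomes:
            referenced |= set(o.effects1) | set(o.effects2)
        for c in self.censoring.values():
            referenced |= set(c.effects)
        unknown = referenced - names
        if unknown:
            raise ConfigError(f"effects reference undeclared covariates: {sorted(unknown)}")
        if self.exposure.weight_effect != 0.0 and "weight" not in self.outcome_names:
            raise ConfigError("weight_effect requires an outcome named 'weight'")
        bad_censor = set(self.censoring) - set(CENSOR_LEVELS)
        if bad_censor:
            raise ConfigError(f"unknown censoring reasons: {sorted(bad_censor)}")

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.outcomes)

    @property
    def effect_protein(self) -> dict[str, float]:
        return {o.name: o.effect_protein for o in self.outcomes}

    def outcome(self, name: str) -> OutcomeParams:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(name)

    def schema(self) -> CovariateSchema:
        return CovariateSchema(
            covariates=tuple(c.definition for c in self.covariates),
            outcomes=self.outcome_names,
        )

    def replace(self, **kw) -> "DGPConfig":
        return dataclasses.replace(self, **kw)

    def with_effects(self, effect_protein: Mapping[str, float]) -> "DGPConfig":
        """Return a copy with per-outcome protein slopes overridden."""
        outs = tuple(
            dataclasses.replace(o, effect_protein=effect_protein.get(o.name, o.effect_protein))
            for o in self.outcomes
        )
        return self.replace(outcomes=outs)

    def without_confounding(self) -> "DGPConfig":
        """Sever every arrow into the exposure: A0/A1 become exogenous."""
        exp = dataclasses.replace(
            self.exposure, effects0={}, effects1={}, carryover=0.0, weight_effect=0.0
        )
        outs = tuple(dataclasses.replace(o, a0_effect=0.0) for o in self.outcomes)
        return self.replace(exposure=exp, outcomes=outs)

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for cov_obj, cov_dict in zip(self.covariates, d["covariates"]):
            cov_dict["params_kind"] = type(cov_obj.params).__name__
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DGPConfig":
        param_types = {
            "ContinuousParams": ContinuousParams,
            "BinaryParams": BinaryParams,
            "CategoricalParams": CategoricalParams,
        }
        covs = []
        for cov in d["covariates"]:
            dd = dict(cov["definition"])
            if dd.get("levels") is not None:
                dd["levels"] = tuple(dd["levels"])
            params = dict(cov["params"])
            if "probs" in params:
                params["probs"] = tuple(params["probs"])
            covs.append(
                SyntheticCovariate(
                    definition=CovariateDef(**dd),
                    params=param_types[cov["params_kind"]](**params),
                )
            )
        outs = tuple(OutcomeParams(**o) for o in d["outcomes"])
        cens = {k: CensoringParams(**v) for k, v in d["censoring"].items()}
        kw = {
            k: d[k]
            for k in (
                "n",
                "a_ref",
                "energy_mean",
                "energy_sd",
                "missing_protein_rate",
                "seed",
            )
            if k in d
        }
        return cls(
            covariates=tuple(covs),
            exposure=ExposureParams(**d["exposure"]),
            outcomes=outs,
            censoring=cens,
            **kw,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DGPConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TruthRecord:
    """Counterfactual population means for one strategy, with provenance."""

    strategy: InterventionStrategy
    true_mean: dict[str, float]
    method: str  # closed_form | oracle_simulation
    oracle_n: int | None = None
    se: dict[str, float] | None = None


# --------------------------------------------------------------------------
# score helpers


def _score_continuous(x, params: ContinuousParams):
    return (np.asarray(x, dtype=float) - params.mean) / params.sd


def _score_binary(x, params: BinaryParams):
    return (np.asarray(x, dtype=float) - params.p) / np.sqrt(params.p * (1 - params.p))


def _cat_index_stats(params: CategoricalParams) -> tuple[float, float]:
    idx = np.arange(len(params.probs), dtype=float)
    p = np.asarray(params.probs)
    mu = float(idx @ p)
    sd = float(np.sqrt(((idx - mu) ** 2) @ p))
    return mu, max(sd, 1e-12)


def _score_categorical(codes, params: CategoricalParams):
    mu, sd = _cat_index_stats(params)
    return (np.asarray(codes, dtype=float) - mu) / sd


def _score(cov: SyntheticCovariate, values, codes=None):
    if isinstance(cov.params, ContinuousParams):
        return _score_continuous(values, cov.params)
    if isinstance(cov.params, BinaryParams):
        return _score_binary(values, cov.params)
    return _score_categorical(codes, cov.params)


# --------------------------------------------------------------------------
# generation


def _draw_l0(cov: SyntheticCovariate, n: int, rng: np.random.Generator):
    """Return (values_for_frame, numeric_codes)."""
    p = cov.params
    if isinstance(p, ContinuousParams):
        vals = rng.normal(p.mean, p.sd, size=n)
        return vals, vals
    if isinstance(p, BinaryParams):
        codes = (rng.random(n) < p.p).astype(int)
        return codes.astype(str), codes
    codes = rng.choice(len(p.probs), size=n, p=np.asarray(p.probs))
    levels = np.asarray(cov.definition.levels)
    return levels[codes], codes


def _draw_l0_codes(cov: SyntheticCovariate, n: int, rng: np.random.Generator):
    p = cov.params
    if isinstance(p, ContinuousParams):
        return rng.normal(p.mean, p.sd, size=n)
    if isinstance(p, BinaryParams):
        return (rng.random(n) < p.p).astype(int)
    return rng.choice(len(p.probs), size=n, p=np.asarray(p.probs))


def _step_l1(cov: SyntheticCovariate, codes0, rng: np.random.Generator):
    p = cov.params
    n = len(codes0)
    if not cov.definition.time_varying:
        return codes0.copy()
    if isinstance(p, ContinuousParams):
        noise_sd = p.sd * np.sqrt(1 - p.rho**2)
        return p.mean + p.rho * (codes0 - p.mean) + rng.normal(0, noise_sd, size=n)
    if isinstance(p, BinaryParams):
        keep = rng.random(n) < p.kappa
        fresh = (rng.random(n) < p.p).astype(int)
        return np.where(keep, codes0, fresh)
    keep = rng.random(n) < p.kappa
    fresh = rng.choice(len(p.probs), size=n, p=np.asarray(p.probs))
    return np.where(keep, codes0, fresh)


def _structural_draw(
    config: DGPConfig, n: int, rng: np.random.Generator, with_labels: bool = True
) -> dict:
    """Simulate the pre-censoring structural system for n individuals.

    Returns raw arrays keyed by variable; categorical covariates appear as
    integer codes (``<name>__code0/1``) alongside level labels (labels are
    skipped when ``with_labels`` is false — the truth oracle only needs
    scores, and string materialisation dominates runtime at oracle sizes).
    """
    out: dict[str, np.ndarray] = {}
    scores0: dict[str, np.ndarray] = {}
    scores1: dict[str, np.ndarray] = {}

    for cov in config.covariates:
        if with_labels:
            vals, codes = _draw_l0(cov, n, rng)
            out[f"{cov.name}_0"] = vals
        else:
            codes = _draw_l0_codes(cov, n, rng)
        out[f"{cov.name}__code0"] = codes
        scores0[cov.name] = _score(cov, codes, codes)

    u = rng.normal(size=n)
    out["__latent"] = u
    for o in config.outcomes:
        out[f"{o.name}_0"] = o.mean0 + o.latent_load * u + rng.normal(
            0, o.resid_sd0, size=n
        )

    ex = config.exposure
    log_a0 = ex.log_mean + sum(
        c * scores0[name] for name, c in ex.effects0.items()
    ) + rng.normal(0, ex.log_sd0, size=n)
    out["protein_0"] = np.exp(log_a0)

    for cov in config.covariates:
        codes1 = _step_l1(cov, out[f"{cov.name}__code0"], rng)
        out[f"{cov.name}__code1"] = codes1
        if with_labels:
            if isinstance(cov.params, CategoricalParams):
                out[f"{cov.name}_1"] = np.asarray(cov.definition.levels)[
                    np.asarray(codes1, dtype=int)
                ]
            elif isinstance(cov.params, BinaryParams):
                out[f"{cov.name}_1"] = np.asarray(codes1, dtype=int).astype(str)
            else:
                out[f"{cov.name}_1"] = codes1
        elif isinstance(cov.params, ContinuousParams):
            out[f"{cov.name}_1"] = codes1
        scores1[cov.name] = _score(cov, codes1, codes1)

    for o in config.outcomes:
        out[f"{o.name}_1"] = (
            o.mean0
            + o.drift1
            + o.ar1 * (out[f"{o.name}_0"] - o.mean0)
            + sum(c * scores1[name] for name, c in o.effects1.items())
            + o.a0_effect * (log_a0 - ex.log_mean)
            + rng.normal(0, o.sd1, size=n)
        )

    log_a1 = (
        ex.center1
        + ex.carryover * (log_a0 - ex.log_mean)
        + sum(c * scores1[name] for name, c in ex.effects1.items())
        + rng.normal(0, ex.log_sd1, size=n)
    )
    if ex.weight_effect != 0.0:
        w = config.outcome("weight")
        log_a1 = log_a1 + ex.weight_effect * (out["weight_1"] - w.mean0) / w.sd0
    out["protein_1"] = np.exp(log_a1)
    out["__scores1"] = scores1  # type: ignore[assignment]
    return out


def _y2_mean(config: DGPConfig, draw: dict, a1: np.ndarray, name: str) -> np.ndarray:
    o = config.outcome(name)
    scores1 = draw["__scores1"]
    return (
        o.mean0
        + o.drift2
        + o.ar2 * (draw[f"{name}_1"] - o.mean0)
        + o.effect_protein * (a1 - config.a_ref)
        + sum(c * scores1[cn] for cn, c in o.effects2.items())
    )


def generate_cohort(config: DGPConfig, seed: int | None = None) -> Cohort:
    """Draw a full synthetic cohort (deterministic given config and seed)."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence((0xC040, seed)))
    n = config.n
    draw = _structural_draw(config, n, rng)

    shared = rng.normal(size=n)
    y2 = {}
    for o in config.outcomes:
        y2[o.name] = (
            _y2_mean(config, draw, draw["protein_1"], o.name)
            + o.shared2 * shared
            + rng.normal(0, o.sd2, size=n)
        )

    # censoring from baseline history (missing-at-random by construction)
    scores1 = draw["__scores1"]
    censor = np.full(n, "none", dtype=object)
    for reason in ("death", "ltfu"):
        if reason not in config.censoring:
            continue
        cp = config.censoring[reason]
        lin = cp.intercept + sum(c * scores1[name] for name, c in cp.effects.items())
        lin = lin + cp.a1_effect * (draw["protein_1"] - config.a_ref)
        if cp.weight_effect != 0.0:
            w = config.outcome("weight")
            lin = lin + cp.weight_effect * (draw["weight_1"] - w.mean0) / w.sd0
        hit = (rng.random(n) < expit(lin)) & (censor == "none")
        censor[hit] = reason

    cols: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    for cov in config.covariates:
        cols[f"{cov.name}_0"] = draw[f"{cov.name}_0"]
        cols[f"{cov.name}_1"] = draw[f"{cov.name}_1"]
    cols["protein_0"] = draw["protein_0"]
    cols["protein_1"] = draw["protein_1"]
    cols["energy_1"] = np.clip(
        rng.normal(config.energy_mean, config.energy_sd, size=n), 50.0, None
    )
    for o in config.outcomes:
        cols[f"{o.name}_0"] = draw[f"{o.name}_0"]
        cols[f"{o.name}_1"] = draw[f"{o.name}_1"]
        y = y2[o.name].copy()
        y[censor != "none"] = np.nan
        cols[f"{o.name}_2"] = y
    cols["censor"] = censor

    df = pd.DataFrame(cols)
    if config.missing_protein_rate > 0:
        for col in ("protein_0", "protein_1"):
            drop = rng.random(n) < config.missing_protein_rate
            df.loc[drop, col] = np.nan
    return Cohort(df=df, schema=config.schema())


# --------------------------------------------------------------------------
# counterfactual truth


def true_intervention_mean(
    config: DGPConfig,
    strategy: InterventionStrategy,
    method: str = "oracle_simulation",
    oracle_n: int = 1_000_000,
    seed: int = 12345,
) -> TruthRecord:
    """E[Y2] under a strategy, with censoring abolished.

    ``oracle_simulation`` brute-forces the structural model at ``oracle_n``
    draws (chunked); ``closed_form`` propagates the linear-Gaussian system
    exactly, enumerating categorical covariate profiles.
    """
    if method == "closed_form":
        means = _closed_form_means(config, strategy)
        return TruthRecord(strategy=strategy, true_mean=means, method=method)
    if method != "oracle_simulation":
        raise ValueError(f"unknown truth method {method!r}")
    if oracle_n < 10**6:
        raise ValueError("oracle_n must be at least 10^6")

    rng = np.random.default_rng(np.random.SeedSequence((0x04AC1E, seed)))
    sums = {o.name: 0.0 for o in config.outcomes}
    sumsq = {o.name: 0.0 for o in config.outcomes}
    remaining = oracle_n
    chunk = 500_000
    while remaining > 0:
        m = min(chunk, remaining)
        draw = _structural_draw(config, m, rng, with_labels=False)
        a = apply_intervention(draw["protein_1"], strategy)
        for o in config.outcomes:
            # residual noise is mean-zero: accumulate conditional means only
            mu = _y2_mean(config, draw, a, o.name)
            sums[o.name] += float(mu.sum())
            sumsq[o.name] += float((mu**2).sum())
        remaining -= m
    means = {k: sums[k] / oracle_n for k in sums}
    ses = {
        k: float(np.sqrt(max(sumsq[k] / oracle_n - means[k] ** 2, 0.0) / oracle_n))
        for k in sums
    }
    return TruthRecord(
        strategy=strategy, true_mean=means, method=method, oracle_n=oracle_n, se=ses
    )


def true_ate(
    config: DGPConfig,
    strategy: InterventionStrategy,
    method: str = "closed_form",
    **kw,
) -> dict[str, float]:
    """True ATE of a strategy versus the natural course."""
    if method == "closed_form":
        gap = _expected_lift(config, strategy)
        return {o.name: o.effect_protein * gap for o in config.outcomes}
    nat = true_intervention_mean(config, InterventionStrategy.natural(), method=method, **kw)
    trt = true_intervention_mean(config, strategy, method=method, **kw)
    return {k: trt.true_mean[k] - nat.true_mean[k] for k in trt.true_mean}


# -- linear-Gaussian propagation -------------------------------------------


def _lin_scale(d: dict, c: float) -> dict:
    return {k: v * c for k, v in d.items()}


def _lin_sum(*terms: dict) -> dict:
    out: dict = {}
    for t in terms:
        for k, v in t.items():
            out[k] = out.get(k, 0.0) + v
    return out


def _log_a1_distribution(config: DGPConfig):
    """Marginal distribution of log A1 as a Gaussian mixture.

    Returns (base_mean, gaussian_sd, offsets, weights): mixture component
    means are base_mean + offsets with common sd.
    """
    ex = config.exposure

    # shock loadings for each standardized covariate score at times 0 and 1
    z0: dict[str, dict] = {}
    z1: dict[str, dict] = {}
    for cov in config.covariates:
        name = cov.name
        if isinstance(cov.params, ContinuousParams):
            z0[name] = {("z0", name): 1.0}
            if cov.definition.time_varying:
                rho = cov.params.rho
                z1[name] = {
                    ("z0", name): rho,
                    ("z1", name): float(np.sqrt(1 - rho**2)),
                }
            else:
                z1[name] = z0[name]
        else:
            # symbolic score keys, resolved by profile enumeration below
            z0[name] = {("s0", name): 1.0}
            z1[name] = {("s1", name): 1.0} if cov.definition.time_varying else z0[name]

    log_a0 = _lin_sum(
        *[_lin_scale(z0[n], c) for n, c in ex.effects0.items()], {("ea0",): ex.log_sd0}
    )
    terms = [_lin_scale(log_a0, ex.carryover)]
    terms += [_lin_scale(z1[n], c) for n, c in ex.effects1.items()]
    terms.append({("ea1",): ex.log_sd1})
    const = ex.center1

    if ex.weight_effect != 0.0:
        w = config.outcome("weight")
        y0_w = {("U",): w.latent_load, ("e0", "weight"): w.resid_sd0}
        y1_w = _lin_sum(
            _lin_scale(y0_w, w.ar1),
            *[_lin_scale(z1[n], c) for n, c in w.effects1.items()],
            _lin_scale(log_a0, w.a0_effect),
            {("e1", "weight"): w.sd1},
        )
        terms.append(_lin_scale(y1_w, ex.weight_effect / w.sd0))
        const += ex.weight_effect * w.drift1 / w.sd0

    loadings = _lin_sum(*terms)

    gauss_var = sum(v**2 for k, v in loadings.items() if k[0] not in ("s0", "s1"))
    sd = float(np.sqrt(gauss_var))

    offsets = np.zeros(1)
    weights = np.ones(1)
    for cov in config.covariates:
        if isinstance(cov.params, ContinuousParams):
            continue
        lam0 = loadings.get(("s0", cov.name), 0.0)
        lam1 = loadings.get(("s1", cov.name), 0.0)
        if lam0 == 0.0 and lam1 == 0.0:
            continue
        if isinstance(cov.params, BinaryParams):
            p = cov.params.p
            levels = np.array([0.0, 1.0])
            probs = np.array([1 - p, p])
            scores = (levels - p) / np.sqrt(p * (1 - p))
        else:
            probs = np.asarray(cov.params.probs)
            mu, sdx = _cat_index_stats(cov.params)
            scores = (np.arange(len(probs)) - mu) / sdx
        kappa = cov.params.kappa if cov.definition.time_varying else 1.0
        pair_d, pair_w = [], []
        for i, pi in enumerate(probs):
            for j, pj in enumerate(probs):
                wgt = pi * (kappa * (i == j) + (1 - kappa) * pj)
                if wgt <= 0:
                    continue
                pair_d.append(lam0 * scores[i] + lam1 * scores[j])
                pair_w.append(wgt)
        offsets = (offsets[:, None] + np.asarray(pair_d)[None, :]).ravel()
        weights = (weights[:, None] * np.asarray(pair_w)[None, :]).ravel()
    return const, sd, offsets, weights


def _lognormal_shortfall(t: float, m, s: float):
    """E[(t - X)+] for X ~ LogNormal(m, s^2)."""
    if t <= 0:
        return np.zeros_like(np.asarray(m, dtype=float))
    d = (np.log(t) - np.asarray(m, dtype=float)) / s
    return t * norm.cdf(d) - np.exp(m + s**2 / 2) * norm.cdf(d - s)


def _expected_a1(config: DGPConfig) -> float:
    m0, s, offs, w = _log_a1_distribution(config)
    return float(np.sum(w * np.exp(m0 + offs + s**2 / 2)))


def _expected_lift(config: DGPConfig, strategy: InterventionStrategy) -> float:
    """E[max(A1, t) - A1] under the natural exposure distribution."""
    if strategy.kind == "natural_course":
        return 0.0
    m0, s, offs, w = _log_a1_distribution(config)
    return float(np.sum(w * _lognormal_shortfall(strategy.t, m0 + offs, s)))


def _closed_form_means(config: DGPConfig, strategy: InterventionStrategy) -> dict[str, float]:
    ea1 = _expected_a1(config) + _expected_lift(config, strategy)
    means = {}
    for o in config.outcomes:
        # covariate scores and shocks are mean-zero; only drifts and the
        # exposure term move the population mean
        means[o.name] = (
            o.mean0 + o.drift2 + o.ar2 * o.drift1 + o.effect_protein * (ea1 - config.a_ref)
        )
    return means


# --------------------------------------------------------------------------
# default configurations


def default_config(n: int = 4681, seed: int = 0) -> DGPConfig:
    """WHI-like defaults: marginals calibrated to the published cohort table.

    The exposure distribution targets the published intake-category split
    (~41% at 0.5-0.8 g/kg/day, ~11% above 1.5); outcome levels and drifts
    target the published baseline and natural-course means.
    """
    C = CovariateDef
    covariates = (
        SyntheticCovariate(C("age", "continuous", time_varying=False), ContinuousParams(63.4, 7.4)),
        SyntheticCovariate(C("hei", "continuous"), ContinuousParams(65.8, 10.6, rho=0.7)),
        SyntheticCovariate(C("alcohol", "continuous"), ContinuousParams(1.9, 4.4, rho=0.7)),
        SyntheticCovariate(C("met", "continuous"), ContinuousParams(12.0, 10.0, rho=0.6)),
        SyntheticCovariate(C("cesd", "continuous"), ContinuousParams(0.08, 0.10, rho=0.5)),
        SyntheticCovariate(C("sleep_hours", "continuous"), ContinuousParams(7.0, 1.0, rho=0.6)),
        SyntheticCovariate(C("diabetes", "binary"), BinaryParams(0.062, kappa=0.95)),
        SyntheticCovariate(C("cancer", "binary"), BinaryParams(0.095, kappa=0.95)),
        SyntheticCovariate(
            C("hispanic", "binary", time_varying=False), BinaryParams(0.074)
        ),
        SyntheticCovariate(
            C(
                "education",
                "categorical",
                levels=("hs_or_less", "some_college", "college", "postgrad"),
                ordered=True,
                time_varying=False,
            ),
            CategoricalParams((0.302, 0.356, 0.187, 0.155)),
        ),
        SyntheticCovariate(
            C(
                "income",
                "categorical",
                levels=("lt_35k", "35_75k", "ge_75k"),
                ordered=True,
                time_varying=False,
            ),
            CategoricalParams((0.525, 0.349, 0.126)),
        ),
        SyntheticCovariate(
            C(
                "race",
                "categorical",
                levels=("white", "black", "asian", "am_indian", "multiple"),
                time_varying=False,
            ),
            CategoricalParams((0.868, 0.111, 0.005, 0.010, 0.006)),
        ),
        SyntheticCovariate(
            C(
                "marital",
                "categorical",
                levels=("never", "divorced", "widowed", "married", "marriage_like"),
                time_varying=False,
            ),
            CategoricalParams((0.039, 0.138, 0.193, 0.619, 0.011)),
        ),
        SyntheticCovariate(
            C("smoking", "categorical", levels=("never", "former", "current")),
            CategoricalParams((0.594, 0.250, 0.156), kappa=0.9),
        ),
    )
    exposure = ExposureParams(
        log_mean=-0.123,
        log_sd0=0.434,
        carryover=0.45,
        log_sd1=0.368,
        effects0={"hei": 0.05, "met": 0.04, "age": -0.02, "diabetes": -0.03},
        effects1={"hei": 0.06, "met": 0.05, "age": -0.02, "diabetes": -0.04, "cesd": -0.02},
        weight_effect=-0.10,
    )
    outcomes = (
        OutcomeParams(
            "vat", 153.6, 81.7, latent_load=60.0, ar1=0.85, drift1=8.0, sd1=25.0,
            ar2=0.9, drift2=8.8, effect_protein=-10.0, sd2=25.0,
            effects1={"age": 3.0, "hei": -3.0, "met": -5.0, "diabetes": 8.0},
            effects2={"hei": -4.0, "met": -6.0, "age": 3.0, "diabetes": 6.0},
            a0_effect=-2.0, shared2=10.0,
        ),
        OutcomeParams(
            "sat", 358.5, 135.2, latent_load=100.0, ar1=0.85, drift1=4.5, sd1=40.0,
            ar2=0.9, drift2=4.95, effect_protein=-20.0, sd2=40.0,
            effects1={"met": -8.0, "hei": -5.0},
            effects2={"met": -8.0, "hei": -5.0, "age": -2.0},
            shared2=20.0,
        ),
        OutcomeParams(
            "bodyfat_pct", 43.0, 7.2, latent_load=5.5, ar1=0.85, drift1=0.2, sd1=1.8,
            ar2=0.9, drift2=0.02, effect_protein=-1.75, sd2=1.6,
            effects1={"met": -0.8, "hei": -0.4},
            effects2={"met": -0.6, "hei": -0.3},
            shared2=0.8,
        ),
        OutcomeParams(
            "lean_pct", 54.0, 7.5, latent_load=-5.8, ar1=0.85, drift1=-0.15, sd1=1.8,
            ar2=0.9, drift2=0.035, effect_protein=1.6, sd2=1.6,
            effects1={"met": 0.8},
            effects2={"met": 0.6},
            shared2=-0.8,
        ),
        OutcomeParams(
            "weight", 70.1, 15.0, latent_load=11.0, ar1=0.9, drift1=0.65, sd1=2.5,
            ar2=0.95, drift2=0.6825, effect_protein=-4.4, sd2=2.5,
            effects1={"met": -1.0, "hei": -0.5},
            effects2={"met": -0.8},
            shared2=1.2,
        ),
    )
    censoring = {
        "death": CensoringParams(
            intercept=-3.55, effects={"age": 0.5}, a1_effect=-0.2, weight_effect=0.15
        ),
        "ltfu": CensoringParams(
            intercept=-2.02, effects={"cesd": 0.25, "age": -0.15}, a1_effect=-0.1
        ),
    }
    return DGPConfig(
        n=n,
        covariates=covariates,
        exposure=exposure,
        outcomes=outcomes,
        censoring=censoring,
        seed=seed,
    )


def calibrated_config(n: int = 4681, seed: int = 0) -> DGPConfig:
    """Slopes scaled so threshold(1.5) effects match the published table's
    order of magnitude (VAT about -13 cm^2, weight about -2.5 kg)."""
    return default_config(n=n, seed=seed).with_effects(
        {"vat": -23.0, "sat": -45.0, "bodyfat_pct": -1.75, "lean_pct": 1.6, "weight": -4.4}
    )


def compact_config(n: int = 2000, seed: int = 0, effect_vat: float = -10.0) -> DGPConfig:
    """A small continuous-only DGP (three covariates, one outcome) for
    simulation experiments that refit the whole pipeline many times."""
    C = CovariateDef
    covariates = (
        SyntheticCovariate(C("age", "continuous", time_varying=False), ContinuousParams(63.4, 7.4)),
        SyntheticCovariate(C("hei", "continuous"), ContinuousParams(65.8, 10.6, rho=0.7)),
        SyntheticCovariate(C("met", "continuous"), ContinuousParams(12.0, 10.0, rho=0.6)),
    )
    exposure = ExposureParams(
        log_mean=-0.123,
        log_sd0=0.434,
        carryover=0.45,
        log_sd1=0.38,
        effects0={"hei": 0.05, "met": 0.04, "age": -0.02},
        effects1={"hei": 0.06, "met": 0.05, "age": -0.02},
    )
    outcomes = (
        OutcomeParams(
            "vat", 153.6, 81.7, latent_load=60.0, ar1=0.85, drift1=8.0, sd1=25.0,
            ar2=0.9, drift2=8.8, effect_protein=effect_vat, sd2=25.0,
            effects1={"age": 3.0, "hei": -3.0, "met": -5.0},
            effects2={"hei": -4.0, "met": -6.0, "age": 3.0},
            a0_effect=-2.0,
        ),
    )
    censoring = {
        "death": CensoringParams(intercept=-3.55, effects={"age": 0.5}, a1_effect=-0.2),
        "ltfu": CensoringParams(intercept=-2.02, effects={"age": -0.15}, a1_effect=-0.1),
    }
    return DGPConfig(
        n=n,
        covariates=covariates,
        exposure=exposure,
        outcomes=outcomes,
        censoring=censoring,
        seed=seed,
    )


# --------------------------------------------------------------------------
# discrete toy cohorts (brute-force verification surface)


def discrete_toy_cohort(
    n: int = 2000,
    seed: int = 0,
    exposure_levels: tuple[float, ...] = (0.6, 1.0, 1.4),
    noise_sd: float = 0.5,
):
    """A fully discrete cohort: one binary confounder, a few exposure levels.

    Cell probabilities P(l), P(a|l) and conditional outcome means E[y|a,l]
    are drawn at random, with the confounder shifting both the exposure
    distribution and the outcome (real confounding).  Returns the cohort,
    a matching saturated model specification set, and the cell-mean table
    ``{(a, l): mean}``.

    Suitable for checking the Monte Carlo engine (empirical mode, saturated
    outcome model) against :func:`~proteintrial.engine.plugin_standardization_oracle`.
    """
    from .fitting import ModelSpec, ModelSpecSet

    rng = np.random.default_rng(np.random.SeedSequence((0xD15C, seed)))
    k = len(exposure_levels)
    p_l = rng.uniform(0.25, 0.75)
    p_a = {lvl: rng.dirichlet(np.ones(k) * 3) for lvl in (0, 1)}
    cell_means = {
        (a, lvl): float(rng.normal(100 + 15 * lvl, 10))
        for a in exposure_levels
        for lvl in (0, 1)
    }

    l = (rng.random(n) < p_l).astype(int)
    a = np.empty(n)
    for lvl in (0, 1):
        mask = l == lvl
        a[mask] = rng.choice(exposure_levels, size=int(mask.sum()), p=p_a[lvl])
    y2 = np.array([cell_means[(av, lv)] for av, lv in zip(a, l)])
    y2 = y2 + rng.normal(0, noise_sd, size=n)

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "l_0": l.astype(str),
            "l_1": l.astype(str),
            "protein_0": a,
            "protein_1": a,
            "energy_1": 2000.0,
            "y_0": 0.0,
            "y_1": 0.0,
            "y_2": y2,
            "censor": "none",
        }
    )
    schema = CovariateSchema(
        covariates=(CovariateDef("l", "binary", time_varying=False),),
        outcomes=("y",),
    )
    cohort = Cohort(df=df, schema=schema)
    specs = ModelSpecSet(
        covariate=(),
        y1=(ModelSpec(target="y_1", family="linear", predictors=()),),
        exposure=ModelSpec(target="protein_1", family="linear", predictors=(), transform="log"),
        outcome=(
            ModelSpec(
                target="y_2",
                family="linear",
                predictors=("protein_1", "l_0"),
                saturated=True,
            ),
        ),
        censoring=(
            ModelSpec(target="censor_death", family="logistic", predictors=()),
            ModelSpec(target="censor_ltfu", family="logistic", predictors=()),
        ),
    )
    return cohort, specs, cell_means
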