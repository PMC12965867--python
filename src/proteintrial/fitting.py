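"""Parametric models for the g-formula: covariates, exposure, outcomes,
censoring.

Families are linear (OLS), logistic, and multinomial; a ``saturated``
variant fits stratum means over fully discrete predictors and is used by
the brute-force verification path.  Categorical predictors are dummy-coded
against levels seen at fit time; prediction at an unseen level raises
rather than silently extrapolating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
import statsmodels.api as sm
from scipy.special import expit

from .cohort import CENSOR_COL, EXPOSURE, Cohort, CovariateSchema, add_derived


class FitError(RuntimeError):
    pass


class ConvergenceError(FitError):
    def __init__(self, model_name: str, detail: str = ""):
        super().__init__(f"model {model_name!r} failed to converge{': ' + detail if detail else ''}")
        self.model_name = model_name


class RankDeficiencyError(FitError):
    def __init__(self, model_name: str, columns: Sequence[str]):
        super().__init__(
            f"design for model {model_name!r} is rank deficient; "
            f"collinear terms: {list(columns)}"
        )
        self.model_name = model_name
        self.columns = tuple(columns)


class UnseenLevelError(FitError):
    def __init__(self, column: str, level):
        super().__init__(f"predictor {column!r} has level {level!r} unseen at fit time")
        self.column = column
        self.level = level


@dataclass(frozen=True)
class ModelSpec:
    target: str
    family: str  # linear | logistic | multinomial
    predictors: tuple[str, ...]
    transform: str = "identity"  # identity | log, applied to a linear target
    saturated: bool = False

    def __post_init__(self):
        if self.family not in ("linear", "logistic", "multinomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


class _Design:
    """Dummy-coded design matrix with an intercept, frozen at fit time."""

    def __init__(self, df: pd.DataFrame, predictors: Sequence[str]):
        self.predictors = tuple(predictors)
        self.drop_idx: tuple[int, ...] = ()
        self.levels: dict[str, tuple] = {}
        for p in self.predictors:
            if _is_categorical(df[p]):
                self.levels[p] = tuple(sorted(df[p].astype(str).unique()))
        self.columns = ["(intercept)"]
        for p in self.predictors:
            if p in self.levels:
                self.columns += [f"{p}[{lv}]" for lv in self.levels[p][1:]]
            else:
                self.columns.append(p)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n)]
        for p in self.predictors:
            if p in self.levels:
                vals = df[p].astype(str).to_numpy()
                known = set(self.levels[p])
                for v in pd.unique(vals):
                    if v not in known:
                        raise UnseenLevelError(p, v)
                for lv in self.levels[p][1:]:
                    cols.append((vals == lv).astype(float))
            else:
                cols.append(df[p].to_numpy(dtype=float))
        X = np.column_stack(cols)
        if self.drop_idx:
            X = np.delete(X, list(self.drop_idx), axis=1)
        return X


def _resolve_rank(X: np.ndarray, design: "_Design", name: str, drop_aliased: bool) -> np.ndarray:
    """Either reject a rank-deficient design or drop its aliased columns.

    Alias dropping mirrors what mainstream regression software does silently
    and is used inside bootstrap replicates, where resampling can freeze a
    rare transition and duplicate a dummy column exactly.
    """
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return X
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    drop = sorted(int(i) for i in piv[rank:])
    if not drop_aliased:
        raise RankDeficiencyError(name, [design.columns[i] for i in drop])
    design.drop_idx = tuple(drop)
    design.columns = [c for i, c in enumerate(design.columns) if i not in set(drop)]
    return np.delete(X, drop, axis=1)


@dataclass
class LinearModel:
    """OLS fit with residual SD; supports a log transform of the target."""

    name: str
    design: _Design
    coef: np.ndarray
    coef_se: np.ndarray
    resid_sd: float
    n: int
    transform: str
    target_range: tuple[float, float]  # observed target range, natural scale

    @classmethod
    def fit(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        name: str | None = None,
        drop_aliased: bool = False,
    ) -> "LinearModel":
        name = name or spec.target
        y = df[spec.target].to_numpy(dtype=float)
        if spec.transform == "log":
            if np.any(y <= 0):
                raise FitError(f"model {name!r}: log transform needs positive target")
            y_fit = np.log(y)
        else:
            y_fit = y
        design = _Design(df, spec.predictors)
        X = _resolve_rank(design.matrix(df), design, name, drop_aliased)
        coef, _, _, _ = np.linalg.lstsq(X, y_fit, rcond=None)
        resid = y_fit - X @ coef
        dof = max(len(y_fit) - X.shape[1], 1)
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
        return cls(
            name=name,
            design=design,
            coef=coef,
            coef_se=se,
            resid_sd=float(np.sqrt(sigma2)),
            n=len(y_fit),
            transform=spec.transform,
            target_range=(float(np.min(y)), float(np.max(y))),
        )

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.design.matrix(df) @ self.coef

    def predict_mean(self, df: pd.DataFrame) -> np.ndarray:
        """Conditional mean on the natural scale (identity transform only).

        For log-transformed targets this returns the median
        (exp of the linear predictor), which is what sampling centres on.
        """
        lp = self.linear_predictor(df)
        if self.transform == "log":
            return np.exp(lp)
        return lp

    def sample(self, df: pd.DataFrame, rng: np.random.Generator, truncate: bool = True) -> np.ndarray:
        lp = self.linear_predictor(df)
        draw = lp + rng.normal(0.0, self.resid_sd, size=len(df))
        if self.transform == "log":
            draw = np.exp(draw)
        if truncate:
            draw = np.clip(draw, *self.target_range)
        return draw

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.design.columns, "coef": self.coef, "se": self.coef_se}
        )


@dataclass
class LogisticModel:
    name: str
    design: _Design
    coef: np.ndarray
    n: int

    @classmethod
    def fit(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        name: str | None = None,
        drop_aliased: bool = False,
    ) -> "LogisticModel":
        name = name or spec.target
        y = df[spec.target].to_numpy(dtype=float)
        design = _Design(df, spec.predictors)
        X = _resolve_rank(design.matrix(df), design, name, drop_aliased)
        # IRLS copes with the near-deterministic cells (e.g. sticky disease
        # status) that make Newton on the Logit likelihood bail out
        coef = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
                if getattr(res, "converged", False) and np.all(np.isfinite(res.params)):
                    coef = np.asarray(res.params)
            except Exception:
                pass
        if coef is None:
            # separation (common in small bootstrap resamples of rare,
            # sticky events): cap the diverging terms with a light ridge
            from sklearn.linear_model import LogisticRegression

            scale = X[:, 1:].std(axis=0)
            scale[scale == 0] = 1.0
            lr = LogisticRegression(C=1e3, solver="lbfgs", max_iter=5000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    lr.fit(X[:, 1:] / scale, y.astype(int))
                except Exception as exc:
                    raise ConvergenceError(name, str(exc)) from exc
            if not np.all(np.isfinite(lr.coef_)):
                raise ConvergenceError(name)
            coef = np.concatenate([lr.intercept_, lr.coef_[0] / scale])
        return cls(name=name, design=design, coef=coef, n=len(y))

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        lp = self.design.matrix(df) @ self.coef
        return expit(lp)

    def sample(self, df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        return (rng.random(len(df)) < self.predict_proba(df)).astype(int)


@dataclass
class MultinomialModel:
    name: str
    design: _Design
    levels: tuple[str, ...]
    coef: np.ndarray  # (p, K-1)
    n: int

    @classmethod
    def fit(
        cls,
        df: pd.DataFrame,
        spec: ModelSpec,
        name: str | None = None,
        drop_aliased: bool = False,
    ) -> "MultinomialModel":
        name = name or spec.target
        levels = tuple(sorted(df[spec.target].astype(str).unique()))
        codes = pd.Categorical(df[spec.target].astype(str), categories=levels).codes
        design = _Design(df, spec.predictors)
        X = _resolve_rank(design.matrix(df), design, name, drop_aliased)
        coef = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MNLogit(codes, X).fit(disp=0, maxiter=200, method="newton")
                if res.mle_retvals.get("converged", False) and np.all(np.isfinite(res.params)):
                    coef = np.asarray(res.params)
            except Exception:
                pass
        if coef is None:
            # quasi-separation (near-deterministic transition cells): fall
            # back to a barely-ridged multinomial fit, which caps the
            # diverging coefficients without materially moving the others
            from sklearn.linear_model import LogisticRegression

            scale = X[:, 1:].std(axis=0)
            scale[scale == 0] = 1.0
            lr = LogisticRegression(C=1e3, solver="lbfgs", max_iter=5000)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    lr.fit(X[:, 1:] / scale, codes)  # sklearn supplies its own intercept
                except Exception as exc:
                    raise ConvergenceError(name, str(exc)) from exc
            if not np.all(np.isfinite(lr.coef_)):
                raise ConvergenceError(name)
            # rebuild baseline-relative coefficients in MNLogit layout (p, K-1)
            full = np.column_stack([lr.intercept_, lr.coef_ / scale])  # (K, p)
            if full.shape[0] == 1:  # binary edge case: sklearn gives 1-vs-0 row
                full = np.vstack([np.zeros_like(full[0]), full[0]])
            coef = (full - full[0]).T[:, 1:]
        return cls(
            name=name, design=design, levels=levels, coef=coef, n=len(codes)
        )

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        X = self.design.matrix(df)
        eta = np.column_stack([np.zeros(len(df)), X @ self.coef])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def sample(self, df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        p = self.predict_proba(df)
        cum = np.cumsum(p, axis=1)
        u = rng.random(len(df))[:, None]
        idx = (u > cum).sum(axis=1)
        return np.asarray(self.levels)[idx]


@dataclass
class SaturatedModel:
    """Stratum means over fully discrete predictors (exact lookup table).

    For a binary target this is the saturated logistic model: the fitted
    probability in each stratum equals the empirical proportion.
    """

    name: str
    predictors: tuple[str, ...]
    means: dict[tuple, float]
    counts: dict[tuple, int]
    resid_sd: float
    n: int
    transform: str = "identity"
    target_range: tuple[float, float] = (-np.inf, np.inf)

    @classmethod
    def fit(cls, df: pd.DataFrame, spec: ModelSpec, name: str | None = None) -> "SaturatedModel":
        name = name or spec.target
        y = df[spec.target].to_numpy(dtype=float)
        keys = list(map(tuple, df[list(spec.predictors)].to_numpy()))
        grouped: dict[tuple, list[float]] = {}
        for k, v in zip(keys, y):
            grouped.setdefault(k, []).append(v)
        means = {k: float(np.mean(v)) for k, v in grouped.items()}
        sq = sum(
            float(np.sum((np.asarray(v) - means[k]) ** 2)) for k, v in grouped.items()
        )
        dof = max(len(y) - len(means), 1)
        return cls(
            name=name,
            predictors=tuple(spec.predictors),
            means=means,
            counts={k: len(v) for k, v in grouped.items()},
            resid_sd=float(np.sqrt(sq / dof)),
            n=len(y),
            target_range=(float(np.min(y)), float(np.max(y))),
        )

    def predict_mean(self, df: pd.DataFrame) -> np.ndarray:
        keys = map(tuple, df[list(self.predictors)].to_numpy())
        out = np.empty(len(df))
        for i, k in enumerate(keys):
            if k not in self.means:
                raise UnseenLevelError("x".join(self.predictors), k)
            out[i] = self.means[k]
        return out

    def sample(self, df: pd.DataFrame, rng: np.random.Generator, truncate: bool = True) -> np.ndarray:
        return self.predict_mean(df) + rng.normal(0.0, self.resid_sd, size=len(df))


@dataclass
class ConstantProbModel:
    """Fallback for degenerate binary targets (e.g. no deaths observed)."""

    name: str
    p: float
    n: int

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return np.full(len(df), self.p)

    def sample(self, df: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
        return (rng.random(len(df)) < self.p).astype(int)


@dataclass(frozen=True)
class ModelSpecSet:
    """All model specifications the estimator needs, in simulation order."""

    covariate: tuple[ModelSpec, ...]
    y1: tuple[ModelSpec, ...]
    exposure: ModelSpec
    outcome: tuple[ModelSpec, ...]
    censoring: tuple[ModelSpec, ...]

    def all_specs(self) -> tuple[ModelSpec, ...]:
        return self.covariate + self.y1 + (self.exposure,) + self.outcome + self.censoring

    def to_dict(self) -> dict:
        def enc(ms: ModelSpec) -> dict:
            return {
                "target": ms.target,
                "family": ms.family,
                "predictors": list(ms.predictors),
                "transform": ms.transform,
                "saturated": ms.saturated,
            }

        return {
            "covariate": [enc(m) for m in self.covariate],
            "y1": [enc(m) for m in self.y1],
            "exposure": enc(self.exposure),
            "outcome": [enc(m) for m in self.outcome],
            "censoring": [enc(m) for m in self.censoring],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpecSet":
        def dec(m: Mapping) -> ModelSpec:
            return ModelSpec(
                target=m["target"],
                family=m["family"],
                predictors=tuple(m["predictors"]),
                transform=m.get("transform", "identity"),
                saturated=bool(m.get("saturated", False)),
            )

        return cls(
            covariate=tuple(dec(m) for m in d["covariate"]),
            y1=tuple(dec(m) for m in d["y1"]),
            exposure=dec(d["exposure"]),
            outcome=tuple(dec(m) for m in d["outcome"]),
            censoring=tuple(dec(m) for m in d["censoring"]),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpecSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_model_specs(schema: CovariateSchema) -> ModelSpecSet:
    """Main-effects specifications over the full adjustment history.

    Every model conditions on the complete pre-baseline block (covariates,
    log pre-baseline intake, pre-baseline outcomes); later models add the
    baseline quantities that temporally precede their target.
    """
    l0_block = [f"{c}_0" for c in schema.covariate_names]
    l0_block += [f"log_{EXPOSURE}_0"]
    l0_block += [f"{y}_0" for y in schema.outcomes]
    # time-fixed covariates are identical at both visits; including both
    # copies would make the design exactly collinear
    l1_cov = [f"{c.name}_1" for c in schema.time_varying()]
    y1_cols = [f"{y}_1" for y in schema.outcomes]

    fam = {"continuous": "linear", "binary": "logistic", "categorical": "multinomial"}
    covariate_specs = []
    prior: list[str] = []
    for cov in schema.time_varying():
        covariate_specs.append(
            ModelSpec(
                target=f"{cov.name}_1",
                family=fam[cov.kind],
                predictors=tuple(l0_block + prior),
            )
        )
        prior.append(f"{cov.name}_1")

    y1_specs = tuple(
        ModelSpec(target=f"{y}_1", family="linear", predictors=tuple(l0_block + l1_cov))
        for y in schema.outcomes
    )
    exposure_spec = ModelSpec(
        target=f"{EXPOSURE}_1",
        family="linear",
        transform="log",
        predictors=tuple(l0_block + l1_cov + y1_cols),
    )
    outcome_specs = tuple(
        ModelSpec(
            target=f"{y}_2",
            family="linear",
            predictors=tuple([f"{EXPOSURE}_1"] + l0_block + l1_cov + y1_cols),
        )
        for y in schema.outcomes
    )
    censoring_specs = tuple(
        ModelSpec(
            target=f"censor_{reason}",
            family="logistic",
            predictors=tuple(l1_cov + [f"{EXPOSURE}_1"] + y1_cols),
        )
        for reason in ("death", "ltfu")
    )
    return ModelSpecSet(
        covariate=tuple(covariate_specs),
        y1=y1_specs,
        exposure=exposure_spec,
        outcome=outcome_specs,
        censoring=censoring_specs,
    )


@dataclass
class FittedModelSet:
    """All fitted models plus the data context the simulator needs."""

    schema: CovariateSchema
    specs: ModelSpecSet
    covariate_models: dict[str, object]  # keyed by covariate name
    y1_models: dict[str, LinearModel]
    exposure_model: LinearModel
    outcome_models: dict[str, object]
    censoring_models: dict[str, LogisticModel]
    source: pd.DataFrame = field(repr=False)
    diagnostics: dict[str, dict] = field(default_factory=dict)

    @property
    def sim_order(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.schema.time_varying())


def _fit_one(df: pd.DataFrame, spec: ModelSpec, drop_aliased: bool = False):
    if spec.saturated:
        return SaturatedModel.fit(df, spec)
    if spec.family == "linear":
        return LinearModel.fit(df, spec, drop_aliased=drop_aliased)
    if spec.family == "logistic":
        return LogisticModel.fit(df, spec, drop_aliased=drop_aliased)
    return MultinomialModel.fit(df, spec, drop_aliased=drop_aliased)


def fit_all(
    cohort: Cohort, specs: ModelSpecSet | None = None, drop_aliased: bool = False
) -> FittedModelSet:
    """Fit every model the g-formula needs.

    Outcome models use uncensored records only; covariate, exposure and
    censoring models use the full eligible cohort.  Deterministic given the
    cohort and specifications.  ``drop_aliased`` tolerates exactly collinear
    designs by dropping aliased columns (used inside bootstrap replicates);
    the default is to reject them.
    """
    schema = cohort.schema
    if specs is None:
        specs = default_model_specs(schema)
    df = add_derived(cohort.df)
    for reason in ("death", "ltfu"):
        df[f"censor_{reason}"] = (df[CENSOR_COL] == reason).astype(int)
    uncensored = df[df[CENSOR_COL] == "none"]

    diagnostics: dict[str, dict] = {}

    def record(model) -> object:
        diagnostics[model.name] = {
            "n": model.n,
            "converged": True,
            "resid_sd": getattr(model, "resid_sd", None),
        }
        return model

    covariate_models = {}
    for ms in specs.covariate:
        name = ms.target[: -len("_1")]
        covariate_models[name] = record(_fit_one(df, ms, drop_aliased))
    y1_models = {
        ms.target[: -len("_1")]: record(_fit_one(df, ms, drop_aliased)) for ms in specs.y1
    }
    exposure_model = record(_fit_one(df, specs.exposure, drop_aliased))
    outcome_models = {
        ms.target[: -len("_2")]: record(_fit_one(uncensored, ms, drop_aliased))
        for ms in specs.outcome
    }
    censoring_models = {}
    for ms in specs.censoring:
        reason = ms.target[len("censor_"):]
        y = df[ms.target]
        if y.nunique() < 2:
            model = ConstantProbModel(name=ms.target, p=float(y.mean()), n=len(y))
            diagnostics[model.name] = {"n": model.n, "converged": True, "resid_sd": None}
            censoring_models[reason] = model
        else:
            censoring_models[reason] = record(_fit_one(df, ms, drop_aliased))
    return FittedModelSet(
        schema=schema,
        specs=specs,
        covariate_models=covariate_models,
        y1_models=y1_models,
        exposure_model=exposure_model,
        outcome_models=outcome_models,
        censoring_models=censoring_models,
        source=df,
        diagnostics=diagnostics,
    )


def predict_outcome(models: FittedModelSet, a, history: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome conditional means at exposure ``a`` given a history frame.

    ``a`` may be a scalar or a vector aligned with ``history``.  Pure
    function of its inputs.
    """
    df = history.copy()
    df[f"{EXPOSURE}_1"] = a
    out = {}
    for name, model in models.outcome_models.items():
        out[name] = model.predict_mean(df)
    return pd.DataFrame(out, index=history.index)
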