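"""Cohort data model, eligibility filtering, and derived-exposure computation.

Column conventions
------------------
A cohort is a tidy table with one row per participant:

* ``id`` — unique participant identifier.
* ``<cov>_0`` / ``<cov>_1`` — covariate values at enrollment (time 0) and at
  the analytic baseline (time 1, the 3-year visit).  Time-fixed covariates
  carry identical values in both columns.
* ``protein_0`` / ``protein_1`` — protein intake in g per kg body weight per
  day at each visit; ``protein_1`` is the exposure.
* ``<outcome>_0`` / ``<outcome>_1`` / ``<outcome>_2`` — body-composition
  outcomes at times 0, 1 and 2 (end of follow-up, the 6-year visit).  The
  time-0/1 values enter analyses as covariates.
* ``energy_1`` — total energy intake (kcal/day) at baseline, used only for
  the plausibility filter.
* ``censor`` — one of ``none``, ``death``, ``ltfu``; end-of-follow-up
  outcomes are present iff ``censor == "none"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ID_COL = "id"
EXPOSURE = "protein"
ENERGY_COL = "energy_1"
CENSOR_COL = "censor"
CENSOR_LEVELS = ("none", "death", "ltfu")

#: energy plausibility window (kcal/day); boundary values are retained
ENERGY_MIN = 500.0
ENERGY_MAX = 5000.0

#: descriptive intake categories (g/kg/day); right-closed above 0.5
PROTEIN_CATEGORIES = ("<0.5", "0.5-0.8", ">0.8-1.0", ">1.0-1.2", ">1.2-1.5", ">1.5")
_CATEGORY_EDGES = (0.5, 0.8, 1.0, 1.2, 1.5)


class CohortError(ValueError):
    """Raised when a cohort violates its declared schema or is unusable."""


@dataclass(frozen=True)
class CovariateDef:
    """Declared type of a single confounder.

    ``kind`` is one of ``continuous``, ``binary``, ``categorical``; ``levels``
    is required for categorical covariates; ``time_varying`` covariates get a
    conditional model at time 1, fixed ones are carried forward unchanged.
    """

    name: str
    kind: str
    levels: tuple[str, ...] | None = None
    ordered: bool = False
    time_varying: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise CohortError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and not self.levels:
            raise CohortError(f"categorical covariate {self.name!r} needs levels")


@dataclass(frozen=True)
class CovariateSchema:
    """Covariate and outcome declarations shared by every pipeline stage."""

    covariates: tuple[CovariateDef, ...]
    outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise CohortError("duplicate covariate names in schema")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def covariate(self, name: str) -> CovariateDef:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def time_varying(self) -> tuple[CovariateDef, ...]:
        return tuple(c for c in self.covariates if c.time_varying)

    def columns(self) -> list[str]:
        cols = [ID_COL]
        for c in self.covariates:
            cols += [f"{c.name}_0", f"{c.name}_1"]
        cols += [f"{EXPOSURE}_0", f"{EXPOSURE}_1", ENERGY_COL]
        for y in self.outcomes:
            cols += [f"{y}_0", f"{y}_1", f"{y}_2"]
        cols.append(CENSOR_COL)
        return cols

    def to_dict(self) -> dict:
        return {
            "covariates": [dataclasses.asdict(c) for c in self.covariates],
            "outcomes": list(self.outcomes),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSchema":
        covs = tuple(
            CovariateDef(
                name=c["name"],
                kind=c["kind"],
                levels=tuple(c["levels"]) if c.get("levels") else None,
                ordered=bool(c.get("ordered", False)),
                time_varying=bool(c.get("time_varying", True)),
            )
            for c in d["covariates"]
        )
        return cls(covariates=covs, outcomes=tuple(d["outcomes"]))

    @classmethod
    def from_yaml(cls, path) -> "CovariateSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class Cohort:
    """A participant table plus the schema it conforms to."""

    df: pd.DataFrame
    schema: CovariateSchema

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        missing = [c for c in self.schema.columns() if c not in self.df.columns]
        if missing:
            raise CohortError(f"cohort missing columns: {missing}")
        if self.df[ID_COL].duplicated().any():
            raise CohortError("duplicate participant ids")
        bad_censor = set(self.df[CENSOR_COL].dropna()) - set(CENSOR_LEVELS)
        if bad_censor:
            raise CohortError(f"unknown censoring codes: {sorted(bad_censor)}")
        for cov in self.schema.covariates:
            if cov.kind == "categorical":
                for t in (0, 1):
                    observed = set(self.df[f"{cov.name}_{t}"].dropna())
                    extra = observed - set(cov.levels)
                    if extra:
                        raise CohortError(
                            f"{cov.name}_{t} has undeclared levels {sorted(extra)}"
                        )
        # outcomes observed iff uncensored
        uncensored = self.df[CENSOR_COL] == "none"
        for y in self.schema.outcomes:
            col = self.df[f"{y}_2"]
            if col[uncensored].isna().any():
                raise CohortError(f"{y}_2 missing for uncensored participants")
            if col[~uncensored].notna().any():
                raise CohortError(f"{y}_2 present for censored participants")

    def uncensored(self) -> pd.DataFrame:
        return self.df[self.df[CENSOR_COL] == "none"]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: CovariateSchema) -> "Cohort":
        df = pd.read_csv(path)
        for cov in schema.covariates:
            if cov.kind != "continuous":
                for t in (0, 1):
                    df[f"{cov.name}_{t}"] = df[f"{cov.name}_{t}"].astype(str)
        return cls(df=df, schema=schema)


def compute_protein_per_kg(grams_per_day, weight_kg):
    """Protein intake normalised to body weight: g/day divided by kg.

    Applied per visit with that visit's weight.  Accepts scalars or arrays;
    any non-positive weight is rejected.
    """
    g = np.asarray(grams_per_day, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(g < 0):
        raise ValueError("negative protein intake")
    if np.any(w <= 0):
        raise ValueError("non-positive body weight")
    out = g / w
    if out.ndim == 0:
        return float(out)
    return out


def categorize_protein(a):
    """Map g/kg/day values to the descriptive intake categories.

    Intervals above 0.5 are left-open/right-closed, so 0.8 falls in
    ``0.5-0.8``.  Descriptive use only; the estimator works on the
    continuous scale.
    """
    arr = np.asarray(a, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("protein intake must be positive")
    idx = np.searchsorted(_CATEGORY_EDGES, arr, side="left")
    # 0.5 itself belongs to the first named interval, not "<0.5"
    idx = np.where(arr == _CATEGORY_EDGES[0], 1, idx)
    labels = np.take(PROTEIN_CATEGORIES, idx)
    if arr.ndim == 0:
        return str(labels)
    return labels


@dataclass
class ExclusionLog:
    """Counts of records removed by eligibility filtering, by reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": list(self.counts), "n_excluded": list(self.counts.values())}
        )


def apply_eligibility(cohort: Cohort) -> tuple[Cohort, ExclusionLog]:
    """Apply the emulated trial's eligibility criteria.

    Removes records with implausible baseline energy intake (< 500 or
    > 5000 kcal/day, boundaries retained), records missing protein intake at
    either visit, and records missing any modelled covariate
    (complete-case).  Idempotent.
    """
    df = cohort.df
    log = ExclusionLog()
    keep = pd.Series(True, index=df.index)

    implausible = (df[ENERGY_COL] < ENERGY_MIN) | (df[ENERGY_COL] > ENERGY_MAX)
    implausible |= df[ENERGY_COL].isna()
    log.add("implausible_energy", int(implausible[keep].sum()))
    keep &= ~implausible

    no_protein = df[f"{EXPOSURE}_0"].isna() | df[f"{EXPOSURE}_1"].isna()
    log.add("incomplete_protein", int(no_protein[keep].sum()))
    keep &= ~no_protein

    cov_cols = [f"{c.name}_{t}" for c in cohort.schema.covariates for t in (0, 1)]
    base_outcome_cols = [f"{y}_{t}" for y in cohort.schema.outcomes for t in (0, 1)]
    incomplete = df[cov_cols + base_outcome_cols].isna().any(axis=1)
    log.add("incomplete_covariates", int(incomplete[keep].sum()))
    keep &= ~incomplete

    out = df[keep].reset_index(drop=True)
    if out.empty:
        raise CohortError("no records remain after eligibility filtering")
    return Cohort(df=out, schema=cohort.schema), log


def censoring_summary(cohort: Cohort) -> dict[str, int]:
    """Counts by censoring reason; totals to the cohort size."""
    counts = {level: 0 for level in CENSOR_LEVELS}
    for level, n in cohort.df[CENSOR_COL].value_counts().items():
        counts[str(level)] = int(n)
    return counts


def derive_exposure_columns(
    df: pd.DataFrame,
    grams_cols: Sequence[str] = ("protein_g_0", "protein_g_1"),
    weight_cols: Sequence[str] = ("weight_0", "weight_1"),
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Compute ``protein_0``/``protein_1`` from g/day and visit weights.

    Rows with a non-positive weight at either visit cannot have a
    well-defined exposure and are dropped with a logged reason.
    """
    log = ExclusionLog()
    out = df.copy()
    bad = pd.Series(False, index=out.index)
    for wcol in weight_cols:
        bad |= ~(out[wcol] > 0)
    log.add("nonpositive_weight", int(bad.sum()))
    out = out[~bad].reset_index(drop=True)
    for t, (gcol, wcol) in enumerate(zip(grams_cols, weight_cols)):
        out[f"{EXPOSURE}_{t}"] = compute_protein_per_kg(out[gcol], out[wcol])
    return out, log


def add_derived(df: pd.DataFrame) -> pd.DataFrame:
    """Attach modelling helper columns (log protein intake at each visit)."""
    out = df.copy()
    for t in (0, 1):
        col = f"{EXPOSURE}_{t}"
        if col in out.columns:
            out[f"log_{col}"] = np.log(out[col].astype(float))
    return out
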