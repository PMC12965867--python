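"""Intervention strategies: the natural course and threshold rules.

A threshold rule ``t`` lifts anyone below ``t`` g/kg/day up to exactly
``t`` and leaves already-adherent intakes unchanged (minimal-change
operationalization of "adhere to >= t").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: thresholds studied in the emulated trial (g/kg/day)
STUDY_THRESHOLDS = (0.8, 1.0, 1.2, 1.5)


@dataclass(frozen=True)
class InterventionStrategy:
    kind: str  # natural_course | threshold
    t: float | None = None

    def __post_init__(self):
        if self.kind not in ("natural_course", "threshold"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "threshold":
            if self.t is None or not self.t > 0:
                raise ValueError("threshold strategies need t > 0")
        elif self.t is not None:
            raise ValueError("natural course takes no threshold")

    @classmethod
    def natural(cls) -> "InterventionStrategy":
        return cls(kind="natural_course")

    @classmethod
    def threshold(cls, t: float) -> "InterventionStrategy":
        return cls(kind="threshold", t=float(t))

    @classmethod
    def parse(cls, text: str) -> "InterventionStrategy":
        s = str(text).strip().lower()
        if s in ("nc", "natural", "natural_course", "none"):
            return cls.natural()
        return cls.threshold(float(s))

    @property
    def label(self) -> str:
        if self.kind == "natural_course":
            return "natural_course"
        return f"threshold_{self.t:g}"

    def __str__(self) -> str:
        return self.label


def study_grid() -> tuple[InterventionStrategy, ...]:
    """Natural course plus the four studied thresholds, reference first."""
    return (InterventionStrategy.natural(),) + tuple(
        InterventionStrategy.threshold(t) for t in STUDY_THRESHOLDS
    )


def apply_intervention(a_natural, strategy: InterventionStrategy):
    """Map natural intakes to intervened intakes (max(a, t) for thresholds)."""
    a = np.asarray(a_natural, dtype=float)
    if strategy.kind == "natural_course":
        out = a
    else:
        out = np.maximum(a, strategy.t)
    if out.ndim == 0:
        return float(out)
    return out


def parse_strategies(spec: str) -> tuple[InterventionStrategy, ...]:
    """Parse a comma list like ``"nc,0.8,1.0,1.2,1.5"``."""
    return tuple(InterventionStrategy.parse(tok) for tok in spec.split(","))
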