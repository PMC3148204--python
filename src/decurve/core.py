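"""Net-benefit algebra for decision curve analysis.

A treatment policy applied at threshold probability ``p_t`` partitions a
sample into four joint proportions: true positives *a*, false positives *b*,
false negatives *c* and true negatives *d* (a + b + c + d = 1).  Writing the
loss/profit ratio as odds of the threshold, L/P = p_t/(1 - p_t), the three
net-benefit functionals are

    u_treated   = a - b * p_t / (1 - p_t)
    u_untreated = d - c * (1 - p_t) / p_t
    u_overall   = u_treated + u_untreated

u_treated is the net benefit per subject among the treated, normalised by the
profit P of treating a diseased subject; u_untreated normalises by the loss L;
u_overall is their sum, invariant to recoding of the outcome, with maximum 1
attained only by a perfect prediction model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "DCAError",
    "InvalidInputError",
    "DomainError",
    "ConfigurationError",
    "BenefitKind",
    "ClassificationProportions",
    "PredictionSet",
    "AbsoluteBenefit",
    "classify",
    "net_benefit",
    "absolute_benefit",
    "reference_curve",
]

#: tolerance for pure-arithmetic identities (no iterative fitting involved)
ARITHMETIC_TOL = 1e-12


class DCAError(Exception):
    """Base class for all decurve errors."""


class InvalidInputError(DCAError, ValueError):
    """Raised for structurally invalid inputs (empty data, bad labels...)."""


class DomainError(DCAError, ValueError):
    """Raised when a numeric argument lies outside its mathematical domain."""


class ConfigurationError(DCAError, ValueError):
    """Raised for invalid run or generator configuration."""


class BenefitKind(str, Enum):
    """Which subpopulation the net benefit is computed for."""

    TREATED = "treated"
    UNTREATED = "untreated"
    OVERALL = "overall"

    @classmethod
    def coerce(cls, kind: "BenefitKind | str") -> "BenefitKind":
        if isinstance(kind, BenefitKind):
            return kind
        try:
            return cls(str(kind).lower())
        except ValueError:
            raise InvalidInputError(
                f"unknown benefit kind {kind!r}; expected one of "
                f"{[k.value for k in cls]}"
            ) from None


@dataclass(frozen=True)
class ClassificationProportions:
    """Joint proportions of the four classification outcomes at one threshold.

    Attributes
    ----------
    a, b, c, d
        Proportions of true positive, false positive, false negative and
        true negative results. They are nonnegative and sum to 1.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"proportion {name}={v} must be finite and >= 0")
        total = self.a + self.b + self.c + self.d
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"proportions must sum to 1, got {total!r}")

    @property
    def prevalence(self) -> float:
        """Disease prevalence pi = a + c."""
        return self.a + self.c

    @property
    def sensitivity(self) -> float:
        """a / (a + c); NaN if there are no diseased subjects."""
        denom = self.a + self.c
        return self.a / denom if denom > 0 else math.nan

    @property
    def specificity(self) -> float:
        """d / (d + b); NaN if there are no disease-free subjects."""
        denom = self.d + self.b
        return self.d / denom if denom > 0 else math.nan


@dataclass(frozen=True)
class PredictionSet:
    """Per-subject binary outcomes paired with predicted probabilities.

    ``outcomes[i]`` is 1 if subject *i* has (or develops) the disease and 0
    otherwise; ``probabilities[i]`` is the model's predicted probability of
    disease, in [0, 1].  ``metadata`` is free-form (e.g. fitted coefficients).
    """

    outcomes: np.ndarray
    probabilities: np.ndarray
    label: str = "model"
    metadata: dict | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.outcomes)
        p = np.asarray(self.probabilities, dtype=float)
        if y.ndim != 1 or p.ndim != 1:
            raise InvalidInputError("outcomes and probabilities must be 1-D")
        if len(y) != len(p):
            raise InvalidInputError(
                f"length mismatch: {len(y)} outcomes vs {len(p)} probabilities"
            )
        if len(y) == 0:
            raise InvalidInputError("prediction set must contain at least one subject")
        if not np.isin(y, (0, 1)).all():
            bad = np.unique(y[~np.isin(y, (0, 1))])
            raise InvalidInputError(f"outcomes must be 0/1; found {bad.tolist()}")
        if not (np.isfinite(p).all() and (p >= 0).all() and (p <= 1).all()):
            raise InvalidInputError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "outcomes", y.astype(np.int8))
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return len(self.outcomes)

    @property
    def prevalence(self) -> float:
        """Observed disease prevalence of the sample."""
        return float(self.outcomes.mean())


@dataclass(frozen=True)
class AbsoluteBenefit:
    """Un-normalised benefits at given utilities per correct decision.

    P is the profit of treating a diseased subject, L the loss of treating a
    disease-free one (same utility units).  U_treated = aP - bL is the benefit
    among the treated, U_untreated = dL - cP among the untreated.  The implied
    indifference threshold is L / (L + P).
    """

    profit_per_case: float
    loss_per_noncase: float
    u_treated: float
    u_untreated: float

    @property
    def implied_threshold(self) -> float:
        return self.loss_per_noncase / (self.loss_per_noncase + self.profit_per_case)


def _check_threshold(p_t: float) -> float:
    p_t = float(p_t)
    if not (0.0 < p_t < 1.0):
        raise DomainError(f"threshold probability must lie strictly in (0, 1), got {p_t}")
    return p_t


def classify(preds: PredictionSet, p_t: float) -> ClassificationProportions:
    """Classification proportions induced by treating subjects with p_i > p_t.

    The treatment rule is a strict inequality: subjects whose predicted
    probability equals the threshold exactly are *not* treated.

    Parameters
    ----------
    preds
        Outcomes and predicted probabilities.
    p_t
        Threshold probability, strictly inside (0, 1).

    Returns
    -------
    ClassificationProportions
        (a, b, c, d) as exact count ratios over n.
    """
    p_t = _check_threshold(p_t)
    y = preds.outcomes
    treated = preds.probabilities > p_t
    n = len(preds)
    a = int(np.count_nonzero(treated & (y == 1))) / n
    b = int(np.count_nonzero(treated & (y == 0))) / n
    c = int(np.count_nonzero(~treated & (y == 1))) / n
    d = int(np.count_nonzero(~treated & (y == 0))) / n
    return ClassificationProportions(a, b, c, d)


def net_benefit(
    props: ClassificationProportions,
    p_t: float,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> float:
    """Evaluate one of the three net-benefit functionals at threshold p_t."""
    p_t = _check_threshold(p_t)
    kind = BenefitKind.coerce(kind)
    w_treated = p_t / (1.0 - p_t)      # = L/P
    w_untreated = (1.0 - p_t) / p_t    # = P/L
    treated = props.a - props.b * w_treated
    untreated = props.d - props.c * w_untreated
    if kind is BenefitKind.TREATED:
        return treated
    if kind is BenefitKind.UNTREATED:
        return untreated
    # the sum form keeps conservation (overall = treated + untreated) exact
    # in floating point, not just in real arithmetic
    return treated + untreated


def absolute_benefit(
    props: ClassificationProportions, profit_per_case: float, loss_per_noncase: float
) -> AbsoluteBenefit:
    """Benefits in raw utility units: U_treated = aP - bL, U_untreated = dL - cP.

    For two models evaluated on the same data at the same threshold, the
    difference in U_treated equals the difference in U_untreated, since both
    equal (a1 - a2)(P + L) for classifications sharing a + c = pi.
    """
    P, L = float(profit_per_case), float(loss_per_noncase)
    if P <= 0 or L <= 0:
        raise DomainError(f"profit and loss must be positive, got P={P}, L={L}")
    return AbsoluteBenefit(
        profit_per_case=P,
        loss_per_noncase=L,
        u_treated=props.a * P - props.b * L,
        u_untreated=props.d * L - props.c * P,
    )


_REFERENCE_STRATEGIES = ("treat_none", "treat_all", "perfect")


def reference_curve(
    prevalence: float,
    grid: "Sequence[float] | ThresholdGrid",  # noqa: F821 - forward ref to curves
    strategy: str,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> "DecisionCurve":  # noqa: F821
    """Decision curve of a degenerate reference strategy.

    ``treat_none`` assigns p_i = 0 to everyone, ``treat_all`` p_i = 1, and
    ``perfect`` p_i = y_i.  Closed forms at prevalence pi:

    =============  ==========================  ==========================
    strategy       treated                     untreated
    =============  ==========================  ==========================
    treat_none     0                           (1-pi) - pi (1-p_t)/p_t
    treat_all      pi - (1-pi) p_t/(1-p_t)     0
    perfect        pi                          1 - pi
    =============  ==========================  ==========================

    and overall is always the sum of the two.
    """
    from .curves import DecisionCurve, ThresholdGrid  # local import, no cycle at load

    pi = float(prevalence)
    if not (0.0 < pi < 1.0):
        raise DomainError(f"prevalence must lie strictly in (0, 1), got {pi}")
    if strategy not in _REFERENCE_STRATEGIES:
        raise InvalidInputError(
            f"unknown strategy {strategy!r}; expected one of {_REFERENCE_STRATEGIES}"
        )
    kind = BenefitKind.coerce(kind)
    grid = ThresholdGrid.coerce(grid)
    t = grid.values

    def _treated() -> np.ndarray:
        if strategy == "treat_none":
            return np.zeros_like(t)
        if strategy == "treat_all":
            return pi - (1.0 - pi) * t / (1.0 - t)
        return np.full_like(t, pi)

    def _untreated() -> np.ndarray:
        if strategy == "treat_none":
            return (1.0 - pi) - pi * (1.0 - t) / t
        if strategy == "treat_all":
            return np.zeros_like(t)
        return np.full_like(t, 1.0 - pi)

    if kind is BenefitKind.TREATED:
        nb = _treated()
    elif kind is BenefitKind.UNTREATED:
        nb = _untreated()
    else:
        nb = _treated() + _untreated()
    return DecisionCurve(strategy_label=strategy, kind=kind, thresholds=t, net_benefits=nb)
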