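"""ROC analysis and its connection to net benefit.

Accuracy-driven cutoff selection (the Youden index, sensitivity +
specificity - 1) and utility-driven selection (maximising u_treated at a
personal threshold p_t) pick operating points on the same empirical ROC
curve.  In real arithmetic the utility-optimal point is where the ROC slope
equals [(1 - pi)/pi] [p_t/(1 - p_t)]; empirically the ROC is a step function,
so the optimum is found by exact maximisation over all candidate cutoffs,
with the analytic slope reported as a diagnostic.  At p_t = pi the two
criteria coincide exactly, since u_treated = pi * (sens + spec - 1) there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    ARITHMETIC_TOL,
    BenefitKind,
    ClassificationProportions,
    DomainError,
    InvalidInputError,
    PredictionSet,
    classify,
    net_benefit,
)
from .curves import DecisionCurve, ThresholdGrid

__all__ = [
    "ROCCurve",
    "OperatingPoint",
    "roc_points",
    "youden_cutoff",
    "netbenefit_cutoff",
    "sens_spec_net_benefit",
    "dichotomized_curve",
]


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC operating points, ordered by cutoff descending.

    ``points[k]`` is (1 - specificity, sensitivity) for the classification
    "treat if p_i > cutoffs[k]".  The first cutoff sits above every observed
    probability (point (0, 0)) and the last below every one (point (1, 1));
    sentinel cutoffs may therefore lie outside [0, 1].
    """

    points: np.ndarray  # shape (m, 2): (1 - specificity, sensitivity)
    cutoffs: np.ndarray  # shape (m,)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        cut = np.asarray(self.cutoffs, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) != len(cut):
            raise InvalidInputError("ROC points must be (m, 2) aligned with m cutoffs")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cutoffs", cut)

    def __len__(self) -> int:
        return len(self.cutoffs)


@dataclass(frozen=True)
class OperatingPoint:
    """One ROC operating point with the criterion value that selected it."""

    cutoff: float
    sensitivity: float
    specificity: float
    criterion_value: float
    target_slope: float | None = None  # analytic ROC-slope diagnostic, [(1-pi)/pi][p_t/(1-p_t)]


def _candidate_cutoffs(probabilities: np.ndarray) -> np.ndarray:
    """Cutoffs realising every distinct classification under strict p > cutoff.

    Midpoints between consecutive distinct sorted probabilities, plus one
    sentinel above the maximum (nobody treated) and one below the minimum
    (everybody treated).  Returned in decreasing order, so the induced
    treated sets grow monotonically.
    """
    u = np.unique(probabilities)
    hi = (u[-1] + 1.0) / 2.0 if u[-1] < 1.0 else 1.0  # p > 1 is impossible anyway
    lo = u[0] / 2.0 if u[0] > 0.0 else -0.5
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([hi], mids[::-1], [lo]))


def _sens_spec_at_cutoffs(
    preds: PredictionSet, cutoffs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    p = preds.probabilities
    y = preds.outcomes
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError(
            "both outcome classes must be present for sensitivity/specificity"
        )
    treated = p[None, :] > cutoffs[:, None]  # (m, n)
    tp = (treated & (y == 1)).sum(axis=1)
    fp = (treated & (y == 0)).sum(axis=1)
    return tp / n_pos, 1.0 - fp / n_neg


def roc_points(preds: PredictionSet) -> ROCCurve:
    """Empirical (step-function) ROC curve of a prediction set.

    One operating point per candidate cutoff; the extremes are always the
    trivial points (0, 0) and (1, 1).
    """
    cutoffs = _candidate_cutoffs(preds.probabilities)
    sens, spec = _sens_spec_at_cutoffs(preds, cutoffs)
    points = np.column_stack([1.0 - spec, sens])
    return ROCCurve(points=points, cutoffs=cutoffs)


def _select_best(
    cutoffs: np.ndarray,
    sens: np.ndarray,
    spec: np.ndarray,
    criterion: np.ndarray,
    tol: float = ARITHMETIC_TOL,
) -> int:
    """Index of the maximising cutoff; ties (within tol) go to the highest
    specificity, i.e. the fewest subjects treated."""
    best = criterion.max()
    tied = np.flatnonzero(criterion >= best - tol)
    return int(tied[np.argmax(spec[tied])])


def youden_cutoff(roc: ROCCurve) -> OperatingPoint:
    """Operating point maximising the Youden index, sens + spec - 1.

    Geometrically the highest point above the chance diagonal.
    """
    fpr = roc.points[:, 0]
    sens = roc.points[:, 1]
    spec = 1.0 - fpr
    youden = sens + spec - 1.0
    i = _select_best(roc.cutoffs, sens, spec, youden)
    return OperatingPoint(
        cutoff=float(roc.cutoffs[i]),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        criterion_value=float(youden[i]),
    )


def netbenefit_cutoff(preds: PredictionSet, p_t: float) -> OperatingPoint:
    """Operating point maximising u_treated at a fixed personal threshold p_t.

    Direct maximisation over all candidate cutoffs — the empirical analogue
    of choosing the ROC point whose slope equals
    [(1 - pi)/pi] [p_t/(1 - p_t)]; that analytic slope is returned in
    ``target_slope``.  At p_t = pi this coincides with the Youden-optimal
    cutoff, exactly.
    """
    p_t = float(p_t)
    if not (0.0 < p_t < 1.0):
        raise DomainError(f"threshold probability must lie strictly in (0, 1), got {p_t}")
    cutoffs = _candidate_cutoffs(preds.probabilities)
    sens, spec = _sens_spec_at_cutoffs(preds, cutoffs)
    pi = preds.prevalence
    w = p_t / (1.0 - p_t)
    u_treated = sens * pi - (1.0 - spec) * (1.0 - pi) * w
    i = _select_best(cutoffs, sens, spec, u_treated)
    return OperatingPoint(
        cutoff=float(cutoffs[i]),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
        criterion_value=float(u_treated[i]),
        target_slope=((1.0 - pi) / pi) * w,
    )


def sens_spec_net_benefit(
    sensitivity: float,
    specificity: float,
    prevalence: float,
    p_t: float,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> float:
    """Net benefit expressed through sensitivity, specificity and prevalence.

    Substituting a = sens*pi, b = (1-spec)(1-pi), c = (1-sens)*pi,
    d = spec*(1-pi) into the proportion forms gives

        treated:   sens*pi - (1-spec)(1-pi) p_t/(1-p_t)
        untreated: spec*(1-pi) - (1-sens)*pi (1-p_t)/p_t

    and overall their sum.  This is the form that stays consistent in
    case-control samples once pi is replaced by an externally known
    prevalence.
    """
    sens, spec, pi = float(sensitivity), float(specificity), float(prevalence)
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise DomainError("sensitivity and specificity must lie in [0, 1]")
    if not (0.0 < pi < 1.0):
        raise DomainError(f"prevalence must lie strictly in (0, 1), got {pi}")
    p_t = float(p_t)
    if not (0.0 < p_t < 1.0):
        raise DomainError(f"threshold probability must lie strictly in (0, 1), got {p_t}")
    kind = BenefitKind.coerce(kind)
    treated = sens * pi - (1.0 - spec) * (1.0 - pi) * p_t / (1.0 - p_t)
    untreated = spec * (1.0 - pi) - (1.0 - sens) * pi * (1.0 - p_t) / p_t
    if kind is BenefitKind.TREATED:
        return treated
    if kind is BenefitKind.UNTREATED:
        return untreated
    return treated + untreated


def dichotomized_curve(
    preds: PredictionSet,
    cutoff: float,
    grid: ThresholdGrid | Sequence[float] | None = None,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> DecisionCurve:
    """Decision curve of a model reduced to a binary test by one fixed cutoff.

    The classification (hence sensitivity and specificity) is the same at
    every grid threshold; only the weights vary with p_t, which produces the
    characteristic arc around the cutoff.  At the grid point p_t = cutoff the
    value equals the continuous model's decision curve there, since the
    classifications are identical.
    """
    cutoff = float(cutoff)
    if not (0.0 < cutoff < 1.0):
        raise DomainError(f"cutoff must lie strictly in (0, 1), got {cutoff}")
    grid = ThresholdGrid.coerce(grid)
    kind = BenefitKind.coerce(kind)
    props = classify(preds, cutoff)  # fixed for the whole grid
    nb = np.array([net_benefit(props, p_t, kind) for p_t in grid.values])
    return DecisionCurve(
        strategy_label=f"{preds.label} @ {cutoff:g}",
        kind=kind,
        thresholds=grid.values,
        net_benefits=nb,
    )
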