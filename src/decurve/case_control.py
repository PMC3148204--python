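"""Decision curve analysis for case-control samples.

In a case-control design the sample prevalence pi is fixed by the sampling
(often near 0.5) and does not estimate the population prevalence pi0, so
predicted probabilities from a model fitted on the sample are systematically
miscalibrated.  If pi0 is known from an external source, each probability is
corrected by rescaling its odds with the prevalence-odds ratio:

    odds(p_adj) = odds(p) * [pi0/(1 - pi0)] * [(1 - pi)/pi]

Classifying the adjusted probabilities at p_t yields proportions
a', b', c', d' whose sensitivity a'/(a'+c') and specificity d'/(b'+d')
remain consistent even though the proportions themselves are not; plugging
them, together with pi0, into the sensitivity/specificity form of the net
benefit gives consistent case-control estimators of all three curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BenefitKind, DomainError, InvalidInputError, PredictionSet, classify
from .curves import DecisionCurve, ThresholdGrid
from .roc_link import sens_spec_net_benefit

__all__ = [
    "CaseControlContext",
    "adjust_probabilities",
    "case_control_curve",
    "prevalence_sweep",
]


@dataclass(frozen=True)
class CaseControlContext:
    """Sample (empirical) prevalence paired with the assumed true prevalence."""

    empirical_prevalence: float
    true_prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 < self.empirical_prevalence < 1.0):
            raise DomainError(
                f"empirical prevalence must lie strictly in (0, 1), "
                f"got {self.empirical_prevalence}"
            )
        if not (0.0 < self.true_prevalence < 1.0):
            raise DomainError(
                f"true prevalence must lie strictly in (0, 1), got {self.true_prevalence}"
            )

    @property
    def odds_factor(self) -> float:
        """[pi0/(1-pi0)] * [(1-pi)/pi] — the odds rescaling applied to predictions."""
        pi, pi0 = self.empirical_prevalence, self.true_prevalence
        return (pi0 / (1.0 - pi0)) * ((1.0 - pi) / pi)


def _context_for(preds: PredictionSet, pi0: float) -> CaseControlContext:
    pi = preds.prevalence
    if not (0.0 < pi < 1.0):
        raise InvalidInputError(
            "case-control adjustment needs both outcome classes in the sample"
        )
    return CaseControlContext(empirical_prevalence=pi, true_prevalence=float(pi0))


def adjust_probabilities(preds: PredictionSet, pi0: float) -> PredictionSet:
    """Rescale predicted odds so probabilities target the true prevalence pi0.

    p = 0 and p = 1 are fixed points; the map is strictly increasing, so the
    ranking of subjects (and hence the ROC curve) is unchanged.  When pi0
    equals the sample prevalence the map is the identity.
    """
    ctx = _context_for(preds, pi0)
    f = ctx.odds_factor
    p = preds.probabilities
    adjusted = f * p / (1.0 - p + f * p)
    return PredictionSet(
        outcomes=preds.outcomes,
        probabilities=adjusted,
        label=preds.label,
        metadata=preds.metadata,
    )


def _adjusted_sens_spec(
    adjusted: PredictionSet, p_t: float
) -> tuple[float, float] | None:
    """Sensitivity/specificity of the adjusted classification at p_t, or None
    when one of them is undefined (no cases, or no controls, in the sample)."""
    props = classify(adjusted, p_t)
    n_pos = props.a + props.c
    n_neg = props.b + props.d
    if n_pos == 0.0 or n_neg == 0.0:
        return None
    return props.a / n_pos, props.d / n_neg


def case_control_curve(
    preds: PredictionSet,
    pi0: float,
    grid: ThresholdGrid | Sequence[float] | None = None,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> DecisionCurve:
    """Prevalence-adjusted decision curve for a case-control sample.

    At each grid threshold the adjusted probabilities are classified, their
    sensitivity and specificity computed, and the net benefit evaluated with
    the assumed true prevalence pi0 in place of the sample prevalence.  With
    pi0 equal to the sample prevalence this reproduces the ordinary cohort
    decision curve exactly.  Grid points with undefined sensitivity or
    specificity yield NaN with a warning rather than a fabricated value.
    """
    ctx = _context_for(preds, pi0)
    grid = ThresholdGrid.coerce(grid)
    kind = BenefitKind.coerce(kind)
    adjusted = adjust_probabilities(preds, pi0)
    nb = np.empty(len(grid))
    n_undefined = 0
    for k, p_t in enumerate(grid.values):
        ss = _adjusted_sens_spec(adjusted, p_t)
        if ss is None:
            nb[k] = np.nan
            n_undefined += 1
            continue
        sens, spec = ss
        nb[k] = sens_spec_net_benefit(sens, spec, ctx.true_prevalence, p_t, kind)
    if n_undefined:
        warnings.warn(
            f"{n_undefined} grid point(s) have undefined sensitivity or "
            "specificity; emitted as missing values",
            RuntimeWarning,
            stacklevel=2,
        )
    return DecisionCurve(
        strategy_label=preds.label,
        kind=kind,
        thresholds=grid.values,
        net_benefits=nb,
        pi0=ctx.true_prevalence,
    )


def prevalence_sweep(
    preds: PredictionSet,
    p_t: float,
    pi0_grid: Sequence[float],
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> list[tuple[float, float]]:
    """Net benefit at a fixed threshold as a function of the assumed pi0.

    One (pi0, net benefit) pair per grid value, each computed exactly as in
    :func:`case_control_curve` at the single threshold p_t.  Useful when the
    true prevalence is uncertain: the model comparison can be shown across a
    plausible prevalence range instead of a single assumed value.
    """
    p_t = float(p_t)
    if not (0.0 < p_t < 1.0):
        raise DomainError(f"threshold probability must lie strictly in (0, 1), got {p_t}")
    pi0_values = np.asarray(pi0_grid, dtype=float)
    if pi0_values.ndim != 1 or len(pi0_values) == 0:
        raise InvalidInputError("pi0 grid must be a non-empty 1-D sequence")
    if not (np.diff(pi0_values) > 0).all():
        raise InvalidInputError("pi0 grid must be strictly increasing")
    out: list[tuple[float, float]] = []
    for pi0 in pi0_values:
        curve = case_control_curve(preds, float(pi0), grid=[p_t], kind=kind)
        out.append((float(pi0), float(curve.net_benefits[0])))
    return out
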