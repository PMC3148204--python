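"""Decision curves over a threshold grid, binary tests, and logistic fitting.

A decision curve plots net benefit against the threshold probability p_t for
one treatment strategy.  Continuous risk models are evaluated by classifying
at each grid threshold; a binary test (sensitivity, specificity, prevalence)
is the degenerate model with p_i = 1 for test-positives and p_i = 0 for
test-negatives, so its proportions are constant in p_t:

    a = sens * pi,  b = (1 - spec)(1 - pi),
    c = (1 - sens) * pi,  d = spec * (1 - pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import (
    BenefitKind,
    ClassificationProportions,
    DomainError,
    InvalidInputError,
    PredictionSet,
    classify,
    net_benefit,
)

__all__ = [
    "ThresholdGrid",
    "DecisionCurve",
    "BinaryTest",
    "decision_curve",
    "binary_test_curve",
    "fit_logistic_model",
]

#: grid endpoints are clipped away from 0 and 1 where the weights diverge
GRID_EPSILON = 0.01


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing threshold probabilities, all inside (0, 1).

    The default grid runs from 0.01 to 0.99 in steps of 0.01; the open
    endpoints are excluded because the untreated weight (1-p_t)/p_t diverges
    at 0 and the treated weight p_t/(1-p_t) diverges at 1.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) == 0:
            raise InvalidInputError("threshold grid must be a non-empty 1-D sequence")
        if not ((v > 0.0).all() and (v < 1.0).all()):
            raise DomainError("all grid thresholds must lie strictly in (0, 1)")
        if not (np.diff(v) > 0).all():
            raise InvalidInputError("grid thresholds must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @classmethod
    def default(cls) -> "ThresholdGrid":
        return cls(np.round(np.arange(1, 100) / 100.0, 12))

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "ThresholdGrid":
        n = int(round((stop - start) / step))
        return cls(np.round(start + step * np.arange(n + 1), 12))

    @classmethod
    def coerce(cls, grid: "ThresholdGrid | Sequence[float] | None") -> "ThresholdGrid":
        if grid is None:
            return cls.default()
        if isinstance(grid, ThresholdGrid):
            return grid
        return cls(np.asarray(grid, dtype=float))


@dataclass(frozen=True)
class DecisionCurve:
    """(threshold, net benefit) pairs for one strategy and one benefit kind."""

    strategy_label: str
    kind: BenefitKind
    thresholds: np.ndarray
    net_benefits: np.ndarray
    pi0: float | None = field(default=None)  # assumed true prevalence, if adjusted

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        nb = np.asarray(self.net_benefits, dtype=float)
        if t.shape != nb.shape or t.ndim != 1:
            raise InvalidInputError("thresholds and net benefits must be aligned 1-D arrays")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "net_benefits", nb)
        object.__setattr__(self, "kind", BenefitKind.coerce(self.kind))

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (strategy_label, kind, p_t, net_benefit)."""
        frame = pd.DataFrame(
            {
                "strategy_label": self.strategy_label,
                "kind": self.kind.value,
                "p_t": self.thresholds,
                "net_benefit": self.net_benefits,
            }
        )
        if self.pi0 is not None:
            frame["pi0"] = self.pi0
        return frame


@dataclass(frozen=True)
class BinaryTest:
    """A binary diagnostic/prognostic test summarised by its error rates."""

    sensitivity: float
    specificity: float
    prevalence: float
    label: str = "binary test"

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise DomainError("sensitivity and specificity must lie in [0, 1]")
        if not (0.0 < self.prevalence < 1.0):
            raise DomainError(
                f"prevalence must lie strictly in (0, 1), got {self.prevalence}"
            )

    @property
    def proportions(self) -> ClassificationProportions:
        """The (a, b, c, d) induced by the test, independent of p_t."""
        sens, spec, pi = self.sensitivity, self.specificity, self.prevalence
        return ClassificationProportions(
            a=sens * pi,
            b=(1.0 - spec) * (1.0 - pi),
            c=(1.0 - sens) * pi,
            d=spec * (1.0 - pi),
        )


def decision_curve(
    preds: PredictionSet,
    grid: ThresholdGrid | Sequence[float] | None = None,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> DecisionCurve:
    """Decision curve of a prediction model: net benefit at every grid threshold.

    Each point is ``net_benefit(classify(preds, p_t), p_t, kind)`` — computed
    pointwise, with no smoothing or interpolation.
    """
    grid = ThresholdGrid.coerce(grid)
    kind = BenefitKind.coerce(kind)
    nb = np.array(
        [net_benefit(classify(preds, p_t), p_t, kind) for p_t in grid.values]
    )
    return DecisionCurve(
        strategy_label=preds.label, kind=kind, thresholds=grid.values, net_benefits=nb
    )


def binary_test_curve(
    test: BinaryTest,
    grid: ThresholdGrid | Sequence[float] | None = None,
    kind: BenefitKind | str = BenefitKind.TREATED,
) -> DecisionCurve:
    """Decision curve of a binary test.

    The test's classification is the same at every threshold (positives are
    always treated, negatives never), so only the weights vary with p_t.
    """
    grid = ThresholdGrid.coerce(grid)
    kind = BenefitKind.coerce(kind)
    props = test.proportions
    nb = np.array([net_benefit(props, p_t, kind) for p_t in grid.values])
    return DecisionCurve(
        strategy_label=test.label, kind=kind, thresholds=grid.values, net_benefits=nb
    )


def fit_logistic_model(
    covariates: np.ndarray | pd.DataFrame | None,
    outcomes: Sequence[int] | np.ndarray,
    label: str = "logistic model",
) -> PredictionSet:
    """Fit a maximum-likelihood logistic regression and return in-sample risks.

    Fitting uses iteratively reweighted least squares (convergence tolerance
    1e-8, at most 100 iterations).  An intercept is always included; with no
    covariates the fitted probability is the sample prevalence for everyone.
    Perfect separation triggers a warning (iterations are capped) rather than
    an error.

    Parameters
    ----------
    covariates
        n x k numeric matrix (k may be 0, or pass None for intercept-only).
    outcomes
        Binary outcome per subject; both classes must be present.

    Returns
    -------
    PredictionSet
        Fitted in-sample event probabilities; ``metadata`` carries the
        coefficient estimates (``params``), their standard errors (``bse``)
        and convergence info.
    """
    y = np.asarray(outcomes)
    if not np.isin(y, (0, 1)).all():
        raise InvalidInputError("outcomes must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise InvalidInputError(
            "outcomes contain a single class; logistic regression is undefined"
        )
    if covariates is None:
        X = np.empty((len(y), 0))
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if len(y) != X.shape[0]:
        raise InvalidInputError("covariates and outcomes must have matching length")
    if len(y) <= X.shape[1]:
        raise InvalidInputError("need more subjects than covariates")

    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        # perfect separation surfaces as convergence/overflow warnings; keep
        # the capped-iteration fit and let one warning through for the caller
        warnings.simplefilter("always")
        model = sm.GLM(y.astype(float), design, family=sm.families.Binomial())
        result = model.fit(maxiter=100, tol=1e-8)
        if not result.converged:
            warnings.warn(
                "logistic fit did not converge within 100 IRLS iterations "
                "(possible perfect separation); using capped-iteration estimates",
                RuntimeWarning,
                stacklevel=2,
            )
    fitted = np.clip(np.asarray(result.fittedvalues, dtype=float), 0.0, 1.0)
    return PredictionSet(
        outcomes=y,
        probabilities=fitted,
        label=label,
        metadata={
            "params": np.asarray(result.params),
            "bse": np.asarray(result.bse),
            "converged": bool(result.converged),
        },
    )
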