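"""Synthetic cohorts, binary tests and case-control samples for testing.

The default cohort loosely emulates a Framingham-style risk setting: a
binary 30-year event outcome generated from a logistic model over six
covariates (one binary "sex" covariate plus five standardised continuous
measurements such as age, BMI, serum cholesterol and blood pressures), with
the intercept tuned so the marginal event prevalence is about 0.30.  No
attempt is made to match any published coefficients; the generator's job is
to produce realistic rank structure and calibration, not a particular study.

All generators are pure functions of their arguments including the seed
(numpy's PCG64 via ``default_rng``); no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from .core import ConfigurationError, DomainError, InvalidInputError, PredictionSet
from .curves import fit_logistic_model

__all__ = [
    "CovariateSpec",
    "CohortSpec",
    "PopulationSample",
    "generate_risk_cohort",
    "generate_binary_test_data",
    "sample_case_control",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate: standard normal, or binary with a given frequency."""

    kind: str  # "normal" | "binary"
    frequency: float = 0.5  # only used for binary
    name: str = "x"

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "binary"):
            raise ConfigurationError(
                f"unknown covariate kind {self.kind!r}; expected 'normal' or 'binary'"
            )
        if self.kind == "binary" and not (0.0 < self.frequency < 1.0):
            raise ConfigurationError(
                f"binary covariate frequency must lie in (0, 1), got {self.frequency}"
            )


# Framingham-like defaults: sex + five standardised continuous risk factors.
# Intercept -1.39 puts the marginal prevalence at ~0.30 for these coefficients.
_DEFAULT_COVARIATES = (
    CovariateSpec("binary", 0.5, "sex"),
    CovariateSpec("normal", name="age"),
    CovariateSpec("normal", name="bmi"),
    CovariateSpec("normal", name="chol"),
    CovariateSpec("normal", name="dbp"),
    CovariateSpec("normal", name="sbp"),
)
_DEFAULT_COEFFICIENTS = (0.6, 0.9, 0.25, 0.5, 0.3, 0.45)
_DEFAULT_INTERCEPT = -1.39


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a logistic-model cohort to simulate."""

    n: int
    seed: int
    intercept: float = _DEFAULT_INTERCEPT
    coefficients: tuple[float, ...] = _DEFAULT_COEFFICIENTS
    covariates: tuple[CovariateSpec, ...] = _DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"cohort size must be >= 1, got {self.n}")
        if len(self.coefficients) != len(self.covariates):
            raise ConfigurationError(
                f"{len(self.coefficients)} coefficients for "
                f"{len(self.covariates)} covariates"
            )


@dataclass(frozen=True)
class PopulationSample:
    """A simulated cohort with its generating probabilities."""

    covariates: np.ndarray  # (n, k)
    outcomes: np.ndarray  # (n,), 0/1
    true_probabilities: np.ndarray  # (n,), logistic-model event probabilities
    covariate_names: tuple[str, ...] = field(default=())

    @property
    def realized_prevalence(self) -> float:
        return float(self.outcomes.mean())

    def __len__(self) -> int:
        return len(self.outcomes)


def generate_risk_cohort(spec: CohortSpec) -> PopulationSample:
    """Simulate a cohort whose outcomes follow the logistic model exactly.

    Covariates are drawn per their specs, the linear predictor is
    ``intercept + X @ coefficients``, true probabilities are its logistic
    transform, and outcomes are Bernoulli draws from those probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n, len(spec.covariates)
    X = np.empty((n, k))
    for j, cov in enumerate(spec.covariates):
        if cov.kind == "binary":
            X[:, j] = rng.binomial(1, cov.frequency, n)
        else:
            X[:, j] = rng.standard_normal(n)
    probs = expit(spec.intercept + X @ np.asarray(spec.coefficients))
    outcomes = rng.binomial(1, probs)
    return PopulationSample(
        covariates=X,
        outcomes=outcomes,
        true_probabilities=probs,
        covariate_names=tuple(c.name for c in spec.covariates),
    )


def generate_binary_test_data(
    n: int,
    sensitivity: float,
    specificity: float,
    prevalence: float,
    seed: int,
    exact: bool = False,
) -> PredictionSet:
    """Simulate a binary test as a degenerate 0/1-probability prediction set.

    In stochastic mode (default), outcomes are Bernoulli(prevalence) and the
    test is positive with probability ``sensitivity`` among cases and
    ``1 - specificity`` among controls.  In exact-fraction mode, the four
    cell counts n*a, n*b, n*c, n*d are required to be integers and the data
    contain exactly those counts with no randomness (the seed is unused).
    """
    if n < 1:
        raise InvalidInputError(f"sample size must be >= 1, got {n}")
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise DomainError("sensitivity and specificity must lie in [0, 1]")
    if not (0.0 < prevalence < 1.0):
        raise DomainError(f"prevalence must lie strictly in (0, 1), got {prevalence}")

    label = f"binary test (sens={sensitivity:g}, spec={specificity:g})"
    if exact:
        counts = {
            "a": n * prevalence * sensitivity,
            "b": n * (1.0 - prevalence) * (1.0 - specificity),
            "c": n * prevalence * (1.0 - sensitivity),
            "d": n * (1.0 - prevalence) * specificity,
        }
        cells = {}
        for name, x in counts.items():
            rounded = round(x)
            if abs(x - rounded) > 1e-9:
                raise InvalidInputError(
                    f"exact-fraction mode needs integer cell counts; "
                    f"n*{name} = {x} is not an integer"
                )
            cells[name] = int(rounded)
        outcomes = np.concatenate(
            [
                np.ones(cells["a"], dtype=int),  # diseased, test positive
                np.zeros(cells["b"], dtype=int),  # disease-free, test positive
                np.ones(cells["c"], dtype=int),  # diseased, test negative
                np.zeros(cells["d"], dtype=int),  # disease-free, test negative
            ]
        )
        probs = np.concatenate(
            [np.ones(cells["a"] + cells["b"]), np.zeros(cells["c"] + cells["d"])]
        )
        return PredictionSet(outcomes=outcomes, probabilities=probs, label=label)

    rng = np.random.default_rng(seed)
    outcomes = rng.binomial(1, prevalence, n)
    positive_rate = np.where(outcomes == 1, sensitivity, 1.0 - specificity)
    probs = rng.binomial(1, positive_rate).astype(float)
    return PredictionSet(outcomes=outcomes, probabilities=probs, label=label)


def sample_case_control(
    population: PopulationSample,
    n_cases: int,
    n_controls: int,
    seed: int,
) -> PredictionSet:
    """Draw a case-control sample and refit the risk model on it.

    Cases and controls are sampled uniformly without replacement within their
    outcome class, then a logistic model over all covariates is refitted on
    the subsample.  Because the refit targets the sample prevalence
    n_cases/(n_cases + n_controls), the returned probabilities exhibit the
    characteristic case-control miscalibration that the prevalence
    adjustment corrects.
    """
    y = population.outcomes
    case_idx = np.flatnonzero(y == 1)
    control_idx = np.flatnonzero(y == 0)
    if n_cases < 1 or n_controls < 1:
        raise InvalidInputError("need at least one case and one control")
    if len(case_idx) < n_cases or len(control_idx) < n_controls:
        raise InvalidInputError(
            f"population has {len(case_idx)} cases and {len(control_idx)} controls; "
            f"requested {n_cases}+{n_controls}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(control_idx, size=n_controls, replace=False),
        ]
    )
    return fit_logistic_model(
        population.covariates[chosen],
        y[chosen],
        label="case-control refit",
    )
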