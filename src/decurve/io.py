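"""File I/O, plotting and the run orchestrator behind the command line.

Input is comma-separated text with a header row: one binary outcome column
and one column per prediction model (probabilities in [0, 1]), or covariate
columns for model fitting.  Output curves are written as long-format TSV
with columns (strategy_label, kind, p_t, net_benefit[, pi0]), floats printed
with 12 significant digits so a write/read round trip is lossless at that
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    BenefitKind,
    ConfigurationError,
    InvalidInputError,
    PredictionSet,
    reference_curve,
)
from .case_control import case_control_curve
from .curves import DecisionCurve, ThresholdGrid, decision_curve

__all__ = [
    "RunConfig",
    "read_predictions",
    "write_curves",
    "read_curves",
    "plot_decision_curves",
    "run_dca",
]

logger = logging.getLogger("decurve")

FLOAT_FORMAT = "%.12g"
#: default y-axis clip for decision-curve plots; the treat-all / treat-none
#: references diverge to -inf and are only drawn where they exceed the clip
PLOT_YLIM = (-0.05, 1.05)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one decision-curve run (the `curve`/`casecontrol` commands)."""

    input_path: str
    outcome_column: str
    probability_columns: tuple[str, ...]
    kinds: tuple[BenefitKind, ...] = (BenefitKind.TREATED,)
    grid: ThresholdGrid = field(default_factory=ThresholdGrid.default)
    pi0_values: tuple[float, ...] | None = None  # case-control mode if set
    output_prefix: str = "decurve"
    plot: bool = False
    seed: int | None = None
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        if not self.probability_columns:
            raise ConfigurationError("at least one probability column is required")
        object.__setattr__(
            self, "kinds", tuple(BenefitKind.coerce(k) for k in self.kinds)
        )


def parse_pi0_spec(spec: str) -> tuple[float, ...]:
    """Parse a pi0 argument: scalar `0.3`, list `0.15,0.45,0.3`, or range `0.1:0.5:0.1`."""
    spec = spec.strip()
    try:
        if ":" in spec:
            start_s, stop_s, step_s = spec.split(":")
            start, stop, step = float(start_s), float(stop_s), float(step_s)
            if step <= 0 or stop < start:
                raise ValueError
            n = int(round((stop - start) / step))
            values = tuple(round(start + k * step, 12) for k in range(n + 1))
        elif "," in spec:
            values = tuple(float(v) for v in spec.split(","))
        else:
            values = (float(spec),)
    except ValueError:
        raise ConfigurationError(
            f"cannot parse pi0 specification {spec!r}; expected a scalar, "
            "a comma-separated list, or start:stop:step"
        ) from None
    for v in values:
        if not (0.0 < v < 1.0):
            raise ConfigurationError(f"pi0 value {v} must lie strictly in (0, 1)")
    return values


def read_predictions(
    path: str | Path,
    outcome_column: str,
    probability_columns: Sequence[str],
) -> list[PredictionSet]:
    """Read a CSV of outcomes and predicted probabilities.

    Returns one PredictionSet per probability column, all sharing the same
    outcomes.  Rows with a missing value in the outcome or any requested
    probability column are dropped (complete-case rule); the dropped count
    is logged at warning level.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    table = pd.read_csv(path)
    needed = [outcome_column, *probability_columns]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ConfigurationError(
            f"column(s) {missing} not found in {path.name}; "
            f"available: {list(table.columns)}"
        )
    complete = table[needed].dropna()
    n_dropped = len(table) - len(complete)
    if n_dropped:
        logger.warning(
            "dropped %d row(s) with missing values in %s (complete-case rule)",
            n_dropped,
            needed,
        )
    if complete.empty:
        raise InvalidInputError("no complete rows left after dropping missing values")
    outcomes = complete[outcome_column].to_numpy()
    bad = np.unique(outcomes[~np.isin(outcomes, (0, 1))])
    if bad.size:
        raise InvalidInputError(
            f"outcome column {outcome_column!r} must be binary 0/1; "
            f"found values {bad.tolist()}"
        )
    return [
        PredictionSet(
            outcomes=outcomes.astype(int),
            probabilities=complete[col].to_numpy(dtype=float),
            label=col,
        )
        for col in probability_columns
    ]


def write_curves(curves: Iterable[DecisionCurve], path: str | Path) -> pd.DataFrame:
    """Write curves as a single long-format TSV; returns the written frame."""
    frames = [c.to_frame() for c in curves]
    if not frames:
        raise InvalidInputError("no curves to write")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return table


def read_curves(path: str | Path) -> pd.DataFrame:
    """Read back a long-format curve TSV."""
    return pd.read_csv(path, sep="\t")


def write_roc(roc, path: str | Path) -> pd.DataFrame:
    """Write ROC operating points as TSV (cutoff, one_minus_specificity, sensitivity)."""
    table = pd.DataFrame(
        {
            "cutoff": roc.cutoffs,
            "one_minus_specificity": roc.points[:, 0],
            "sensitivity": roc.points[:, 1],
        }
    )
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return table


def plot_decision_curves(
    curves: Sequence[DecisionCurve],
    path: str | Path,
    title: str | None = None,
    ylim: tuple[float, float] = PLOT_YLIM,
) -> None:
    """Plot decision curves (model curves plus references) to an image file.

    Best-effort presentation: curves are drawn as linear interpolations of
    the grid points and the y-axis is clipped, so diverging reference curves
    appear only where they exceed the clip.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    reference_styles = {
        "treat_none": {"color": "0.4", "linestyle": ":"},
        "treat_all": {"color": "0.4", "linestyle": "--"},
        "perfect": {"color": "0.6", "linestyle": "-."},
    }
    for curve in curves:
        style = reference_styles.get(curve.strategy_label, {})
        mask = np.isfinite(curve.net_benefits) & (curve.net_benefits >= ylim[0])
        ax.plot(
            curve.thresholds[mask],
            curve.net_benefits[mask],
            label=curve.strategy_label,
            **style,
        )
    ax.set_xlabel("threshold probability $p_t$")
    ax.set_ylabel("net benefit")
    ax.set_ylim(*ylim)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_dca(config: RunConfig) -> list[Path]:
    """Run a full decision-curve analysis per the configuration.

    Reads the predictions, computes the requested curves for every model and
    benefit kind together with the treat-none / treat-all / perfect
    references (the classical five-curve layout), writes one TSV per kind
    (and optionally one plot per kind), and returns the written paths.  In
    case-control mode (``pi0_values`` set) model curves are prevalence
    adjusted, one block per pi0, with references drawn at each pi0.
    On failure, partially written outputs are removed before re-raising.
    """
    logging.basicConfig(level=config.log_level.upper())
    preds = read_predictions(
        config.input_path, config.outcome_column, config.probability_columns
    )
    prevalence = preds[0].prevalence
    written: list[Path] = []
    try:
        for kind in config.kinds:
            curves: list[DecisionCurve] = []
            if config.pi0_values is None:
                for ps in preds:
                    curves.append(decision_curve(ps, config.grid, kind))
                for strategy in ("treat_none", "treat_all", "perfect"):
                    curves.append(reference_curve(prevalence, config.grid, strategy, kind))
            else:
                for pi0 in config.pi0_values:
                    for ps in preds:
                        curves.append(case_control_curve(ps, pi0, config.grid, kind))
                    for strategy in ("treat_none", "treat_all", "perfect"):
                        ref = reference_curve(pi0, config.grid, strategy, kind)
                        curves.append(
                            DecisionCurve(
                                strategy_label=ref.strategy_label,
                                kind=ref.kind,
                                thresholds=ref.thresholds,
                                net_benefits=ref.net_benefits,
                                pi0=pi0,
                            )
                        )
            out = Path(f"{config.output_prefix}_{kind.value}.tsv")
            write_curves(curves, out)
            written.append(out)
            if config.plot:
                plot_path = Path(f"{config.output_prefix}_{kind.value}.png")
                plot_decision_curves(
                    curves, plot_path, title=f"net benefit for the {kind.value}"
                )
                written.append(plot_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
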