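"""Computational experiments: category-mean sweeps, therapy sweeps over
presented stimuli, effective-interval detection, and post-learning curves.

These functions reproduce the model's headline phenomena: the valley of
the typical condition turning into a cliff as the human-category mean
shifts right, the band of therapeutic stimuli that actually reshape the
human category, and the gradual lifting of the valley/cliff bottom over
learning trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .learning import LearningConfig, LearningTrace, _simulate
from .model import ModelConfig, ResponseCurve, response_curve

__all__ = [
    "SweepResult",
    "EffectiveInterval",
    "DEFAULT_GRID_STEP",
    "DEFAULT_SP_STEP",
    "stimulus_grid",
    "sp_grid",
    "mu_sweep",
    "therapy_sweep",
    "effective_interval",
    "post_learning_curves",
    "valley_depth",
]

#: Stimulus-axis resolution for response curves; fine enough to place
#: extrema within half a step.
DEFAULT_GRID_STEP = 0.005
#: Presented-stimulus resolution for therapy sweeps.
DEFAULT_SP_STEP = 0.01


def stimulus_grid(step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Default stimulus grid: [0, 1] inclusive."""
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


def sp_grid(step: float = DEFAULT_SP_STEP) -> np.ndarray:
    """Default presented-stimulus grid: [0, 1] inclusive."""
    return np.round(np.arange(0.0, 1.0 + step / 2, step), 10)


@dataclass(frozen=True)
class SweepResult:
    """Outputs of a one-parameter sweep.

    ``outputs`` holds one ResponseCurve (mu sweeps) or LearningTrace
    (therapy sweeps) per swept value.
    """

    sweep_values: np.ndarray
    outputs: tuple
    condition_label: str = "custom"
    parameter: str = ""

    def __post_init__(self) -> None:
        if len(self.outputs) != len(self.sweep_values):
            raise ValueError("outputs length must match the sweep grid length")

    @property
    def terminal_variances(self) -> np.ndarray:
        """Terminal learned variance per swept value (therapy sweeps only)."""
        return np.array([t.terminal_variance for t in self.outputs])

    @property
    def initial_variance(self) -> float:
        return float(self.outputs[0].variance[0])


@dataclass(frozen=True)
class EffectiveInterval:
    """Contiguous presented-stimulus range that materially reshapes the
    human category.  ``lower``/``upper`` are None when no grid point meets
    the criterion; ``n_regions`` > 1 flags that the criterion selected
    several disjoint regions and the widest one is reported."""

    lower: float | None
    upper: float | None
    criterion: str
    n_regions: int = 1

    @property
    def empty(self) -> bool:
        return self.lower is None

    def as_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "criterion": self.criterion,
            "n_regions": self.n_regions,
        }


def mu_sweep(
    mu_values: Sequence[float],
    base: ModelConfig,
    grid: Sequence[float] | None = None,
    label: str = "custom",
) -> SweepResult:
    """One response curve per human-category mean, all else held at ``base``."""
    mu_values = np.asarray(mu_values, dtype=float)
    if mu_values.size == 0:
        raise ValueError("mu_values must be non-empty")
    if grid is None:
        grid = stimulus_grid()
    curves = []
    for mu in mu_values:
        cats = list(base.categories)
        cats[base.human_index] = replace(cats[base.human_index], mean=float(mu))
        curves.append(response_curve(replace(base, categories=tuple(cats)), grid))
    return SweepResult(
        sweep_values=mu_values,
        outputs=tuple(curves),
        condition_label=label,
        parameter="mu_c2",
    )


def therapy_sweep(
    sp_values: Sequence[float],
    model: ModelConfig,
    learn_template: LearningConfig,
    label: str = "custom",
) -> SweepResult:
    """One learning trace per presented stimulus.

    All stimuli are advanced in one vectorized batch; each trace equals the
    single-stimulus run exactly.
    """
    sp_values = np.asarray(sp_values, dtype=float)
    if sp_values.size == 0:
        raise ValueError("sp_values must be non-empty")
    sim = _simulate(model, sp_values, learn_template)
    k = learn_template.n_trials
    trials = np.arange(k + 1)
    traces = tuple(
        LearningTrace(
            trial=trials,
            variance=sim["variance"][:, i],
            gamma=sim["gamma"][:, i],
            posterior_c2=sim["posterior"][:, i],
            response_Y=sim["response"][:, i],
        )
        for i in range(sp_values.size)
    )
    return SweepResult(
        sweep_values=sp_values,
        outputs=traces,
        condition_label=label,
        parameter="S_p",
    )


def effective_interval(
    sweep: SweepResult,
    abs_threshold: float = 0.05,
    rel_threshold: float | None = None,
) -> EffectiveInterval:
    """Presented-stimulus range over which learning materially changes the
    human-category variance.

    The default criterion is an absolute change in terminal variance,
    |sigma^2(K) - sigma^2(0)| > ``abs_threshold``: a change of 0.05 in
    variance units reshapes the category SD by about 0.2 on the unit
    stimulus axis, separating the runaway-learning band from the slow
    drift that every stimulus induces.  Passing ``rel_threshold`` switches
    to the relative criterion |sigma^2(K) - sigma^2(0)| / sigma^2(0) >
    ``rel_threshold`` instead.

    If several disjoint regions meet the criterion the widest is returned
    and ``n_regions`` records the multiplicity.  Endpoints are snapped to
    two decimals for comparability with published ranges.
    """
    term = sweep.terminal_variances
    init = sweep.initial_variance
    change = np.abs(term - init)
    if rel_threshold is not None:
        mask = change / init > rel_threshold
        criterion = f"|var_K - var_0| / var_0 > {rel_threshold}"
    else:
        mask = change > abs_threshold
        criterion = f"|var_K - var_0| > {abs_threshold}"
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return EffectiveInterval(None, None, criterion, n_regions=0)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    runs = [(idx[a], idx[b]) for a, b in zip(starts, ends)]
    widths = [sweep.sweep_values[b] - sweep.sweep_values[a] for a, b in runs]
    a, b = runs[int(np.argmax(widths))]
    return EffectiveInterval(
        lower=round(float(sweep.sweep_values[a]), 2),
        upper=round(float(sweep.sweep_values[b]), 2),
        criterion=criterion,
        n_regions=len(runs),
    )


def post_learning_curves(
    model: ModelConfig,
    learn: LearningConfig,
    checkpoints: Sequence[int],
    grid: Sequence[float] | None = None,
) -> list[ResponseCurve]:
    """Response curves with the human-category SD frozen at trace checkpoints."""
    checkpoints = list(checkpoints)
    for c in checkpoints:
        if not (0 <= c <= learn.n_trials):
            raise ValueError(
                f"checkpoint {c} outside the simulated range [0, {learn.n_trials}]"
            )
    if grid is None:
        grid = stimulus_grid()
    sim = _simulate(model, np.array([learn.presented_stimulus]), learn)
    variances = sim["variance"][:, 0]
    return [
        response_curve(model.with_human_sd(np.sqrt(variances[c])), grid)
        for c in checkpoints
    ]


def valley_depth(curve: ResponseCurve, config: ModelConfig) -> float:
    """Minimum combined response strictly between the category centers.

    The valley (or cliff bottom) lies between the background and human
    means by construction; the human mean is clipped to the grid's end for
    shifted conditions whose category center lies beyond the plotted axis.
    """
    lo = min(c.mean for c in config.categories)
    hi = max(c.mean for c in config.categories)
    hi = min(hi, float(curve.grid[-1]))
    mask = (curve.grid > lo) & (curve.grid <= hi)
    if not np.any(mask):
        raise ValueError("no grid points between the category centers")
    return float(np.min(curve.Y[mask]))
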