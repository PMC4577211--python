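"""Optional static figures mirroring the simulation outputs.

Imported lazily by the CLI; the data files remain the source of truth.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .experiments import EffectiveInterval, SweepResult  # noqa: E402
from .learning import LearningTrace  # noqa: E402
from .model import ResponseCurve  # noqa: E402


def plot_curves(curves: dict[str, ResponseCurve], path: str | Path) -> None:
    """Combined emotional-response curves, one line per labelled condition."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.plot(curve.grid, curve.Y, label=label)
    ax.set_xlabel("human-likeness h")
    ax.set_ylabel("combined emotional response Y")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mu_sweep(sweep: SweepResult, path: str | Path) -> None:
    """Valley-to-cliff transition as the human-category mean shifts right."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for mu, curve in zip(sweep.sweep_values, sweep.outputs):
        ax.plot(curve.grid, curve.Y, label=f"mu_h={mu:g}")
    ax.set_xlabel("human-likeness h")
    ax.set_ylabel("combined emotional response Y")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_learning(
    trace: LearningTrace,
    checkpoint_curves: dict[int, ResponseCurve],
    path: str | Path,
) -> None:
    """Learning curve of the variance plus post-learning response curves."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(trace.trial, trace.variance)
    ax1.set_xlabel("trial")
    ax1.set_ylabel("human-category variance")
    for mark, curve in checkpoint_curves.items():
        ax2.plot(curve.grid, curve.Y, label=f"trial {mark}")
    ax2.set_xlabel("human-likeness h")
    ax2.set_ylabel("Y")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_terminal_variance(
    sweep: SweepResult,
    interval: EffectiveInterval | None,
    path: str | Path,
) -> None:
    """Terminal learned variance per presented stimulus, interval shaded."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sweep.sweep_values, sweep.terminal_variances)
    ax.axhline(sweep.initial_variance, color="0.7", lw=0.8, ls="--")
    if interval is not None and not interval.empty:
        ax.axvspan(interval.lower, interval.upper, color="tab:orange", alpha=0.2)
    ax.set_xlabel("presented stimulus S_p")
    ax.set_ylabel("terminal variance after learning")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
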