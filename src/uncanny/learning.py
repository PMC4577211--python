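"""Simulated robot-assisted therapy: iterative learning of the human-category variance.

A therapeutic stimulus of fixed human-likeness ``S_p`` is presented for
``K`` trials.  Each trial nudges the human category's variance toward the
squared distance between the stimulus and the category mean, gated by how
strongly the stimulus engages the human category (its combined posterior)
and signed by the observer's emotional response: positive responses foster
learning, negative responses inhibit it.  Everything is deterministic —
the rule has no noise — so traces are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ModelConfig,
    UnsupportedConfigurationError,
    _cue_stats,
    combined_response,
)

__all__ = [
    "LearningConfig",
    "LearningTrace",
    "combined_posterior",
    "learning_rate",
    "variance_update",
    "run_therapy",
]


@dataclass(frozen=True)
class LearningConfig:
    """Therapy-simulation settings.

    Parameters
    ----------
    presented_stimulus : float
        Human-likeness S_p of the therapeutic robot, nominally in [0, 1].
    delta : float
        Learning-scale factor; the per-trial rate is gamma = delta * Y(S_p).
    n_trials : int
        Number of update steps K, >= 1.
    variance_floor : float
        Lower clamp on the learned variance; keeps the category Gaussian
        valid when a negative response drives the update below zero.
    seed : int or None
        Accepted for interface stability; the dynamics are deterministic
        and the value is ignored.
    """

    presented_stimulus: float
    delta: float = 0.1
    n_trials: int = 500
    variance_floor: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.presented_stimulus):
            raise ValueError("presented_stimulus must be finite")
        if not (self.delta >= 0):
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if not (self.n_trials >= 1):
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if not (self.variance_floor > 0):
            raise ValueError(f"variance_floor must be > 0, got {self.variance_floor}")


@dataclass(frozen=True)
class LearningTrace:
    """Per-trial record of one therapy simulation.

    All series have length ``n_trials + 1``; index 0 is the pre-learning
    state.  ``gamma``, ``posterior_c2`` and ``response_Y`` at index k are
    evaluated at the state *of* trial k (the values that produce state
    k + 1; the final entry is the terminal-state evaluation).
    """

    trial: np.ndarray
    variance: np.ndarray
    gamma: np.ndarray
    posterior_c2: np.ndarray
    response_Y: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.trial)
        for name in ("variance", "gamma", "posterior_c2", "response_Y"):
            if len(getattr(self, name)) != n:
                raise ValueError("all trace series must share one length")

    @property
    def terminal_variance(self) -> float:
        return float(self.variance[-1])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "variance": self.variance,
                "gamma": self.gamma,
                "posterior_c2": self.posterior_c2,
                "Y": self.response_Y,
            }
        )


def combined_posterior(h, config: ModelConfig, *, human_sd=None):
    """Attention-weighted human-category posterior.

    P(C_h | S_p) = beta P(C_h | S1) + (1 - beta) P(C_h | S2): the same
    linear cue combination used for the total emotional response.
    """
    if len(config.cues) != 2:
        raise UnsupportedConfigurationError(
            f"combined_posterior requires exactly 2 cues, got {len(config.cues)}"
        )
    h_arr = np.asarray(h, dtype=float)
    post = [
        _cue_stats(h_arr, cue, config, human_sd)[0][config.human_index]
        for cue in config.cues
    ]
    out = config.beta * post[0] + (1.0 - config.beta) * post[1]
    return float(out) if np.ndim(h) == 0 else out


def learning_rate(h, config: ModelConfig, delta: float, *, human_sd=None):
    """Per-trial rate gamma = delta * Y(S_p); its sign follows the response."""
    return delta * combined_response(h, config, human_sd=human_sd)


def variance_update(
    current_variance: float,
    h: float,
    config: ModelConfig,
    delta: float,
    floor: float = 1e-6,
) -> float:
    """One step of the categorical-perception learning rule.

    sigma^2(k+1) = sigma^2(k) + gamma * P(C_h | S_p) * ((S_p - mu_h)^2 - sigma^2(k))

    gamma and the posterior are evaluated at the *current* variance; the
    result is clamped at ``floor``.  Only the human category's variance
    changes.
    """
    new_var = _step(
        np.asarray([float(current_variance)]),
        np.asarray([float(h)]),
        config,
        delta,
        floor,
    )[0][0]
    return float(new_var)


def _step(var: np.ndarray, sp, config: ModelConfig, delta: float, floor: float):
    """Vectorized update step; ``var`` holds one human-category variance per
    presented-stimulus value.  Returns (next_var, gamma, posterior, Y)."""
    sd = np.sqrt(var)
    y = combined_response(sp, config, human_sd=sd)
    post = combined_posterior(sp, config, human_sd=sd)
    gamma = delta * np.asarray(y)
    target = (np.asarray(sp, dtype=float) - config.human.mean) ** 2
    new_var = var + gamma * np.asarray(post) * (target - var)
    if not np.all(np.isfinite(new_var)):
        raise FloatingPointError("non-finite variance produced by learning step")
    return np.maximum(new_var, floor), gamma, np.asarray(post), np.asarray(y)


def _simulate(config: ModelConfig, sp: np.ndarray, learn: LearningConfig) -> dict:
    """Run the learning dynamics for a batch of presented stimuli at once.

    Returns arrays of shape ``(n_trials + 1, len(sp))``.  The batch update
    is algebraically identical to running each stimulus alone.
    """
    sp = np.atleast_1d(np.asarray(sp, dtype=float))
    k = learn.n_trials
    var = np.full((k + 1, sp.size), np.nan)
    gam = np.full_like(var, np.nan)
    post = np.full_like(var, np.nan)
    resp = np.full_like(var, np.nan)
    var[0] = max(config.human.sd ** 2, learn.variance_floor)
    for i in range(k):
        try:
            var[i + 1], gam[i], post[i], resp[i] = _step(
                var[i], sp, config, learn.delta, learn.variance_floor
            )
        except FloatingPointError as exc:
            raise FloatingPointError(f"trial {i}: {exc}") from exc
    # terminal-state evaluation (recorded, never applied)
    _, gam[k], post[k], resp[k] = _step(
        var[k], sp, config, learn.delta, learn.variance_floor
    )
    return {"variance": var, "gamma": gam, "posterior": post, "response": resp}


def run_therapy(model: ModelConfig, learn: LearningConfig) -> LearningTrace:
    """Iterate the variance-update rule and record the full trajectory.

    The rate, posterior and response are re-evaluated every trial with the
    updated variance, so the emotional response curve itself evolves as
    the category reshapes.
    """
    sim = _simulate(model, np.array([learn.presented_stimulus]), learn)
    k = learn.n_trials
    return LearningTrace(
        trial=np.arange(k + 1),
        variance=sim["variance"][:, 0],
        gamma=sim["gamma"][:, 0],
        posterior_c2=sim["posterior"][:, 0],
        response_Y=sim["response"][:, 0],
    )
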