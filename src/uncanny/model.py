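"""Static evaluation of the Bayesian categorical-perception model of the uncanny valley.

The model places Gaussian perceptual categories on a one-dimensional
human-likeness axis (0 = completely machine-like, 1 = fully human-like).
A physical stimulus value ``h`` is observed through one or more noisy cues;
Bayesian inference over the latent perceived humanness ``H`` pulls the
percept toward category centers (the perceptual magnet effect).  The
disagreement between cues of different reliability creates perceptual
tension, and subtracting scaled tension from the stimulus familiarity
(the marginal density) yields the characteristic valley-shaped emotional
response curve.

All operations are deterministic, vectorized over ``h`` (scalars in give
scalars out, arrays in give arrays out), and computed in log space where
densities can underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "Category",
    "Cue",
    "ModelConfig",
    "ResponseCurve",
    "DegenerateDensityError",
    "UnderflowError",
    "UnsupportedConfigurationError",
    "category_likelihood",
    "category_posterior",
    "marginal_density",
    "expected_humanness",
    "displacement",
    "perceptual_tension",
    "emotional_response",
    "combined_response",
    "response_curve",
]


class DegenerateDensityError(ValueError):
    """Category and cue variances are both zero: the likelihood is a point mass."""


class UnderflowError(FloatingPointError):
    """Every category likelihood underflowed to zero at some stimulus value."""


class UnsupportedConfigurationError(ValueError):
    """The operation requires a configuration shape the model does not define."""


@dataclass(frozen=True)
class Category:
    """One perceptual category on the human-likeness axis.

    Parameters
    ----------
    mean : float
        Category center (mu_c), in human-likeness units.
    sd : float
        Category standard deviation (sigma_c), > 0.
    prior : float
        Prior probability mass P(C) of the category, in [0, 1].
    label : str
        Identifier used in logs and serialized output.
    """

    mean: float
    sd: float
    prior: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError(f"category mean must be finite, got {self.mean}")
        if not (self.sd > 0):
            raise ValueError(f"category sd must be > 0, got {self.sd}")
        if not (0.0 <= self.prior <= 1.0):
            raise ValueError(f"category prior must be in [0, 1], got {self.prior}")


@dataclass(frozen=True)
class Cue:
    """One perceptual channel with measurement uncertainty sigma_s >= 0."""

    sigma_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.sigma_s >= 0):
            raise ValueError(f"cue sigma_s must be >= 0, got {self.sigma_s}")


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterization of one perceptual condition.

    Parameters
    ----------
    categories : sequence of Category
        The perceptual categories; priors must sum to 1.  By convention
        index 0 is the broad background category and index 1 the narrow
        human category.
    cues : sequence of Cue
        The perceptual channels.  The two-cue default contrasts a noisy
        cue S1 (sigma_s = 0.2) with a reliable cue S2 (sigma_s = 0.05).
    alpha : float
        Tension scaling (sensitivity to perceptual conflict), >= 0.
    beta : float
        Attention weight on the first cue in the combined response,
        in [0, 1].
    human_index : int
        Which category is the learnable "human" category.
    tension_ddof : int
        Delta degrees of freedom of the across-cue variance that defines
        perceptual tension: 1 (default) is the sample variance, which for
        two cues is (D1 - D2)^2 / 2 and is what reproduces the published
        response curves; 0 is the population variance (D1 - D2)^2 / 4.
    """

    categories: tuple[Category, ...]
    cues: tuple[Cue, ...]
    alpha: float = 150.0
    beta: float = 0.5
    human_index: int = 1
    tension_ddof: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "categories", tuple(self.categories))
        object.__setattr__(self, "cues", tuple(self.cues))
        if len(self.categories) == 0:
            raise ValueError("at least one category is required")
        if len(self.cues) == 0:
            raise ValueError("at least one cue is required")
        total = sum(c.prior for c in self.categories)
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"category priors must sum to 1, got {total}")
        if not (self.alpha >= 0):
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if not (0 <= self.human_index < len(self.categories)):
            raise ValueError(
                f"human_index {self.human_index} out of range for "
                f"{len(self.categories)} categories"
            )
        if self.tension_ddof not in (0, 1):
            raise ValueError(f"tension_ddof must be 0 or 1, got {self.tension_ddof}")

    # -- convenience views -------------------------------------------------

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.categories])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.categories])

    @property
    def priors(self) -> np.ndarray:
        return np.array([c.prior for c in self.categories])

    @property
    def human(self) -> Category:
        return self.categories[self.human_index]

    def with_human_sd(self, sd: float) -> "ModelConfig":
        """Return a copy whose human-category SD is replaced (used by learning)."""
        cats = list(self.categories)
        cats[self.human_index] = replace(cats[self.human_index], sd=float(sd))
        return replace(self, categories=tuple(cats))


@dataclass(frozen=True)
class ResponseCurve:
    """Model outputs evaluated on a stimulus grid.

    Arrays all share the grid's length: ``V`` is the perceptual tension,
    ``per_cue_F`` holds one emotional-response row per cue (shape
    ``(n_cues, n_grid)``), and ``Y`` is the attention-weighted combined
    response.
    """

    grid: np.ndarray
    Y: np.ndarray
    per_cue_F: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ValueError("grid must be a non-empty 1-D array")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        for name in ("Y", "V"):
            if np.asarray(getattr(self, name)).shape != grid.shape:
                raise ValueError(f"{name} must share the grid's shape")
        if np.asarray(self.per_cue_F).shape[-1] != grid.size:
            raise ValueError("per_cue_F must share the grid's length")
        object.__setattr__(self, "grid", grid)


# -- internals ---------------------------------------------------------------


def _broadcast_params(config: ModelConfig, h: np.ndarray, human_sd):
    """Category parameter arrays shaped ``(n_cat,) + h.shape``.

    ``human_sd`` optionally overrides the human category's SD and may
    itself be an array broadcastable against ``h`` (each stimulus point
    evaluated under its own category width, as in learning sweeps).
    """
    shape = (len(config.categories),) + h.shape
    expand = (slice(None),) + (None,) * h.ndim
    means = np.broadcast_to(config.means[expand], shape)
    priors = np.broadcast_to(config.priors[expand], shape)
    sds = np.broadcast_to(config.sds[expand], shape).copy()
    if human_sd is not None:
        sds[config.human_index] = np.broadcast_to(human_sd, h.shape)
    return means, sds, priors


def _cue_stats(h, cue: Cue, config: ModelConfig, human_sd=None):
    """Posterior, log marginal and posterior-mean humanness for one cue.

    Returns ``(posterior, log_marginal, expected_H)`` where the posterior
    has shape ``(n_cat,) + h.shape`` and the rest follow ``h``.
    """
    h = np.asarray(h, dtype=float)
    means, sds, priors = _broadcast_params(config, h, human_sd)
    total_var = sds**2 + cue.sigma_s**2
    if np.any(total_var <= 0):
        raise DegenerateDensityError(
            "combined variance sigma_c^2 + sigma_s^2 must be positive"
        )
    loglik = norm.logpdf(h, loc=means, scale=np.sqrt(total_var))
    with np.errstate(divide="ignore"):
        logweights = loglik + np.log(priors)
    log_marginal = logsumexp(logweights, axis=0)
    if np.any(np.isneginf(log_marginal)):
        bad = h[np.isneginf(log_marginal)]
        raise UnderflowError(f"all category likelihoods underflow at h={bad!r}")
    posterior = np.exp(logweights - log_marginal)
    # Posterior mean of the latent humanness: per-category precision-weighted
    # shrinkage of h toward the category mean, mixed by the posterior.
    shrunk = (sds**2 * h + cue.sigma_s**2 * means) / total_var
    expected_h = np.sum(posterior * shrunk, axis=0)
    return posterior, log_marginal, expected_h


def _maybe_scalar(x: np.ndarray, h) -> np.ndarray | float:
    return float(x) if np.ndim(h) == 0 else x


# -- public operations -------------------------------------------------------


def category_likelihood(h, cue: Cue, cat: Category):
    """Likelihood P(S | C): Gaussian density of ``h`` with the category and
    cue variances added, N(h; mu_c, sigma_c^2 + sigma_s^2)."""
    h_arr = np.asarray(h, dtype=float)
    total_var = cat.sd**2 + cue.sigma_s**2
    if total_var <= 0:
        raise DegenerateDensityError(
            "combined variance sigma_c^2 + sigma_s^2 must be positive"
        )
    dens = norm.pdf(h_arr, loc=cat.mean, scale=np.sqrt(total_var))
    return _maybe_scalar(dens, h)


def category_posterior(h, cue: Cue, config: ModelConfig):
    """Posterior P(C_j | S) over categories; shape ``(n_cat,) + shape(h)``."""
    posterior, _, _ = _cue_stats(h, cue, config)
    return posterior


def marginal_density(h, cue: Cue, config: ModelConfig):
    """Prior-weighted mixture density P(S) = sum_j P(S | C_j) P(C_j)."""
    _, log_marginal, _ = _cue_stats(h, cue, config)
    return _maybe_scalar(np.exp(log_marginal), h)


def expected_humanness(h, cue: Cue, config: ModelConfig):
    """Posterior-mean perceived humanness E[H | S].

    Exact for Gaussian mixtures: each category shrinks ``h`` toward its
    mean by the factor sigma_c^2 / (sigma_c^2 + sigma_s^2), and the
    shrunken values are mixed by the category posterior.
    """
    _, _, expected_h = _cue_stats(h, cue, config)
    return _maybe_scalar(expected_h, h)


def displacement(h, cue: Cue, config: ModelConfig):
    """Perceptual displacement D(S) = E[H | S] - S.

    Positive values pull the percept up the human-likeness axis.
    """
    _, _, expected_h = _cue_stats(h, cue, config)
    return _maybe_scalar(expected_h - np.asarray(h, dtype=float), h)


def _displacements(h, config: ModelConfig, human_sd=None) -> np.ndarray:
    h_arr = np.asarray(h, dtype=float)
    return np.stack(
        [_cue_stats(h_arr, cue, config, human_sd)[2] - h_arr for cue in config.cues]
    )


def perceptual_tension(h, config: ModelConfig, *, beta_weighted: bool = False,
                       ddof: int | None = None, human_sd=None):
    """Across-cue variance of the displacements at a fixed stimulus.

    With equal cue weights (default) and ``ddof`` taken from the config
    this is ``var([D_1 ... D_n], ddof)``; ``beta_weighted=True`` instead
    weights the two cues by (beta, 1 - beta), a variant left open by the
    model's definition (identical at beta = 0.5).
    """
    if ddof is None:
        ddof = config.tension_ddof
    disp = _displacements(h, config, human_sd)
    n = disp.shape[0]
    if n == 1:
        return _maybe_scalar(np.zeros(np.shape(np.asarray(h, float))), h)
    if beta_weighted:
        if n != 2:
            raise UnsupportedConfigurationError(
                "beta-weighted tension is defined for exactly 2 cues"
            )
        w = np.array([config.beta, 1.0 - config.beta])[:, None]
        mean = np.sum(w * disp, axis=0)
        v = np.sum(w * (disp - mean) ** 2, axis=0)
        if ddof:
            denom = 1.0 - np.sum(w**2)
            v = v / denom if denom > 0 else np.zeros_like(v)
    else:
        v = np.var(disp, axis=0, ddof=ddof)
    return _maybe_scalar(v, h)


def emotional_response(h, cue: Cue, config: ModelConfig, *, human_sd=None):
    """Per-cue emotional response F(S) = P(S) - alpha * V.

    The tension V is shared across cues (it is defined over the whole cue
    set), so each cue's response differs only through its marginal density.
    """
    _, log_marginal, _ = _cue_stats(h, cue, config, human_sd)
    v = perceptual_tension(h, config, human_sd=human_sd)
    return _maybe_scalar(np.exp(log_marginal) - config.alpha * np.asarray(v), h)


def combined_response(h, config: ModelConfig, *, human_sd=None):
    """Attention-weighted total response Y = beta F(S1) + (1 - beta) F(S2)."""
    if len(config.cues) != 2:
        raise UnsupportedConfigurationError(
            f"combined_response requires exactly 2 cues, got {len(config.cues)}"
        )
    h_arr = np.asarray(h, dtype=float)
    v = perceptual_tension(h_arr, config, human_sd=human_sd)
    f = [
        np.exp(_cue_stats(h_arr, cue, config, human_sd)[1]) - config.alpha * v
        for cue in config.cues
    ]
    return _maybe_scalar(config.beta * f[0] + (1.0 - config.beta) * f[1], h)


def response_curve(config: ModelConfig, grid: Sequence[float]) -> ResponseCurve:
    """Evaluate V, per-cue F and Y at every grid point."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-D array")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    v = np.atleast_1d(perceptual_tension(grid, config))
    per_cue = np.stack(
        [
            np.exp(_cue_stats(grid, cue, config)[1]) - config.alpha * v
            for cue in config.cues
        ]
    )
    if len(config.cues) == 2:
        y = config.beta * per_cue[0] + (1.0 - config.beta) * per_cue[1]
    else:
        y = np.mean(per_cue, axis=0)
    return ResponseCurve(grid=grid, Y=y, per_cue_F=per_cue, V=v)
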