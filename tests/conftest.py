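import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from uncanny import Category, Cue, ModelConfig, load_config


@pytest.fixture(scope="session")
def typical():
    model, _ = load_config("typical")
    return model


@pytest.fixture(scope="session")
def asd():
    model, _ = load_config("asd")
    return model


@pytest.fixture
def single_category():
    return ModelConfig(
        categories=(Category(mean=0.5, sd=0.5, prior=1.0),),
        cues=(Cue(sigma_s=0.2, label="S1"), Cue(sigma_s=0.05, label="S2")),
        human_index=0,
    )


def mixture_pdf(x, config: ModelConfig):
    """Latent-humanness prior density: the prior-weighted category mixture."""
    return sum(
        c.prior * norm.pdf(x, c.mean, c.sd) for c in config.categories
    )


def quadrature_posterior_mean(s, sigma_s, config: ModelConfig):
    """Posterior mean E[H | S] computed by direct numerical integration over
    the generative model H ~ mixture, S = H + N(0, sigma_s^2).

    Independent of the closed-form shrinkage implementation.
    """
    anchors = sorted(c.mean for c in config.categories)

    def joint(h):
        return mixture_pdf(h, config) * norm.pdf(s, h, sigma_s)

    kwargs = dict(points=anchors, limit=200, epsabs=1e-13, epsrel=1e-11)
    num, _ = quad(lambda h: h * joint(h), -6.0, 7.0, **kwargs)
    den, _ = quad(joint, -6.0, 7.0, **kwargs)
    return num / den


def quadrature_category_posterior(s, sigma_s, config: ModelConfig):
    """P(C_j | S) by integrating the generative model within each category."""
    kwargs = dict(limit=200, epsabs=1e-13, epsrel=1e-11)
    terms = []
    for c in config.categories:
        val, _ = quad(
            lambda h: c.prior * norm.pdf(h, c.mean, c.sd) * norm.pdf(s, h, sigma_s),
            c.mean - 10 * c.sd - 5 * sigma_s,
            c.mean + 10 * c.sd + 5 * sigma_s,
            **kwargs,
        )
        terms.append(val)
    terms = np.array(terms)
    return terms / terms.sum()
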