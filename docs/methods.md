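# Methods

## Model

Perception of an artificial agent is cast as Bayesian inference over a
latent humanness variable H on a one-dimensional axis (0 machine-like,
1 fully human). The prior over H is a two-component Gaussian mixture —
a broad *background* category and a narrow *human* category — and a
physical stimulus of human-likeness h is observed through cues
S_i = H + N(0, σ_si²) of differing reliability. For a Gaussian mixture
the posterior mean is available in closed form: each category shrinks h
toward its own mean by σ_cj²/(σ_cj² + σ_si²), and the shrunken values
are mixed by the category posterior P(C_j | S_i), whose likelihood is
N(h; μ_cj, σ_cj² + σ_si²). The displacement D(S_i) = E[H | S_i] − h is
the perceptual-magnet distortion: near a narrow category it points
toward the category center, near the boundary between categories it
changes sign sharply.

Two cues with different noise levels are displaced by different amounts
at the same h. The across-cue variance of the displacements, V, measures
this conflict ("perceptual tension"). The emotional response through cue
i is F(S_i) = P(S_i) − α·V — the familiarity of the stimulus (its
mixture density) penalized by scaled tension — and the total response is
the attention-weighted sum Y = β·F(S_1) + (1 − β)·F(S_2). F mixes a
probability density with a scaled variance; the units clash is part of
the model's definition and is reproduced as such, with no
renormalization. Near the narrow human category the tension term wins
and Y dips below zero (the valley); at the category center the
displacements vanish, tension collapses and the density peak produces
the recovery. Shifting the human-category mean beyond the physical
range (μ_c2 = 1.25) pushes the recovery outside [0, 1]: a cliff.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| μ_c1, σ_c1 | 0.5, 0.5 | background-category center and width |
| μ_c2, σ_c2 | 1.0 (typical) / 1.25 (ASD), 0.05 | human-category center and width |
| P(C_1), P(C_2) | 0.5, 0.5 | category priors |
| σ_s1, σ_s2 | 0.2, 0.05 | cue noise (broad vs reliable channel) |
| α | 150 | sensitivity to perceptual conflict |
| β | 0.5 | attention weight on the noisy cue |
| δ | 0.1 | learning scale; per-trial rate γ = δ·Y |
| K | 500 | learning trials |
| variance floor | 1e-6 | lower clamp on the learned variance |

All quantities are in human-likeness units (the axis is dimensionless).
Stimulus grids default to [0, 1] with step 0.005 for response curves
(fine enough to localize extrema within half a step) and step 0.01 for
presented-stimulus sweeps.

## Tension normalization

The across-cue variance that defines V is computed, by default, as the
*sample* variance of the displacement set — for two cues
(D_1 − D_2)²/2 — rather than the population variance (D_1 − D_2)²/4
(`tension_ddof=0` selects the latter; for two cues at β = 0.5 the choice
is equivalent to doubling α). The sample normalization is what standard
numerical environments compute for a variance over a small set, and it
is the reading under which the package reproduces the published
benchmarks for this model family: the initial response curve's zero
crossings sit near 0.54 and 0.80 (typical condition), which in turn
places the effective therapy band at 0.25–0.5 (typical) and 0.5–0.8
(ASD). Under the population normalization the valley is half as deep,
the zero crossings move to ≈0.64/0.87, and the effective bands end
≈0.1 too high. Both variants are first-class; only the default differs.
An optional β-weighted tension (weights β, 1 − β instead of equal) is
exposed as well; at the default β = 0.5 it is identical to the
equal-weight form.

## Learning rule

The human-category variance is updated once per trial:

σ²(k+1) = σ²(k) + γ·P(C₂|S_p)·[(S_p − μ_c2)² − σ²(k)]

with γ = δ·Y(S_p) and P(C₂|S_p) = β·P(C₂|S₁) + (1 − β)·P(C₂|S₂), both
re-evaluated each trial at the current variance, so the response curve
itself evolves during learning (post-learning curves at successive
checkpoints differ, which requires this feedback). Only σ_c2 learns;
means, priors and cue noises are fixed. When γ·P ∈ (0, 1) the update is
a contraction toward the attractor (S_p − μ_c2)²; when Y < 0 the rule
runs backwards, away from the attractor, which drives the variance to
the floor (default 1e-6, preserving a valid Gaussian — the rule as
written can cross zero). The dynamics are deterministic; a `seed`
parameter is accepted and ignored so that calling code can treat the
simulator uniformly.

Within a trial the order is: evaluate P, Y, γ at state k, then step to
state k+1. Traces record K+1 entries (index 0 is the pre-learning
state); the rate/posterior/response recorded at index k are the values
that produced state k+1, with the final entry being the terminal-state
evaluation. Sweeps over many presented stimuli advance all trajectories
as one vectorized batch, which is algebraically identical to running
them one at a time (verified bit-for-bit in the tests).

## Effective interval

The band of presented stimuli that "works" is read off the terminal
variances of a sweep. The dynamics are effectively bistable: either the
positive feedback (larger variance → larger P(C₂|S_p) → faster growth)
carries the variance to its attractor within the 500 trials — a change
of order 0.1–0.5 — or learning stalls and the variance drifts by a few
percent at most (every stimulus induces *some* drift, so a
small-relative-change criterion degenerates to the whole axis).
The default criterion is therefore an absolute one:
|σ²(K) − σ²(0)| > 0.05, i.e. the category SD reshapes by ≳0.2 on the
unit stimulus axis. Because the runaway transition is steep, the
detected endpoints move by at most ±0.03 as the threshold varies over
0.03–0.10. A relative criterion (|σ²(K) − σ²(0)|/σ²(0) > threshold) is
available as an option. If several disjoint regions qualify, the widest
is returned and the multiplicity flagged; endpoints are snapped to two
decimals for comparability with published ranges.

With the defaults the intervals come out as [0.25, 0.52] (typical) and
[0.46, 0.80] (ASD). Within each band the terminal variance is largest
near the lower endpoint — a distant stimulus has a large squared offset
to learn — and declines toward the upper endpoint.

## Numerical choices

Likelihoods are evaluated in log space and posteriors via
log-sum-exp: with σ_c2 = 0.05 the human-category density underflows
linearly a short distance from its mean, while the log-space posterior
stays exact. An underflow error is raised only if *every* category's
log-likelihood is −∞ at some h (unreachable for finite inputs).
Response curves are pure functions of the configuration and grid;
repeated evaluation is bit-identical. Validation is strict at
construction time (σ_c > 0, σ_s ≥ 0, priors summing to 1, β ∈ [0, 1],
α ≥ 0, δ ≥ 0, K ≥ 1, floor > 0); the presented stimulus is only
required to be finite, since fixed-point configurations of interest can
lie outside [0, 1].

## Scope and limitations

The package simulates the model, not people: it makes no claims about
children with ASD, and the ASD condition is nothing more than a
rightward shift of the human-category mean. There is no fitting of
parameters to behavioral data, no stimulus rendering, and no
alternative uncanny-valley models. The tests exercise closed-form
limits, quadrature oracles for the Bayesian core, structural properties
of the learning dynamics, and reproduction of the model's published
response-curve morphology and effective intervals — they show the
implementation is faithful to the model, not that the model is faithful
to human perception.
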