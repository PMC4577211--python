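# uncanny

A Bayesian categorical-perception model of the **uncanny valley** effect,
with a deterministic learning rule that simulates how repeated exposure to
a robot of fixed human-likeness reshapes the perceiver's "human" category
— the mechanism proposed to underlie robot-assisted therapy for autism
spectrum disorder (ASD).

The package is aimed at computational-psychiatry and human–robot
interaction researchers who want to evaluate the model's response curves,
sweep its parameters, and rerun the therapy simulations exactly.

## The model

Stimuli live on a one-dimensional human-likeness axis *h* (0 =
machine-like, 1 = fully human). Perception uses two Gaussian categories,
a broad *background* category C₁ ~ N(μ_c1, σ_c1²) and a narrow *human*
category C₂ ~ N(μ_c2, σ_c2²), observed through two cues S₁, S₂ with
measurement noise σ_s1 > σ_s2. For each cue:

- likelihood: P(Sᵢ | Cⱼ) = N(h; μ_cj, σ_cj² + σ_si²), posterior by Bayes'
  rule with priors P(Cⱼ);
- perceptual magnet: E[H | Sᵢ] = Σⱼ P(Cⱼ | Sᵢ) · (σ_cj² h + σ_si² μ_cj) / (σ_cj² + σ_si²),
  and displacement D(Sᵢ) = E[H | Sᵢ] − h;
- perceptual tension V = Var across cues of D(Sᵢ) (for two cues
  (D₁ − D₂)²/2; see `docs/methods.md` for the normalization choice);
- emotional response F(Sᵢ) = P(Sᵢ) − α·V, combined as
  Y = β·F(S₁) + (1 − β)·F(S₂).

With the default parameters (μ_c1 = 0.5, σ_c1 = 0.5, μ_c2 = 1.0,
σ_c2 = 0.05, σ_s1 = 0.2, σ_s2 = 0.05, α = 150, β = 0.5) the curve Y(h)
dips sharply below zero before μ_c2 and recovers near h = 1 — the uncanny
valley. Shifting the human-category mean right (μ_c2 = 1.25, the ASD
condition) turns the valley into a **cliff**: the response stays negative
at h = 1.

Therapy is modelled as iterative learning of the human-category variance
driven by a presented stimulus S_p:

σ²(k+1) = σ²(k) + γ · P(C₂|S_p) · [(S_p − μ_c2)² − σ²(k)],  γ = δ·Y(S₁,S₂),

with γ and the combined posterior P(C₂|S_p) = β·P(C₂|S₁) + (1−β)·P(C₂|S₂)
re-evaluated every trial at the current variance. Positive emotional
responses foster learning; negative responses inhibit it. The model is
fully deterministic.

## Worked example

```python
import numpy as np
import uncanny as u

model, learn = u.load_config("typical")        # or "asd", a file, or None
grid = u.stimulus_grid()                       # [0, 1] step 0.005

curve = u.response_curve(model, grid)
inner = (grid > 0.5) & (grid < 1.0)
i = np.argmin(curve.Y[inner])
print(f"valley minimum: Y({grid[inner][i]:.3f}) = {curve.Y[inner][i]:.3f}")
print(f"recovery peak:  Y({grid[np.argmax(curve.Y)]:.3f}) = {curve.Y.max():.3f}")

trace = u.run_therapy(model, u.LearningConfig(presented_stimulus=0.4))
print(f"human-category variance: {trace.variance[0]:.4f} -> "
      f"{trace.terminal_variance:.4f} after {learn.n_trials} trials")

sweep = u.therapy_sweep(u.sp_grid(), model,
                        u.LearningConfig(presented_stimulus=0.0))
print("effective interval:", u.effective_interval(sweep))
```

This prints:

```
valley minimum: Y(0.705) = -0.685
recovery peak:  Y(0.995) = 2.124
human-category variance: 0.0025 -> 0.3589 after 500 trials
effective interval: EffectiveInterval(lower=0.25, upper=0.52, criterion='|var_K - var_0| > 0.05', n_regions=1)
```

Reading: the typical observer's response collapses to −0.685 at
h ≈ 0.70 (the valley) and recovers to 2.124 just below full humanness.
Presenting a robot of human-likeness 0.4 for 500 trials expands the
human-category variance from 0.0025 to 0.359 ≈ (0.4 − 1)², the rule's
attractor — the category learns to cover the robot. Sweeping the
presented stimulus shows that only robots in roughly [0.25, 0.5]
(typical condition) reshape the category at all; in the ASD condition
the effective band is roughly [0.5, 0.8], i.e. stimuli that fall *into*
the typical observer's valley.

## Command line

```bash
uncanny curve -c typical -o out/            # response curve CSV
uncanny sweep-mu -o out/                    # valley -> cliff transition
uncanny therapy -c asd --set sp=0.7 -o out/ # one simulation + checkpoints
uncanny sweep-sp -c asd -o out/             # terminal variances + interval
uncanny reproduce-all -o out/ --plot        # everything, both conditions
```

Configs resolve defaults → `-c` file/preset → `--set key=value`
overrides; every run writes a manifest with a config digest, and curves
serialize as CSV with header `h,V,F_S1,F_S2,Y`.

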