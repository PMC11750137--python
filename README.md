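# probswitch

Behavioral and neural analysis of the mouse two-port probabilistic
switching task: task simulation, trial-history statistics, a recursive
logistic-regression choice model, frequency-modulated fiber-photometry
demodulation, and a time-shifted kernel GLM linking task events to the
photometry signal — with a synthetic-data generator providing ground truth
for every stage.

## The problem

In the switching task a water-restricted mouse chooses between two side
ports that pay probabilistically (e.g. 90% vs 10%); after 50 earned
rewards the probabilities swap sides without a cue. Analyzing such an
experiment requires a stack of connected methods:

- **Behavior.** Block-transition-aligned p(high port) and p(switch)
  curves; the recovery time constant τ_p(high port) from an exponential
  fit p(t) = A − B·e^{−t/τ} to the first 20 post-transition trials;
  switch probabilities conditioned on two-trial history words; session
  summaries and stable-performance criteria.
- **Choice model (RFLR).** With choices c ∈ {+1 left, −1 right} and
  rewards r ∈ {0, 1}:

      φ_{t+1} = c_t r_t + e^{−1/τ} φ_t,
      ψ_{t+1} = α c_t + β φ_{t+1},   P(left) = σ(ψ_{t+1})

  α = perseveration, β = evidence weight, τ = evidence decay (trials).
  Fit by maximum likelihood (SGD with analytic gradients; L-BFGS
  cross-check). Psychometric curves bin ψ into 13 quantile bins and are
  compared across conditions with an extra sum-of-squares F-test.
- **Photometry.** Two excitation LEDs amplitude-modulated at 167 Hz
  (signal) and 223 Hz (static control), one detector at 2000 Hz.
  Demodulation: Hamming windows of 216 samples, hop 108 (54 ms frames),
  spectral power averaged over an 8 Hz band around the carrier, then a
  1 min rolling z-score. Peri-event tensors and 500 ms window means,
  split ipsi/contra and rewarded/unrewarded.
- **Kernel GLM.** Ten binary event predictors × 41 time shifts (T = 20,
  54 ms each; 410 columns), trial-windowed rows with boundary frames
  duplicated, ridge cost ‖y − Xβ‖² + α‖β‖² (α = 1, intercept
  unpenalized), group-shuffle-split cross-validation by trial, and a
  10-variant variable-omission battery (−Rew, −Direction, …).

## Worked example

Simulate an RFLR cohort, compute transition metrics, and refit the model:

```bash
probswitch simulate --agent rflr --alpha 1.0 --beta 2.0 --tau 1.4 \
    --n-mice 6 --sessions-per-mouse 2 --n-trials 500 --seed 3 --out sessions.csv
probswitch metrics --sessions sessions.csv --out metrics/
probswitch fit-rflr --sessions sessions.csv --seed 0 --out params.json
```

which prints

```
wrote 6000 trials to sessions.csv
tau_p(high port) = 9.061 trials; max p(switch) = 0.140
alpha=1.069 beta=1.719 tau=1.750 nll=0.1221
```

The metrics line says p(high port) recovers after a block flip with a
~9-trial time constant and that switching peaks at 0.14 within the 20
trials after the flip. The refit recovers the generating parameters
(α=1, β=2, τ=1.4) up to the sampling error of a 6,000-trial cohort (the
pooled maximum-likelihood optimum on this dataset is α=1.04, β=1.85,
τ=1.64); at the 20,000-trial scale the acceptance script uses, each
parameter lands within ±10%. The mean per-trial negative log-likelihood
is 0.122 nats.

The same flow in Python, including photometry and the GLM:

```python
from probswitch import synth, photometry, glm
from probswitch.task import TaskConfig

spec = synth.TruthSpec(task=TaskConfig(n_trials=350))
cohort = synth.generate_cohort(spec, n_mice=3, sessions_per_mouse=1, seed=1)
fit, design = synth.fit_cohort_glm(cohort, alpha=1.0)
print(synth.kernel_recovery(cohort, fit))   # per-predictor correlations ~0.96-1.0
```

## Repository layout

- `src/probswitch/` — the library: `task`, `behavior`, `rflr`,
  `photometry`, `glm`, `synth`, `io`, `cli`.
- `analysis/01…07_*.py` — numbered drivers that run the full analysis on
  simulated cohorts and write tables under `results/`.
- `tests/` — unit, property and end-to-end tests (all fixtures are
  generated programmatically).
- `docs/methods.md` — models, parameter defaults, numerical choices, and
  what the synthetic benchmark does and does not demonstrate.

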