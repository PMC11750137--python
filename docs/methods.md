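# Methods

This note documents the models, numerical choices, and the synthetic-data
conditions behind `probswitch`. It is the place to look when a default
seems arbitrary or a test seems oddly specific.

## Task model

The simulator implements a two-port probabilistic switching task. Each
trial: center-port entry (CE) and exit (CX), a side-port choice (SE), a
first lick (FL) at which the outcome is revealed, and side-port exit (SX).
The chosen port pays with its current probability — `p_high` on the "high"
side, `p_low` on the other (90/10 means 0.9 and 0.1; the two need not sum
to 1). Rewards are independent Bernoulli draws per choice; the unchosen
port keeps no latent state (no baiting). After `rewards_per_block`
(default 50) rewards are earned within a block, the probabilities swap
sides with no cue. Sides are coded left = +1, right = −1 throughout, so
positive choice log-odds mean "left".

Event latencies are log-normal per segment, with defaults chosen once to
give: a quick center poke (~0.25 s), ~0.55 s travel to the side port,
~0.3 s to first lick, ~1.1 s of lick/consumption occupancy before exit on
rewarded trials and a fast (~0.2 s) exit on unrewarded ones. The median
rewarded trial is 2–3 s. Draws are clipped at 7 s so the 8 s side-poke
deadline can never be violated; aborted/timed-out trials are not modeled.
The inter-trial interval is `min_iti` (1 s) plus a log-normal excess.

A caveat on transition-aligned curves: the last trial of a block is
rewarded *by definition* (it delivers the block's final reward), and
rewarded trials concentrate on the high port. p(high port) at offsets just
before a transition is therefore inflated by selection even for a
history-blind agent; tests and interpretations should condition on
post-transition offsets.

## Choice model (RFLR)

The recursively formulated logistic regression predicts the next choice
from a decaying evidence trace:

    φ_{t+1} = c_t · r_t + e^{−1/τ} · φ_t
    ψ_{t+1} = α · c_t + β · φ_{t+1},    P(c_{t+1} = left) = σ(ψ_{t+1})

with c ∈ {+1, −1}, r ∈ {0, 1}. α is a perseveration weight, β the
evidence weight, τ (trials) the evidence decay constant. φ starts at 0;
the first trial has no prediction and is excluded from the likelihood;
predicted probabilities are clamped to [1e−12, 1−1e−12].

Fitting is maximum likelihood by stochastic gradient descent: one session
per mini-batch, learning rate 0.5 decaying as 1/√epoch, 500 epochs, τ
optimized as log τ so it stays positive. Gradients are analytic; the φ
recursion and its λ-derivative are evaluated with an IIR filter
(`scipy.signal.lfilter`), so a fit on 20,000 trials takes ~2 s. The
learning rate and epoch count were set so that SGD reaches the same
optimum as L-BFGS on the pooled objective (the package exposes
`method="lbfgs"` as a cross-check): with a substantially smaller rate or
budget the iterate stalls on the correlated β–τ ridge short of the MLE.
Parameter recovery on simulated agents (α=1, β=2, τ=1.4; 20 sessions ×
1000 trials) is within ±10% per parameter.

Psychometric curves bin teacher-forced log-odds into 13 equal-count
(quantile) bins and fit p = σ((ψ − m)/s) by least squares on the binned
points; smaller s = steeper. Groups of curves are compared with the extra
sum-of-squares F-test (shared vs per-curve fits). Degenerate duplicate
bin edges are merged with a warning.

## Photometry

Two LEDs are amplitude modulated at 167 Hz (signal) and 223 Hz (static
control) and summed on one detector sampled at 2000 Hz. Demodulation is
short-time spectral power: Hamming windows of 216 samples with 108-sample
hop (frame period exactly 54 ms), the DFT evaluated by direct
complex-exponential projection at 1 Hz-spaced frequencies across an 8 Hz
band centered on the carrier (the native FFT resolution 2000/216 Hz is
not 1 Hz, so FFT-bin rounding would be wrong), power averaged over the
band and normalized by window energy. The result is detrended with a
rolling z-score over 60 s (1111 frames), centered, with truncated edge
windows and the local σ floored at 1e−12. Absolute power units are
irrelevant after z-scoring; the full chain is invariant to detector gain.

An optional `predetrend_raw` flag applies a 60 s rolling z-score to the
raw modulated trace before demodulation. It is off by default: with two
independently modulated carriers on one detector, a shared raw-level
normalization couples the channels' envelopes, which would contaminate
the control channel; on recordings whose raw variance is dominated by the
(ligand-independent) modulation itself the step is harmless and removes
bleaching early.

Two properties of this chain matter for interpretation:

- The envelope response of the power estimate is the normalized squared
  Hamming window (~108 ms wide), which smooths transients and leaks one
  to two frames acausally. Kernel-recovery comparisons therefore use the
  generating kernel *projected* through this response (plus a one-frame
  box for sub-frame event-timing jitter).
- The rolling z-score's local mean and σ track the trial structure over
  the 60 s window. This is a mild nonlinearity: on noise-free synthetic
  data it limits kernel-recovery correlation to ~0.99 rather than 1.0,
  and it is the dominant chain distortion. A constant-envelope channel is
  mapped by the z-score to unit-scale windowed ripple (the ripple of the
  spectral estimator itself), so "null channel" contracts are stated as
  pre-z-score power constancy plus absence of event-locked structure,
  not as a literally zero trace.

Event alignment snaps each timestamp to the nearest frame center (ties to
the earlier frame); snippets are labeled ipsi/contra relative to the
configured recording hemisphere and by outcome. Scalar responses are the
mean over frames with centers in (0, 500] ms after the event — exactly 9
frames on the 54 ms grid — aggregated per mouse, then across mice.

## Kernel GLM

Ten binary predictors on the frame grid — CE/CX/SE/SX each split
ipsi/contra, plus Rew and Unrew — are expanded into T = 20 time shifts
forward and backward (41 lags of 54 ms, ±1.08 s), giving 410 columns for
the full model. Only trial periods are modeled: frames from `margin` = T
frames before the CE frame to T after the SX frame, so every in-trial
event has full kernel support in-window; frames shared by consecutive
trial windows are duplicated, once per trial's row group. The model is
ridge regression, J = ‖y − Xβ‖² + α‖β‖² with α = 1 and an unpenalized
intercept, solved in closed form from the normal equations (α = 0 gives
OLS; a singular OLS system falls back to the pseudo-inverse with a
warning). Neither predictors nor response are column-standardized: the
response is already z-scored and α = 1 is quoted against that scale.
Cross-validation is group shuffle split *by trial* (80/20, 10 folds;
5 folds in the omission battery), so no trial's rows straddle a split.

Omission variants: Full, −Rew (Rew+Unrew removed), −Direction
(ipsi/contra pairs collapsed to single event series with timing
preserved), −Direction&Rew, −CE/CX, −CE, −CX, −SE/SX, −SE, −SX. Column
counts follow F·(2T+1): 410 full, 246 for −Direction, etc.

Rew/Unrew predictors are placed at the side-entry frame by default, with
a config switch for first-lick placement. Note an identifiability caveat:
with SE placement, SE_ipsi + SE_contra − Rew − Unrew is an *exact* linear
dependency at every lag (the same event times partitioned two ways), so
individual kernels for those four predictors are only determined up to
that null space (ridge picks the minimum-norm split). Predictions, MSE
and the omission battery are unaffected. The synthetic generator
therefore anchors outcome transients at first lick — where the outcome is
actually revealed — and recovery analyses build predictors the same way.

## Synthetic data

`TruthSpec` holds everything the generator needs and everything recovery
is judged against: agent parameters, task config, latency distributions,
per-predictor kernels, noise, drift, carriers, and seeds. Fluorescence is
the sum of per-event transients (difference of exponentials, rise 100 ms,
decay 400 ms, causal support 21 frames so the T = 20 regression can
represent them exactly) plus AR(1) noise generated at the frame level
(coefficient 0.8, σ 0.5 z-units) and an exponential bleaching gain
(amplitude 0.3, τ 600 s) applied before modulation to exercise the
detrending path. The signal multiplies the 167 Hz carrier's amplitude
with 4% modulation depth — demodulated power is then linear in the signal
to first order, with an O(depth²) quadratic residual — and a constant
control fluorophore rides on 223 Hz; both carriers are summed as on one
detector.

Default kernel amplitudes (z-units): CE_ipsi +3.0, CE_contra −1.5,
CX_ipsi +1.5, CX_contra −1.5, SE_ipsi/SE_contra +1.5, SX_ipsi +1.5,
SX_contra +2.0, Rew −2.0, Unrew +2.5. The sign pattern mirrors the
recorded population (large ipsiversive rise at trial start, suppression
on rewarded outcomes, activation on unrewarded ones); the magnitudes are
at the large end of realistic event transients and deliberately
comparable across predictors so that per-predictor recovery is a
well-posed benchmark. A consequence worth stating plainly: the generator's
event-explained variance (GLM R² ≈ 0.7 at the default noise) is well
above what population calcium recordings typically show, so passing
kernel-recovery tests here demonstrates correctness of the estimator, not
that kernels are recoverable at real-data signal-to-noise. The generator
also does not emulate hemodynamic/motion artifacts, sensor nonlinearity,
or session-scale nonstationarity beyond monotone bleaching.

Recovery study sizes were fixed once: RFLR recovery at 20 sessions ×
1000 trials; GLM kernel recovery at 3 recorded sessions × 350 trials
(~84k design rows), at which the AR-noise floor leaves comfortable margin
over the 0.95 correlation benchmark for the smallest kernels; the
noise-free exact-grid check at one 1000-trial session (~80k rows), where
ridge (α = 1) shrinkage bias is small enough for ≥0.999 correlation and
OLS is exact to machine precision.

## Numerical details and edge cases

- Exponential recovery fits p(t) = A − B·e^{−t/τ} over the first 20
  post-transition trials (t = 1…20), initialized from the series
  endpoints, bounds τ > 0. A flat series returns B ≈ 0 flagged
  `identifiable=False` instead of raising.
- The performance-criteria check (5 consecutive sessions) uses inclusive
  mean bounds, strict variance bounds, and the population (ddof=0)
  variance over the 5 sessions: p(high) ≥ 0.80 var < 0.003, p(switch) ≤
  0.15 var < 0.001, p(left) in [0.45, 0.55] var < 0.005, ≥ 200 trials
  per session.
- History words use the alphabet {A, a, B, b}: same (A/a) or different
  (B/b) side as the reference (most recent) choice, upper case =
  rewarded, older trial first. The frequency-weighted mean of p(switch)
  over words equals the overall p(switch) identically; this identity is
  asserted in tests.
- The first trial of a session contributes no switch value and no choice
  prediction; both denominators exclude it.
- Session CSVs carry timestamps at 6 decimals; a missing first lick is an
  empty field and is accepted on any trial.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; identical (inputs, seed) give
  byte-identical outputs everywhere, including the generator.

## Known limitations

- The simulator never aborts trials; the 8 s deadline is honored by
  construction of the latency support rather than by censoring.
- The elastic-net arm of the regression comparison is not implemented;
  ridge and OLS are (ridge α = 1 is the production setting).
- Per-predictor kernel identifiability under SE-anchored outcome
  predictors is limited by the exact collinearity described above; this
  mirrors the structure of the task, not an implementation defect.
- Group-level inferential statistics (ANOVAs, post hocs) are out of
  scope; the package computes the descriptive statistics and the two
  fits (exponential recovery, psychometric F-test) they would consume.
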