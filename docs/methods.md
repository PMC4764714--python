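# Methods

## The decoding model

The analysis treats eye position as a quantity linearly decodable from a
population rate vector. Two read-out units represent the horizontal (X)
and vertical (Y) eye coordinate, in degrees, as

    X̂(t) = R(t) βX + cX ,   Ŷ(t) = R(t) βY + cY ,

with `R(t)` the time × neuron matrix of trial-averaged instantaneous
firing rates and one weight per neuron per unit. Four constraints define
the scientific claim being tested:

1. **Fixed weights across time** — the read-out is a single monosynaptic
   computation, not a decoder rebuilt per time window.
2. **Fixed weights across saccade directions** — the rightward and
   downward design matrices and targets are concatenated in time and
   fitted jointly, so only changes in population activity can move the
   output.
3. **Metric output** — the regression target is a continuous eye
   trajectory (cumulative Gaussian, amplitude 10°, transition mean
   μ = 25 ms relative to saccade onset, SD σ = 10 ms), not a class label.
4. **Cross-validation** — weights are estimated on a random half of the
   trials of each of the 10 task conditions and evaluated on the other
   half; all reported time courses are means (± SD) over repeated random
   splits.

Time-lagged variants of the target (lag −400…+400 ms in 100 ms steps,
applied to the target only, never to the neural data) probe predictive and
postdictive eye-position signals.

### Ridge dialect

Weights solve the penalized least-squares problem on the *standardized*
scale: predictors are z-scored (SD with n−1 normalization), the target is
centered, `β_std = (ZᵀZ + γI)⁻¹ Zᵀy`, and slopes are rescaled to original
units with the intercept recovered at the training mean. This matches the
default behaviour of the widely used MATLAB `ridge` routine, makes
γ comparable across populations, and leaves the intercept unpenalized (a
literal ones-column would be degenerate under standardization). γ = 30 for
all reported results. Zero-variance neuron columns are dropped with a
warning and receive zero weight. The closed-form solution is checked in
the test suite against two independent routes (scikit-learn's ridge solver
and augmented least squares) to 1e−8.

### Rate matrices

Spike times, aligned to saccade onset, are converted to instantaneous
rates with a 50 ms counting window stepped in 25 ms increments from −800
to +800 ms (65 grid points). Grid times are window *centers* and windows
are half-open `[t−w/2, t+w/2)`, so boundary spikes are counted exactly
once; the paper-style overlap (window = 2 × step) means adjacent windows
share spikes while any disjoint tiling conserves the total count. Rates
are averaged over trials within each condition and then, unweighted, over
the five initial fixation positions, giving one time × neuron matrix per
saccade direction (`R_rwd`, `R_dwd`). Random half/half splits are drawn
per condition; an odd trial count sends the extra trial to the training
side (weight-estimation stability).

### Quantifying decoded dynamics

The mean decoder outputs over cross-validation sets are fit with a
cumulative Gaussian `offset + amplitude·Φ((t−μ)/σ)` jointly over the two
saccade channels (X̂ for rightward, Ŷ for downward entering with negated
amplitude), four free parameters in total. The **achieved lag** is
μ − 25 ms; the **represented saccade duration** is the 1st–99th percentile
width 4.6527 σ, reported as a ratio to the true-saccade value (σ = 10 ms).
Initialization uses the half-range crossing for μ, σ₀ = 10 ms and plateau
medians for amplitude/offset, with four deterministic jittered restarts;
the best-SSE solution is kept. 95% confidence intervals come from the
Jacobian at the optimum (asymptotic linearization). Per-set refits fix
amplitude and offset at the mean-fit values and re-estimate only (μ, σ);
non-converging sets are flagged, not silently dropped.

Because a decoder may satisfy an early target by drifting *obliquely*
(equally in both directions) before the saccade direction is known, the
direction-specific difference (rightward − downward per channel) is fitted
with the same procedure; common drift cancels in that difference. All
signals are stored physically signed (downward = negative y); the vertical
channel is sign-flipped only when plotted.

R² is pooled: SSE and SST accumulate over both channels and both
directions before the ratio. The peri-saccadic window is ±100 ms around
the *target's* transition time (μ = 25 ms + lag), so lagged targets are
scored around their own transition.

### Weight summaries

For target lags decoded well (peri-saccadic R² > 0.75), per-set weights
are averaged first (signed), then a neuron's pooling weight is
(|βX| + |βY|)/2, normalized to unit sum over the population. Histograms
use 20 fixed-width bins on [0, max weight]. Weight modulation is
100·(max − min)/mean per neuron across admitted lags; cross-lag
consistency is the Pearson correlation of the neuron-contribution vectors
for every lag pair (mean ± SE over pairs). All three summaries are
invariant to a global rescaling of the raw weights.

### PCA of direction-specific dynamics

The differential time course `D = R_dwd − R_rwd` isolates
direction-dependent modulation. Columns (neurons) are mean-centered over
time — this removes tonic direction-independent offsets and is the package
default; z-scoring is exposed as a flag but off by default — and the
time × time covariance is eigendecomposed (via SVD). Component sign is
fixed so each component's largest-magnitude element is positive. Bootstrap
standard errors resample neurons with replacement; each replicate's
components are aligned to the full-sample components by greedy matching on
|correlation| with sign flip before the pointwise SD is taken.

## The synthetic population generator

No recordings ship with the package; the generator emulates the study
design the analysis assumes. The task: fixation, then a 10° step of the
fixation target either rightward or downward, from five initial positions
arranged like the 5-face of a die ([0,0], [±10,±10]); ≥ 6 (default 20)
trials per condition; eye trajectory a cumulative Gaussian (μ = 25 ms,
σ = 10 ms). Sessions are emitted already aligned to saccade onset over
−900…+900 ms; saccade detection, visual latency to the cue and behavioural
errors are not simulated.

Each neuron's intensity is a rectified linear sum

    λ(t) = max(0, baseline + gx·x(t−Δ) + gy·y(t−Δ)
                 + Σc amp[c,dir]·φc(t−Δt) + burst·ψ(t))

with a tonic gain field read at the neuron's own temporal offset Δ
(uniform on −100…+200 ms; negative = predictive), a direction-specific
transient complex at its own offset Δt (uniform on −150…+250 ms), and a
direction-nonspecific Gaussian bump ψ locked to the saccade. The transient
basis φc comprises four unit shapes: a smooth **plateau** rising near
−100 ms and decaying by +150 ms, a **biphasic** derivative-of-Gaussian
(width 18 ms), a sustained pre→post **step** tracking the eye trajectory's
pace (σ = 10 ms), and a narrow **burst** (σ = 12 ms) favouring one
direction over the other. Spikes are drawn per trial from an inhomogeneous
Poisson process by thinning a piecewise-linear intensity on a 1 ms
lattice, with one spawned random stream per trial so trial subsets are
reproducible.

Default parameter distributions (per neuron): baseline U[10, 40] spk/s;
gain-field slopes N(0, 1) spk/s/°; plateau, biphasic, step and burst
amplitudes N(0, 5), N(0, 30), N(0, 10) and N(0, 30) spk/s per direction;
nonspecific bump U[0, 6] spk/s. Two considerations set these scales.
First, signal-to-noise: after averaging ~50 trials per direction the
Poisson standard error of a 50 ms rate estimate is ~3 spk/s, so gain-field
steps (~10 spk/s) and transients must sit well above it, as recorded
neurons do. Second, variance composition: in recorded samples nearly every
neuron modulates strongly around saccades — often more strongly than its
tonic gain field — so the direction-specific variance budget is dominated
by the sharp transient shapes at diverse latencies. That latency-diverse
sharp structure is what lets a shrinkage-regularized read-out place a
fast transition at any time in the decodable band; populations built from
slow or latency-locked shapes support the band's lags only with badly
smeared transitions. The transient-latency span is slightly wider than
the tonic band so edge lags keep full coverage.

The generator stores its ground-truth parameters in the session, so
decoding results can be scored against truth.

### What the generator does not emulate

Rate models are conditionally Poisson and trial-independent: no shared
(correlated) variability, no spike-history effects, no multiplexed visual,
motor-preparatory, attentional or reward signals, no slow nonstationarity.
Transients are draws from four fixed shapes rather than the unconstrained
diversity of real cells, and tonic gain fields are linear and planar.
Passing tests therefore show that the *pipeline* recovers what this model
family contains — they do not certify performance on recorded data, where
correlated noise in particular can reduce the effective information.

## Problem sizes and numerical choices

Simulated analyses use 100 neurons, 20 trials per condition and 50
cross-validation sets — large enough that condition averages are stable
and the cross-validation SD is meaningful, small enough that the full test
suite and acceptance run complete in seconds. The bootstrap default in the
end-to-end pipeline is 200 resamples (1000 for publication-grade SEs).
Ties, degenerate inputs and failure modes are signalled explicitly:
zero-variance predictors (dropped, warned), empty conditions, spans
outside the session, σ ≤ 0 targets, zero-variance R² targets, per-set
sigmoid non-convergence, and lags with no admissible R².

## Known limitations

* Under the default conditions the decoded transition is systematically
  broader than the target: the lag sweep recovers in-band achieved lags to
  within one grid step with peri-saccadic R² ≥ 0.95, but the represented
  saccade duration runs 2–4× the true 46.5 ms (the ratio degrades further,
  >2 with grossly displaced transitions, outside the band). This
  broadening is a joint property of the 50 ms counting window, the
  shrinkage penalty acting on a unit-variance (standardized) design, and
  the latency spread the band coverage requires: sharpening the output
  requires weight patterns whose design-matrix eigenvalues are comparable
  to γ, so γ = 30 smooths them; γ → 0 recovers σ = 10 ms exactly on
  noise-free rates. Real recorded populations evidently carry sharper,
  higher-SNR saccade-locked structure than this rate-model family
  provides.
* The inter-target correlation statistic depends on the assumed analysis
  window; the reported value uses the full −800…+800 ms grid, where the
  shared fixation epochs dominate.
* Confidence intervals for (μ, σ) are asymptotic (Jacobian-based); for
  strongly non-Gaussian per-set distributions the per-set refit spread is
  the more faithful uncertainty.
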