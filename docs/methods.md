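# Methods

## The reduced spine model

Each axon synapses 10 times on neighbouring spines of one dendritic
branch; the group is scored as a unit.  The full cable/Hodgkin–Huxley
biophysics is replaced by closed-form per-spine dynamics that keep only
the ingredients the computation needs:

- **Voltage.** `V(t) = V_rest + BAP(t) + EPSP(t) + η(t)`.  The BAP
  waveform is a difference of exponentials (rise 0.2 ms, decay 2 ms,
  60 mV peak at the spine) placed at each spine-local arrival time; the
  EPSP likewise (rise 0.5 ms, decay 5 ms, 0.9 mV per synapse × 10
  co-located synapses) at each presynaptic spike.  `η` is
  Ornstein–Uhlenbeck membrane noise (SD 4 mV, correlation time 5 ms).
- **Coincidence gate.** A glutamate-bound NMDA fraction rises and decays
  per presynaptic spike (rise 6.2 ms, decay 12 ms, saturating at 1) and is
  multiplied by the standard extracellular-Mg block sigmoid
  `1 / (1 + [Mg]/3.57 · exp(−0.062 V))` with [Mg] = 1 mM.
- **Calcium.** Influx proportional to the gated fraction, first-order
  clearance with τ = 6 ms.  Units are arbitrary: only ratios and
  threshold-normalized scores are meaningful.
- **Detector.** The similarity score is `∫ [Ca²⁺]⁴ dt`, emulating a
  four-site calcium sensor (calmodulin-like): the fourth power suppresses
  the small calcium leak that membrane noise admits through partially
  unblocked NMDA receptors, while sharpening genuine coincidence events.

Integration uses exponential-Euler factors at dt = 0.1 ms; every per-step
update is a one-pole linear filter or a pointwise map, so thousands of
spines are simulated as `(traces × time)` arrays.  The BAP voltage
waveform within one run is computed once and time-shifted per spine group
by its propagation latency (exact on the step grid).  Each trace draws its
noise from its own child seed stream, making results independent of how
traces are batched.  Requesting a step coarser than 0.5 ms is an error
(the waveform kernels would be undersampled).

### Gate kinetics are effective, calibrated constants

The surrogate's coincidence gate stands in for several processes at once
(glutamate binding and unbinding, channel kinetics, BAP broadening along
the dendrite, spine electrical filtering).  Its two time constants, the
calcium clearance and the noise SD were therefore treated as the model's
free parameters and calibrated once against the full model's printed
observables: the optimal pre-before-BAP lead of 7 ms, the
true-positive-rate table over match windows (45/82/98%), and the graded
effect of 1–2 ms spike jitter.  Textbook NMDA deactivation (tens of ms)
with a ~2 ms rise reproduces the 7 ms optimum only as a broad plateau: the
resulting tuning curve is so flat that millisecond jitter has no effect
and random keys earn too much partial credit.  The calibrated gate
(rise 6.2 ms, decay 12 ms) narrows the coincidence window, which both
sharpens the 7 ms optimum and restores the jitter sensitivity, at the cost
of compressing the literal receptor kinetics — an accepted distortion in a
reduced model whose job is the computation, not the channel biophysics.

## Stimulus conditions

All spike trains are Poisson with a 50 ms absolute dead time.  The
exponential-interval rate is inflated to `r/(1 − r·τ_ref)` so the
*realized* long-run rate equals the nominal 6 Hz (an uncompensated variant
is available behind a flag).  A matched key places one spike 7 ms before
each BAP arrival at its spine group; arrivals earlier than the lead are
dropped.  Jitter adds independent Gaussian shifts per spike (SD 1–2 ms),
re-sorts, and clips at the window boundaries; refractory violations after
jitter are allowed.  Match windows are 0.5, 1 or 2 s; keys and values are
temporally concatenated with a 500 ms gap.

## Kernel model and fit

The bilinear model `score ≈ Σ Σ K(t_post − t_pre)` is tabulated at 1 ms
on ±60 ms and multiplied by a fixed double-sigmoid envelope that is ≈1
inside ±30 ms and decays exponentially (τ = 10 ms) outside; the envelope
is applied inside the forward model, so only the interior is effectively
fitted.  Because the model is linear in the tabulated heights, the
least-squares optimum is found by a direct linear solve (the same minimum
gradient descent would reach).  The fit dataset is 100 simulations × 150
axons (one matched) on 1 s windows; the train/test split is 85/15 **by
simulation**, so shared query trains cannot leak across the split.
Scores more than 4 SD above the mean are removed within each split before
fitting (one pass, no iteration); in practice this removes ≈0.7% of
scores, almost all of them matched-axon scores, mirroring the full model's
0.5–0.6% outlier rate.

## Threshold calibration and detection

The potentiation threshold is the empirical 0.9 quantile (linear
interpolation between order statistics) of the per-run *maximum* score
over 149 null spine groups, estimated from 500 null-only runs; fewer than
50 runs is an error unless explicitly allowed.  Scores are reported
normalized by the threshold (1 = potentiation).  True-positive rates use
independent matched-run batches (calibration and evaluation draw from
disjoint seed streams); the false-positive rate is always family-wise
(any null group crossing).  The ROC sweeps the threshold over all observed
scores.

Paired designs (common random numbers) are used where only differences
matter: the offset sweep evaluates every offset on the same query trains
and noise streams, and the jitter study scores jittered and unjittered
matched trains on the same runs.  Each condition's mean is unbiased;
only the between-condition variance is removed.

## Control phase

The normalized score maps to a target potentiation factor through a
sigmoid with floor 1, ceiling 8, center 0.92 and width 0.03 (normalized
units) — chosen to satisfy the two anchors the full model states: baseline
1 at low scores and ×8 at the threshold.  The realized factor lags the
target as a first-order low-pass with τ = 500 ms, starting at 1.

Transmission is an all-or-none relay: an axon whose factor is ≥ 6 at a
value-spike time elicits a somatic spike after a 3 ms latency with
probability 0.95, subject to a 5 ms somatic refractory period.
Sub-threshold axons do not transmit; membrane noise contributes spurious
somatic spikes as a homogeneous Poisson process at 0.05 Hz per mV of noise
SD (0.2 Hz at the default 4 mV).  These transmission constants are free
parameters of the reduced relay, set so that successful-spike percentages
land in the full model's range; all are exposed in the configuration.
With continued potentiation enabled, every somatic spike that follows an
axon's value spike within 20 ms increments that axon's score by 0.25
normalized units, so weak matches keep potentiating during control.

A matched value spike is **successful** if a somatic spike follows within
20 ms; somatic spikes are claimed greedily one-to-one in time order (one
somatic spike cannot redeem two value spikes — the 20 ms windows are
stated by the design, the attribution rule is ours).  A somatic spike is
**spurious** if no matched value spike preceded it within 20 ms.  0/0
fractions are reported as 0 with an explicit flag.

## Attention oracle

The reference semantics of the whole mechanism is exact threshold-selected
hard attention: score keys with the kernel overlap, select all keys above
threshold (possibly none — the "recall failure" case — or several, whose
values are merged), output the union of selected values.  On noiseless
runs the set of spine groups crossing the calibrated threshold agrees with
the oracle's selected set in ≥95% of random instances; this is an
acceptance property of the build.

## Problem sizes and determinism

Default analysis sizes are 500 calibration runs per window, 1000 matched
runs per condition, a 100-simulation kernel dataset and 300 repetitions
per offset — sizes at which the stochastic quantities are stable to a few
percent while the full pipeline stays in the minutes range on one CPU.
The test suite uses further reduced sizes (300 matched runs, 30-simulation
kernel datasets) with the same conventions.  All randomness flows from one
master seed through named `SeedSequence` streams (per module, per rep);
identical configuration and seed reproduce byte-identical reports.

## What the synthetic conditions do and do not show

The generator emulates the study conditions exactly (stationary 6 Hz
refractory Poisson trains, one or two matched axons, Gaussian jitter); it
does not emulate rate fluctuations, bursting, correlated axons, synaptic
failures or depression, dendritic inhibition, or voltage-resolved
dendritic spike propagation.  Passing tests therefore validate the
computation under the stated idealized conditions, not robustness of the
mechanism in vivo.  Known limitations: calcium units are arbitrary (no
trace-amplitude comparisons); the relay rule is binary rather than
voltage-resolved, so graded dendritic-spike failures are outside scope;
and the fourth-power detector is a surrogate for what is certainly a more
complex calcium-sensing cascade.
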