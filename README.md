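# matchcontrol

A desk-scale simulator and analysis toolkit for the **match-and-control**
principle: the idea that a pyramidal-neuron-like cell can implement a
transformer-style *hard attention* lookup with spike trains and short-term
Hebbian potentiation.

- **Queries** are somatic spike trains; their back-propagating action
  potentials (BAPs) reach each dendritic spine after a propagation latency.
- **Keys** are axonal spike trains, one axon per key, each synapsing on a
  group of 10 neighbouring spines (150 axons, 1500 spines).
- In the **match phase**, each spine group compares its key with the query:
  NMDA-receptor calcium only enters when glutamate binding (a presynaptic
  spike) coincides with depolarization (a BAP).  The similarity score is the
  integral of the fourth power of spine calcium, `∫ [Ca²⁺]⁴ dt`, a
  four-binding-site detector that suppresses noise-driven calcium leaks.
- Spine groups whose score clears a calibrated threshold potentiate their
  fast synaptic conductance up to 8× (with a 500 ms lag).  In the
  **control phase** those axons drive somatic spiking, transmitting the
  **value** segment of their train: the output is the value of the best
  matching key.

The package replaces the original multi-compartment cable model with a
reduced per-spine surrogate (closed-form BAP/EPSP voltage kernels, a
saturating NMDA coincidence gate with Mg block, first-order calcium, and
Ornstein–Uhlenbeck membrane noise), which preserves the coincidence
computation while running thousands of simulations per minute on one CPU.

## The model in brief

The detector score of a spine group is well approximated by a bilinear
overlap of the two trains,

```
∫ [Ca²⁺]⁴ dt  ≈  Σ_{t_pre} Σ_{t_post} K(t_post − t_pre),
```

with a temporal kernel `K` that is fitted by least squares on a 1 ms grid
and forced to decay exponentially (τ = 10 ms) outside ±30 ms.  A delta-like
`K` would make the score the Euclidean inner product of the binned spike
trains; the fitted kernel is a temporally smeared dot product peaking where
pre spikes lead the BAP by ~7 ms.

The potentiation threshold is calibrated so that a run with 149 random
axons keeps *every* spine group below threshold 90% of the time
(family-wise null rejection); scores are normalized so 1 = threshold.

## Worked example

`examples/` contains one narrative script per capability.  For instance:

```
$ python examples/02_spine_coincidence.py
 optimal 7 ms lead: detector score 0.0140 au^4*s
       30 ms early: detector score 0.0003 au^4*s
         5 ms late: detector score 0.0002 au^4*s
 glutamate, no BAP: detector score 1.63e-04 (Mg block holds)

offset sweep (40 reps): score peaks at a 6 ms lead
```

A presynaptic spike 7 ms before the BAP drives ~50–80× more detector
signal than one 30 ms early or 5 ms late — the spine is a sharp, asymmetric
coincidence detector.  And the detection pipeline:

```
$ python examples/04_threshold_detection.py
calibrated threshold (1 s window, 100 null runs): 0.0214 au^4*s
TPR  = 77%  (matched group crosses threshold)
family-wise rejection = 90%  (target 90%)
normalized matched score: median 1.37 (1.0 = threshold)
TPR with 2 ms jitter = 69% (same runs, jittered matched spikes)
```

With a 1 s match window the matched axon is detected in roughly three
quarters of runs at this quick demonstration scale (the full 500-run
calibration puts it at ~80%), while a random axon ensemble stays fully
below threshold 90% of the time, as calibrated.

The same machinery is exactly a hard attention lookup:

```
$ python examples/06_attention_oracle.py
noiseless kernel fit: held-out r^2 = 0.996
threshold (30-axon ensembles): 0.0129
selected-set agreement over 25 instances: 96%
```

A thin CLI wraps the same drivers:
`matchctl gen-ensemble | fit-kernel | calibrate | detect | run | oracle-check`.

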