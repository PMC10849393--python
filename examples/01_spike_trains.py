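"""Generate the study's spike trains: queries, matched keys, jitter.

All activity is carried by Poisson spike trains with a 6 Hz realized rate
and a 50 ms refractory dead time.  A "matched" key fires 7 ms before each
back-propagating action potential (BAP) arrives at its spine group.
"""

import numpy as np

from matchcontrol import (
    concatenate_phases,
    jitter,
    make_matched_train,
    sample_poisson_refractory,
)

# the somatic query: what the neuron is "asking about"
query = sample_poisson_refractory(rate=6, refractory=0.05, duration=1.0, seed=1)
print(f"query: {len(query)} spikes in {query.duration} s "
      f"(realized rate {query.rate:.1f} Hz)")

# a long run shows the dead-time-compensated sampler hits the nominal rate
long_run = sample_poisson_refractory(6, 0.05, 1000.0, seed=2)
print(f"long-run realized rate: {long_run.rate:.2f} Hz (nominal 6)")

# the matched key leads each BAP arrival by 7 ms
matched = make_matched_train(query, lead=0.007)
print(f"matched key: {len(matched)} spikes, first at {matched.times[0]:.3f} s "
      f"(query's first at {query.times[0]:.3f} s)")

# jitter models imprecise axonal timing; 1 ms SD barely moves the spikes
noisy = jitter(matched, sigma=0.001, seed=3)
shift_ms = 1e3 * np.abs(noisy.times - matched.times)
print(f"after 1 ms jitter: mean |shift| = {shift_ms.mean():.2f} ms")

# key and value phases are carried by the same axon, concatenated in time
value = sample_poisson_refractory(6, 0.05, 1.0, seed=4)
axon_train = concatenate_phases(matched, value, gap=0.5)
print(f"key+value train: {len(axon_train)} spikes over {axon_train.duration} s "
      "(500 ms silent gap between phases)")
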