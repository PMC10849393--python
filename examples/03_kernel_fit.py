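"""Fit the temporal kernel: calcium entry as a smeared dot product.

The integral of calcium^4 is well approximated by a bilinear overlap
sum_{pre,post} K(t_post - t_pre).  We simulate a small dataset, fit K by
least squares (with the fixed decay envelope outside +-30 ms), and check
the fit on held-out simulations.
"""

import numpy as np

from matchcontrol import fit_kernel, generate_fit_dataset

# 20 simulations x 150 axons = 3000 (pre, post, score) triples
dataset = generate_fit_dataset(n_sims=20, seed=0)
print(f"dataset: {len(dataset)} spine-group scores "
      f"({int(dataset['matched'].sum())} from matched axons)")

kernel, report = fit_kernel(dataset, seed=1)
print(f"held-out r^2 = {report.test_r2:.2f} "
      f"(train r^2 = {report.train_r2:.2f})")
print(f"outliers removed (>4 SD): {report.n_outliers_train} train, "
      f"{report.n_outliers_test} test")

effective = kernel.values * kernel.envelope
peak = kernel.grid[int(np.argmax(effective))]
print(f"kernel peak at dt = t_post - t_pre = {peak:g} ms "
      "(pre spikes are most effective slightly before the BAP)")
half = effective > 0.5 * effective.max()
print(f"kernel half-height support: {kernel.grid[half][0]:g}..{kernel.grid[half][-1]:g} ms")
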