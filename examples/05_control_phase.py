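"""Match, potentiate, control: the full pipeline.

After the match phase, spine groups whose normalized score clears the
sigmoid potentiate (up to 8x) with a 500 ms lag; potentiated axons then
drive the soma during the control phase.  Somatic spikes are classified
against the matched axon's value train with a 20 ms window.
"""

import numpy as np

from matchcontrol import control_study
from matchcontrol.experiments import StudyDesign, calibrate

design = StudyDesign()
cal = calibrate(window=1.0, n_runs=150, design=design, seed=11)
print(f"threshold: {cal.threshold:.4f} (90% family-wise rejection)")

reports = control_study(
    n_runs=25, match_window=1.0, control_window=1.0,
    threshold=cal, design=design, seed=12,
)
succ = 100 * np.mean([r.pct_successful for r in reports])
spur = 100 * np.mean([r.pct_spurious for r in reports])
took = np.mean([max(r.final_factors) >= 6 for r in reports])
print(f"over {len(reports)} runs (1 s match window):")
print(f"  {succ:.0f}% of matched value spikes produced a somatic spike "
      "within 20 ms (successful)")
print(f"  {spur:.0f}% of somatic spikes were spurious")
print(f"  an axon reached the relay factor (>= 6x) in {100 * took:.0f}% of runs")

one = next((r for r in reports if r.n_soma_spikes > 0), reports[0])
print(f"\nexample successful run: {one.n_matched_value_spikes} matched value "
      f"spikes, {one.n_soma_spikes} somatic spikes, "
      f"success {100 * one.pct_successful:.0f}%")
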