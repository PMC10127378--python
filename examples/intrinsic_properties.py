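"""Measure passive and active properties of simulated CA1 pyramidal cells.

Generates a small control-condition cell set, runs the step protocol
(input resistance from the fitted gradient), the 0.33 pA/ms ramp
(rheobase), and a 40-s naturalistic sweep (firing rate), then prints the
group summary.  Values land near the control calibration targets
(-68 mV, 143.6 MOhm, 87 pA, 2.3 Hz).
"""

import numpy as np

from slicephys.intrinsic import summarize_cell
from slicephys.synth.dataset import calibrate_ou_gain, make_condition_dataset

gain = calibrate_ou_gain(seed=0)
ds = make_condition_dataset("control", seed=0, n_cells=5, ou_gain=gain)

rows = []
for rec in ds.cells:
    s = summarize_cell(rec.step_sweeps, rec.ramp_sweep, rec.ou_sweeps[0])
    rows.append(s)
    print(f"cell: RMP {s.rmp:6.1f} mV  Rin {s.input_resistance:5.1f} MOhm  "
          f"rheobase {s.rheobase:5.1f} pA  rate {s.firing_rate:4.2f} Hz")

print("-" * 60)
print(f"group mean RMP  {np.mean([r.rmp for r in rows]):6.1f} mV   "
      f"(depolarised cells are more excitable)")
print(f"group mean Rin  {np.mean([r.input_resistance for r in rows]):6.1f} MOhm "
      f"(higher resistance = fewer open channels)")
print(f"group mean rheobase {np.mean([r.rheobase for r in rows]):5.1f} pA   "
      f"(minimum ramp current that fires the cell)")
print(f"group mean rate {np.mean([r.firing_rate for r in rows]):5.2f} Hz   "
      f"(under the shared naturalistic drive, gain {gain:.1f})")
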