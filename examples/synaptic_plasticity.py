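"""Field-potential physiology for one simulated slice: input-output curve,
paired-pulse facilitation and LTP.

Each evoked sweep carries a stimulus artefact, fibre volley and fEPSP;
the analysis measures the slope over a 1-ms window after the volley,
builds the IO curve, computes paired-pulse ratios (template subtraction
at overlapping intervals), and quantifies LTP as the normalised slope
55-60 min after high-frequency stimulation.
"""

import numpy as np

from slicephys.fieldpot import io_curve, ltp_from_sweeps, ppf_ratio
from slicephys.synth import get_preset
from slicephys.synth.field import field_spec_from_preset, make_field_dataset

rng = np.random.default_rng(3)
preset = get_preset("csf_tau")
spec = field_spec_from_preset(preset, rng, seed=7)
ds = make_field_dataset(spec, label="csf_tau")

io = io_curve(ds.io_sweeps)
print("input-output curve (stimulus V -> fEPSP slope mV/ms):")
for _, row in io.iterrows():
    print(f"  {row.stimulus:3.1f} V  slope {row.fepsp_slope:5.3f}  "
          f"volley {row.fibre_volley_amp:5.3f} mV")

print("paired-pulse ratios (facilitation > 1 means higher release on pulse 2):")
for interval in sorted(ds.ppf_pairs):
    r = ppf_ratio(ds.ppf_pairs[interval], interval, ds.ppf_template)
    print(f"  {interval:5.0f} ms  ratio {r:4.2f}")

res = ltp_from_sweeps(ds.ltp_sweeps, ds.ltp_times_min, ds.hfs_time_min)
print(f"LTP: baseline-normalised slope 55-60 min after HFS = "
      f"{res.potentiation_55_60:.2f} (>1 means potentiated transmission)")
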