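"""Run the complete three-condition study at a reduced size.

Generates control, CSF-tau and CSF-tau-depleted datasets, runs all four
analysis blocks (intrinsic, field, mEPSC, theta) and prints the group
means with the Kruskal-Wallis omnibus p values.  The printed-group-size
run takes a few minutes; this reduced design finishes in about a minute.
"""

import json

from slicephys import PipelineConfig, run_pipeline

n = {c: {"cells": 4, "mepsc": 4, "field": 4, "osc": 4}
     for c in ("control", "csf_tau", "csf_tau_depleted")}
cfg = PipelineConfig(seed=1, n_overrides=n, mepsc_duration_s=240.0,
                     osc_baseline_s=60.0, osc_post_s=240.0,
                     theta_window_s=120.0, dynamic_iv_cells=0,
                     out="results/pipeline_report.json")
report = run_pipeline(cfg)

b = report["blocks"]
print(f"shared naturalistic-drive gain: {report['log']['ou_gain']:.1f}")
for name in ("intrinsic", "mepsc", "field", "theta"):
    print(f"block {name}: {b[name]['status']}")

g = b["intrinsic"]["groups"]
print("\nresting potential (mV) and firing rate (Hz) by condition:")
for cond, v in g.items():
    print(f"  {cond:18s} RMP {v['rmp']['mean']:6.1f} +- {v['rmp']['sem']:.1f}   "
          f"rate {v['firing_rate']['mean']:4.2f}")
print(f"  Kruskal-Wallis RMP p = {b['intrinsic']['stats']['rmp']['p']:.4f}")

m = b["mepsc"]["groups"]
print("\nmEPSC interval (s) by condition "
      "(shorter interval = higher release frequency):")
for cond, v in m.items():
    print(f"  {cond:18s} {v['interval']['mean']:6.2f}")

t = b["theta"]["groups"]
print("\npeak theta power (mV^2) by condition:")
for cond, v in t.items():
    print(f"  {cond:18s} {v['peak_theta_power']['mean']:.2e}")
print("\nfull report written to results/pipeline_report.json")
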