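"""End-to-end pipeline: generate condition datasets, run every analysis
stage, and assemble a figure-style report.

The report is a plain nested dict (JSON-serialisable) with one block per
recording modality -- intrinsic properties, field synaptic physiology
(input-output, paired-pulse, LTP), mEPSCs, and theta oscillations -- each
carrying per-condition group means with SEMs, the omnibus and post-hoc
statistics, and an audit log of every seed and threshold used.  A failing
stage marks its block ``failed`` and the remaining blocks still run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import fieldpot, mepsc, oscillations
from .dynamic_iv import fit_cell
from .intrinsic import summarize_cell
from .stats import kruskal_dunn, ks_two_sample, paired_wilcoxon, two_way_anova_io
from .synth.dataset import ConditionDataset, calibrate_ou_gain, make_condition_dataset

PRINTED_N = {
    "control": {"cells": 10, "mepsc": 6, "field": 8, "osc": 8},
    "csf_tau": {"cells": 11, "mepsc": 8, "field": 8, "osc": 8},
    "csf_tau_depleted": {"cells": 10, "mepsc": 8, "field": 8, "osc": 8},
    "csf_mock_depleted": {"cells": 8, "mepsc": 8, "field": 8, "osc": 8},
}


@dataclass
class PipelineConfig:
    """What to generate and which analysis blocks to run."""

    conditions: tuple = ("control", "csf_tau", "csf_tau_depleted")
    seed: int = 0
    blocks: tuple = ("intrinsic", "field", "mepsc", "theta")
    n_overrides: dict = field(default_factory=dict)  # condition -> modality -> n
    mepsc_duration_s: float = 900.0
    osc_baseline_s: float = 120.0
    osc_post_s: float = 400.0
    theta_window_s: float = 180.0
    dynamic_iv_cells: int = 2  # per condition; the dynamic I-V fit is slow
    out: str | None = None  # optional JSON path

    def n_for(self, condition: str, modality: str) -> int:
        return int(self.n_overrides.get(condition, {}).get(
            modality, PRINTED_N[condition][modality]))


def _group(values) -> dict:
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    return {"mean": float(np.mean(v)) if v.size else None,
            "sem": float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else None,
            "n": int(v.size), "values": v.tolist()}


def analyze_intrinsic_block(datasets: dict[str, ConditionDataset],
                            dynamic_iv_cells: int = 0) -> dict:
    """Fig-2-style block: RMP, Rin, rheobase, firing rate (+ optional DIV)."""
    per_cond: dict[str, dict] = {}
    for label, ds in datasets.items():
        cells = []
        for rec in ds.cells:
            s = summarize_cell(rec.step_sweeps, rec.ramp_sweep, rec.ou_sweeps[0])
            cells.append(s)
        block = {k: _group([getattr(c, k) for c in cells])
                 for k in ("rmp", "input_resistance", "rheobase", "firing_rate",
                           "ap_amplitude", "ap_halfwidth")}
        if dynamic_iv_cells:
            fits = []
            for rec in ds.cells[:dynamic_iv_cells]:
                if len(rec.ou_sweeps) >= 2:
                    f = fit_cell(*rec.ou_sweeps[0], holdout=rec.ou_sweeps[1])
                    fits.append(f)
            block["div_rin"] = _group([f.params.Rin for f in fits])
            block["div_prediction"] = _group([f.prediction_score for f in fits])
        per_cond[label] = block
    labels = list(per_cond)
    stats = {}
    if len(labels) >= 3:
        for k in ("rmp", "input_resistance", "rheobase", "firing_rate"):
            groups = [per_cond[c][k]["values"] for c in labels]
            if all(len(g) >= 3 for g in groups):
                stats[k] = asdict(kruskal_dunn(groups, labels=labels))
    return {"groups": per_cond, "stats": stats}


def analyze_mepsc_block(datasets: dict[str, ConditionDataset]) -> dict:
    """Fig-4-style block: mEPSC interval/amplitude per slice + pooled KS."""
    per_cond = {}
    pooled = {}
    for label, ds in datasets.items():
        tables = [mepsc.detect_mepscs(tr) for tr, _ in ds.mepsc_slices]
        st = mepsc.event_statistics(tables)
        pooled[label] = st
        per_cond[label] = {
            "interval": _group(st.per_slice_mean_interval),
            "amplitude": _group(st.per_slice_mean_amplitude),
            "frequency": _group(1.0 / st.per_slice_mean_interval),
        }
    labels = list(per_cond)
    stats = {}
    if len(labels) >= 3:
        for k in ("interval", "amplitude"):
            stats[k] = asdict(kruskal_dunn(
                [per_cond[c][k]["values"] for c in labels], labels=labels))
    if "control" in pooled and "csf_tau" in pooled:
        stats["ks_interval"] = asdict(ks_two_sample(
            pooled["csf_tau"].pooled_intervals, pooled["control"].pooled_intervals))
        stats["ks_amplitude"] = asdict(ks_two_sample(
            pooled["csf_tau"].pooled_amplitudes, pooled["control"].pooled_amplitudes))
        f_ctrl = per_cond["control"]["frequency"]["mean"]
        f_tau = per_cond["csf_tau"]["frequency"]["mean"]
        stats["frequency_ratio_csf_tau_over_control"] = (
            f_tau / f_ctrl if f_ctrl else None)
    return {"groups": per_cond, "stats": stats}


def analyze_field_block(datasets: dict[str, ConditionDataset]) -> dict:
    """Fig-3-style block: IO curves, PPF across intervals, LTP."""
    per_cond = {}
    io_by_cond = {}
    for label, ds in datasets.items():
        ios, ppf100, ltp, ppf_curves = [], [], [], {}
        for sl in ds.field_slices:
            io = fieldpot.io_curve(sl.io_sweeps)
            ios.append(io)
            for interval, sweep in sl.ppf_pairs.items():
                r = fieldpot.ppf_ratio(sweep, interval, sl.ppf_template)
                ppf_curves.setdefault(interval, []).append(r)
            ppf100.append(ppf_curves[100.0][-1])
            res = fieldpot.ltp_from_sweeps(sl.ltp_sweeps, sl.ltp_times_min,
                                           sl.hfs_time_min)
            ltp.append(res.potentiation_55_60)
        io_by_cond[label] = ios
        slope3 = [float(io.loc[io.stimulus == 3.0, "fepsp_slope"].iloc[0])
                  for io in ios if (io.stimulus == 3.0).any()]
        fv4 = [float(io.loc[io.stimulus == 4.0, "fibre_volley_amp"].iloc[0])
               for io in ios if (io.stimulus == 4.0).any()]
        per_cond[label] = {
            "fepsp_slope_3v": _group(slope3),
            "fibre_volley_4v": _group(fv4),
            "ppf_100ms": _group(ppf100),
            "ltp_55_60": _group(ltp),
            "ppf_curve": {str(k): _group(v) for k, v in sorted(ppf_curves.items())},
        }
    labels = list(per_cond)
    stats = {}
    if len(labels) >= 2:
        try:
            stats["io_anova"] = asdict(two_way_anova_io(io_by_cond))
        except ValueError as e:
            stats["io_anova"] = {"failed": str(e)}
    if len(labels) >= 3:
        for k in ("ppf_100ms", "ltp_55_60"):
            stats[k] = asdict(kruskal_dunn(
                [per_cond[c][k]["values"] for c in labels], labels=labels))
    return {"groups": per_cond, "stats": stats}


def analyze_theta_block(datasets: dict[str, ConditionDataset],
                        window_s: float = 180.0) -> dict:
    """Fig-5-style block: peak theta power, baseline power, onset latency."""
    per_cond = {}
    excluded = {}
    for label, ds in datasets.items():
        peaks, bases, lats = [], [], []
        n_excluded = 0
        for tr in ds.osc_slices:
            s = oscillations.summarize_oscillation(tr, window_length=window_s)
            if s.flag == "no oscillation":
                n_excluded += 1
                continue
            peaks.append(s.peak_theta_power)
            bases.append(s.baseline_theta_power)
            lats.append(s.onset_latency)
        per_cond[label] = {"peak_theta_power": _group(peaks),
                           "baseline_theta_power": _group(bases),
                           "onset_latency": _group(lats)}
        excluded[label] = n_excluded
    labels = list(per_cond)
    stats = {}
    if len(labels) >= 3 and all(
            len(per_cond[c]["peak_theta_power"]["values"]) >= 3 for c in labels):
        stats["peak_power"] = asdict(kruskal_dunn(
            [per_cond[c]["peak_theta_power"]["values"] for c in labels], labels=labels))
        stats["latency"] = asdict(kruskal_dunn(
            [per_cond[c]["onset_latency"]["values"] for c in labels], labels=labels))
    for c in labels:
        pk = per_cond[c]["peak_theta_power"]["values"]
        bs = per_cond[c]["baseline_theta_power"]["values"]
        if len(pk) >= 6:
            stats[f"wilcoxon_{c}"] = asdict(paired_wilcoxon(bs, pk))
    return {"groups": per_cond, "stats": stats, "excluded_no_oscillation": excluded}


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Generate every requested dataset, run the analyses, build the report.

    Re-running with the same config (same master seed) reproduces the
    report bit-identically.
    """
    cfg = config or PipelineConfig()
    report: dict = {"config": {**asdict(cfg)}, "blocks": {}, "log": {}}
    need_cells = "intrinsic" in cfg.blocks
    gain = calibrate_ou_gain(seed=cfg.seed) if need_cells else 0.0
    report["log"]["ou_gain"] = gain

    datasets: dict[str, ConditionDataset] = {}
    for cond in cfg.conditions:
        datasets[cond] = make_condition_dataset(
            cond, seed=cfg.seed,
            n_cells=cfg.n_for(cond, "cells") if "intrinsic" in cfg.blocks else 0,
            n_mepsc_slices=cfg.n_for(cond, "mepsc") if "mepsc" in cfg.blocks else 0,
            n_field_slices=cfg.n_for(cond, "field") if "field" in cfg.blocks else 0,
            n_osc_slices=cfg.n_for(cond, "osc") if "theta" in cfg.blocks else 0,
            ou_gain=gain,
            mepsc_duration=cfg.mepsc_duration_s,
            osc_baseline=cfg.osc_baseline_s,
            osc_post=cfg.osc_post_s,
        )
        report["log"][f"manifest_{cond}"] = datasets[cond].manifest

    runners = {
        "intrinsic": lambda: analyze_intrinsic_block(datasets, cfg.dynamic_iv_cells),
        "mepsc": lambda: analyze_mepsc_block(datasets),
        "field": lambda: analyze_field_block(datasets),
        "theta": lambda: analyze_theta_block(datasets, cfg.theta_window_s),
    }
    for name in cfg.blocks:
        try:
            report["blocks"][name] = runners[name]()
            report["blocks"][name]["status"] = "ok"
        except Exception as e:  # a failed stage must not kill the report
            report["blocks"][name] = {"status": "failed", "error": repr(e)}
    if cfg.out:
        Path(cfg.out).parent.mkdir(parents=True, exist_ok=True)
        Path(cfg.out).write_text(json.dumps(report, indent=1, default=float))
    return report
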