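"""End-to-end orchestration: simulate → features → excitability → vclamp → stats.

A :class:`RunConfig` fully determines a run; the config copy, package
version and master seed are written into the output directory's
``manifest.json`` so identical config + seed reproduces an identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .excitability import analyze_cohort, analyze_recording
from .simulate import CohortConfig, CohortResult, GroupSpec, generate_cohort
from .spikes import DetectionCriteria, detect_aps
from .stats import Contingency2x2, fisher_exact_2x2, proportion, summarize_groups
from .traces import Recording, read_bundle
from .vclamp import fit_leak, leak_subtract, ramp_peak_inward, step_iv, density_at, isolate_a_type

__all__ = ["RunConfig", "run_pipeline", "feature_table", "vclamp_table", "default_run_config"]

log = logging.getLogger("nociplast")

WAVEFORM_METRICS = ["rheobase_ramp", "rheobase_step", "v_rest", "r_in", "c_m",
                    "aps_1x", "aps_2x", "aps_3x", "aps_4x",
                    "ap_amplitude", "ap_overshoot", "ap_rise", "ap_fall",
                    "ap_half_width"]


@dataclass
class RunConfig:
    cohort: CohortConfig
    out_dir: str
    criteria: DetectionCriteria = field(default_factory=DetectionCriteria)
    stages: tuple[str, ...] = ("simulate", "features", "excitability", "vclamp", "stats")
    write_bundles: bool = False

    def to_json(self) -> dict:
        d = asdict(self)
        return d


def default_run_config(out_dir: str, n: int = 8, seed: int = 1) -> RunConfig:
    """The demo design: control / KCl / recovery groups of ``n`` mouse cells."""
    cohort = CohortConfig(
        groups=[
            GroupSpec("control", "control", n),
            GroupSpec("kcl", "kcl24h", n),
            GroupSpec("kcl_recovery", "recovery", n),
        ],
        seed=seed,
        fine_rheobase=False,
    )
    return RunConfig(cohort=cohort, out_dir=out_dir)


def feature_table(recordings: list[Recording],
                  criteria: DetectionCriteria | None = None) -> pd.DataFrame:
    """One row per detected AP across all current-clamp sweeps."""
    rows = []
    for rec in recordings:
        for fam, grp in rec.groups.items():
            if grp.protocol.clamp_mode != "current":
                continue
            for sw in grp.sweeps:
                for k, ev in enumerate(detect_aps(sw, criteria)):
                    rows.append({
                        "cell_id": rec.cell_id, "group": rec.group, "family": fam,
                        "sweep_index": sw.sweep_index, "ap_index": k,
                        "threshold_time": ev.threshold_time,
                        "threshold_voltage": ev.threshold_voltage,
                        "peak_time": ev.peak_time, "peak_voltage": ev.peak_voltage,
                        "max_dvdt": ev.max_dvdt,
                    })
    return pd.DataFrame(rows)


def vclamp_table(recordings: list[Recording], c_m: float = 25.0) -> pd.DataFrame:
    """Leak-subtracted voltage-clamp summary, one row per cell."""
    rows = []
    for rec in recordings:
        row: dict = {"cell_id": rec.cell_id, "group": rec.group}
        has_vc = False
        ramp_leak = None
        if "vc_na_ramp" in rec.groups:
            grp = rec.family("vc_na_ramp")
            ramp_leak = fit_leak(grp.sweeps)
            sw = leak_subtract(grp.sweeps[0], ramp_leak)
            peak, v_at, det = ramp_peak_inward(sw, grp.protocol)
            row.update(ramp_peak_pa=peak, ramp_peak_density=peak / c_m,
                       ramp_peak_v=v_at, ramp_detected=det)
            has_vc = True
        if "vc_na_step" in rec.groups:
            grp = rec.family("vc_na_step")
            # the −100…−80 mV leak window lives on the ramp; for a bare step
            # family fit across the hold and the gate-free −60 mV step
            leak = ramp_leak or fit_leak(grp.sweeps, window=(-81.0, -59.5),
                                         nonlinearity_tol=0.2)
            corrected = [leak_subtract(s, leak) for s in grp.sweeps]
            iv = step_iv(corrected, grp.protocol, c_m)
            for v, dens in zip(iv.voltages, iv.densities):
                row[f"iv_density_{int(v):+d}mV"] = dens
            has_vc = True
        if "vc_k_prepulse" in rec.groups:
            grp = rec.family("vc_k_prepulse")
            res = isolate_a_type(grp.sweeps[0], grp.sweeps[1], grp.protocol, c_m)
            row.update(a_type_density=res.a_type_peak_density,
                       sustained_density=res.sustained_density)
            has_vc = True
        if has_vc:
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns a dict of the in-memory artifacts (cohort, tables).  Identical
    config + seed produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    if not config.stages:
        log.warning("all stages disabled; writing empty report")
    if "simulate" in config.stages:
        log.info("simulating cohort (seed=%d)", config.cohort.seed)
        cohort = generate_cohort(config.cohort,
                                 out_dir=out / "bundles" if config.write_bundles else None)
        cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
        artifacts["cohort"] = cohort
    cohort = artifacts.get("cohort")
    if cohort is not None:
        recs = cohort.recordings
        if "features" in config.stages:
            ft = feature_table(recs, config.criteria)
            ft.to_csv(out / "aps.csv", index=False)
            artifacts["features"] = ft
        if "excitability" in config.stages:
            cells = analyze_cohort(recs, config.criteria)
            excluded = cells.loc[~cells["included"], "cell_id"].tolist()
            if excluded:
                log.warning("excluded by V_rest rule: %s", ", ".join(excluded))
            cells.to_csv(out / "cells.csv", index=False)
            artifacts["cells"] = cells
        if "vclamp" in config.stages and any("vc_na_ramp" in r.groups or
                                             "vc_na_step" in r.groups or
                                             "vc_k_prepulse" in r.groups for r in recs):
            vt = vclamp_table(recs)
            vt.to_csv(out / "vclamp.csv", index=False)
            artifacts["vclamp"] = vt
    if "stats" in config.stages and "cells" in artifacts:
        cells = artifacts["cells"]
        inc = cells[cells["included"]]
        summary = summarize_groups(cells, [m for m in WAVEFORM_METRICS if m in cells],
                                   "group")
        summary.to_csv(out / "summary.csv", index=False)
        artifacts["summary"] = summary
        props = []
        for grp, sub in inc.groupby("group"):
            k = int(sub["responder_ramp"].sum())
            n = len(sub)
            props.append({"group": grp, "responders": k, "n": n,
                          "percent": proportion(k, n)})
        props = pd.DataFrame(props)
        props.to_csv(out / "responder_proportions.csv", index=False)
        artifacts["proportions"] = props
        tests = []
        groups = list(props["group"])
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi = props.iloc[i]
                gj = props.iloc[j]
                tab = Contingency2x2(int(gi.responders), int(gi.n - gi.responders),
                                     int(gj.responders), int(gj.n - gj.responders))
                p, degen = fisher_exact_2x2(tab)
                tests.append({"group_1": gi.group, "group_2": gj.group,
                              "p_fisher": p, "degenerate": degen})
        tests = pd.DataFrame(tests)
        tests.to_csv(out / "responder_fisher.csv", index=False)
        artifacts["fisher"] = tests
    manifest = {
        "package": "nociplast",
        "version": __version__,
        "seed": config.cohort.seed,
        "config": config.to_json(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return artifacts
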