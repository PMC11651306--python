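"""Per-cell excitability pipeline.

Turns a family of current-clamp sweeps into the quantities used to compare
treatment groups: rheobase (minimum current evoking at least one AP, on the
10 pA mouse / 100 pA human grid, with non-responders assigned the 1 nA /
10 nA cap), suprathreshold AP counts at 1–4× rheobase, passive properties
(V_rest with the −75…−40 mV inclusion rule, input resistance, capacitance),
firing-pattern classification (single / delayed / repeated), and optogenetic
firing fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spikes import APEvent, APMetrics, DetectionCriteria, detect_aps, measure_ap, first_ap_at_rheobase
from .traces import Protocol, Recording, Sweep, SPECIES_PRESETS, segments_peak_amplitude

__all__ = [
    "RheobaseResult",
    "FiringSubtype",
    "ExcitabilityProfile",
    "rheobase_from_family",
    "suprathreshold_counts",
    "classify_firing",
    "resting_potential",
    "input_resistance",
    "estimate_capacitance",
    "firing_fidelity",
    "analyze_recording",
    "analyze_cohort",
    "ONSET_WINDOW_MS",
    "DELAYED_LATENCY_MS",
]

ONSET_WINDOW_MS = 100.0  # "start of current injection" window (= delayed rule)
DELAYED_LATENCY_MS = 100.0  # minimum first-AP latency of a delayed spiker
V_REST_WINDOW = (-75.0, -40.0)  # inclusion rule


@dataclass(frozen=True)
class RheobaseResult:
    """Rheobase from an ascending step or ramp family."""

    protocol_kind: str  # "ramp" | "step"
    rheobase: float  # pA (== cutoff for non-responders)
    responder: bool
    sweep_index: int | None  # responding sweep, None for non-responders
    cutoff: float  # pA
    threshold_current: float | None = None  # ramp only: instantaneous pA at AP threshold

    def __post_init__(self) -> None:
        if self.responder:
            if self.rheobase > self.cutoff:
                raise ValueError("responder rheobase cannot exceed the cutoff")
        elif self.rheobase != self.cutoff:
            raise ValueError("non-responder rheobase must equal the cutoff")


@dataclass(frozen=True)
class FiringSubtype:
    label: str  # single | delayed | repeated | unclassified
    first_ap_latency: float  # ms from stimulus onset at rheobase
    reason: str = ""


@dataclass
class ExcitabilityProfile:
    """Everything the group-level analysis needs from one cell."""

    cell_id: str
    group: str
    v_rest: float = math.nan
    included: bool = False
    r_in: float = math.nan  # MΩ
    c_m: float = math.nan  # pF
    ramp: RheobaseResult | None = None
    step: RheobaseResult | None = None
    counts: dict[int, float] = field(default_factory=dict)  # multiple -> n APs (NaN = off grid)
    subtype: FiringSubtype | None = None
    first_ap: APMetrics | None = None
    fidelity: float | None = None

    def as_row(self) -> dict:
        row = {
            "cell_id": self.cell_id, "group": self.group,
            "v_rest": self.v_rest, "included": self.included,
            "r_in": self.r_in, "c_m": self.c_m,
        }
        for kind, rb in (("ramp", self.ramp), ("step", self.step)):
            row[f"rheobase_{kind}"] = rb.rheobase if rb else math.nan
            row[f"responder_{kind}"] = rb.responder if rb else False
        for m in (1, 2, 3, 4):
            row[f"aps_{m}x"] = self.counts.get(m, math.nan)
        row["subtype"] = self.subtype.label if self.subtype else "unclassified"
        row["first_ap_latency"] = self.subtype.first_ap_latency if self.subtype else math.nan
        if self.first_ap is not None:
            for name in ("amplitude", "overshoot", "rise", "fall", "half_width",
                         "shoulder_score"):
                row[f"ap_{name}"] = getattr(self.first_ap, name)
            row["ap_shoulder"] = self.first_ap.shoulder_flag
        else:
            for name in ("amplitude", "overshoot", "rise", "fall", "half_width",
                         "shoulder_score"):
                row[f"ap_{name}"] = math.nan
            row["ap_shoulder"] = False
        row["fidelity"] = math.nan if self.fidelity is None else self.fidelity
        return row


def _stim_events(sweep: Sweep, protocol: Protocol, criteria) -> list[APEvent]:
    """APs whose threshold falls inside the stimulus epoch."""
    lo, hi = protocol.stimulus_window(0)
    return [e for e in detect_aps(sweep, criteria) if lo <= e.threshold_time < hi]


def rheobase_from_family(sweeps: list[Sweep], protocol: Protocol,
                         criteria: DetectionCriteria | None = None) -> RheobaseResult:
    """Rheobase = peak command amplitude of the first sweep evoking ≥ 1 AP.

    The family must be ordered by increasing amplitude.  If no sweep up to
    the species cap fires, the cell is a non-responder and its rheobase is
    defined as the cap (1 nA mouse / 10 nA human).  For ramp families the
    instantaneous injected current at the first AP threshold is recorded as
    an auxiliary value.
    """
    if not sweeps:
        raise ValueError("empty sweep family")
    kinds = {s.segments[1].kind if len(s.segments) > 1 else "step" for s in sweeps}
    if len(kinds) > 1:
        raise ValueError(f"mixed protocol kinds in family: {kinds}")
    kind = "ramp" if protocol.kind == "cc_ramp" else "step"
    cap = SPECIES_PRESETS[protocol.species_preset or "mouse"]["cap"]
    amps = [segments_peak_amplitude(s.segments) if s.segments
            else protocol.peak_amplitude(s.sweep_index) for s in sweeps]
    if any(np.diff(amps) <= 0):
        raise ValueError("family must be sorted by increasing amplitude")
    for sw, amp in zip(sweeps, amps):
        events = _stim_events(sw, protocol, criteria)
        if events:
            thr_i = None
            if kind == "ramp":
                from .traces import command_at

                thr_i = command_at(sw, events[0].threshold_time)
            return RheobaseResult(kind, float(amp), True, sw.sweep_index, cap, thr_i)
    return RheobaseResult(kind, float(cap), False, None, cap)


def suprathreshold_counts(sweeps: list[Sweep], protocol: Protocol,
                          rheobase: RheobaseResult,
                          criteria: DetectionCriteria | None = None) -> dict[int, float]:
    """AP counts at 1–4× rheobase, snapped down to the family's amplitude grid.

    Multiples beyond the species cap are NaN (absent), never 0.
    """
    if not rheobase.responder:
        raise ValueError("suprathreshold counts require a responder")
    inc = protocol.increment or 10.0
    by_index = {s.sweep_index: s for s in sweeps}
    counts: dict[int, float] = {}
    for mult in (1, 2, 3, 4):
        target = mult * rheobase.rheobase
        if target > rheobase.cutoff + 1e-9:
            counts[mult] = math.nan
            continue
        k = int(math.floor(target / inc + 1e-9)) - 1  # grid amp <= exact multiple
        sw = by_index.get(k)
        if sw is None:
            counts[mult] = math.nan
            continue
        counts[mult] = float(len(_stim_events(sw, protocol, criteria)))
    return counts


def classify_firing(sweeps: list[Sweep], protocol: Protocol,
                    rheobase: RheobaseResult, counts: dict[int, float],
                    criteria: DetectionCriteria | None = None,
                    onset_window: float = ONSET_WINDOW_MS) -> FiringSubtype:
    """Classify a step responder as single, delayed or repeated.

    * delayed — first AP at rheobase arrives ≥ 100 ms after stimulus onset;
    * single — every suprathreshold sweep fires exactly one AP, within the
      onset window;
    * repeated — fires within the onset window and ≥ 2 APs on some sweep.
    """
    if not rheobase.responder or rheobase.sweep_index is None:
        return FiringSubtype("unclassified", math.nan, "non-responder")
    stim_start = protocol.stimulus_window(0)[0]
    by_index = {s.sweep_index: s for s in sweeps}
    rb_events = _stim_events(by_index[rheobase.sweep_index], protocol, criteria)
    if not rb_events:
        return FiringSubtype("unclassified", math.nan, "no AP on rheobase sweep")
    latency = rb_events[0].threshold_time - stim_start
    if latency >= DELAYED_LATENCY_MS:
        return FiringSubtype("delayed", latency)

    inc = protocol.increment or 10.0
    onset_ok = []
    n_aps = []
    for mult in (1, 2, 3, 4):
        if math.isnan(counts.get(mult, math.nan)):
            continue
        k = int(math.floor(mult * rheobase.rheobase / inc + 1e-9)) - 1
        sw = by_index.get(k)
        if sw is None:
            continue
        ev = _stim_events(sw, protocol, criteria)
        n_aps.append(len(ev))
        onset_ok.append(bool(ev) and (ev[0].threshold_time - stim_start) < onset_window)
    if not n_aps:
        return FiringSubtype("unclassified", latency, "missing suprathreshold sweeps")
    if all(n == 1 for n in n_aps) and all(onset_ok):
        return FiringSubtype("single", latency)
    if all(onset_ok) and any(n >= 2 for n in n_aps):
        return FiringSubtype("repeated", latency)
    return FiringSubtype("unclassified", latency, "mixed onset/count pattern")


def resting_potential(sweep: Sweep, protocol: Protocol) -> tuple[float, bool]:
    """Mean potential over the 1 s zero-injection epoch + inclusion flag.

    Cells resting above −40 mV or below −75 mV are excluded from analysis.
    """
    t = sweep.time_ms
    zero = np.abs(sweep.command) < 1e-12
    if not zero.any():
        raise ValueError("no zero-injection epoch in sweep")
    v = float(sweep.recorded[zero].mean())
    return v, bool(V_REST_WINDOW[0] <= v <= V_REST_WINDOW[1])


def input_resistance(sweep: Sweep, protocol: Protocol) -> float:
    """R_in (MΩ) from a hyperpolarizing step: ΔV_steady / I_injected.

    ΔV_steady is the mean over the last 20 % of the step relative to the
    pre-stimulus baseline; a slope test guards against an unreached plateau.
    """
    lo, hi = protocol.stimulus_window(0)
    steps = [s for s in sweep.segments if s.kind == "step"]
    injected = steps[0].amp_start if steps else protocol.peak_amplitude(sweep.sweep_index)
    if injected == 0:
        raise ValueError("input resistance requires a nonzero injected current")
    if injected > 0:
        raise ValueError("input resistance uses a hyperpolarizing (negative) current")
    t = sweep.time_ms
    base = sweep.recorded[t < lo]
    tail_mask = (t >= hi - 0.2 * (hi - lo)) & (t < hi)
    tail = sweep.recorded[tail_mask]
    # plateau check: drift across the tail window must be small vs the deflection
    half = tail.size // 2
    drift = abs(tail[half:].mean() - tail[:half].mean())
    dv = tail.mean() - base.mean()
    if abs(dv) > 1e-9 and drift > 0.25 * abs(dv):
        raise ValueError("steady-state plateau not reached")
    return float(abs(dv / injected) * 1000.0)  # mV/pA = GΩ -> MΩ


def estimate_capacitance(sweep: Sweep, protocol: Protocol, r_in_mohm: float) -> float:
    """C_m (pF) = τ / R_in from a mono-exponential fit to the step-onset relaxation.

    A software surrogate for the amplifier's slow-capacitance compensation;
    raises if the fit does not converge or explains the relaxation poorly.
    """
    from scipy.optimize import curve_fit

    lo, hi = protocol.stimulus_window(0)
    t = sweep.time_ms
    m = (t >= lo) & (t < min(hi, lo + 200.0))
    tt = t[m] - lo
    vv = sweep.recorded[m]
    v0, v1 = vv[0], vv[-1]

    def model(x, dv, tau, v_inf):
        return v_inf - dv * np.exp(-x / tau)

    try:
        popt, pcov = curve_fit(model, tt, vv, p0=[v0 - v1, 10.0, v1], maxfev=2000)
    except RuntimeError as exc:
        raise ValueError("capacitance fit failed to converge") from exc
    dv, tau, v_inf = popt
    resid = vv - model(tt, *popt)
    if tau <= 0 or abs(dv) < 1e-6 or resid.std() > 0.5 * abs(dv):
        raise ValueError("capacitance fit failed: relaxation not mono-exponential")
    return float(tau / r_in_mohm * 1000.0)  # ms / MΩ = nF -> pF


def firing_fidelity(sweep: Sweep, protocol: Protocol,
                    response_window: float = 25.0,
                    criteria: DetectionCriteria | None = None) -> float:
    """Fraction of light pulses answered by ≥ 1 AP within ``response_window`` ms.

    "Reliable" firing means fidelity == 1.0 exactly.
    """
    train = [seg for seg in protocol.sweeps[sweep.sweep_index]
             if seg.kind == "pulse_train"]
    if not train:
        raise ValueError("sweep has no pulse_train stimulus")
    seg = train[0]
    onsets = np.arange(seg.t_start, seg.t_end - 1e-9, seg.period)
    if onsets.size == 0:
        raise ValueError("empty pulse schedule")
    events = detect_aps(sweep, criteria)
    times = np.array([e.threshold_time for e in events])
    hit = 0
    for on in onsets:
        if np.any((times >= on) & (times < on + response_window)):
            hit += 1
    return hit / onsets.size


# ---------------------------------------------------------------------------
# Whole-recording / whole-cohort drivers
# ---------------------------------------------------------------------------

def analyze_recording(rec: Recording,
                      criteria: DetectionCriteria | None = None) -> ExcitabilityProfile:
    """Run the full excitability pipeline on whatever families a cell has."""
    prof = ExcitabilityProfile(rec.cell_id, rec.group)
    if "cc_zero" in rec.groups:
        grp = rec.family("cc_zero")
        prof.v_rest, prof.included = resting_potential(grp.sweeps[0], grp.protocol)
    else:
        prof.included = True  # no V_rest sweep: inclusion cannot be assessed
    if "cc_hyper" in rec.groups:
        grp = rec.family("cc_hyper")
        try:
            prof.r_in = input_resistance(grp.sweeps[0], grp.protocol)
            prof.c_m = estimate_capacitance(grp.sweeps[0], grp.protocol, prof.r_in)
        except ValueError:
            pass
    if "cc_ramp" in rec.groups:
        grp = rec.family("cc_ramp")
        prof.ramp = rheobase_from_family(grp.sweeps, grp.protocol, criteria)
    if "cc_step" in rec.groups:
        grp = rec.family("cc_step")
        prof.step = rheobase_from_family(grp.sweeps, grp.protocol, criteria)
        if prof.step.responder:
            prof.counts = suprathreshold_counts(grp.sweeps, grp.protocol, prof.step, criteria)
            prof.subtype = classify_firing(grp.sweeps, grp.protocol, prof.step,
                                           prof.counts, criteria)
            rb_sweep = next(s for s in grp.sweeps if s.sweep_index == prof.step.sweep_index)
            prof.first_ap = first_ap_at_rheobase(rb_sweep, criteria)
    if "opto_train" in rec.groups:
        grp = rec.family("opto_train")
        prof.fidelity = firing_fidelity(grp.sweeps[0], grp.protocol, criteria=criteria)
    return prof


def analyze_cohort(recordings: list[Recording],
                   criteria: DetectionCriteria | None = None) -> pd.DataFrame:
    """One row per cell; excluded cells (V_rest rule) are flagged, not dropped."""
    return pd.DataFrame([analyze_recording(r, criteria).as_row() for r in recordings])
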