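"""Action-potential detection and waveform metrology for current-clamp sweeps.

Conventions (all crossing times sub-sample, by linear interpolation):

* AP threshold: voltage where dV/dt first crosses the detection criterion
  (default 10 mV/ms) on the rising phase of a peak exceeding ``min_peak``.
* amplitude: threshold → peak;  overshoot: 0 mV → peak.
* rise: 10→90 % of the rising phase;  fall: 90→10 % of the falling phase;
  half-width: 50 % rise → 50 % fall.  All percentage levels are referenced
  to the threshold→peak amplitude, symmetrically for both phases.
* shoulder: a falling-phase inflection, scored as the relative dip of
  |dV/dt| between the 90 % and 10 % levels against its surrounding envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .traces import Sweep

__all__ = [
    "DetectionCriteria",
    "APEvent",
    "APMetrics",
    "detect_aps",
    "measure_ap",
    "first_ap_at_rheobase",
]


@dataclass(frozen=True)
class DetectionCriteria:
    """Spike-detection knobs; defaults suit 50 kHz somatic recordings."""

    dvdt_threshold: float = 10.0  # mV/ms
    min_peak: float = 0.0  # mV — a spike must at least reach 0 mV
    refractory: float = 2.0  # ms between distinct events
    smoothing: float = 0.0  # ms boxcar applied before detection (0 = raw)
    use_curvature: bool = False  # alternative threshold: max of d2V/dt2

    def __post_init__(self) -> None:
        if self.dvdt_threshold <= 0 or self.refractory <= 0:
            raise ValueError("dvdt_threshold and refractory must be positive")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")


@dataclass(frozen=True)
class APEvent:
    """One detected action potential."""

    threshold_time: float  # ms
    threshold_voltage: float  # mV
    peak_time: float  # ms
    peak_voltage: float  # mV
    max_dvdt: float  # mV/ms

    def __post_init__(self) -> None:
        if not self.peak_time > self.threshold_time:
            raise ValueError("peak must follow threshold")
        if not self.peak_voltage > self.threshold_voltage:
            raise ValueError("peak must exceed threshold voltage")


@dataclass(frozen=True)
class APMetrics:
    """Waveform measurements of one AP (durations in ms, voltages in mV)."""

    amplitude: float  # threshold -> peak
    overshoot: float  # 0 mV -> peak
    rise: float  # 10 -> 90 % of rising phase
    fall: float  # 90 -> 10 % of falling phase
    half_width: float  # 50 % rise -> 50 % fall
    shoulder_score: float
    shoulder_flag: bool
    partial: bool = False  # falling phase truncated; durations may be NaN


SHOULDER_FLAG_DEFAULT = 0.25  # relative |dV/dt| dip that counts as a shoulder


def _smooth(v: np.ndarray, window_ms: float, rate: float) -> np.ndarray:
    w = int(round(window_ms * rate / 1000.0))
    if w <= 1:
        return v
    k = np.ones(w) / w
    return np.convolve(v, k, mode="same")


def detect_aps(sweep: Sweep, criteria: DetectionCriteria | None = None) -> list[APEvent]:
    """Detect APs in a current-clamp sweep, ordered by threshold time.

    A candidate event is a contiguous epoch with V ≥ ``min_peak``; epochs
    separated by less than the refractory period are merged.  Each event's
    threshold is the interpolated time/voltage of the last upward crossing
    of the dV/dt criterion before its peak (or, with ``use_curvature``, the
    maximum of the second derivative on the rising phase).  Deterministic.
    """
    crit = criteria or DetectionCriteria()
    if sweep.clamp_mode != "current":
        raise ValueError("AP detection requires a current-clamp sweep")
    if sweep.sampling_rate < 10_000:
        raise ValueError("AP detection requires sampling_rate >= 10 kHz")
    v = _smooth(sweep.recorded, crit.smoothing, sweep.sampling_rate)
    dt = 1000.0 / sweep.sampling_rate
    t = sweep.time_ms
    dvdt = np.diff(v) / dt  # slope of segment i -> i+1, centred at t[i] + dt/2

    above = v >= crit.min_peak
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)  # exclusive
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(v.size)

    # merge epochs separated by less than the refractory period
    merged = []
    for s, e in zip(starts, ends):
        if merged and (s - merged[-1][1]) * dt < crit.refractory:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    events: list[APEvent] = []
    for s, e in merged:
        pk = s + int(np.argmax(v[s:e]))
        # walk back from the peak to the dV/dt criterion crossing
        j = pk - 1
        lo = 0 if not events else int(events[-1].peak_time / dt)
        while j >= lo and dvdt[j] < crit.dvdt_threshold:
            j -= 1
        if j < lo:
            continue  # no fast upstroke before this peak: not an AP
        while j > lo and dvdt[j - 1] >= crit.dvdt_threshold:
            j -= 1
        if crit.use_curvature:
            seg = dvdt[j:pk]
            if seg.size >= 2:
                jj = j + int(np.argmax(np.diff(seg)))
                t_thr = t[jj] + dt  # curvature max between slope samples jj, jj+1
            else:
                t_thr = t[j] + dt / 2.0
        elif j == 0 or dvdt[j] == dvdt[j - 1]:
            t_thr = t[j] + dt / 2.0
        else:
            frac = (crit.dvdt_threshold - dvdt[j - 1]) / (dvdt[j] - dvdt[j - 1])
            t_thr = t[j - 1] + dt / 2.0 + frac * dt
        v_thr = float(np.interp(t_thr, t, v))
        max_dvdt = float(dvdt[max(j - 1, 0):pk].max()) if pk > j else float(dvdt[j])
        if events and t_thr - events[-1].threshold_time < crit.refractory:
            continue
        if v[pk] <= v_thr or t[pk] <= t_thr:
            continue
        events.append(APEvent(float(t_thr), v_thr, float(t[pk]), float(v[pk]), max_dvdt))
    return events


def _cross_time(t: np.ndarray, v: np.ndarray, level: float, rising: bool) -> float | None:
    """First sub-sample crossing of ``level`` in the given direction, or None."""
    if rising:
        hits = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    else:
        hits = np.nonzero((v[:-1] >= level) & (v[1:] < level))[0]
    if hits.size == 0:
        return None
    i = int(hits[0])
    if v[i + 1] == v[i]:
        return float(t[i])
    frac = (level - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def _shoulder_score(t: np.ndarray, v: np.ndarray, rate: float) -> float:
    """Relative dip of |dV/dt| inside the falling-phase window (0 if monotone)."""
    if v.size < 7:
        return 0.0
    speed = np.abs(np.diff(v)) * rate / 1000.0
    speed = _smooth(speed, 0.1, rate)  # 0.1 ms boxcar tames sample noise
    best = 0.0
    for i in range(1, speed.size - 1):
        if speed[i] <= speed[i - 1] and speed[i] <= speed[i + 1]:
            env = min(speed[: i + 1].max(), speed[i:].max())
            if env > 0:
                best = max(best, 1.0 - speed[i] / env)
    return float(best)


def measure_ap(sweep: Sweep, event: APEvent, next_event: APEvent | None = None,
               shoulder_flag_level: float = SHOULDER_FLAG_DEFAULT) -> APMetrics:
    """Measure the waveform of one detected AP.

    All level crossings (10/50/90 % of the threshold→peak amplitude) are
    linearly interpolated between samples.  If the falling phase does not
    return below the 10 % level before the next event or the sweep end, the
    metrics are flagged ``partial`` and the affected durations are NaN.
    """
    t = sweep.time_ms
    v = sweep.recorded
    amp = event.peak_voltage - event.threshold_voltage
    overshoot = event.peak_voltage
    lvl = {p: event.threshold_voltage + p * amp for p in (0.1, 0.5, 0.9)}

    i_pk = int(round(event.peak_time * sweep.sampling_rate / 1000.0))
    i_thr = int(event.threshold_time * sweep.sampling_rate / 1000.0)
    rise_t, rise_v = t[i_thr:i_pk + 1], v[i_thr:i_pk + 1]
    r10 = _cross_time(rise_t, rise_v, lvl[0.1], rising=True)
    r50 = _cross_time(rise_t, rise_v, lvl[0.5], rising=True)
    r90 = _cross_time(rise_t, rise_v, lvl[0.9], rising=True)

    end = v.size if next_event is None else int(next_event.threshold_time * sweep.sampling_rate / 1000.0)
    fall_t, fall_v = t[i_pk:end], v[i_pk:end]
    f90 = _cross_time(fall_t, fall_v, lvl[0.9], rising=False)
    f50 = _cross_time(fall_t, fall_v, lvl[0.5], rising=False)
    f10 = _cross_time(fall_t, fall_v, lvl[0.1], rising=False)

    partial = any(x is None for x in (r10, r50, r90, f90, f50, f10))
    rise = (r90 - r10) if (r10 is not None and r90 is not None) else math.nan
    fall = (f10 - f90) if (f90 is not None and f10 is not None) else math.nan
    half = (f50 - r50) if (r50 is not None and f50 is not None) else math.nan

    if f90 is not None and (f10 is not None):
        m = (fall_t >= f90) & (fall_t <= f10)
        score = _shoulder_score(fall_t[m], fall_v[m], sweep.sampling_rate)
    else:
        score = 0.0
    return APMetrics(amplitude=float(amp), overshoot=float(overshoot),
                     rise=rise, fall=fall, half_width=half,
                     shoulder_score=score,
                     shoulder_flag=bool(score > shoulder_flag_level),
                     partial=partial)


def first_ap_at_rheobase(rheobase_sweep: Sweep | None,
                         criteria: DetectionCriteria | None = None) -> APMetrics | None:
    """Metrics of the first AP on the rheobase sweep; None for a non-responder."""
    if rheobase_sweep is None:
        return None
    events = detect_aps(rheobase_sweep, criteria)
    if not events:
        return None
    nxt = events[1] if len(events) > 1 else None
    return measure_ap(rheobase_sweep, events[0], nxt)
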