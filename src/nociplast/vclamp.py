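"""Voltage-clamp analysis: leak subtraction, Na⁺ peak currents and IV curves,
current densities, and A-type / non-inactivating K⁺ current separation.

Sign conventions: inward current is negative (so the Na⁺ "peak" is the most
negative sample); the A-type difference current is reported as positive
outward.  Densities are pA/pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .traces import Protocol, Sweep

__all__ = [
    "LeakModel",
    "IVCurve",
    "ATypeResult",
    "fit_leak",
    "leak_subtract",
    "ramp_peak_inward",
    "step_iv",
    "density_at",
    "isolate_a_type",
]

LEAK_WINDOW = (-100.0, -80.0)  # mV, gate-free fit window on the ramp foot


@dataclass(frozen=True)
class LeakModel:
    """Linear (ohmic) leak: I_leak = g·(V − V_hold) + offset."""

    g: float  # nS
    offset: float  # pA
    v_hold: float  # mV
    window: tuple[float, float]
    residual_sd: float  # pA

    def current(self, v_cmd: np.ndarray) -> np.ndarray:
        return self.g * (np.asarray(v_cmd, float) - self.v_hold) + self.offset


@dataclass(frozen=True)
class IVCurve:
    """Peak current (and density) per command step."""

    voltages: np.ndarray  # mV, strictly increasing
    peaks: np.ndarray  # pA (signed; inward negative)
    c_m: float  # pF
    protocol_kind: str = "vc_na_step"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("IV voltages must be strictly increasing")
        if self.c_m <= 0:
            raise ValueError("C_m must be positive")

    @property
    def densities(self) -> np.ndarray:
        return self.peaks / self.c_m


@dataclass(frozen=True)
class ATypeResult:
    """Prepulse-subtraction separation of the K⁺ current components."""

    a_type_peak_density: float  # pA/pF, positive outward
    sustained_density: float  # pA/pF, non-inactivating steady component
    difference_trace: np.ndarray  # pA over the test epoch (positive outward)
    time_ms: np.ndarray


def fit_leak(sweeps: list[Sweep], window: tuple[float, float] = LEAK_WINDOW,
             nonlinearity_tol: float = 0.05) -> LeakModel:
    """Fit the linear leak on command voltages inside ``window``.

    Pools all samples whose command lies in the (gate-free, default
    −100…−80 mV) window across the given sweeps and regresses current on
    command voltage.  Raises if the window spans < 1 mV of distinct commands
    (underdetermined) or if the fit residuals reveal gated (nonlinear)
    current.
    """
    vs, is_ = [], []
    v_hold = None
    for sw in sweeps:
        if sw.clamp_mode != "voltage":
            raise ValueError("leak fit requires voltage-clamp sweeps")
        if v_hold is None:
            v_hold = float(sw.command[0])
        m = (sw.command >= window[0]) & (sw.command <= window[1])
        # keep only the first contiguous in-window epoch: samples after a
        # depolarized excursion carry gated tail currents
        if m.any():
            first = int(np.argmax(m))
            later = np.nonzero(~m[first:])[0]
            if later.size:
                m[first + later[0]:] = False
        vs.append(sw.command[m])
        is_.append(sw.recorded[m])
    v = np.concatenate(vs)
    i = np.concatenate(is_)
    if v.size < 2 or np.ptp(v) < 1.0:
        raise ValueError("leak window must span >= 2 distinct command voltages")
    A = np.column_stack([v - v_hold, np.ones_like(v)])
    (g, offset), *_ = np.linalg.lstsq(A, i, rcond=None)
    resid = i - (g * (v - v_hold) + offset)
    scale = max(float(np.abs(i).max()), 1.0)
    if resid.std() > nonlinearity_tol * scale:
        raise ValueError("leak window appears to contain gated current "
                         f"(residual SD {resid.std():.2f} pA)")
    return LeakModel(float(g), float(offset), v_hold, window, float(resid.std()))


def leak_subtract(sweep: Sweep, leak: LeakModel) -> Sweep:
    """Subtract the linear leak from a voltage-clamp sweep."""
    corrected = sweep.recorded - leak.current(sweep.command)
    return Sweep(sweep.sweep_index, sweep.sampling_rate, corrected,
                 sweep.command, sweep.clamp_mode, sweep.segments)


def _noise_floor(sweep: Sweep, protocol: Protocol) -> float:
    """3 × SD of the pre-stimulus baseline."""
    lo = protocol.stimulus_window(sweep.sweep_index)[0]
    base = sweep.recorded[sweep.time_ms < lo]
    return 3.0 * float(base.std()) if base.size else 0.0


def ramp_peak_inward(sweep: Sweep, protocol: Protocol) -> tuple[float, float, bool]:
    """(peak pA, command mV at peak, detected) for a leak-subtracted Na⁺ ramp.

    The peak is the most negative sample during the ramp; if no sample drops
    below the baseline noise floor the peak is reported as 0 with
    ``detected=False``.
    """
    lo, hi = protocol.stimulus_window(sweep.sweep_index)
    t = sweep.time_ms
    m = (t >= lo) & (t < hi)
    seg = sweep.recorded[m]
    k = int(np.argmin(seg))
    peak = float(seg[k])
    floor = max(_noise_floor(sweep, protocol), 1.0)
    if peak >= -floor:
        return 0.0, math.nan, False
    v_at = float(sweep.command[m][k])
    return peak, v_at, True


def step_iv(sweeps: list[Sweep], protocol: Protocol, c_m: float) -> IVCurve:
    """Peak inward current per step of a (leak-subtracted) step family."""
    volts, peaks = [], []
    for sw in sweeps:
        lo, hi = protocol.stimulus_window(sw.sweep_index)
        t = sw.time_ms
        m = (t >= lo) & (t < hi)
        step = [seg for seg in protocol.sweeps[sw.sweep_index] if seg.kind == "step"]
        if not step:
            raise ValueError("step_iv requires step-family sweeps")
        volts.append(step[0].amp_start)
        peaks.append(float(sw.recorded[m].min()))
    order = np.argsort(volts)
    return IVCurve(np.asarray(volts, float)[order], np.asarray(peaks, float)[order],
                   c_m, protocol.kind)


def density_at(iv: IVCurve, v: float) -> float:
    """Current density (pA/pF) at a command voltage on the IV grid (exact match)."""
    hits = np.nonzero(np.isclose(iv.voltages, v, atol=1e-6))[0]
    if hits.size == 0:
        raise ValueError(f"{v} mV is not on the IV grid {iv.voltages.tolist()}")
    return float(iv.densities[hits[0]])


def isolate_a_type(sweep_m80: Sweep, sweep_p10: Sweep, protocol: Protocol,
                   c_m: float) -> ATypeResult:
    """Separate A-type and non-inactivating K⁺ currents by prepulse subtraction.

    The +40 mV test current after a −80 mV prepulse (A-type available)
    minus the current after a +10 mV prepulse (A-type inactivated) leaves
    the A-type component; the literal subtraction order of the source
    protocol description yields its negative, so the difference is computed
    as (−80 prepulse) − (+10 prepulse) and reported positive outward.  The
    non-inactivating component is the mean of the +10-prepulse trace over
    the last 20 % of the test epoch.
    """
    if sweep_m80.n_samples != sweep_p10.n_samples or \
            sweep_m80.sampling_rate != sweep_p10.sampling_rate:
        raise ValueError("prepulse sweeps must share a time base")
    # test epoch = final non-hold segment (the +40 mV step)
    segs = [s for s in protocol.sweeps[sweep_m80.sweep_index] if s.kind != "hold"]
    test = segs[-1]
    t = sweep_m80.time_ms
    m = (t >= test.t_start) & (t < test.t_end)
    if not np.allclose(sweep_m80.command[m], sweep_p10.command[m]):
        raise ValueError("prepulse sweeps disagree on the test-epoch command")
    diff = sweep_m80.recorded[m] - sweep_p10.recorded[m]
    tt = t[m]
    tail = tt >= test.t_end - 0.2 * (test.t_end - test.t_start)
    # slowly/non-inactivating residue that survives both prepulses shows up
    # as a late plateau of the difference; reference the peak to it so only
    # the transient (A-type) component is counted
    diff = diff - diff[tail].mean()
    a_peak = float(diff.max())
    sustained = float(sweep_p10.recorded[m][tail].mean())
    return ATypeResult(a_type_peak_density=a_peak / c_m,
                       sustained_density=sustained / c_m,
                       difference_trace=diff, time_ms=tt)
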