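"""Single-compartment conductance-based DRG-neuron simulator.

The model is a Hodgkin–Huxley-style point neuron tailored to small-diameter
(putatively nociceptive) sensory neurons:

``C_m dV/dt = −(I_NaF + I_NaS + I_Kdr + I_KA + I_leakK + I_leakNS + I_ChR2)
             + I_inj(t) + ξ(t)``

with currents of the form ``g · m^p · h^q · (V − E)``:

* ``I_NaF`` — fast transient Na⁺ (``m³ h s``), the spike upstroke.  The extra
  slow gate ``s`` carries use-dependent (slow) inactivation; its floor and
  recovery time constant are the main firing-phenotype knobs.
* ``I_NaS`` — slower, incompletely inactivating Na⁺ (``m_s h_s``) that carries
  the falling-phase shoulder and a small persistent window current.
* ``I_Kdr`` — delayed-rectifier K⁺ (``n⁴``).
* ``I_KA`` — A-type K⁺ (``a³ b``), rapidly activating and inactivating;
  elevated A-type conductance with slowed inactivation produces the delayed
  firing phenotype, and its steady-state inactivation (half −78 mV) is what
  the two-prepulse voltage-clamp protocol exploits.
* two leaks: K⁺-selective (reversal at the Nernst potential of K⁺, so bath
  KCl acts through it) and non-selective (reversal 0 mV).
* ``I_ChR2`` — a square-pulse light-gated conductance (reversal 0 mV).

``ξ`` is additive membrane-voltage noise with standard deviation
``noise_sigma·√dt`` (current clamp only).  Gate kinetics use Boltzmann
steady states with sigmoidal voltage-dependent time constants; all constants
are module-level and frozen by regression tests.  E_K is always computed from
K⁺ concentrations via the Nernst relation — never stored.

Integration is exponential-Euler for the gates and Euler(–Maruyama) for the
voltage on a fixed grid that oversamples the 50 kHz acquisition grid.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .traces import (
    Protocol,
    Recording,
    Sweep,
    SPECIES_PRESETS,
    make_protocol,
)

__all__ = [
    "ModelParams",
    "PhenotypePreset",
    "TreatmentPreset",
    "GroupSpec",
    "CohortConfig",
    "CohortResult",
    "PHENOTYPES",
    "TREATMENTS",
    "CHANNEL_MASKS",
    "nernst_EK",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "generate_cohort",
    "iter_cohort",
    "gate_steady_states",
    "ionic_current_ss",
    "slope_conductance",
    "steady_state_voltage",
    "true_rheobase",
    "fires_at",
]

# ---------------------------------------------------------------------------
# Gating kinetics (mV, ms).  Frozen constants — see docs/methods.md.
# ---------------------------------------------------------------------------
# activation/inactivation half-voltages and slopes (slope sign encodes
# direction: positive = activation, negative = inactivation)
M_VH, M_K = -32.0, 4.2          # NaF activation
H_VH, H_K = -42.0, -3.5         # NaF fast inactivation
S_VH, S_K = -47.0, -4.0         # NaF slow (use-dependent) inactivation
MS_VH, MS_K = -16.0, 4.0        # NaS activation
HS_VH, HS_K = -45.0, -6.0       # NaS slow inactivation
N_VH, N_K = -25.0, 12.0         # Kdr activation
A_VH, A_K = -45.0, 15.0         # KA activation
B_VH, B_K = -78.0, -6.0         # KA inactivation
U_VH, U_K = -35.0, -7.0         # Kdr slow inactivation
U_FLOOR, TAU_U = 0.30, 5000.0   # Kdr slow-inactivation floor / time constant (ms)

OVERSAMPLE = 2  # integration substeps per acquisition sample (dt = 10 µs at 50 kHz)
SETTLE_MS = 25000.0  # unrecorded settling for free-running sweeps (≥5 tau of the slowest gate)

_NPAR = 18  # packed parameter-vector length


def nernst_EK(k_out: float, k_in: float, rt_over_f: float = 25.7) -> float:
    """K⁺ reversal potential (mV): ``RT/F · ln([K]_out / [K]_in)``.

    At room temperature RT/F ≈ 25.7 mV; 5 mM/140 mM gives −85.6 mV and a
    30 mM KCl bath shifts it to −39.6 mV.
    """
    if k_out <= 0 or k_in <= 0:
        raise ValueError("K+ concentrations must be positive")
    return rt_over_f * math.log(k_out / k_in)


@dataclass
class ModelParams:
    """Biophysical parameters of one model cell (pF, nS, mV, mM, ms)."""

    c_m: float = 25.0
    g_naf: float = 300.0
    g_nas: float = 85.0
    g_kdr: float = 75.0
    g_ka: float = 40.0
    g_leak_k: float = 2.0
    g_leak_ns: float = 0.85
    g_chr2: float = 0.0
    e_na: float = 60.0
    e_ns: float = 0.0
    k_in: float = 140.0
    k_out: float = 5.0
    rt_over_f: float = 25.7
    s_floor: float = 0.15
    tau_s_rest: float = 300.0
    tau_s_depol: float = 0.9
    hs_floor: float = 0.055
    tau_b_scale: float = 1.0
    s_vh: float = -58.0  # slow-inactivation midpoint (mV)
    noise_sigma: float = 0.05  # mV·ms^-1/2

    def __post_init__(self) -> None:
        for name in ("g_naf", "g_nas", "g_kdr", "g_ka", "g_leak_k", "g_leak_ns", "g_chr2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        if self.k_in <= 0 or self.k_out <= 0:
            raise ValueError("K+ concentrations must be positive")

    @property
    def e_k(self) -> float:
        """Nernst K⁺ reversal — always derived from the concentrations."""
        return nernst_EK(self.k_out, self.k_in, self.rt_over_f)

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.c_m, self.g_naf, self.g_nas, self.g_kdr, self.g_ka,
            self.g_leak_k, self.g_leak_ns, self.g_chr2,
            self.e_na, self.e_ns, self.e_k,
            self.s_floor, self.tau_s_rest, self.tau_s_depol,
            self.hs_floor, self.tau_b_scale, self.noise_sigma, self.s_vh,
        ])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypePreset:
    """Parameter deltas producing one firing phenotype under control treatment."""

    label: str
    g_ka_mult: float = 1.0
    g_naf_mult: float = 1.0
    g_nas_mult: float = 1.0
    g_kdr_mult: float = 1.0
    tau_b_scale: float = 1.0
    s_floor: float = 0.15
    tau_s_rest: float = 300.0
    tau_s_depol: float = 0.9
    s_vh: float = -58.0

    def apply(self, p: ModelParams) -> ModelParams:
        return replace(p, g_ka=p.g_ka * self.g_ka_mult,
                       g_naf=p.g_naf * self.g_naf_mult,
                       g_nas=p.g_nas * self.g_nas_mult,
                       g_kdr=p.g_kdr * self.g_kdr_mult, tau_b_scale=self.tau_b_scale,
                       s_floor=self.s_floor, tau_s_rest=self.tau_s_rest,
                       tau_s_depol=self.tau_s_depol, s_vh=self.s_vh)


#: repeated = baseline; single = strong slow Na⁺ inactivation (rapid
#: accommodation); delayed = elevated, slowly inactivating A-type conductance.
PHENOTYPES = {
    "repeated": PhenotypePreset("repeated"),
    "single": PhenotypePreset("single", g_naf_mult=0.7, g_nas_mult=0.2, s_floor=0.0,
                              tau_s_rest=2000.0, tau_s_depol=1.0, s_vh=-63.0),
    "delayed": PhenotypePreset("delayed", g_ka_mult=5.0, tau_b_scale=20.0),
}

CHR2_CONDUCTANCE = 1.8  # nS, light-gated conductance of opsin-expressing cells


@dataclass(frozen=True)
class TreatmentPreset:
    """Cohort-level treatment: bath K⁺, Na⁺/A-type conductance scaling, light."""

    label: str
    k_out: float = 5.0
    s_na: float = 1.0  # Na+ conductance scale (the 24-h KCl adaptation)
    s_a: float = 1.0  # A-type conductance scale
    g_chr2: float = 0.0
    light_hz: float | None = None

    def __post_init__(self) -> None:
        if self.label in ("control", "recovery") and self.s_na != 1.0:
            raise ValueError(f"{self.label} treatment must have s_na == 1")
        if self.label == "kcl24h" and not 0.0 < self.s_na < 1.0:
            raise ValueError("kcl24h treatment requires 0 < s_na < 1")
        if self.label == "acute_kcl" and (self.k_out != 30.0 or self.s_na != 1.0):
            raise ValueError("acute_kcl treatment is K_out=30 with s_na == 1")

    def apply(self, p: ModelParams) -> ModelParams:
        return replace(p, k_out=self.k_out, g_naf=p.g_naf * self.s_na,
                       g_nas=p.g_nas * self.s_na, g_ka=p.g_ka * self.s_a,
                       g_chr2=self.g_chr2)


TREATMENTS = {
    "control": TreatmentPreset("control"),
    "kcl24h": TreatmentPreset("kcl24h", s_na=0.45, s_a=1.15),
    "recovery": TreatmentPreset("recovery"),
    "acute_kcl": TreatmentPreset("acute_kcl", k_out=30.0),
    "dark": TreatmentPreset("dark", g_chr2=CHR2_CONDUCTANCE),
    "hz1": TreatmentPreset("hz1", g_chr2=CHR2_CONDUCTANCE, light_hz=1.0),
}

#: which conductances a voltage-clamp recording "sees", emulating the
#: pharmacological isolation solutions (TTX/lidocaine kill Na⁺ for the K⁺
#: solution; TEA/Cs kill K⁺ for the Na⁺ solution).  Order:
#: (NaF, NaS, Kdr, KA, leakK, leakNS)
CHANNEL_MASKS = {
    "all": np.ones(6),
    "na_isolated": np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0]),
    "k_isolated": np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0]),
    "leak_only": np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0]),
}


# ---------------------------------------------------------------------------
# Gating math (single source for the numba kernels and the numpy oracles)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _sig(v, vh, k):
    return 1.0 / (1.0 + math.exp(-(v - vh) / k))


@njit(cache=True)
def _gates_inf_tau(v, s_floor, tau_s_rest, tau_s_depol, hs_floor, tau_b_scale, s_vh, out):
    """Fill ``out[18]`` with (inf, tau) for gates m,h,s,ms,hs,n,a,b,u."""
    out[0] = _sig(v, M_VH, M_K)
    out[1] = 0.03 + 0.12 / (1.0 + math.exp((v + 45.0) / 10.0))
    out[2] = _sig(v, H_VH, H_K)
    out[3] = 1.1 + 10.0 / (1.0 + math.exp((v + 30.0) / 6.0))
    out[4] = s_floor + (1.0 - s_floor) * _sig(v, s_vh, S_K)
    out[5] = tau_s_depol + (tau_s_rest - tau_s_depol) / (1.0 + math.exp((v + 38.0) / 4.5))
    out[6] = _sig(v, MS_VH, MS_K)
    out[7] = 0.7 + 1.9 / (1.0 + math.exp(-(v + 5.0) / 6.0))
    out[8] = hs_floor + (1.0 - hs_floor) * _sig(v, HS_VH, HS_K)
    out[9] = 6.0 + 50.0 / (1.0 + math.exp((v + 40.0) / 10.0))
    out[10] = _sig(v, N_VH, N_K)
    out[11] = 1.2 + 18.0 / (1.0 + math.exp((v + 28.0) / 8.0))
    out[12] = _sig(v, A_VH, A_K)
    out[13] = 1.5 + 3.0 / (1.0 + math.exp((v + 35.0) / 15.0))
    out[14] = _sig(v, B_VH, B_K)
    out[15] = tau_b_scale * (8.0 + 30.0 / (1.0 + math.exp((v + 55.0) / 10.0)))
    out[16] = U_FLOOR + (1.0 - U_FLOOR) * _sig(v, U_VH, U_K)
    out[17] = TAU_U


@njit(cache=True, inline="always")
def _ionic(v, g, p, light, mask):
    """Total ionic current (pA) for gate state ``g`` at voltage ``v``."""
    m, h, s, ms, hs, n, a, b, u = g[0], g[1], g[2], g[3], g[4], g[5], g[6], g[7], g[8]
    i = 0.0
    i += mask[0] * p[1] * m * m * m * h * s * (v - p[8])
    i += mask[1] * p[2] * ms * hs * (v - p[8])
    i += mask[2] * p[3] * n * n * n * n * u * (v - p[10])
    i += mask[3] * p[4] * a * a * a * b * (v - p[10])
    i += mask[4] * p[5] * (v - p[10])
    i += mask[5] * p[6] * (v - p[9])
    i += p[7] * light * (v - p[9])
    return i


@njit(cache=True)
def _init_gates(v, p, g):
    it = np.empty(18)
    _gates_inf_tau(v, p[11], p[12], p[13], p[14], p[15], p[17], it)
    for j in range(9):
        g[j] = it[2 * j]


@njit(cache=True)
def _cc_kernel(i_inj, light, oversample, dt, p, v0, i_hold, noise, settle_sub, v_out):
    """Current-clamp integration; records V on the acquisition grid."""
    g = np.empty(9)
    it = np.empty(18)
    ones = np.ones(6)
    _init_gates(v0, p, g)
    v = v0
    c = p[0]
    # unrecorded, noise-free settling under the first command value
    for _ in range(settle_sub):
        _gates_inf_tau(v, p[11], p[12], p[13], p[14], p[15], p[17], it)
        for j in range(9):
            g[j] += (it[2 * j] - g[j]) * (1.0 - math.exp(-dt / it[2 * j + 1]))
        v += dt * (-_ionic(v, g, p, 0.0, ones) + i_hold) / c
    n_out = v_out.shape[0]
    v_out[0] = v
    sq = math.sqrt(dt)
    k = 0
    for i in range(1, n_out):
        for _ in range(oversample):
            _gates_inf_tau(v, p[11], p[12], p[13], p[14], p[15], p[17], it)
            for j in range(9):
                g[j] += (it[2 * j] - g[j]) * (1.0 - math.exp(-dt / it[2 * j + 1]))
            v += dt * (-_ionic(v, g, p, light[i - 1], ones) + i_inj[i - 1] + i_hold) / c
            v += noise[k] * sq
            k += 1
        v_out[i] = v


@njit(cache=True)
def _vc_kernel(v_cmd, oversample, dt, p, mask, i_out):
    """Ideal voltage clamp: gates follow the command; membrane current recorded."""
    g = np.empty(9)
    it = np.empty(18)
    _init_gates(v_cmd[0], p, g)
    n_out = i_out.shape[0]
    i_out[0] = _ionic(v_cmd[0], g, p, 0.0, mask)
    for i in range(1, n_out):
        # command follows the sampled waveform (linear within a sample)
        for u in range(oversample):
            frac = (u + 1.0) / oversample
            v = v_cmd[i - 1] + frac * (v_cmd[i] - v_cmd[i - 1])
            _gates_inf_tau(v, p[11], p[12], p[13], p[14], p[15], p[17], it)
            for j in range(9):
                g[j] += (it[2 * j] - g[j]) * (1.0 - math.exp(-dt / it[2 * j + 1]))
        i_out[i] = _ionic(v_cmd[i], g, p, 0.0, mask)


# ---------------------------------------------------------------------------
# numpy mirrors for analytics/oracles
# ---------------------------------------------------------------------------

def _np_sig(v, vh, k):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - vh) / k))


def gate_steady_states(v, params: ModelParams) -> dict[str, np.ndarray]:
    """Steady-state gate values and time constants at voltage(s) ``v``.

    Returns a dict with keys ``m,h,s,ms,hs,n,a,b`` and ``tau_<gate>`` —
    the closed-form surface used by analytic oracles.
    """
    v = np.asarray(v, float)
    p = params
    out = {
        "m": _np_sig(v, M_VH, M_K),
        "tau_m": 0.03 + 0.12 / (1 + np.exp((v + 45.0) / 10.0)),
        "h": _np_sig(v, H_VH, H_K),
        "tau_h": 1.1 + 10.0 / (1 + np.exp((v + 30.0) / 6.0)),
        "s": p.s_floor + (1 - p.s_floor) * _np_sig(v, p.s_vh, S_K),
        "tau_s": p.tau_s_depol + (p.tau_s_rest - p.tau_s_depol) / (1 + np.exp((v + 38.0) / 4.5)),
        "ms": _np_sig(v, MS_VH, MS_K),
        "tau_ms": 0.7 + 1.9 / (1 + np.exp(-(v + 5.0) / 6.0)),
        "hs": p.hs_floor + (1 - p.hs_floor) * _np_sig(v, HS_VH, HS_K),
        "tau_hs": 6.0 + 50.0 / (1 + np.exp((v + 40.0) / 10.0)),
        "n": _np_sig(v, N_VH, N_K),
        "tau_n": 1.2 + 18.0 / (1 + np.exp((v + 28.0) / 8.0)),
        "a": _np_sig(v, A_VH, A_K),
        "tau_a": 1.5 + 3.0 / (1 + np.exp((v + 35.0) / 15.0)),
        "b": _np_sig(v, B_VH, B_K),
        "tau_b": p.tau_b_scale * (8.0 + 30.0 / (1 + np.exp((v + 55.0) / 10.0))),
        "u": U_FLOOR + (1 - U_FLOOR) * _np_sig(v, U_VH, U_K),
        "tau_u": np.full_like(np.asarray(v, float), TAU_U),
    }
    return out


def ionic_current_ss(v, params: ModelParams, mask: np.ndarray | None = None,
                     light: float = 0.0) -> np.ndarray:
    """Steady-state total ionic current (pA) at voltage(s) ``v``."""
    g = gate_steady_states(v, params)
    m = np.ones(6) if mask is None else np.asarray(mask, float)
    p = params
    v = np.asarray(v, float)
    i = (m[0] * p.g_naf * g["m"] ** 3 * g["h"] * g["s"] * (v - p.e_na)
         + m[1] * p.g_nas * g["ms"] * g["hs"] * (v - p.e_na)
         + m[2] * p.g_kdr * g["n"] ** 4 * g["u"] * (v - p.e_k)
         + m[3] * p.g_ka * g["a"] ** 3 * g["b"] * (v - p.e_k)
         + m[4] * p.g_leak_k * (v - p.e_k)
         + m[5] * p.g_leak_ns * (v - p.e_ns)
         + p.g_chr2 * light * (v - p.e_ns))
    return i


def slope_conductance(params: ModelParams, v: float, dv: float = 0.5) -> float:
    """Slope conductance dI_ss/dV (nS) at ``v`` — analytic R_in oracle."""
    return float((ionic_current_ss(v + dv, params) - ionic_current_ss(v - dv, params)) / (2 * dv))


def steady_state_voltage(params: ModelParams, lo: float = -95.0, hi: float = -25.0) -> float:
    """Zero of the steady-state I–V curve (the model's resting potential)."""
    from scipy.optimize import brentq

    f = lambda v: float(ionic_current_ss(v, params))
    vv = np.linspace(lo, hi, 141)
    ii = ionic_current_ss(vv, params)
    sign_change = np.nonzero(np.diff(np.sign(ii)) != 0)[0]
    if sign_change.size == 0:
        raise RuntimeError("no steady state in the search window")
    k = sign_change[0]
    return float(brentq(f, vv[k], vv[k + 1]))


# ---------------------------------------------------------------------------
# Simulation drivers
# ---------------------------------------------------------------------------

def _noise_array(seed, n: int, sigma: float) -> np.ndarray:
    if sigma == 0.0 or seed is None:
        return np.zeros(n)
    rng = np.random.Generator(np.random.PCG64(seed))
    return sigma * rng.standard_normal(n)


def _holding_current(params: ModelParams, v_hold: float) -> float:
    """Bias current an experimenter would apply to hold ``v_hold`` pre-stimulus."""
    return float(ionic_current_ss(v_hold, params))


def simulate_sweep_cc(params: ModelParams, protocol: Protocol, sweep_index: int,
                      seed=None, oversample: int = OVERSAMPLE) -> Sweep:
    """Integrate one current-clamp sweep of ``protocol``."""
    cmd = protocol.command_array(sweep_index)
    n = cmd.size
    dt = 1000.0 / protocol.sampling_rate / oversample
    if protocol.kind == "opto_train":
        light, i_inj = cmd, np.zeros(n)
    else:
        light, i_inj = np.zeros(n), cmd
    if protocol.holding_level is not None:
        v0, i_hold, settle = protocol.holding_level, _holding_current(params, protocol.holding_level), 0
    else:
        v0, i_hold = -60.0, 0.0
        settle = int(round(SETTLE_MS / dt))
    noise = _noise_array(seed, (n - 1) * oversample, params.noise_sigma)
    v_out = np.empty(n)
    _cc_kernel(i_inj, light, oversample, dt, params.to_vector(), v0, i_hold,
               noise, settle, v_out)
    if not np.all(np.isfinite(v_out)):
        raise RuntimeError(f"integration diverged on sweep {sweep_index}")
    return Sweep(sweep_index, protocol.sampling_rate, v_out, cmd, "current",
                 protocol.sweeps[sweep_index])


def simulate_current_clamp(params: ModelParams, protocol: Protocol, seed: int = 0,
                           sweep_indices: Sequence[int] | None = None,
                           cell_id: str = "sim", group: str = "control",
                           oversample: int = OVERSAMPLE) -> Recording:
    """Simulate a current-clamp protocol family into a Recording.

    The holding current needed to sit at the protocol's holding potential is
    computed from the steady-state I–V curve and applied throughout the
    sweep (mirroring the experimenter's bias current).  Unheld protocols
    (zero-current, optogenetic trains) settle from −60 mV for 1.5 s of
    unrecorded model time instead.  Deterministic given ``seed``.
    """
    if protocol.clamp_mode != "current":
        raise ValueError("simulate_current_clamp requires a current-clamp protocol")
    idx = list(range(protocol.n_sweeps)) if sweep_indices is None else sorted(sweep_indices)
    sweeps = []
    ss = np.random.SeedSequence([zlib.crc32(cell_id.encode()) % (2 ** 31), seed or 0])
    child = ss.generate_state(protocol.n_sweeps, dtype=np.uint32)
    for k in idx:
        sweeps.append(simulate_sweep_cc(params, protocol, k, int(child[k]), oversample))
    rec = Recording(cell_id, group, species=protocol.species_preset or "mouse",
                    provenance={"synthetic_seed": seed})
    rec.add(protocol.kind, protocol, sweeps)
    return rec


def simulate_voltage_clamp(params: ModelParams, protocol: Protocol,
                           channel_mask="all", cell_id: str = "sim",
                           group: str = "control",
                           oversample: int = OVERSAMPLE) -> Recording:
    """Simulate a voltage-clamp family under an ideal clamp (no series-R error).

    ``channel_mask`` selects the active conductances, emulating the
    pharmacological isolation solutions; use ``"na_isolated"``,
    ``"k_isolated"``, ``"leak_only"``, ``"all"`` or a 6-vector
    (NaF, NaS, Kdr, KA, leakK, leakNS).
    """
    if protocol.clamp_mode != "voltage":
        raise ValueError("simulate_voltage_clamp requires a voltage-clamp protocol")
    mask = CHANNEL_MASKS[channel_mask] if isinstance(channel_mask, str) else np.asarray(channel_mask, float)
    if mask.size != 6 or not mask.any():
        raise ValueError("channel_mask must select at least one conductance")
    dt = 1000.0 / protocol.sampling_rate / oversample
    p = params.to_vector()
    sweeps = []
    for k in range(protocol.n_sweeps):
        cmd = protocol.command_array(k)
        i_out = np.empty(cmd.size)
        _vc_kernel(cmd, oversample, dt, p, mask, i_out)
        if not np.all(np.isfinite(i_out)):
            raise RuntimeError(f"integration diverged on sweep {k}")
        sweeps.append(Sweep(k, protocol.sampling_rate, i_out, cmd, "voltage",
                            protocol.sweeps[k]))
    rec = Recording(cell_id, group, species=protocol.species_preset or "mouse",
                    provenance={"channel_mask": list(map(float, mask))})
    rec.add(protocol.kind, protocol, sweeps)
    return rec


# ---------------------------------------------------------------------------
# Ground-truth rheobase (fine grid, noise-free)
# ---------------------------------------------------------------------------

def _single_amp_protocol(kind: str, amp: float, species: str) -> Protocol:
    from .traces import StimulusSegment

    pre, stim, post = 100.0, 1000.0, 200.0
    if kind == "ramp":
        seg = StimulusSegment("ramp", pre, pre + stim, 0.0, amp)
    else:
        seg = StimulusSegment("step", pre, pre + stim, amp, amp)
    segs = [StimulusSegment("hold", 0.0, pre, 0.0, 0.0), seg,
            StimulusSegment("hold", pre + stim, pre + stim + post, 0.0, 0.0)]
    return Protocol(f"cc_{kind}", "current", [segs], holding_level=-60.0,
                    species_preset=species)


def fires_at(params: ModelParams, kind: str, amp: float, species: str = "mouse") -> bool:
    """Noise-free firing test: does a 1 s step/ramp of ``amp`` pA evoke a spike?

    A spike is any sample reaching 0 mV during the stimulus epoch — the same
    criterion as the brute-force AP-count oracle.
    """
    quiet = replace(params, noise_sigma=0.0)
    proto = _single_amp_protocol(kind, amp, species)
    sw = simulate_sweep_cc(quiet, proto, 0, seed=None)
    t = sw.time_ms
    lo, hi = proto.stimulus_window(0)
    return bool(np.any(sw.recorded[(t >= lo) & (t < hi)] >= 0.0))


def true_rheobase(params: ModelParams, kind: str = "step", species: str = "mouse",
                  resolution: float = 1.0) -> float:
    """Fine-grid rheobase (pA) by noise-free bisection; ``inf`` if a non-responder.

    Assumes firing is monotone in stimulus amplitude (holds for this model —
    property-tested).  The default 1 pA resolution is the simulator's
    ground-truth grid against which the 10 pA pipeline estimate is bounded.
    """
    cap = SPECIES_PRESETS[species]["cap"]
    if not fires_at(params, kind, cap, species):
        return math.inf
    # bisection over the integer multiples of `resolution`, so the result is
    # the smallest grid amplitude that fires (the coarse family grid is a
    # subset of this grid, which makes the grid-bound property exact)
    klo, khi = 0, int(math.ceil(cap / resolution))
    while khi - klo > 1:
        kmid = (klo + khi) // 2
        if fires_at(params, kind, kmid * resolution, species):
            khi = kmid
        else:
            klo = kmid
    return khi * resolution


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One experimental group: a treatment applied to a phenotype mixture."""

    name: str  # closed vocabulary of Recording.group labels
    treatment: str  # key into TREATMENTS
    n: int
    mixture: dict[str, float] = field(default_factory=lambda: {
        "single": 12 / 36, "delayed": 5 / 36, "repeated": 19 / 36,
    })

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        tot = sum(self.mixture.values())
        if not math.isclose(tot, 1.0, rel_tol=1e-6):
            raise ValueError("phenotype mixture must sum to 1")


@dataclass
class CohortConfig:
    """Design of a synthetic cohort; identical config + seed ⇒ identical bundles."""

    groups: list[GroupSpec]
    families: tuple[str, ...] = ("cc_zero", "cc_ramp", "cc_step", "cc_hyper")
    species: str = "mouse"
    jitter_cv: float = 0.15
    seed: int = 0
    matched: bool = False  # same base cells in every group (in-silico counterfactual)
    fine_rheobase: bool = True
    full_families: bool = False  # simulate every sweep instead of stopping early
    opto_n_pulses: int = 30


@dataclass
class CohortResult:
    recordings: list[Recording]
    ground_truth: pd.DataFrame


_JITTERED = ("g_naf", "g_nas", "g_kdr", "g_ka", "g_leak_k", "g_leak_ns", "c_m")


def _jittered_params(base: ModelParams, cv: float, rng: np.random.Generator) -> ModelParams:
    """Log-normal multiplicative jitter (median preserved) on conductances and C_m."""
    if cv <= 0:
        return base
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    fields = {name: getattr(base, name) * math.exp(sigma * rng.standard_normal())
              for name in _JITTERED}
    return replace(base, **fields)


def _stratified_labels(mixture: dict[str, float], n: int) -> list[str]:
    """Realize a phenotype mixture exactly (largest-remainder apportionment).

    The cohort composition is treated as a controlled design variable, so
    equal-n groups share an identical phenotype make-up and group contrasts
    are not confounded by sampling of the mixture itself.
    """
    labels = sorted(mixture)
    quotas = {l: mixture[l] * n for l in labels}
    counts = {l: int(math.floor(quotas[l])) for l in labels}
    short = n - sum(counts.values())
    for l in sorted(labels, key=lambda l: quotas[l] - counts[l], reverse=True)[:short]:
        counts[l] += 1
    out = []
    for l in labels:
        out.extend([l] * counts[l])
    return out


def _spike_in_stim(sw: Sweep, window: tuple[float, float]) -> bool:
    t = sw.time_ms
    return bool(np.any(sw.recorded[(t >= window[0]) & (t < window[1])] >= 0.0))


def _simulate_family(params: ModelParams, protocol: Protocol, seed: int,
                     cell_id: str, full: bool) -> list[Sweep]:
    """Simulate a cc family, optionally stopping once the firing pattern is known.

    The early-stop policy keeps every sweep up to the first spiking sweep and
    (for step families) adds the grid-snapped 2–4× rheobase sweeps the
    accommodation analysis needs; non-responders are simulated to the cap.
    """
    ss = np.random.SeedSequence([zlib.crc32(cell_id.encode()) % (2 ** 31), seed])
    child = ss.generate_state(protocol.n_sweeps, dtype=np.uint32)
    if full or protocol.kind not in ("cc_ramp", "cc_step"):
        return [simulate_sweep_cc(params, protocol, k, int(child[k]))
                for k in range(protocol.n_sweeps)]
    sweeps = []
    window = protocol.stimulus_window(0)
    first = None
    for k in range(protocol.n_sweeps):
        sw = simulate_sweep_cc(params, protocol, k, int(child[k]))
        sweeps.append(sw)
        if _spike_in_stim(sw, window):
            first = k
            break
    if first is not None and protocol.kind == "cc_step":
        for mult in (2, 3, 4):
            k = (first + 1) * mult - 1  # snapped to the grid amp <= exact multiple
            if k < protocol.n_sweeps and k > first:
                sweeps.append(simulate_sweep_cc(params, protocol, k, int(child[k])))
    seen = {}
    for sw in sweeps:
        seen[sw.sweep_index] = sw
    return [seen[k] for k in sorted(seen)]


def species_base_params(species: str) -> ModelParams:
    """Baseline cell for a species preset.

    Human somata are far larger than mouse; the preset scales capacitance to
    ~120 pF with matching conductance scaling (preserving current densities
    and kinetics), which together with the 100 pA / 10 nA stimulus grid keeps
    rheobase on the human grid.  Kinetics are not species-specific.
    """
    base = ModelParams()
    if species == "human":
        f = 120.0 / base.c_m
        base = replace(base, c_m=120.0,
                       **{name: getattr(base, name) * f for name in _JITTERED
                          if name != "c_m"})
    return base


def iter_cohort(config: CohortConfig):
    """Yield ``(Recording, ground_truth_row)`` per cell without holding the cohort.

    Memory-light streaming variant of :func:`generate_cohort`; the iteration
    order and every trace are identical to the collected version.
    """
    base = species_base_params(config.species)
    cell_counter = 0
    seen_ids = set()
    for gi, spec in enumerate(config.groups):
        treat = TREATMENTS[spec.treatment]
        phen_list = _stratified_labels(spec.mixture, spec.n)
        for ci in range(spec.n):
            key = ci if config.matched else cell_counter
            rng = np.random.Generator(np.random.PCG64(
                np.random.SeedSequence([config.seed, 1000 + key])))
            phen = phen_list[ci]
            cell = _jittered_params(base, config.jitter_cv, rng)
            cell = PHENOTYPES[phen].apply(cell)
            cell = treat.apply(cell)
            cell_id = f"{spec.name}_{ci:03d}"
            if cell_id in seen_ids:
                raise ValueError(f"duplicate cell id {cell_id}")
            seen_ids.add(cell_id)
            noise_seed = int(np.random.SeedSequence(
                [config.seed, 2000 + gi * 10000 + ci]).generate_state(1)[0] % (2 ** 31))
            rec = Recording(cell_id, spec.name, species=config.species,
                            diameter_um=20.0,
                            provenance={"synthetic_seed": noise_seed,
                                        "phenotype": phen,
                                        "treatment": spec.treatment})
            for fam in config.families:
                if fam == "opto_train":
                    hz = treat.light_hz or 1.0
                    proto = make_protocol(fam, config.species, freq_hz=hz,
                                          n_pulses=config.opto_n_pulses)
                else:
                    proto = make_protocol(fam, config.species)
                if proto.clamp_mode == "voltage":
                    mask = "na_isolated" if fam.startswith("vc_na") else "k_isolated"
                    vrec = simulate_voltage_clamp(cell, proto, mask, cell_id=cell_id,
                                                  group=spec.name)
                    rec.add(fam, proto, vrec.family(fam).sweeps)
                else:
                    sweeps = _simulate_family(cell, proto, noise_seed, cell_id,
                                              config.full_families)
                    rec.add(fam, proto, sweeps)
            row = {"cell_id": cell_id, "group": spec.name,
                   "treatment": spec.treatment, "phenotype": phen,
                   "species": config.species, "noise_seed": noise_seed,
                   "s_na": treat.s_na, "k_out": treat.k_out}
            row.update({name: getattr(cell, name) for name in _JITTERED})
            if config.fine_rheobase:
                for kind in ("step", "ramp"):
                    rb = true_rheobase(cell, kind, config.species)
                    row[f"true_rheobase_{kind}"] = rb
            yield rec, row
            cell_counter += 1


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> CohortResult:
    """Generate a full synthetic cohort plus its ground-truth table.

    Every cell gets per-cell log-normally jittered parameters, its group's
    treatment preset, and the requested protocol families.  Fully
    deterministic for a given config; per-cell seeds derive from the master
    seed by a counter scheme.  With ``matched=True`` the same base cells are
    reused in every group (treatment contrasts become paired).  For large
    cohorts prefer the streaming :func:`iter_cohort`, which this wraps.
    """
    recs: list[Recording] = []
    rows = []
    writer = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .traces import write_bundle as writer
    for rec, row in iter_cohort(config):
        if writer is not None:
            writer(rec, out_dir / rec.cell_id)
        recs.append(rec)
        rows.append(row)
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return CohortResult(recs, truth)
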