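"""Simulator behavior: Nernst physics, determinism, calibration windows,
rheobase monotonicity, voltage-clamp linearity, and cohort generation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nociplast.simulate import (
    CHANNEL_MASKS,
    CohortConfig,
    GroupSpec,
    ModelParams,
    PHENOTYPES,
    TREATMENTS,
    fires_at,
    gate_steady_states,
    generate_cohort,
    ionic_current_ss,
    nernst_EK,
    simulate_current_clamp,
    simulate_voltage_clamp,
    steady_state_voltage,
    true_rheobase,
)
from nociplast.spikes import detect_aps
from nociplast.traces import make_protocol
from nociplast.vclamp import fit_leak, leak_subtract, ramp_peak_inward


@pytest.mark.parametrize("k_out,k_in,rtf,expected", [
    (140.0, 140.0, 25.7, 0.0),
    (30.0, 140.0, 25.7, -39.6),
    (5.0, 140.0, 25.7, -85.6),
])
def test_nernst(k_out, k_in, rtf, expected):
    assert nernst_EK(k_out, k_in, rtf) == pytest.approx(expected, abs=0.05)


def test_nernst_rejects_nonpositive():
    with pytest.raises(ValueError):
        nernst_EK(0.0, 140.0)


def test_ek_never_stale(params):
    assert replace(params, k_out=30.0).e_k == pytest.approx(nernst_EK(30, 140))


def test_current_clamp_determinism(params):
    proto = make_protocol("cc_zero", "mouse")
    a = simulate_current_clamp(params, proto, seed=42).family("cc_zero").sweeps[0]
    b = simulate_current_clamp(params, proto, seed=42).family("cc_zero").sweeps[0]
    c = simulate_current_clamp(params, proto, seed=43).family("cc_zero").sweeps[0]
    assert np.array_equal(a.recorded, b.recorded)
    assert not np.array_equal(a.recorded, c.recorded)


def test_resting_potential_window(params):
    proto = make_protocol("cc_zero", "mouse")
    v = simulate_current_clamp(params, proto, seed=1).family("cc_zero").sweeps[0].recorded
    assert -75.0 <= v.mean() <= -40.0


def test_acute_kcl_depolarizes_steadily(params):
    proto = make_protocol("cc_zero", "mouse")
    pk = TREATMENTS["acute_kcl"].apply(params)
    v = simulate_current_clamp(pk, proto, seed=1).family("cc_zero").sweeps[0].recorded
    assert -20.0 <= v[v.size // 2:].mean() <= -10.0


def test_raising_k_out_raises_v_rest(params):
    proto = make_protocol("cc_zero", "mouse")
    quiet = replace(params, noise_sigma=0.0)
    means = []
    for k_out in (5.0, 10.0, 30.0):
        p = replace(quiet, k_out=k_out)
        v = simulate_current_clamp(p, proto, seed=None).family("cc_zero").sweeps[0].recorded
        means.append(v[v.size // 2:].mean())
    assert means[0] < means[1] < means[2]


def test_no_spikes_without_na(params):
    p = replace(params, g_naf=0.0, g_nas=0.0, noise_sigma=0.0)
    proto = make_protocol("cc_step", "mouse")
    rec = simulate_current_clamp(p, proto, seed=None, sweep_indices=[49])  # 500 pA
    assert detect_aps(rec.family("cc_step").sweeps[0]) == []


def test_rheobase_monotone_in_conductances(params):
    base = replace(params, noise_sigma=0.0)
    rb_naf = [true_rheobase(replace(base, g_naf=g), "step", resolution=2.0)
              for g in (240.0, 300.0, 360.0)]
    assert rb_naf[0] >= rb_naf[1] >= rb_naf[2]
    rb_kdr = [true_rheobase(replace(base, g_kdr=g), "step", resolution=2.0)
              for g in (55.0, 75.0, 95.0)]
    assert rb_kdr[0] <= rb_kdr[1] <= rb_kdr[2]


def test_integration_blowup_raises(params):
    # a nonsensical huge conductance must fail loudly, not emit garbage
    p = replace(params, g_naf=1e9, noise_sigma=0.0)
    proto = make_protocol("cc_step", "mouse")
    with pytest.raises(RuntimeError):
        simulate_current_clamp(p, proto, seed=None, sweep_indices=[49])


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def test_leak_only_mask_is_ohmic(params):
    proto = make_protocol("vc_na_step")
    rec = simulate_voltage_clamp(params, proto, "leak_only")
    for sw in rec.family("vc_na_step").sweeps:
        expected = (params.g_leak_k * (sw.command - params.e_k)
                    + params.g_leak_ns * (sw.command - params.e_ns))
        assert np.allclose(sw.recorded, expected, atol=1e-6)


def test_empty_mask_rejected(params):
    with pytest.raises(ValueError):
        simulate_voltage_clamp(params, make_protocol("vc_na_ramp"), np.zeros(6))


def test_na_current_linear_in_conductance(params):
    proto = make_protocol("vc_na_ramp")

    def peak(scale):
        p = replace(params, g_naf=params.g_naf * scale, g_nas=params.g_nas * scale)
        rec = simulate_voltage_clamp(p, proto, "na_isolated")
        sw = rec.family("vc_na_ramp").sweeps[0]
        leak = fit_leak([sw])
        return ramp_peak_inward(leak_subtract(sw, leak), proto)[0]

    full, half = peak(1.0), peak(0.5)
    assert half / full == pytest.approx(0.5, rel=0.02)


def test_na_step_iv_minimum_matches_analytic(params):
    """The simulated IV minimum sits where a dense analytic sweep of the peak
    transient Na+ current puts it (and inside the -20..0 mV band)."""
    proto = make_protocol("vc_na_step")
    rec = simulate_voltage_clamp(params, proto, "na_isolated")
    peaks = []
    volts = np.arange(-60.0, 30.0, 10.0)
    for sw in rec.family("vc_na_step").sweeps:
        lo, hi = proto.stimulus_window(sw.sweep_index)
        m = (sw.time_ms >= lo) & (sw.time_ms < hi)
        leak = (params.g_leak_k * (sw.command - params.e_k)
                + params.g_leak_ns * sw.command)
        peaks.append((sw.recorded - leak)[m].min())
    sim_vmin = volts[int(np.argmin(peaks))]

    # analytic: peak transient current ~ g*m_inf(V)^3*h0*s0*(V-E_Na) on a dense grid
    g0 = gate_steady_states(-80.0, params)
    vv = np.linspace(-60.0, 20.0, 801)
    gv = gate_steady_states(vv, params)
    i_peak = (params.g_naf * gv["m"] ** 3 * g0["h"] * g0["s"]
              + params.g_nas * gv["ms"] * g0["hs"]) * (vv - params.e_na)
    ana_vmin = vv[int(np.argmin(i_peak))]
    assert abs(sim_vmin - ana_vmin) <= 10.0  # same grid point
    assert -20.0 <= sim_vmin <= 0.0


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def test_cohort_bundles_byte_identical(tmp_path):
    cfg = CohortConfig(
        groups=[GroupSpec(g, t, 2) for g, t in
                (("control", "control"), ("kcl", "kcl24h"),
                 ("kcl_recovery", "recovery"), ("dark", "dark"))],
        families=("cc_zero", "cc_hyper"), seed=7, fine_rheobase=False)
    generate_cohort(cfg, out_dir=tmp_path / "a")
    generate_cohort(cfg, out_dir=tmp_path / "b")
    files = sorted(p.relative_to(tmp_path / "a") for p in (tmp_path / "a").rglob("*") if p.is_file())
    assert files
    for f in files:
        assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()


def test_cohort_validation():
    with pytest.raises(ValueError):
        GroupSpec("control", "control", 0)
    with pytest.raises(ValueError):
        GroupSpec("control", "control", 5, mixture={"single": 0.7})


def test_kcl_cohort_true_rheobase_shifts_up():
    cfg = CohortConfig(groups=[GroupSpec("control", "control", 6),
                               GroupSpec("kcl", "kcl24h", 6)],
                       families=(), seed=3, fine_rheobase=True)
    res = generate_cohort(cfg)
    truth = res.ground_truth
    ctrl = truth[truth.group == "control"]["true_rheobase_ramp"]
    kcl = truth[truth.group == "kcl"]["true_rheobase_ramp"]
    assert kcl.median() > ctrl.median()


def test_opto_group_has_light_pulses():
    cfg = CohortConfig(groups=[GroupSpec("hz1", "hz1", 1)],
                       families=("opto_train",), seed=2, fine_rheobase=False,
                       opto_n_pulses=5)
    rec = generate_cohort(cfg).recordings[0]
    grp = rec.family("opto_train")
    assert grp.protocol.sweeps[0][0].kind == "pulse_train"
    assert grp.sweeps[0].command.max() == 1.0  # light gate present


def test_treatment_preset_invariants():
    from nociplast.simulate import TreatmentPreset

    with pytest.raises(ValueError):
        TreatmentPreset("control", s_na=0.5)
    with pytest.raises(ValueError):
        TreatmentPreset("kcl24h", s_na=1.0)
    with pytest.raises(ValueError):
        TreatmentPreset("acute_kcl", k_out=5.0)


def test_steady_state_voltage_matches_simulation(params):
    v_ss = steady_state_voltage(params)
    proto = make_protocol("cc_zero", "mouse")
    v = simulate_current_clamp(replace(params, noise_sigma=0.0), proto,
                               seed=None).family("cc_zero").sweeps[0].recorded
    assert v[-5000:].mean() == pytest.approx(v_ss, abs=0.5)
    assert abs(ionic_current_ss(v_ss, params)) < 1e-6
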