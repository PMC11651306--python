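"""Rheobase, suprathreshold counts, firing classification, passive properties,
and optogenetic fidelity."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nociplast.excitability import (
    classify_firing,
    estimate_capacitance,
    firing_fidelity,
    input_resistance,
    resting_potential,
    rheobase_from_family,
    suprathreshold_counts,
    analyze_recording,
)
from nociplast.simulate import (
    ModelParams,
    PHENOTYPES,
    TREATMENTS,
    simulate_current_clamp,
    slope_conductance,
    true_rheobase,
)
from nociplast.simulate import _simulate_family, _single_amp_protocol
from nociplast.traces import Protocol, Sweep, make_protocol

RATE = 50_000.0


def _fake_step_family(spikes_by_sweep: dict[int, list[float]], n_sweeps: int = 100,
                      baseline: float = -60.0) -> tuple[list[Sweep], Protocol]:
    """Cheap synthetic mouse step family: Gaussian spikes at given times (ms)."""
    proto = make_protocol("cc_step", "mouse")
    sweeps = []
    n = proto.n_samples(0)
    t = np.arange(n) / RATE * 1000.0
    for k in range(n_sweeps):
        v = np.full(n, baseline)
        for t0 in spikes_by_sweep.get(k, []):
            v += 100.0 * np.exp(-((t - t0) ** 2) / (2 * 0.4 ** 2))
        sweeps.append(Sweep(k, RATE, v, proto.command_array(k), "current", proto.sweeps[k]))
    return sweeps, proto


def test_rheobase_first_firing_sweep():
    sweeps, proto = _fake_step_family({24: [150.0], 30: [150.0]}, n_sweeps=40)
    rb = rheobase_from_family(sweeps, proto)
    assert rb.responder and rb.rheobase == 250.0 and rb.sweep_index == 24


def test_rheobase_non_responder_gets_cap():
    sweeps, proto = _fake_step_family({}, n_sweeps=100)
    rb = rheobase_from_family(sweeps, proto)
    assert not rb.responder and rb.rheobase == 1000.0 and rb.sweep_index is None


def test_rheobase_first_sweep_boundary():
    sweeps, proto = _fake_step_family({0: [150.0]}, n_sweeps=5)
    rb = rheobase_from_family(sweeps, proto)
    assert rb.responder and rb.rheobase == 10.0


def test_rheobase_rejects_empty_and_unsorted():
    sweeps, proto = _fake_step_family({0: [150.0]}, n_sweeps=3)
    with pytest.raises(ValueError):
        rheobase_from_family([], proto)
    with pytest.raises(ValueError):
        rheobase_from_family(sweeps[::-1], proto)


def test_rheobase_grid_bound_on_simulated_cell(params):
    """Family rheobase brackets the fine-grid truth from above by <= one step."""
    quiet = replace(params, noise_sigma=0.0)
    proto = make_protocol("cc_step", "mouse")
    sweeps = _simulate_family(quiet, proto, seed=0, cell_id="cell", full=False)
    rb = rheobase_from_family(sweeps, proto)
    truth = true_rheobase(quiet, "step")
    assert truth <= rb.rheobase < truth + 10.0


def test_suprathreshold_counts_and_cap_flag():
    spikes = {9: [150.0], 19: [150.0, 300.0], 29: [150.0] * 1, 39: [150.0, 200.0, 250.0]}
    sweeps, proto = _fake_step_family(spikes, n_sweeps=100)
    rb = rheobase_from_family(sweeps, proto)
    counts = suprathreshold_counts(sweeps, proto, rb)
    assert counts == {1: 1.0, 2: 2.0, 3: 1.0, 4: 3.0}

    # rheobase 990 pA: 2-4x are beyond the 1 nA cap and must be absent, not 0
    sweeps, proto = _fake_step_family({98: [150.0]}, n_sweeps=100)
    rb = rheobase_from_family(sweeps, proto)
    counts = suprathreshold_counts(sweeps, proto, rb)
    assert counts[1] == 1.0
    assert all(math.isnan(counts[m]) for m in (2, 3, 4))


@pytest.mark.parametrize("spikes,expected", [
    # first AP 578 ms after onset (onset at 100 ms) -> delayed
    ({9: [678.0], 19: [678.0], 29: [678.0], 39: [678.0]}, "delayed"),
    # exactly one onset AP on every suprathreshold sweep -> single
    ({9: [150.0], 19: [150.0], 29: [150.0], 39: [150.0]}, "single"),
    # onset firing with continued APs at higher drive -> repeated
    ({9: [150.0], 19: [150.0, 500.0], 29: [150.0, 400.0, 700.0], 39: [150.0, 300.0]},
     "repeated"),
])
def test_classifier_rules(spikes, expected):
    sweeps, proto = _fake_step_family(spikes, n_sweeps=50)
    rb = rheobase_from_family(sweeps, proto)
    counts = suprathreshold_counts(sweeps, proto, rb)
    sub = classify_firing(sweeps, proto, rb, counts)
    assert sub.label == expected


def test_classifier_requires_responder():
    sweeps, proto = _fake_step_family({}, n_sweeps=10)
    rb = rheobase_from_family(sweeps, proto)
    sub = classify_firing(sweeps, proto, rb, {})
    assert sub.label == "unclassified" and "non-responder" in sub.reason


@pytest.mark.parametrize("level,included", [(-57.5, True), (-30.0, False), (-80.0, False)])
def test_resting_potential_rule(level, included):
    proto = make_protocol("cc_zero", "mouse")
    n = proto.n_samples(0)
    sw = Sweep(0, RATE, np.full(n, level), np.zeros(n), "current", proto.sweeps[0])
    v, inc = resting_potential(sw, proto)
    assert v == pytest.approx(level) and inc is included


def _rc_sweep(r_mohm=500.0, c_pf=20.0, i_pa=-10.0):
    proto = make_protocol("cc_hyper", "mouse")
    n = proto.n_samples(0)
    t = np.arange(n) / RATE * 1000.0
    tau = r_mohm * c_pf / 1000.0  # ms
    dv = i_pa * r_mohm / 1000.0  # mV
    v = np.full(n, -60.0)
    lo, hi = proto.stimulus_window(0)
    on = (t >= lo) & (t < hi)
    v[on] = -60.0 + dv * (1 - np.exp(-(t[on] - lo) / tau))
    off = t >= hi
    v[off] = -60.0 + dv * np.exp(-(t[off] - hi) / tau) * (1 - math.exp(-(hi - lo) / tau))
    cmd = proto.command_array(0) * (i_pa / -10.0)
    segs = [replace(s, amp_start=s.amp_start * (i_pa / -10.0),
                    amp_end=s.amp_end * (i_pa / -10.0)) for s in proto.sweeps[0]]
    return Sweep(0, RATE, v, cmd, "current", segs), proto


def test_input_resistance_ohms_law():
    sw, proto = _rc_sweep(r_mohm=500.0, i_pa=-10.0)
    assert input_resistance(sw, proto) == pytest.approx(500.0, rel=1e-3)


def test_input_resistance_requires_hyperpolarizing():
    sw, proto = _rc_sweep()
    pos = Sweep(0, RATE, sw.recorded, -sw.command, "current",
                [replace(s, amp_start=-s.amp_start, amp_end=-s.amp_end) for s in sw.segments])
    with pytest.raises(ValueError):
        input_resistance(pos, proto)


def test_capacitance_from_tau():
    sw, proto = _rc_sweep(r_mohm=500.0, c_pf=20.0)
    r = input_resistance(sw, proto)
    assert estimate_capacitance(sw, proto, r) == pytest.approx(20.0, rel=0.02)


def test_capacitance_fit_failure_flagged():
    proto = make_protocol("cc_hyper", "mouse")
    n = proto.n_samples(0)
    rng = np.random.default_rng(0)
    sw = Sweep(0, RATE, -60.0 + rng.standard_normal(n), proto.command_array(0),
               "current", proto.sweeps[0])
    with pytest.raises(ValueError):
        estimate_capacitance(sw, proto, 500.0)


def test_simulated_passive_properties_recover_truth(params):
    quiet = replace(params, noise_sigma=0.0)
    proto = make_protocol("cc_hyper", "mouse")
    rec = simulate_current_clamp(quiet, proto, seed=None)
    sw = rec.family("cc_hyper").sweeps[0]
    r_in = input_resistance(sw, proto)
    g_slope = slope_conductance(quiet, -60.0)
    assert r_in == pytest.approx(1000.0 / g_slope, rel=0.10)
    c_m = estimate_capacitance(sw, proto, r_in)
    assert c_m == pytest.approx(quiet.c_m, rel=0.15)


def _fake_opto_sweep(n_pulses=60, missing=()):
    proto = make_protocol("opto_train", freq_hz=1.0, n_pulses=n_pulses)
    n = proto.n_samples(0)
    t = np.arange(n) / RATE * 1000.0
    v = np.full(n, -60.0)
    for k in range(n_pulses):
        if k in missing:
            continue
        v += 100.0 * np.exp(-((t - (k * 1000.0 + 5.0)) ** 2) / (2 * 0.4 ** 2))
    return Sweep(0, RATE, v, proto.command_array(0), "current", proto.sweeps[0]), proto


def test_fidelity_strict_rule():
    sw, proto = _fake_opto_sweep(60)
    assert firing_fidelity(sw, proto) == 1.0
    sw, proto = _fake_opto_sweep(60, missing=(17,))
    assert firing_fidelity(sw, proto) == pytest.approx(59 / 60)


def test_simulated_fidelity_1hz_vs_10hz(params):
    po = replace(TREATMENTS["hz1"].apply(params), noise_sigma=0.0)
    out = {}
    for hz in (1.0, 10.0):
        proto = make_protocol("opto_train", "mouse", freq_hz=hz, n_pulses=15)
        rec = simulate_current_clamp(po, proto, seed=3)
        grp = rec.family("opto_train")
        out[hz] = firing_fidelity(grp.sweeps[0], grp.protocol)
    assert out[1.0] == 1.0
    assert out[10.0] < 1.0


def test_analyze_recording_end_to_end(params):
    from nociplast.simulate import CohortConfig, GroupSpec, iter_cohort

    cfg = CohortConfig(groups=[GroupSpec("control", "control", 1)], seed=4,
                       fine_rheobase=False)
    rec, _ = next(iter(iter_cohort(cfg)))
    prof = analyze_recording(rec)
    assert prof.included
    assert prof.step is not None and prof.step.responder
    assert prof.counts[1] >= 1
    assert prof.subtype is not None and prof.subtype.label in (
        "single", "delayed", "repeated")
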