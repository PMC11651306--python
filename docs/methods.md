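# Methods

`nociplast` quantifies intrinsic excitability of small-diameter (putatively
nociceptive) DRG sensory neurons from current- and voltage-clamp sweep
families, and ships a conductance-based synthetic-recording generator so the
whole measurement chain can be verified against known ground truth at desk
scale. This note documents the measurement definitions, the model, the
numerical choices, and the known limitations.

## Measurement definitions

All analysis operates on `Sweep` objects: a recorded trace (mV in current
clamp, pA in voltage clamp) paired with its command waveform, sampled at
50 kHz by default. Units are fixed at mV / pA / ms / pF / nS throughout;
sample 0 is protocol time 0 and stimulus segments cover half-open intervals.

**Spike detection.** An AP is a contiguous epoch with V ≥ `min_peak`
(default 0 mV); epochs closer than the refractory period (2 ms) merge. The
AP threshold is the sub-sample-interpolated time and voltage at which dV/dt
last crosses the detection criterion (default 10 mV/ms) upward before the
peak. The criterion value is a configurable package default — published
descriptions of threshold as "the mV/ms rate of change before AP generation"
do not pin a number — and a curvature-maximum alternative is available via
`DetectionCriteria(use_curvature=True)`. No smoothing is applied at 50 kHz.

**Waveform metrology.** Amplitude is threshold→peak; overshoot is 0 mV→peak;
rise is the 10→90 % interval of the rising phase; fall the 90→10 % interval
of the falling phase; half-width the 50 %-rise → 50 %-fall interval. All
level crossings are linearly interpolated; all percentage levels reference
the threshold→peak amplitude, symmetrically for both phases. A truncated
falling phase flags the metrics `partial` instead of silently dropping them.
The falling-phase **shoulder** is scored as the relative dip of |dV/dt|
between the 90 % and 10 % levels against its surrounding envelope (0 = no
inflection); the flag threshold (0.10) is exploratory — fall time and
half-width are the quantitative surface.

**Rheobase.** Families of 1 s step or ramp injections rise in 10 pA (mouse,
cap 1 nA) or 100 pA (human, cap 10 nA) increments from a −60 mV holding
potential. Rheobase is the peak command amplitude of the first sweep with at
least one detected AP inside the stimulus epoch; cells silent up to the cap
are non-responders and carry the cap value, with a separate boolean so both
the all-cells and responders-only summaries can be formed. For ramps the
instantaneous injected current at the first AP threshold is also recorded.
"Reliable AP" is read as ≥ 1 detected AP; no repeat-sweep confirmation.

**Accommodation.** AP counts at 1–4× rheobase, each multiple snapped to the
nearest family amplitude ≤ the exact multiple; multiples beyond the cap are
reported absent (NaN), never zero.

**Firing-pattern classification.** Applied to step responders, in order:
*delayed* if the first AP at rheobase arrives ≥ 100 ms after stimulus onset;
*single* if every available 1–4× sweep carries exactly one AP, inside the
onset window; *repeated* if firing starts inside the onset window and any
sweep carries ≥ 2 APs; otherwise unclassified with a reason. The onset
window defaults to 100 ms, mirroring the delayed rule's latency bound (the
"start of current injection" is not otherwise quantified).

**Passive properties.** V_rest is the mean over a 1 s zero-injection epoch;
cells outside −75…−40 mV are excluded before any group statistic. Input
resistance is |ΔV_steady/I| from a −10 pA (mouse) / −100 pA (human) step,
with ΔV_steady the mean over the last 20 % of the step and a drift test
guarding the plateau assumption. Capacitance is τ/R_in from a
mono-exponential fit of the step-onset relaxation — a software surrogate for
amplifier-based compensation.

**Optogenetic fidelity.** The fraction of light pulses answered by ≥ 1 AP
within 25 ms of pulse onset; "reliable" means exactly 1.0.

**Voltage clamp.** The leak is a single linear conductance fitted on a
gate-free command window (default −100…−80 mV on the ramp foot; for bare
step families the hold plus the −60 mV step). Only the first contiguous
in-window epoch is used, because samples after a depolarized excursion carry
gated tail currents. Na⁺ ramp/step peaks are the most negative
leak-subtracted samples in the stimulus epoch (no smoothing; a peak above
3× the baseline SD noise floor is reported as absent). Densities divide by
C_m. A-type/non-inactivating K⁺ separation uses the two-prepulse protocol
(−80 mV vs +10 mV prepulse, +40 mV test): the difference
(−80-prepulse minus +10-prepulse) is reported positive outward — the
literal subtraction order of the protocol description gives its negative —
and is referenced to its own late plateau before the peak is read. The
plateau referencing removes the residue of slowly inactivating
delayed-rectifier current that does not cancel between prepulses; without it
the "A-type" peak absorbs a ~20 % contamination that a selective-blocker
experiment would not show. The prepulse default is 150 ms, long enough to
inactivate the modeled A-type conductance at +10 mV more than 50-fold.

## The model cell

A single-compartment Hodgkin–Huxley-style neuron:

C_m dV/dt = −(I_NaF + I_NaS + I_Kdr + I_KA + I_leakK + I_leakNS + I_ChR2) + I_inj + ξ

| current | gating | role |
| --- | --- | --- |
| I_NaF = g_NaF·m³·h·s·(V−E_Na) | fast activation/inactivation + slow gate s | spike upstroke; s carries use-dependent availability |
| I_NaS = g_NaS·m_s·h_s·(V−E_Na) | slower activation (half −16 mV), partial inactivation (floor 0.055) | falling-phase shoulder; persistent depolarizing window |
| I_Kdr = g_Kdr·n⁴·u·(V−E_K) | fast activation + very slow inactivation u (τ = 5 s, floor 0.30) | repolarization; u lets sustained depolarization sag the rectifier |
| I_KA = g_KA·a³·b·(V−E_K) | fast activation, inactivation half −78 mV | onset delay; the prepulse-separable transient K⁺ current |
| leaks | K⁺-selective (E_K) and non-selective (0 mV) | resting potential |
| I_ChR2 = g_ChR2·light(t)·V | square light gate | optogenetic drive |

E_K is always computed from [K⁺]ₒ/[K⁺]ᵢ via Nernst (RT/F = 25.7 mV at room
temperature; K_in = 140 mM approximates the K-gluconate internal). Gate
steady states are Boltzmann functions with sigmoidal voltage-dependent time
constants; every constant lives in `simulate.py` and is frozen by the
regression suite. Membrane noise is additive, σ·√dt with σ = 0.05
mV·ms^-1/2 (current clamp only). Integration is exponential-Euler for gates
and Euler(–Maruyama) for voltage at 2× the 50 kHz acquisition grid
(dt = 10 µs); free-running (unheld) sweeps settle for 25 s of unrecorded
model time (≥ 5τ of the slowest gate) so slow states are at their physical
attractor. Held protocols start exactly at the holding potential with the
bias current computed from the steady-state I–V curve, mirroring the
experimenter. Non-finite states raise instead of emitting garbage.

**Why Kdr slowly inactivates.** Two behaviors must coexist: 30 mM bath K⁺
(E_K = −39.6 mV) produces a stable rest near −15 mV, and control cells
driven to 4× rheobase must not be captured by a depolarized plateau. A
non-inactivating rectifier cannot do both — any conductance strong enough to
guard −15 mV in control pins the KCl steady state far below −15 mV. Slow
inactivation (as in Kv2-type channels) resolves this: during seconds of
sustained depolarization the rectifier sags to its 30 % floor, while during
1 s sweeps it remains essentially fully available.

**Default cell** (mouse): C_m 25 pF, g_NaF 300, g_NaS 85, g_Kdr 75,
g_KA 40, g_leakK 2.0, g_leakNS 0.85 nS. This yields V_rest ≈ −60 mV, input
resistance ≈ 350 MΩ, step rheobase ≈ 45 pA, ramp rheobase ≈ 55 pA, spikes of
≈ 75 mV amplitude with a prominent NaS shoulder, and a steady −14 mV under
acute 30 mM KCl. Human presets reuse the kinetics and scale the stimulus
grids (100 pA increments, 10 nA cap).

## Phenotype and treatment presets

Firing phenotypes are parameter deltas on the slow-availability system:

* **repeated** — baseline (s floor 0.15): sustained firing throughout 1 s
  steps, counts rising with the rheobase multiple.
* **single** — s collapses completely and does not recover within a sweep
  (floor 0, recovery τ 2 s, left-shifted midpoint, 0.7× g_NaF, 0.2× g_NaS):
  exactly one onset AP per sweep at every multiple, and near-certain ramp
  non-response — reproducing the observed coupling between the single
  phenotype and ramp non-responders.
* **delayed** — 5× A-type conductance with 20× slower inactivation: first
  AP several hundred ms after onset at rheobase.

Treatments: **control**/**recovery** are identity; **kcl24h** scales both
Na⁺ conductances by s_Na = 0.45 (with a mild 1.15× A-type trend);
**acute_kcl** sets bath K⁺ to 30 mM and nothing else; **dark**/**hz1** add
a 1.8 nS ChR2 conductance. The 0.45 scale makes ramp rheobase rise several
fold (slow inactivation during the ramp approach pushes cells over the
spiking-viability cliff, often to non-response) while step rheobase moves
only ~1 grid step — the ramp/step dissociation characteristic of the
phenomenon being modeled. Delayed cells under kcl24h lose their trains and
classify single, shifting the group composition toward single spikers.

Cohorts draw per-cell log-normal jitter (CV 0.15, median-preserving) on all
conductances and C_m; per-cell seeds derive from the master seed by a
counter scheme, so identical config + seed is byte-identical. Phenotype
mixtures are realized *exactly* (largest-remainder apportionment) rather
than sampled per cell: composition is treated as a controlled design
variable so that equal-n groups are not confounded by mixture sampling
noise. The `matched=True` mode reuses the same base cells in every group
(an in-silico counterfactual), which is how conductance-scaling ratios can
be measured to ±2 % at n = 20; current-clamp treatment cohorts default to
independent cells.

## What the generator does and does not emulate

It emulates: resting potentials inside the −75…−40 mV inclusion window,
rheobases resolvable on the 10 pA grid, the three firing phenotypes, the
acute 30 mM KCl depolarization to ≈ −15 mV without sustained firing,
reversible Na⁺-conductance down-scaling as the sustained-depolarization
adaptation, fast inward Na⁺ plus inactivating/non-inactivating K⁺ currents
under ideal voltage clamp, and 1 Hz-reliable / 10 Hz-unreliable
light-evoked firing. It does not emulate: multi-compartment morphology,
series-resistance and capacitive-transient artifacts, channel subtype
diversity (the fast/slow Na⁺ split is a modeling convenience), ChR2
photocycle kinetics beyond a square conductance, temperature dependence, or
biological variability beyond log-normal conductance jitter. Passing tests
therefore validate the *measurement chain* and the qualitative treatment
logic, not quantitative agreement with any real recording.

## Numerical choices and edge cases

* Sub-sample interpolation everywhere a level or criterion crossing is read;
  piecewise-linear waveforms are measured exactly (machine precision).
* The fine-grid "true" rheobase is a noise-free bisection to 1 pA using the
  same 0 mV spike criterion as the brute-force count oracle; firing is
  monotone in amplitude for this model (property-tested), which bisection
  requires. Grid-bound checks run noise-free because near-threshold noise
  can legitimately flip firing in either direction.
* Early-stop family simulation keeps every sweep up to the first spiking
  sweep plus the grid-snapped 2–4× sweeps; non-responders are simulated to
  the cap. Bundles written from such families carry per-sweep stimulus
  segments so analyses do not depend on the full family being present.
* CSV bundles store values with 17 significant digits (bit-exact round
  trip); the HDF5 layout mirrors the directory layout.
* Degenerate inputs raise with specific messages: empty families, mixed
  protocol kinds, zero-current R_in requests, non-convergent capacitance
  fits, leak windows spanning < 1 mV or containing gated current, off-grid
  IV voltage queries, mismatched prepulse time bases.

## Known limitations

* **Half-width under Na⁺ scaling.** Scaling Na⁺ conductances to 0.45 slows
  the near-rheobase upstroke; the resulting widening of the first AP at the
  grid rheobase offsets the shoulder-loss narrowing, so the group
  half-width in treated cohorts comes out slightly (2–6 %) *higher* than
  control even though fall time shows the expected large decrease. A pure
  conductance-scaling treatment cannot reproduce a half-width decrease at
  the first-AP-at-rheobase statistic in this model; additional kinetic
  changes (e.g. in time-dependent gating) would be required. The
  corresponding assertion in the acceptance suite fails by design rather
  than being weakened.
* The exact gate kinetics are an implementation choice, frozen by
  regression tests; only the behavioral calibration windows above are
  claimed.
* The classifier's "exactly one AP" single rule is strict: cells firing an
  onset doublet classify repeated. Fidelity of the presets under control
  treatment is ≥ 90 % by design (tested at n = 30/preset).
* Ideal voltage clamp: no series-resistance error; the prepulse difference
  still contains the real, protocol-intrinsic rectifier transients
  discussed above.
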