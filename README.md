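# nociplast

Quantitative analysis of **intrinsic adaptive plasticity in sensory
neurons**: a tested, reusable pipeline for patch-clamp sweep families from
small-diameter (putatively nociceptive) DRG neurons, together with a
conductance-based synthetic-recording generator that makes every stage of
the pipeline verifiable against known ground truth.

Sustained depolarization of sensory neurons (24 h in 30 mM KCl) lowers
intrinsic excitability — higher ramp rheobase, more non-responders, fewer
spikes at suprathreshold drive, a shift toward single-spiking, loss of the
falling-phase shoulder — and the change reverses after a 24 h washout,
consistent with a reduction of voltage-gated Na⁺ currents. `nociplast`
implements the full measurement chain behind such a study, for
electrophysiologists who want reproducible, scriptable sweep analysis and
for modelers who want a ground-truth harness for it:

* **AP waveform metrology** — threshold (dV/dt criterion, sub-sample
  interpolated), amplitude, overshoot, 10–90 % rise, 90–10 % fall,
  50–50 % half-width, falling-phase shoulder score;
* **excitability** — rheobase from 10 pA/100 pA step and ramp families
  (non-responders carry the 1 nA / 10 nA cap), AP counts at 1–4× rheobase,
  V_rest with the −75…−40 mV inclusion rule, input resistance, capacitance,
  single/delayed/repeated firing classification, optogenetic firing
  fidelity;
* **voltage clamp** — linear leak subtraction, Na⁺ ramp/step peak currents
  and IV curves, current densities, A-type vs non-inactivating K⁺
  separation by two-prepulse subtraction;
* **cohort statistics** — exact two-sided Fisher tests on responder tables,
  mean ± SEM summaries, Benjamini–Hochberg adjustment, and the RNA-seq TPM
  rules (detection threshold 0.2, protein-coding renormalisation,
  log₂(TPM + 0.2));
* **synthetic cohorts** — a Hodgkin–Huxley-style DRG neuron
  (C·dV/dt = −Σ gᵢ·mᵖhᵠ·(V−Eᵢ) + I) with firing-phenotype and treatment
  presets (control, 24 h KCl as Na⁺-conductance scaling, recovery, acute
  30 mM KCl via the K⁺ Nernst potential, optogenetic drive), deterministic
  per seed. See `docs/methods.md` for the model and its limitations.

## Worked example

Simulate a control vs KCl vs recovery cohort (2 cells per group for speed)
and run the whole pipeline:

```python
from nociplast.pipeline import default_run_config, run_pipeline

cfg = default_run_config("demo_out", n=2, seed=1)
artifacts = run_pipeline(cfg)
cells = artifacts["cells"]
print(cells[["cell_id", "group", "rheobase_ramp", "responder_ramp",
             "aps_3x", "ap_fall", "subtype"]].to_string(index=False))
```

```
         cell_id        group  rheobase_ramp  responder_ramp  aps_3x  ap_fall  subtype
     control_000      control           60.0            True    43.0 5.917531 repeated
     control_001      control          390.0            True     1.0 1.414578   single
         kcl_000          kcl          120.0            True     2.0 1.771483 repeated
         kcl_001          kcl         1000.0           False     1.0 1.490427   single
kcl_recovery_000 kcl_recovery           50.0            True    39.0 4.342409 repeated
kcl_recovery_001 kcl_recovery          300.0            True     1.0 1.293563   single
```

Reading the table: the repeated-spiking control cell fires a ~40-spike
train at 3× rheobase with a slow, shouldered falling phase (`ap_fall`
5.9 ms); its KCl-treated counterpart needs twice the ramp current, fires
only a couple of spikes, and its first AP falls in 1.8 ms (shoulder lost).
The single-spiking cell becomes an outright ramp non-responder under KCl
(rheobase pinned at the 1 nA cap, `responder_ramp` False). Under the
recovery preset every number returns to control levels. `demo_out/` also receives the per-AP
feature table, group mean ± SEM summaries, responder proportions with
pairwise Fisher exact tests, and a manifest recording the seed and config.

The same stages are available as a CLI over sweep bundles on disk
(`meta.json` + per-sweep CSV, or one HDF5 file):

```bash
nociplast simulate --config cohort.yaml --out bundles/
nociplast excitability --bundle bundles/ --out cells.csv
nociplast vclamp --bundle bundles/ --out vclamp.csv
nociplast stats --cells cells.csv --out report/
nociplast expr-filter --tpm tpm.csv --groups groups.csv --out kept.csv
```

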