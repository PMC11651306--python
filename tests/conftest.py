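"""Shared fixtures: model cells, synthetic waveforms, and the seeded cohorts
used by the group-level (treatment-direction) tests."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from nociplast.excitability import analyze_recording
from nociplast.simulate import CohortConfig, GroupSpec, ModelParams, iter_cohort
from nociplast.traces import Sweep

COHORT_SEED = 11  # fixed master seed of the treatment-direction cohorts


@pytest.fixture(scope="session")
def params():
    return ModelParams()


def gaussian_spike_sweep(sigma_ms=0.5, baseline=-60.0, peak=40.0, rate=50_000.0,
                         t0_ms=50.0, dur_ms=100.0, n_spikes=1, spacing_ms=20.0):
    """A sweep containing Gaussian 'spikes' riding on a flat baseline."""
    n = int(dur_ms * rate / 1000.0)
    t = np.arange(n) / rate * 1000.0
    v = np.full(n, baseline)
    for k in range(n_spikes):
        v += (peak - baseline) * np.exp(-((t - t0_ms - k * spacing_ms) ** 2)
                                        / (2 * sigma_ms ** 2))
    cmd = np.zeros(n)
    return Sweep(0, rate, v, cmd, "current", [])


def brute_force_ap_count(v: np.ndarray, rate: float, level: float = 0.0,
                         gap_ms: float = 2.0) -> int:
    """Independent spike-count oracle: maximal runs of samples above ``level``
    separated by at least ``gap_ms``."""
    above = v >= level
    if not above.any():
        return 0
    idx = np.nonzero(above)[0]
    gaps = np.diff(idx) * 1000.0 / rate
    return 1 + int(np.sum(gaps >= gap_ms))


def run_cohort(groups, seed=COHORT_SEED, families=("cc_zero", "cc_ramp", "cc_step", "cc_hyper"),
               **kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stream a cohort through the excitability pipeline; returns (cells, truth)."""
    cfg = CohortConfig(groups=groups, families=families, seed=seed,
                       fine_rheobase=False, **kw)
    rows, meta = [], []
    for rec, row in iter_cohort(cfg):
        rows.append(analyze_recording(rec).as_row())
        meta.append(row)
    return pd.DataFrame(rows), pd.DataFrame(meta)


@pytest.fixture(scope="session")
def treatment_cohort():
    """Control / 24-h KCl / recovery groups, 30 cells each (the Fig 1-3 design)."""
    cells, truth = run_cohort([
        GroupSpec("control", "control", 30),
        GroupSpec("kcl", "kcl24h", 30),
        GroupSpec("kcl_recovery", "recovery", 30),
    ])
    return cells.merge(truth[["cell_id", "phenotype"]], on="cell_id")
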