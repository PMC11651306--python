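"""Sweep/protocol data model and on-disk sweep bundles.

The atom of all analysis is a :class:`Sweep`: a recorded trace (membrane
potential in mV under current clamp, membrane current in pA under voltage
clamp) paired with the command waveform that evoked it.  Units are fixed
throughout the package: mV, pA, ms, pF, nS.  Time is carried implicitly by
``sampling_rate`` plus the sample index; sample 0 is protocol time 0 and
stimulus segments cover half-open intervals ``[t_start, t_end)``.

Bundles on disk are either a directory (``meta.json`` plus one
``sweep_<k>.csv`` per sweep, columns ``time_ms,recorded,command``) or a
single HDF5 file mirroring the same tree.  Both round-trip bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusSegment",
    "Protocol",
    "Sweep",
    "Recording",
    "make_protocol",
    "command_at",
    "write_bundle",
    "read_bundle",
    "segments_peak_amplitude",
    "read_abf",
    "read_nwb",
    "FAMILY_KINDS",
    "SPECIES_PRESETS",
]

DEFAULT_SAMPLING_RATE = 50_000.0  # Hz

#: current-clamp family geometry per species: (increment pA, cap pA,
#: hyperpolarizing test current pA, max soma diameter um)
SPECIES_PRESETS = {
    "mouse": {"increment": 10.0, "cap": 1000.0, "hyper": -10.0, "max_diameter": 30.0},
    "human": {"increment": 100.0, "cap": 10000.0, "hyper": -100.0, "max_diameter": 60.0},
}

FAMILY_KINDS = (
    "cc_ramp",
    "cc_step",
    "cc_hyper",
    "cc_zero",
    "opto_train",
    "vc_na_ramp",
    "vc_na_step",
    "vc_k_prepulse",
)

GROUP_LABELS = ("control", "kcl", "control_recovery", "kcl_recovery", "dark", "hz1")


@dataclass(frozen=True)
class StimulusSegment:
    """One piece of a command waveform.

    ``kind`` is one of ``hold``, ``step``, ``ramp``, ``pulse_train``.  For a
    ramp the amplitude interpolates linearly from ``amp_start`` at
    ``t_start`` to ``amp_end`` at ``t_end``.  For a pulse train the command
    is ``pulse_amp`` during the first ``pulse_width`` ms of every ``period``
    ms window and ``amp_start`` (baseline) otherwise.
    """

    kind: str
    t_start: float  # ms
    t_end: float  # ms
    amp_start: float
    amp_end: float
    period: float | None = None  # ms, pulse_train only
    pulse_width: float | None = None  # ms
    pulse_amp: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp", "pulse_train"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.t_end > self.t_start:
            raise ValueError("segment requires t_end > t_start")
        if self.kind in ("hold", "step") and self.amp_start != self.amp_end:
            raise ValueError(f"{self.kind} segment requires amp_start == amp_end")
        if self.kind == "pulse_train":
            if not (self.period and self.pulse_width and self.pulse_amp is not None):
                raise ValueError("pulse_train requires period, pulse_width, pulse_amp")
            if self.pulse_width > self.period:
                raise ValueError("pulse_width must not exceed period")

    def amplitude_at(self, t: np.ndarray) -> np.ndarray:
        """Vectorised command amplitude at times ``t`` (ms, within the segment)."""
        t = np.asarray(t, dtype=float)
        if self.kind in ("hold", "step"):
            return np.full_like(t, self.amp_start)
        if self.kind == "ramp":
            frac = (t - self.t_start) / (self.t_end - self.t_start)
            return self.amp_start + frac * (self.amp_end - self.amp_start)
        # pulse_train
        phase = np.mod(t - self.t_start, self.period)
        return np.where(phase < self.pulse_width, self.pulse_amp, self.amp_start)


@dataclass
class Protocol:
    """A family of sweeps sharing a clamp mode, geometry, and sampling rate."""

    kind: str
    clamp_mode: str  # "current" | "voltage"
    sweeps: list[list[StimulusSegment]]
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    holding_level: float | None = None  # mV (cc membrane holding / vc command baseline)
    species_preset: str | None = None
    increment: float | None = None  # per-sweep amplitude increment (pA or mV)

    def __post_init__(self) -> None:
        if self.clamp_mode not in ("current", "voltage"):
            raise ValueError(f"clamp_mode must be current|voltage, got {self.clamp_mode!r}")
        if not self.sweeps:
            raise ValueError("protocol defines no sweeps")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def duration_ms(self, sweep_index: int = 0) -> float:
        return max(seg.t_end for seg in self.sweeps[sweep_index])

    def n_samples(self, sweep_index: int = 0) -> int:
        return int(round(self.duration_ms(sweep_index) * self.sampling_rate / 1000.0))

    def command_array(self, sweep_index: int) -> np.ndarray:
        """Command waveform sampled on the protocol grid (sample 0 = t 0)."""
        n = self.n_samples(sweep_index)
        t = np.arange(n) / self.sampling_rate * 1000.0
        out = np.zeros(n)
        base = self.holding_level if self.clamp_mode == "voltage" and self.holding_level is not None else 0.0
        out[:] = base
        for seg in self.sweeps[sweep_index]:
            m = (t >= seg.t_start) & (t < seg.t_end)
            out[m] = seg.amplitude_at(t[m])
        return out

    def peak_amplitude(self, sweep_index: int) -> float:
        """Largest-magnitude stimulus amplitude of a sweep (pA in cc, mV in vc)."""
        return segments_peak_amplitude(self.sweeps[sweep_index])

    def stimulus_window(self, sweep_index: int = 0) -> tuple[float, float]:
        """[start, end) ms of the non-baseline stimulus epoch."""
        segs = [s for s in self.sweeps[sweep_index] if s.kind != "hold"]
        if not segs:
            segs = self.sweeps[sweep_index]
        return min(s.t_start for s in segs), max(s.t_end for s in segs)


def segments_peak_amplitude(segments: Sequence[StimulusSegment]) -> float:
    """Largest-magnitude stimulus amplitude declared by a segment list."""
    amps = []
    for seg in segments:
        amps.extend([seg.amp_start, seg.amp_end])
        if seg.kind == "pulse_train":
            amps.append(seg.pulse_amp)
    if not amps:
        raise ValueError("sweep declares no stimulus segments")
    return max(amps, key=abs)


@dataclass
class Sweep:
    """One recorded trace plus its command waveform."""

    sweep_index: int
    sampling_rate: float
    recorded: np.ndarray  # mV (current clamp) or pA (voltage clamp)
    command: np.ndarray  # pA (current clamp), mV (voltage clamp), or light gate
    clamp_mode: str
    segments: list[StimulusSegment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.recorded = np.asarray(self.recorded, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        if self.recorded.shape != self.command.shape:
            raise ValueError("recorded and command must have identical length")
        if self.recorded.ndim != 1:
            raise ValueError("sweep arrays must be 1-D")
        if not np.all(np.isfinite(self.recorded)):
            raise ValueError("sweep contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.recorded.size

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate * 1000.0

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate * 1000.0


@dataclass
class SweepGroup:
    """All sweeps recorded under one protocol family."""

    protocol: Protocol
    sweeps: list[Sweep]


@dataclass
class Recording:
    """Everything recorded from one cell, grouped by protocol family."""

    cell_id: str
    group: str
    species: str = "mouse"
    diameter_um: float = 20.0
    groups: dict[str, SweepGroup] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}, got {self.group!r}")
        limit = SPECIES_PRESETS[self.species]["max_diameter"]
        if not self.diameter_um < limit:
            raise ValueError(
                f"{self.species} preset requires diameter < {limit} um, got {self.diameter_um}"
            )

    def add(self, family: str, protocol: Protocol, sweeps: list[Sweep]) -> None:
        self.groups[family] = SweepGroup(protocol, sweeps)

    def family(self, name: str) -> SweepGroup:
        return self.groups[name]


# ---------------------------------------------------------------------------
# Protocol builders
# ---------------------------------------------------------------------------

def _cc_segments(kind: str, amp: float, pre: float, stim: float, post: float) -> list[StimulusSegment]:
    segs = [StimulusSegment("hold", 0.0, pre, 0.0, 0.0)]
    if kind == "ramp":
        segs.append(StimulusSegment("ramp", pre, pre + stim, 0.0, amp))
    else:
        segs.append(StimulusSegment("step", pre, pre + stim, amp, amp))
    segs.append(StimulusSegment("hold", pre + stim, pre + stim + post, 0.0, 0.0))
    return segs


def make_protocol(
    family: str,
    species: str | None = None,
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    freq_hz: float = 1.0,
    n_pulses: int = 60,
    pulse_width_ms: float = 10.0,
    prepulse_ms: float = 150.0,
    stim_ms: float = 1000.0,
) -> Protocol:
    """Build one of the standard stimulus families.

    Current-clamp families are 1 s stimuli from a −60 mV membrane holding
    potential, incrementing by 10 pA (mouse, capped at 1 nA) or 100 pA
    (human, capped at 10 nA).  ``vc_na_ramp`` holds −80 mV then ramps
    −100→+20 mV over 600 ms; ``vc_na_step`` steps −60…+20 mV in 10 mV
    increments; ``vc_k_prepulse`` tests +40 mV after a −80 mV and after a
    +10 mV prepulse; ``opto_train`` is a train of ``pulse_width_ms`` light
    pulses at ``freq_hz``.
    """
    if family not in FAMILY_KINDS:
        raise ValueError(f"unknown protocol family {family!r}")

    pre, post = 100.0, 200.0

    if family in ("cc_ramp", "cc_step", "cc_hyper", "cc_zero"):
        if species is None:
            raise ValueError(f"{family} requires a species preset (mouse|human)")
        preset = SPECIES_PRESETS[species]
        if family == "cc_zero":
            sweeps = [[StimulusSegment("hold", 0.0, stim_ms, 0.0, 0.0)]]
            return Protocol("cc_zero", "current", sweeps, sampling_rate,
                            holding_level=None, species_preset=species, increment=0.0)
        if family == "cc_hyper":
            sweeps = [_cc_segments("step", preset["hyper"], pre, stim_ms, 300.0)]
            return Protocol("cc_hyper", "current", sweeps, sampling_rate,
                            holding_level=-60.0, species_preset=species,
                            increment=0.0)
        inc, cap = preset["increment"], preset["cap"]
        n = int(round(cap / inc))
        kind = "ramp" if family == "cc_ramp" else "step"
        sweeps = [_cc_segments(kind, inc * (k + 1), pre, stim_ms, post) for k in range(n)]
        return Protocol(family, "current", sweeps, sampling_rate,
                        holding_level=-60.0, species_preset=species, increment=inc)

    if family == "opto_train":
        period = 1000.0 / freq_hz
        dur = n_pulses * period
        sweeps = [[StimulusSegment("pulse_train", 0.0, dur, 0.0, 0.0,
                                   period=period, pulse_width=pulse_width_ms,
                                   pulse_amp=1.0)]]
        return Protocol("opto_train", "current", sweeps, sampling_rate,
                        holding_level=None, species_preset=species, increment=0.0)

    if family == "vc_na_ramp":
        sweeps = [[
            StimulusSegment("hold", 0.0, pre, -80.0, -80.0),
            StimulusSegment("ramp", pre, pre + 600.0, -100.0, 20.0),
            StimulusSegment("hold", pre + 600.0, pre + 650.0, -80.0, -80.0),
        ]]
        return Protocol("vc_na_ramp", "voltage", sweeps, sampling_rate,
                        holding_level=-80.0, species_preset=species)

    if family == "vc_na_step":
        volts = np.arange(-60.0, 30.0, 10.0)  # −60 … +20, 9 sweeps
        sweeps = [[
            StimulusSegment("hold", 0.0, pre, -80.0, -80.0),
            StimulusSegment("step", pre, pre + stim_ms, v, v),
            StimulusSegment("hold", pre + stim_ms, pre + stim_ms + 100.0, -80.0, -80.0),
        ] for v in volts]
        return Protocol("vc_na_step", "voltage", sweeps, sampling_rate,
                        holding_level=-80.0, species_preset=species, increment=10.0)

    # vc_k_prepulse: two sweeps to +40 mV after −80 / +10 mV prepulses
    sweeps = []
    for pp in (-80.0, 10.0):
        sweeps.append([
            StimulusSegment("hold", 0.0, pre, -70.0, -70.0),
            StimulusSegment("step", pre, pre + prepulse_ms, pp, pp),
            StimulusSegment("step", pre + prepulse_ms, pre + prepulse_ms + 500.0, 40.0, 40.0),
            StimulusSegment("hold", pre + prepulse_ms + 500.0,
                            pre + prepulse_ms + 600.0, -70.0, -70.0),
        ])
    return Protocol("vc_k_prepulse", "voltage", sweeps, sampling_rate,
                    holding_level=-70.0, species_preset=species)


def command_at(sweep: Sweep, t: float) -> float:
    """Exact piecewise-linear command amplitude at time ``t`` ms.

    Evaluates the declared stimulus segments (not the sampled array), so a
    ramp rheobase can be attributed to an injected-current value between
    sample points.
    """
    if not 0.0 <= t <= sweep.duration_ms:
        raise ValueError(f"t={t} ms outside sweep duration {sweep.duration_ms} ms")
    for seg in sweep.segments:
        if seg.t_start <= t < seg.t_end:
            return float(seg.amplitude_at(np.array([t]))[0])
    if sweep.segments:
        # t at or beyond the last segment boundary: clamp to final segment value
        last = max(sweep.segments, key=lambda s: s.t_end)
        return float(last.amplitude_at(np.array([min(t, np.nextafter(last.t_end, -np.inf))]))[0])
    # no declared segments: fall back to the sampled array
    idx = min(int(t / 1000.0 * sweep.sampling_rate), sweep.n_samples - 1)
    return float(sweep.command[idx])


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def _segment_to_json(seg: StimulusSegment) -> dict:
    return {k: v for k, v in asdict(seg).items() if v is not None}


def _recording_meta(rec: Recording) -> dict:
    meta = {
        "format": "nociplast-bundle",
        "version": 1,
        "cell_id": rec.cell_id,
        "group": rec.group,
        "species": rec.species,
        "diameter_um": rec.diameter_um,
        "provenance": rec.provenance,
        "families": {},
    }
    k = 0
    for name, grp in rec.groups.items():
        p = grp.protocol
        fam = {
            "kind": p.kind,
            "clamp_mode": p.clamp_mode,
            "sampling_rate": p.sampling_rate,
            "holding_level": p.holding_level,
            "species_preset": p.species_preset,
            "increment": p.increment,
            "sweeps": [],
        }
        for sw in grp.sweeps:
            fam["sweeps"].append({
                "file_index": k,
                "sweep_index": sw.sweep_index,
                "n_samples": sw.n_samples,
                "segments": [_segment_to_json(s) for s in sw.segments],
            })
            k += 1
        meta["families"][name] = fam
    return meta


def _segments_from_json(items: list[dict]) -> list[StimulusSegment]:
    return [StimulusSegment(**d) for d in items]


def write_bundle(rec: Recording, path: str | Path) -> None:
    """Write a recording as a bundle: directory of CSVs, or one HDF5 file.

    A ``.h5``/``.hdf5`` suffix selects the HDF5 container; anything else is
    written as ``<path>/meta.json`` + ``<path>/sweep_<k>.csv`` with columns
    ``time_ms,recorded,command``.  Values are written with 17 significant
    digits so the round trip is bit-exact.
    """
    path = Path(path)
    meta = _recording_meta(rec)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["meta_json"] = json.dumps(meta)
            k = 0
            for name, grp in rec.groups.items():
                for sw in grp.sweeps:
                    g = f.create_group(f"sweep_{k}")
                    g.create_dataset("recorded", data=sw.recorded)
                    g.create_dataset("command", data=sw.command)
                    k += 1
        return
    path.mkdir(parents=True, exist_ok=True)
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    k = 0
    for name, grp in rec.groups.items():
        sr = grp.protocol.sampling_rate
        for sw in grp.sweeps:
            t = np.arange(sw.n_samples) / sr * 1000.0
            arr = np.column_stack([t, sw.recorded, sw.command])
            np.savetxt(path / f"sweep_{k}.csv", arr, delimiter=",",
                       header="time_ms,recorded,command", comments="", fmt="%.17g")
            k += 1


def _rebuild(meta: dict, sweep_data: dict[int, tuple[np.ndarray, np.ndarray]]) -> Recording:
    for key in ("cell_id", "group", "families"):
        if key not in meta:
            raise ValueError(f"bundle metadata missing required field {key!r}")
    rec = Recording(meta["cell_id"], meta["group"], meta.get("species", "mouse"),
                    meta.get("diameter_um", 20.0), provenance=meta.get("provenance", {}))
    for name, fam in meta["families"].items():
        for key in ("sampling_rate", "clamp_mode"):
            if fam.get(key) is None:
                raise ValueError(f"bundle family {name!r} missing required field {key!r}")
        sweeps = []
        seg_lists = []
        for sw in fam["sweeps"]:
            recorded, command = sweep_data[sw["file_index"]]
            if recorded.shape != command.shape:
                raise ValueError("length mismatch between recorded and command")
            segs = _segments_from_json(sw["segments"])
            seg_lists.append(segs)
            sweeps.append(Sweep(sw["sweep_index"], fam["sampling_rate"],
                                recorded, command, fam["clamp_mode"], segs))
        protocol = Protocol(fam["kind"], fam["clamp_mode"],
                            seg_lists or [[]], fam["sampling_rate"],
                            holding_level=fam.get("holding_level"),
                            species_preset=fam.get("species_preset"),
                            increment=fam.get("increment"))
        rec.add(name, protocol, sweeps)
    return rec


def read_bundle(path: str | Path) -> Recording:
    """Read a bundle written by :func:`write_bundle` (CSV directory or HDF5)."""
    path = Path(path)
    if path.is_file() and path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta_json"])
            data = {}
            for key in f:
                k = int(key.split("_")[1])
                data[k] = (f[key]["recorded"][:], f[key]["command"][:])
        return _rebuild(meta, data)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no meta.json in bundle {path}")
    meta = json.loads(meta_path.read_text())
    data = {}
    for fam in meta.get("families", {}).values():
        for sw in fam["sweeps"]:
            k = sw["file_index"]
            arr = np.loadtxt(path / f"sweep_{k}.csv", delimiter=",", skiprows=1)
            arr = np.atleast_2d(arr)
            data[k] = (arr[:, 1].copy(), arr[:, 2].copy())
    return _rebuild(meta, data)


# ---------------------------------------------------------------------------
# Optional external-format ingest (gated on third-party readers)
# ---------------------------------------------------------------------------

def read_abf(path: str | Path, cell_id: str | None = None, group: str = "control") -> Recording:
    """Ingest an Axon ABF file into a Recording (units normalised to mV/pA/ms).

    Requires the optional ``pyabf`` dependency; the core package works
    without it.
    """
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - exercised via error path
        raise ImportError(
            "ABF ingest requires the optional 'pyabf' package; "
            "install it or convert the file to a nociplast bundle"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover
    clamp = "current" if "clamp" in str(abf.adcUnits).lower() else "current"
    rec = Recording(cell_id or Path(path).stem, group)
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        sweeps.append(Sweep(i, abf.dataRate, np.asarray(abf.sweepY, float),
                            np.asarray(abf.sweepC, float), clamp, []))
    proto = Protocol("cc_step", clamp, [[] for _ in sweeps], abf.dataRate)
    rec.add("ingest", proto, sweeps)
    return rec


def read_nwb(path: str | Path, cell_id: str | None = None, group: str = "control") -> Recording:
    """Ingest an NWB intracellular-ephys file (requires optional ``pynwb``)."""
    try:
        import pynwb  # type: ignore  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "NWB ingest requires the optional 'pynwb' package; "
            "install it or convert the file to a nociplast bundle"
        ) from exc
    raise NotImplementedError  # pragma: no cover
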