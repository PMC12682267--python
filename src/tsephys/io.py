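"""Data model for current-clamp sweeps and cells, plain-text bundle I/O, QC.

The interchange format is a plain-text *sweep bundle*: a directory holding a
manifest (two CSV tables, ``cells.csv`` and ``sweeps.csv``) plus one
two-column trace table per sweep (``time_s,vm_mV``). Everything is text so
bundles diff, round-trip and version cleanly; vendor episodic binary files
(ABF) are supported only through an adapter contract (:func:`read_abf`)
behind an optional dependency, so the core has zero binary-format logic.

Units are fixed package-wide: membrane potential in mV, current in pA,
durations reported in ms, sample timestamps in s. Samples are stored at
native rate and never resampled on ingest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimProtocol",
    "Sweep",
    "CellRecording",
    "FormatError",
    "IntegrityError",
    "ParameterError",
    "AnalysisError",
    "CapabilityError",
    "read_sweep_bundle",
    "write_sweep_bundle",
    "qc_filter",
    "write_feature_table",
    "read_abf",
]

PHARMACOLOGY_TAGS = frozenset({"picrotoxin", "ttx_4ap_zd", "cgp_pre", "cgp_post"})


class FormatError(ValueError):
    """A bundle or config file does not conform to the documented layout."""


class IntegrityError(ValueError):
    """Manifest and trace data disagree (length, rate, missing file)."""


class ParameterError(ValueError):
    """Invalid or inconsistent parameter values."""


class AnalysisError(ValueError):
    """An analysis precondition is not met (e.g. no spiking sweeps)."""


class CapabilityError(RuntimeError):
    """The input cannot be analyzed with the requested method."""


@dataclass(frozen=True)
class StimProtocol:
    """Optogenetic stimulation protocol attached to a sweep.

    kind
        ``"none"`` (no light), ``"single_pulse"`` or ``"pulse_train"``.
    pulse_onset_s
        Time of the first light pulse from sweep start, seconds.
    pulse_duration_ms
        Duration of each pulse, milliseconds.
    n_pulses
        Number of pulses (1 for a single pulse).
    train_rate_hz
        Pulse rate for trains; ``None`` otherwise.
    """

    kind: str = "none"
    pulse_onset_s: float = 0.0
    pulse_duration_ms: float = 0.0
    n_pulses: int = 0
    train_rate_hz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "single_pulse", "pulse_train"):
            raise ParameterError(f"unknown protocol kind {self.kind!r}")
        if self.pulse_onset_s < 0:
            raise ParameterError("pulse_onset_s must be >= 0")
        if self.kind != "none":
            if self.pulse_duration_ms <= 0:
                raise ParameterError("pulse_duration_ms must be > 0 for light protocols")
            if self.kind == "single_pulse" and self.n_pulses != 1:
                raise ParameterError("single_pulse requires n_pulses == 1")
            if self.kind == "pulse_train":
                if self.n_pulses < 2:
                    raise ParameterError("pulse_train requires n_pulses >= 2")
                if not self.train_rate_hz or self.train_rate_hz <= 0:
                    raise ParameterError("pulse_train requires a positive train_rate_hz")
                if 1000.0 / self.train_rate_hz < self.pulse_duration_ms:
                    raise ParameterError("inter-pulse interval shorter than pulse duration")

    def pulse_onsets_s(self) -> np.ndarray:
        """Onset time of every pulse, seconds."""
        if self.kind == "none":
            return np.empty(0)
        if self.kind == "single_pulse":
            return np.array([self.pulse_onset_s])
        period = 1.0 / float(self.train_rate_hz)
        return self.pulse_onset_s + period * np.arange(self.n_pulses)

    @property
    def offset_s(self) -> float:
        """End of the last pulse, seconds from sweep start."""
        if self.kind == "none":
            return self.pulse_onset_s
        return float(self.pulse_onsets_s()[-1] + self.pulse_duration_ms / 1000.0)

    @property
    def key(self) -> str:
        """Stable protocol name refined by duration / rate
        (e.g. ``single_pulse_10ms``, ``pulse_train_20hz``)."""
        if self.kind == "none":
            return "none"
        if self.kind == "pulse_train":
            return f"pulse_train_{self.train_rate_hz:g}hz"
        return f"single_pulse_{self.pulse_duration_ms:g}ms"


NO_LIGHT = StimProtocol()


@dataclass
class Sweep:
    """One episodic current-clamp trace with its stimulus metadata."""

    cell_id: str
    sweep_index: int
    sample_rate_hz: float
    vm: np.ndarray
    step_amplitude_pA: float
    step_onset_s: float
    step_offset_s: float
    condition: str = "no_light"
    protocol: StimProtocol = NO_LIGHT
    pharmacology: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.vm = np.asarray(self.vm, dtype=float)
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be > 0")
        if self.step_offset_s <= self.step_onset_s:
            raise ParameterError("step_offset_s must exceed step_onset_s")
        if self.condition not in ("no_light", "light"):
            raise ParameterError(f"unknown condition {self.condition!r}")
        if self.condition == "light" and self.protocol.kind == "none":
            raise ParameterError("light condition requires a light protocol")
        bad = set(self.pharmacology) - PHARMACOLOGY_TAGS
        if bad:
            raise ParameterError(f"unknown pharmacology tags: {sorted(bad)}")
        self.pharmacology = frozenset(self.pharmacology)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.vm.size) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.vm.size / self.sample_rate_hz

    @property
    def step_duration_s(self) -> float:
        return self.step_offset_s - self.step_onset_s

    def sample_at(self, t_s: float) -> int:
        """Sample index for a time in seconds (clipped to the trace)."""
        return int(np.clip(round(t_s * self.sample_rate_hz), 0, self.vm.size - 1))


@dataclass
class CellRecording:
    """Ordered sweeps for one neuron plus subtype, QC and provenance metadata."""

    cell_id: str
    subtype: str = "unknown"
    slice_id: str = ""
    mouse_id: str = ""
    access_resistance_MOhm: float | None = None
    sweeps: list[Sweep] = field(default_factory=list)
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.subtype not in ("D1", "D2", "unknown"):
            raise ParameterError(f"unknown subtype {self.subtype!r}")
        self.sweeps = sorted(self.sweeps, key=lambda s: s.sweep_index)

    def fi_sweeps(self, condition: str) -> list[Sweep]:
        """Current-step sweeps of one condition, ordered by step amplitude.

        A sweep belongs to the f-I protocol when it carries a nonzero
        current step; light sweeps additionally carry the 500 ms pulse.
        """
        out = [s for s in self.sweeps if s.condition == condition and s.step_amplitude_pA != 0]
        return sorted(out, key=lambda s: s.step_amplitude_pA)

    def fi_pairs(self) -> list[tuple[Sweep, Sweep]]:
        """(no_light, light) sweep pairs sharing a step amplitude, ascending."""
        no_light = {s.step_amplitude_pA: s for s in self.fi_sweeps("no_light")}
        light = {s.step_amplitude_pA: s for s in self.fi_sweeps("light")}
        amps = sorted(set(no_light) & set(light))
        return [(no_light[a], light[a]) for a in amps]

    def psp_sweeps(self, kind: str, pharmacology: frozenset[str] | None = None) -> list[Sweep]:
        """Light PSP sweeps (no current step) of one protocol kind."""
        out = []
        for s in self.sweeps:
            if s.condition != "light" or s.step_amplitude_pA != 0:
                continue
            if s.protocol.kind != kind:
                continue
            if pharmacology is not None and s.pharmacology != pharmacology:
                continue
            out.append(s)
        return out


# ---------------------------------------------------------------------------
# bundle I/O

_CELL_COLUMNS = ["cell_id", "subtype", "slice_id", "mouse_id", "access_resistance_MOhm", "qc_flags"]
_SWEEP_COLUMNS = [
    "cell_id", "sweep_index", "trace_file", "sample_rate_hz", "n_samples",
    "step_amplitude_pA", "step_onset_s", "step_offset_s", "condition",
    "protocol_kind", "pulse_onset_s", "pulse_duration_ms", "n_pulses",
    "train_rate_hz", "pharmacology",
]


def write_sweep_bundle(cells: Iterable[CellRecording], path: str | Path) -> None:
    """Write cells to a plain-text sweep bundle directory.

    Trace samples are written with 9 significant digits, preserving at
    least 6 significant digits through a round trip.
    """
    path = Path(path)
    (path / "traces").mkdir(parents=True, exist_ok=True)
    cell_rows, sweep_rows = [], []
    for cell in sorted(cells, key=lambda c: c.cell_id):
        cell_rows.append({
            "cell_id": cell.cell_id,
            "subtype": cell.subtype,
            "slice_id": cell.slice_id,
            "mouse_id": cell.mouse_id,
            "access_resistance_MOhm": "" if cell.access_resistance_MOhm is None
            else f"{cell.access_resistance_MOhm:.9g}",
            "qc_flags": ";".join(sorted(cell.qc_flags)),
        })
        for s in cell.sweeps:
            trace_file = f"traces/{cell.cell_id}_{s.sweep_index:04d}.csv"
            p = s.protocol
            sweep_rows.append({
                "cell_id": cell.cell_id,
                "sweep_index": s.sweep_index,
                "trace_file": trace_file,
                "sample_rate_hz": f"{s.sample_rate_hz:.9g}",
                "n_samples": s.vm.size,
                "step_amplitude_pA": f"{s.step_amplitude_pA:.9g}",
                "step_onset_s": f"{s.step_onset_s:.9g}",
                "step_offset_s": f"{s.step_offset_s:.9g}",
                "condition": s.condition,
                "protocol_kind": p.kind,
                "pulse_onset_s": f"{p.pulse_onset_s:.9g}",
                "pulse_duration_ms": f"{p.pulse_duration_ms:.9g}",
                "n_pulses": p.n_pulses,
                "train_rate_hz": "" if p.train_rate_hz is None else f"{p.train_rate_hz:.9g}",
                "pharmacology": ";".join(sorted(s.pharmacology)),
            })
            t = np.arange(s.vm.size) / s.sample_rate_hz
            arr = np.column_stack([t, s.vm])
            np.savetxt(path / trace_file, arr, fmt="%.9g", delimiter=",",
                       header="time_s,vm_mV", comments="")
    for name, cols, rows in (("cells.csv", _CELL_COLUMNS, cell_rows),
                             ("sweeps.csv", _SWEEP_COLUMNS, sweep_rows)):
        with open(path / name, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            w.writerows(rows)


def _parse_float(value: str, default: float | None = None) -> float | None:
    if value is None or value == "":
        return default
    return float(value)


def read_sweep_bundle(path: str | Path) -> list[CellRecording]:
    """Read a sweep bundle directory into CellRecordings.

    Ordering is deterministic — by (cell_id, sweep_index) — and independent
    of file-system enumeration order.

    Raises
    ------
    FormatError
        Manifest tables missing or malformed.
    IntegrityError
        Trace file missing, or its length disagrees with the manifest.
    """
    path = Path(path)
    cells_csv, sweeps_csv = path / "cells.csv", path / "sweeps.csv"
    if not cells_csv.is_file() or not sweeps_csv.is_file():
        raise FormatError(f"not a sweep bundle (missing manifest tables) at {path}")
    try:
        cell_df = pd.read_csv(cells_csv, dtype=str, keep_default_na=False)
        sweep_df = pd.read_csv(sweeps_csv, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"malformed manifest in {path}: {exc}") from exc
    for col in _CELL_COLUMNS:
        if col not in cell_df.columns:
            raise FormatError(f"cells.csv missing column {col!r}")
    for col in _SWEEP_COLUMNS:
        if col not in sweep_df.columns:
            raise FormatError(f"sweeps.csv missing column {col!r}")

    cells: dict[str, CellRecording] = {}
    for row in cell_df.to_dict("records"):
        cid = row["cell_id"]
        cells[cid] = CellRecording(
            cell_id=cid,
            subtype=row["subtype"] or "unknown",
            slice_id=row["slice_id"],
            mouse_id=row["mouse_id"],
            access_resistance_MOhm=_parse_float(row["access_resistance_MOhm"]),
            qc_flags=set(filter(None, row["qc_flags"].split(";"))),
        )
    for row in sweep_df.to_dict("records"):
        cid = row["cell_id"]
        if cid not in cells:
            raise FormatError(f"sweeps.csv references unknown cell {cid!r}")
        trace_path = path / row["trace_file"]
        label = f"{cid} sweep {row['sweep_index']}"
        if not trace_path.is_file():
            raise IntegrityError(f"missing trace file for {label}: {trace_path}")
        try:
            trace = np.loadtxt(trace_path, delimiter=",", skiprows=1, ndmin=2)
        except Exception as exc:  # noqa: BLE001
            raise IntegrityError(f"unreadable trace for {label}: {exc}") from exc
        n_expected = int(row["n_samples"])
        if trace.shape[0] != n_expected or trace.shape[1] != 2:
            raise IntegrityError(
                f"trace length mismatch for {label}: manifest says {n_expected} samples,"
                f" file has {trace.shape[0]}"
            )
        rate = float(row["sample_rate_hz"])
        if trace.shape[0] > 1:
            dt = trace[1, 0] - trace[0, 0]
            if dt > 0 and abs(1.0 / dt - rate) > 0.01 * rate:
                raise IntegrityError(f"sample-rate mismatch for {label}")
        protocol = StimProtocol(
            kind=row["protocol_kind"] or "none",
            pulse_onset_s=_parse_float(row["pulse_onset_s"], 0.0),
            pulse_duration_ms=_parse_float(row["pulse_duration_ms"], 0.0),
            n_pulses=int(row["n_pulses"] or 0),
            train_rate_hz=_parse_float(row["train_rate_hz"]),
        )
        cells[cid].sweeps.append(Sweep(
            cell_id=cid,
            sweep_index=int(row["sweep_index"]),
            sample_rate_hz=rate,
            vm=trace[:, 1],
            step_amplitude_pA=float(row["step_amplitude_pA"]),
            step_onset_s=float(row["step_onset_s"]),
            step_offset_s=float(row["step_offset_s"]),
            condition=row["condition"],
            protocol=protocol,
            pharmacology=frozenset(filter(None, row["pharmacology"].split(";"))),
        ))
    out = []
    for cid in sorted(cells):
        cell = cells[cid]
        cell.sweeps.sort(key=lambda s: s.sweep_index)
        out.append(cell)
    return out


# ---------------------------------------------------------------------------
# quality control

@dataclass(frozen=True)
class Discard:
    """A QC-discarded cell with a machine-readable reason."""

    cell: CellRecording
    reason: str


def qc_filter(
    cells: Iterable[CellRecording],
    ra_max_MOhm: float = 30.0,
    require_continuous_trains: bool = False,
    spike_counter: Callable[[Sweep], int] | None = None,
) -> tuple[list[CellRecording], list[Discard]]:
    """Apply the recording quality-control rules.

    Cells with access resistance strictly larger than ``ra_max_MOhm`` are
    discarded (Ra == 30 MOhm is kept); cells without a recorded Ra are
    discarded with reason ``"ra_missing"`` rather than silently kept. With
    ``require_continuous_trains``, a cell whose no-light f-I ladder contains
    a zero-AP sweep between its first and last spiking sweeps is discarded
    ("discontinuous train"). Filtering never raises; kept and discarded
    partition the input.
    """
    if spike_counter is None:
        from .spikes import detect_aps

        def spike_counter(sweep: Sweep) -> int:
            return len(detect_aps(sweep))

    kept: list[CellRecording] = []
    discarded: list[Discard] = []
    for cell in cells:
        if cell.access_resistance_MOhm is None:
            discarded.append(Discard(cell, "ra_missing"))
            continue
        if cell.access_resistance_MOhm > ra_max_MOhm:
            discarded.append(Discard(cell, "ra_above_max"))
            continue
        if require_continuous_trains:
            counts = [spike_counter(s) for s in cell.fi_sweeps("no_light")]
            spiking = [i for i, n in enumerate(counts) if n > 0]
            if spiking:
                first, last = spiking[0], spiking[-1]
                if any(counts[i] == 0 for i in range(first, last + 1)):
                    discarded.append(Discard(cell, "discontinuous_train"))
                    continue
        kept.append(cell)
    return kept, discarded


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-(cell, sweep) feature table as CSV."""
    pd.DataFrame(table).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# vendor-format adapter contract

def read_abf(path: str | Path, mapping: Mapping[str, object]) -> CellRecording:
    """Adapter contract for vendor episodic binary files (Axon ABF).

    ``mapping`` supplies what the binary file does not: cell metadata and a
    per-sweep table of (step_amplitude_pA, condition, protocol). Requires the
    optional ``pyabf`` dependency; the plain-text bundle is the native format
    and nothing else in the package depends on this function.
    """
    try:
        import pyabf  # type: ignore[import-not-found]
    except ImportError as exc:
        raise CapabilityError(
            "reading ABF files requires the optional dependency pyabf "
            "(pip install tsephys[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))
    cell_meta = dict(mapping.get("cell", {}))
    sweep_meta: Sequence[Mapping[str, object]] = mapping.get("sweeps", [])  # type: ignore[assignment]
    channel = int(mapping.get("channel", 0))
    sweeps = []
    for i in range(abf.sweepCount):
        abf.setSweep(i, channel=channel)
        meta = dict(sweep_meta[i]) if i < len(sweep_meta) else {}
        protocol = meta.get("protocol", NO_LIGHT)
        sweeps.append(Sweep(
            cell_id=str(cell_meta.get("cell_id", Path(path).stem)),
            sweep_index=i,
            sample_rate_hz=float(abf.dataRate),
            vm=np.asarray(abf.sweepY, dtype=float),
            step_amplitude_pA=float(meta.get("step_amplitude_pA", 0.0)),
            step_onset_s=float(meta.get("step_onset_s", 0.0)),
            step_offset_s=float(meta.get("step_offset_s", abf.sweepX[-1])),
            condition=str(meta.get("condition", "no_light")),
            protocol=protocol,  # type: ignore[arg-type]
            pharmacology=frozenset(meta.get("pharmacology", ())),  # type: ignore[arg-type]
        ))
    return CellRecording(
        cell_id=str(cell_meta.get("cell_id", Path(path).stem)),
        subtype=str(cell_meta.get("subtype", "unknown")),
        slice_id=str(cell_meta.get("slice_id", "")),
        mouse_id=str(cell_meta.get("mouse_id", "")),
        access_resistance_MOhm=cell_meta.get("access_resistance_MOhm"),  # type: ignore[arg-type]
        sweeps=sweeps,
    )
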