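"""Optogenetically evoked PSP quantification and response classification.

A cell's response to a light protocol is classified from the average of
its sweeps: peak depolarization and peak hyperpolarization relative to the
pre-pulse baseline are measured inside the response window (pulse onset to
pulse offset + 300 ms, long enough to capture slow GABA_B
hyperpolarization), and compared to a threshold

    theta = max(k * baseline_noise_sd, floor_mV)      (k = 3, floor 0.3 mV)

* excitatory — only the depolarization exceeds theta,
* inhibitory — only the hyperpolarization exceeds theta,
* mixed — both exceed, * none — neither.

The source recordings report classes without a millivolt criterion; this
threshold rule is the package's own and is stored in every ResponseCall.
The slow-inhibition magnitude follows the published window metric: mean
Vm change 200-300 ms after pulse onset.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .io import AnalysisError, Sweep

__all__ = [
    "ResponseCall",
    "TransitionTable",
    "baseline_vm",
    "delta_vm_window",
    "classify_response",
    "breakdown",
    "transition_table",
    "washon_effect",
]

PROTOCOL_ORDER = ("single_pulse_10ms", "pulse_train_20hz", "single_pulse_500ms")
CLASS_ORDER = ("excitatory", "mixed", "inhibitory", "none")


@dataclass
class ResponseCall:
    """Classified response of one cell to one stimulation protocol."""

    cell_id: str
    protocol_kind: str
    response_class: str
    baseline_vm_mV: float
    peak_depol_mV: float
    peak_hyperpol_mV: float
    delta_vm_200_300_mV: float
    threshold_mV: float
    threshold_rule: str
    n_sweeps: int
    subtype: str = "unknown"


def _pulse_onset(sweep: Sweep) -> float:
    if sweep.protocol.kind == "none":
        raise AnalysisError("sweep has no light protocol")
    return sweep.protocol.pulse_onset_s


def baseline_vm(sweep: Sweep, window_ms: float = 100.0, vm: np.ndarray | None = None) -> float:
    """Mean Vm over the window ending at pulse onset (mV)."""
    onset = _pulse_onset(sweep)
    i1 = sweep.sample_at(onset)
    i0 = sweep.sample_at(onset - window_ms / 1000.0)
    if onset <= 0 or i1 <= i0:
        raise AnalysisError("no pre-pulse baseline window in this sweep")
    v = sweep.vm if vm is None else vm
    return float(np.mean(v[i0:i1]))


def delta_vm_window(
    sweep: Sweep,
    t0_ms: float = 200.0,
    t1_ms: float = 300.0,
    baseline_window_ms: float = 100.0,
    vm: np.ndarray | None = None,
) -> float:
    """Mean Vm change from baseline over [onset + t0, onset + t1] (mV).

    With the defaults this is the slow-inhibition metric: the average Vm
    200-300 ms after light pulse onset minus the pre-pulse baseline.
    """
    onset = _pulse_onset(sweep)
    v = sweep.vm if vm is None else vm
    i0 = int(round((onset + t0_ms / 1000.0) * sweep.sample_rate_hz))
    i1 = int(round((onset + t1_ms / 1000.0) * sweep.sample_rate_hz))
    if i1 > v.size or i0 >= i1:
        raise AnalysisError("response window exceeds the sweep")
    return float(np.mean(v[i0:i1])) - baseline_vm(sweep, baseline_window_ms, vm=v)


def _average_sweeps(sweeps: list[Sweep]) -> np.ndarray:
    n = min(s.vm.size for s in sweeps)
    return np.mean([s.vm[:n] for s in sweeps], axis=0)


def classify_response(
    sweeps: list[Sweep],
    k_sd: float = 3.0,
    floor_mV: float = 0.3,
    window_after_offset_ms: float = 300.0,
    baseline_window_ms: float = 100.0,
    smooth_ms: float = 2.0,
) -> ResponseCall:
    """Classify a cell's averaged response to one protocol.

    Sweeps are averaged first (matching the mean-of-sweeps presentation of
    the recordings) and low-pass filtered with a ``smooth_ms`` boxcar —
    short against the PSP kernels but enough that the peak measurements
    read the synaptic envelope rather than single-sample noise extremes.
    Peak depolarization / hyperpolarization relative to baseline are then
    measured from pulse onset to pulse offset + ``window_after_offset_ms``
    and compared to the threshold rule (the baseline noise sd is taken on
    the same smoothed trace the peaks are read from). Every field except
    the baseline itself is invariant under a DC shift of the traces.
    """
    if not sweeps:
        raise AnalysisError("classify_response requires at least one sweep")
    kinds = {s.protocol.kind for s in sweeps}
    durations = {s.protocol.pulse_duration_ms for s in sweeps}
    if len(kinds) != 1 or kinds == {"none"} or len(durations) != 1:
        raise AnalysisError(f"sweeps mix protocols: {sorted(kinds)}")
    sweep = sweeps[0]
    vm = _average_sweeps(sweeps)
    smooth_n = int(round(smooth_ms / 1000.0 * sweep.sample_rate_hz))
    vm_s = uniform_filter1d(vm, smooth_n) if smooth_n >= 2 else vm
    base = baseline_vm(sweep, baseline_window_ms, vm=vm_s)
    onset = _pulse_onset(sweep)
    end_s = sweep.protocol.offset_s + window_after_offset_ms / 1000.0
    i0 = sweep.sample_at(onset)
    i1 = min(vm.size, int(round(end_s * sweep.sample_rate_hz)))
    window = vm_s[i0:i1] - base
    peak_depol = float(window.max())
    peak_hyper = float(-window.min())

    ib0 = sweep.sample_at(onset - baseline_window_ms / 1000.0)
    noise_sd = float(np.std(vm_s[ib0:i0], ddof=1)) if i0 - ib0 > 1 else 0.0
    theta = max(k_sd * noise_sd, floor_mV)

    exc = peak_depol > theta
    inh = peak_hyper > theta
    response_class = {(True, False): "excitatory", (True, True): "mixed",
                      (False, True): "inhibitory", (False, False): "none"}[(exc, inh)]
    return ResponseCall(
        cell_id=sweep.cell_id,
        protocol_kind=_protocol_key(sweep),
        response_class=response_class,
        baseline_vm_mV=base,
        peak_depol_mV=peak_depol,
        peak_hyperpol_mV=peak_hyper,
        delta_vm_200_300_mV=delta_vm_window(sweep, vm=vm,
                                            baseline_window_ms=baseline_window_ms),
        threshold_mV=theta,
        threshold_rule=f"max({k_sd:g}*baseline_sd, {floor_mV:g} mV)",
        n_sweeps=len(sweeps),
    )


def _protocol_key(sweep: Sweep) -> str:
    return sweep.protocol.key


def breakdown(calls: list[ResponseCall], by_subtype: bool = False) -> pd.DataFrame:
    """Per-class counts and nearest-integer percentages.

    Percentages are rounded half away from zero (10/57 -> 18%); counts are
    reported alongside so the rounding is auditable.
    """
    if not calls:
        raise AnalysisError("breakdown requires at least one call")
    rows = []
    groups: dict[str, list[ResponseCall]] = {}
    for call in calls:
        key = call.subtype if by_subtype else "all"
        groups.setdefault(key, []).append(call)
    for key in sorted(groups):
        counts = Counter(c.response_class for c in groups[key])
        total = sum(counts.values())
        for cls in CLASS_ORDER:
            if counts[cls] == 0:
                continue
            rows.append({
                "group": key,
                "response_class": cls,
                "count": counts[cls],
                "total": total,
                "percent": round_half_away(100.0 * counts[cls] / total),
            })
    return pd.DataFrame(rows)


def round_half_away(x: float) -> int:
    """Nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class TransitionTable:
    """Joint response classes across the three protocols.

    ``counts`` maps (class at 10 ms, class at 20 Hz, class at 500 ms) to
    the number of cells; only cells with calls under all three protocols
    are included, so the total equals the number of fully characterized
    cells.
    """

    counts: dict
    protocols: tuple

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def marginal(self, protocol_kind: str) -> Counter:
        axis = self.protocols.index(protocol_kind)
        out: Counter = Counter()
        for combo, n in self.counts.items():
            out[combo[axis]] += n
        return out

    def to_edge_list(self) -> pd.DataFrame:
        """Long-format edges between consecutive protocols (Sankey-ready)."""
        rows = []
        for a, b in zip(self.protocols[:-1], self.protocols[1:]):
            ia, ib = self.protocols.index(a), self.protocols.index(b)
            edges: Counter = Counter()
            for combo, n in self.counts.items():
                edges[(combo[ia], combo[ib])] += n
            for (ca, cb), n in sorted(edges.items()):
                rows.append({"from_protocol": a, "from_class": ca,
                             "to_protocol": b, "to_class": cb, "n_cells": n})
        return pd.DataFrame(rows)


def transition_table(
    calls: list[ResponseCall],
    protocols: tuple = PROTOCOL_ORDER,
) -> TransitionTable:
    """Cross-protocol transition table over fully characterized cells."""
    by_cell: dict[str, dict[str, str]] = {}
    for call in calls:
        by_cell.setdefault(call.cell_id, {})[call.protocol_kind] = call.response_class
    counts: Counter = Counter()
    for classes in by_cell.values():
        if all(p in classes for p in protocols):
            counts[tuple(classes[p] for p in protocols)] += 1
    return TransitionTable(counts=dict(counts), protocols=tuple(protocols))


def washon_effect(
    pre_sweeps: list[Sweep],
    post_sweeps: list[Sweep],
    t0_ms: float = 200.0,
    t1_ms: float = 300.0,
) -> tuple[float, float]:
    """(pre, post) slow-window Vm change for one cell's wash-on experiment.

    ``pre`` sweeps carry the cgp_pre tag (GABA_B intact), ``post`` sweeps
    cgp_post (receptor blocked); both phases must share the protocol. The
    two values are the window metric on the phase-averaged traces, paired
    for a signed-rank comparison across cells. Baseline-relative, so a DC
    offset between phases does not bias the pair.
    """
    if not pre_sweeps or not post_sweeps:
        raise AnalysisError("washon_effect requires sweeps in both phases")
    kinds = {s.protocol.kind for s in pre_sweeps} | {s.protocol.kind for s in post_sweeps}
    if len(kinds) != 1:
        raise AnalysisError("pre and post phases use different protocols")
    out = []
    for sweeps in (pre_sweeps, post_sweeps):
        vm = _average_sweeps(sweeps)
        out.append(delta_vm_window(sweeps[0], t0_ms=t0_ms, t1_ms=t1_ms, vm=vm))
    return out[0], out[1]


def calls_table(calls: list[ResponseCall]) -> pd.DataFrame:
    """Flat export of response calls (one row per cell x protocol)."""
    return pd.DataFrame([vars(c) for c in calls])
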