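"""Action-potential detection and per-train feature extraction.

Conventions follow standard current-clamp practice for medium spiny
neurons:

* AP threshold is the point where dV/dt first exceeds a slope criterion
  (default 20 mV/ms) on the rising limb before the peak.
* AP height is threshold-to-peak; half-width is the full width at half
  height with linear interpolation between samples; rise time is 10-90% of
  height on the rising limb.
* "First spike" features refer to the first AP of a train; "train mean"
  features average all APs excluding the first. The mean inter-spike
  interval always averages over all APs of the train, which makes it equal
  to (t_last - t_first) / (n - 1).
* Latency is measured from current-step onset to the first AP's threshold
  crossing (onset semantics; switchable to the peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .io import CapabilityError, CellRecording, Sweep

__all__ = [
    "ActionPotential",
    "TrainFeatures",
    "detect_aps",
    "extract_ap_features",
    "train_features",
    "feature_table",
]


@dataclass
class ActionPotential:
    """Geometry of one action potential.

    Times are in seconds from sweep start; voltages in mV; widths in ms.
    ``half_width_ms`` / ``rise_time_ms`` are NaN when the waveform does not
    admit the measurement (flagged undefined, never fabricated).
    """

    threshold_time_s: float
    peak_time_s: float
    threshold_vm_mV: float
    peak_vm_mV: float
    half_width_ms: float = math.nan
    rise_time_ms: float = math.nan

    @property
    def height_mV(self) -> float:
        return self.peak_vm_mV - self.threshold_vm_mV


@dataclass
class TrainFeatures:
    """Per-sweep spike-train summary.

    ``latency_ms`` is defined for n_aps >= 1, ``mean_isi_ms`` for
    n_aps >= 2; undefined fields are NaN. ``train_mean_*`` average the APs
    of the train excluding the first; they are NaN for single-AP trains.
    """

    n_aps: int
    frequency_hz: float
    latency_ms: float
    mean_isi_ms: float
    first_spike: ActionPotential | None
    train_mean_height_mV: float
    train_mean_half_width_ms: float
    train_mean_rise_time_ms: float


def _smoothed_dvdt(vm: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """dV/dt in mV/ms from a 5-point quadratic Savitzky-Golay derivative."""
    dt_ms = 1000.0 / sample_rate_hz
    if vm.size < 5:
        return np.gradient(vm, dt_ms)
    return savgol_filter(vm, window_length=5, polyorder=2, deriv=1, delta=dt_ms)


def detect_aps(
    sweep: Sweep,
    dvdt_threshold_mV_per_ms: float = 20.0,
    min_peak_prominence_mV: float = 10.0,
    refractory_ms: float = 1.0,
    restrict_to_step: bool = True,
) -> list[ActionPotential]:
    """Detect action potentials in one sweep.

    Peaks are found by prominence on the raw trace; each peak's threshold is
    the first sample before it where the smoothed dV/dt crosses the slope
    criterion. Peaks closer than ``refractory_ms`` are merged to the larger
    one. When the sweep defines a current step and ``restrict_to_step`` is
    set, only APs whose peak falls inside the step window are returned. The
    detector is translation-invariant: a DC offset changes no output.

    Raises
    ------
    CapabilityError
        If the sample rate is below 10 kHz, too low for a slope criterion.
    """
    if sweep.sample_rate_hz < 10_000:
        raise CapabilityError(
            f"sample rate {sweep.sample_rate_hz:g} Hz too low for dV/dt detection (need >= 10 kHz)"
        )
    vm = sweep.vm
    if vm.size < 5:
        return []
    dvdt = _smoothed_dvdt(vm, sweep.sample_rate_hz)
    peaks, _ = find_peaks(vm, prominence=min_peak_prominence_mV)
    if peaks.size == 0:
        return []

    # merge peaks within the refractory window, keeping the larger
    refractory_n = max(1, int(round(refractory_ms / 1000.0 * sweep.sample_rate_hz)))
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < refractory_n:
            if vm[p] > vm[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)

    aps: list[ActionPotential] = []
    # the upstroke must lie close to the peak; bounding the walk-back also
    # keeps boundary artifacts of the smoothed derivative out of reach
    upstroke_window_n = int(round(0.005 * sweep.sample_rate_hz))
    prev_peak = 0
    for p in merged:
        # walk back from the peak through the suprathreshold-slope region;
        # the threshold sample is the first crossing of that region. A peak
        # with no fast upstroke before it (e.g. a noise bump riding the
        # subthreshold plateau) is not an AP.
        lo = max(prev_peak, p - upstroke_window_n, 2)
        i = p
        while i > lo and dvdt[i] < dvdt_threshold_mV_per_ms:
            i -= 1  # skip the peak plateau where dV/dt ~ 0
        if dvdt[i] < dvdt_threshold_mV_per_ms:
            continue
        while i > lo and dvdt[i - 1] >= dvdt_threshold_mV_per_ms:
            i -= 1
        if vm[p] - vm[i] < min_peak_prominence_mV:
            continue  # threshold-to-peak too small for a regenerative event
        aps.append(ActionPotential(
            threshold_time_s=i / sweep.sample_rate_hz,
            peak_time_s=p / sweep.sample_rate_hz,
            threshold_vm_mV=float(vm[i]),
            peak_vm_mV=float(vm[p]),
        ))
        prev_peak = p

    if restrict_to_step and sweep.step_amplitude_pA != 0:
        aps = [a for a in aps if sweep.step_onset_s <= a.peak_time_s <= sweep.step_offset_s]
    return aps


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float, rising: bool) -> float:
    """Linearly interpolated first time v crosses level (rising or falling)."""
    if rising:
        above = v >= level
    else:
        above = v <= level
    idx = np.flatnonzero(above)
    if idx.size == 0 or idx[0] == 0:
        return math.nan
    i = idx[0]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t[i])
    frac = (level - v0) / (v1 - v0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def extract_ap_features(sweep: Sweep, aps: list[ActionPotential]) -> list[ActionPotential]:
    """Fill half-width and rise time on detected APs (in place, returned).

    Half-width is measured at threshold_vm + height/2 by linear
    interpolation; rise time between the 10% and 90% height crossings on
    the rising limb. Features that cannot be measured (clipped waveform,
    non-monotonic limb) are left NaN.
    """
    vm = sweep.vm
    rate = sweep.sample_rate_hz
    n = vm.size
    for k, ap in enumerate(aps):
        i_thr = int(round(ap.threshold_time_s * rate))
        i_peak = int(round(ap.peak_time_s * rate))
        # search for the repolarization out to the next AP (or 10 ms)
        i_end = min(n - 1, i_peak + int(0.010 * rate))
        if k + 1 < len(aps):
            i_end = min(i_end, int(round(aps[k + 1].threshold_time_s * rate)))
        height = ap.height_mV
        if height <= 0 or i_peak <= i_thr:
            continue
        t = np.arange(i_thr, i_end + 1) / rate
        seg = vm[i_thr:i_end + 1]
        rise_t = np.arange(i_thr, i_peak + 1) / rate
        rise_v = vm[i_thr:i_peak + 1]

        half = ap.threshold_vm_mV + height / 2.0
        t_up = _interp_crossing(rise_t, rise_v, half, rising=True)
        fall_t = np.arange(i_peak, i_end + 1) / rate
        fall_v = vm[i_peak:i_end + 1]
        t_down = _interp_crossing(fall_t, fall_v, half, rising=False)
        if not (math.isnan(t_up) or math.isnan(t_down)):
            ap.half_width_ms = (t_down - t_up) * 1000.0

        t10 = _interp_crossing(rise_t, rise_v, ap.threshold_vm_mV + 0.1 * height, rising=True)
        t90 = _interp_crossing(rise_t, rise_v, ap.threshold_vm_mV + 0.9 * height, rising=True)
        if not (math.isnan(t10) or math.isnan(t90)) and t90 > t10:
            ap.rise_time_ms = (t90 - t10) * 1000.0
        del t, seg
    return aps


def train_features(
    sweep: Sweep,
    aps: list[ActionPotential],
    latency_reference: str = "threshold",
) -> TrainFeatures:
    """Summarize a detected spike train.

    Frequency is n_aps over the current-step duration (a 500 ms step gives
    Hz = n_aps * 2). Latency runs from step onset to the first AP's
    threshold crossing by default (``latency_reference="peak"`` switches to
    the peak). The mean ISI averages successive peak-time differences over
    all APs, i.e. (t_last - t_first)/(n-1).
    """
    n = len(aps)
    frequency = n / sweep.step_duration_s
    latency = math.nan
    mean_isi = math.nan
    if n >= 1:
        t0 = aps[0].threshold_time_s if latency_reference == "threshold" else aps[0].peak_time_s
        latency = (t0 - sweep.step_onset_s) * 1000.0
    if n >= 2:
        peaks = np.array([a.peak_time_s for a in aps])
        mean_isi = float(np.mean(np.diff(peaks))) * 1000.0

    def _train_mean(attr: str) -> float:
        vals = [getattr(a, attr) for a in aps[1:]]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    return TrainFeatures(
        n_aps=n,
        frequency_hz=frequency,
        latency_ms=latency,
        mean_isi_ms=mean_isi,
        first_spike=aps[0] if aps else None,
        train_mean_height_mV=_train_mean("height_mV"),
        train_mean_half_width_ms=_train_mean("half_width_ms"),
        train_mean_rise_time_ms=_train_mean("rise_time_ms"),
    )


def feature_table(cells: list[CellRecording], **detect_kwargs) -> pd.DataFrame:
    """Per-(cell, sweep) feature table over the f-I sweeps of a cohort.

    One row per current-step sweep with the train summary plus first-spike
    geometry; the CSV written from this table is the package's feature
    export.
    """
    rows = []
    for cell in cells:
        for condition in ("no_light", "light"):
            for sweep in cell.fi_sweeps(condition):
                aps = extract_ap_features(sweep, detect_aps(sweep, **detect_kwargs))
                tf = train_features(sweep, aps)
                first = tf.first_spike
                rows.append({
                    "cell_id": cell.cell_id,
                    "subtype": cell.subtype,
                    "sweep_index": sweep.sweep_index,
                    "condition": condition,
                    "step_amplitude_pA": sweep.step_amplitude_pA,
                    "n_aps": tf.n_aps,
                    "frequency_hz": tf.frequency_hz,
                    "latency_ms": tf.latency_ms,
                    "mean_isi_ms": tf.mean_isi_ms,
                    "first_height_mV": first.height_mV if first else math.nan,
                    "first_half_width_ms": first.half_width_ms if first else math.nan,
                    "first_rise_time_ms": first.rise_time_ms if first else math.nan,
                    "train_mean_height_mV": tf.train_mean_height_mV,
                    "train_mean_half_width_ms": tf.train_mean_half_width_ms,
                    "train_mean_rise_time_ms": tf.train_mean_rise_time_ms,
                })
    return pd.DataFrame(rows)
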