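"""Paired light / no-light input-output curves and paired feature deltas.

Each current step is recorded twice — without and then with optogenetic
stimulation — so every comparison is paired within a sweep pair. Group
curves are built under two alignment anchors:

* ``first_spike_anchor`` — each cell's steps re-indexed relative to the
  first step with recorded spikes (rheobase alignment);
* ``max_current_anchor`` — relative to the cell's highest completed paired
  step (cells stop at depolarization block, so this aligns the
  high-depolarization end).

"Normalized to" is read as re-indexing, not amplitude scaling: the curves
plot mean firing frequency per condition against the relative step index.

Designated comparison sweeps follow the recording conventions: latency is
compared at the first step with APs in both conditions; the low-
depolarization ISI one step above that (so trains hold multiple APs); every
high-depolarization measurement at the no-light depolarization-block sweep,
for both conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .block import BlockResult, detect_block_sweep
from .io import AnalysisError, CellRecording
from .spikes import detect_aps, extract_ap_features, train_features

__all__ = [
    "IOCurve",
    "PairedDelta",
    "CellExclusion",
    "select_latency_sweep",
    "select_isi_low_depol_sweep",
    "select_high_depol_sweep",
    "build_io_curve",
    "paired_deltas",
]

FEATURES = ("latency_ms", "mean_isi_ms", "frequency_hz",
            "height", "half_width", "rise_time")


@dataclass(frozen=True)
class CellExclusion:
    """A cell excluded from a comparison, with a machine-readable reason."""

    cell_id: str
    reason: str


@dataclass
class IOCurve:
    """Group input-output curve under one alignment anchor.

    ``table`` holds every (relative_index, condition) aggregate including
    under-populated indices; ``curve`` filters to indices with at least
    ``min_cells`` contributing cells.
    """

    alignment: str
    min_cells: int
    table: pd.DataFrame
    long: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def curve(self) -> pd.DataFrame:
        return self.table[self.table["n_cells"] >= self.min_cells].reset_index(drop=True)


@dataclass(frozen=True)
class PairedDelta:
    """One cell's paired light-minus-no-light feature difference."""

    cell_id: str
    feature: str
    state: str
    sweep_step_index: int
    value_no_light: float
    value_light: float

    @property
    def delta(self) -> float:
        return self.value_light - self.value_no_light


def _pair_spike_counts(cell: CellRecording, **detect_kwargs) -> list[tuple[int, int]]:
    """(no_light, light) AP counts per paired step, ascending current."""
    return [
        (len(detect_aps(nl, **detect_kwargs)), len(detect_aps(lt, **detect_kwargs)))
        for nl, lt in cell.fi_pairs()
    ]


def select_latency_sweep(cell: CellRecording, **detect_kwargs) -> int:
    """First paired step index with at least one AP in both conditions.

    Raises AnalysisError when no step qualifies (the cell is excluded from
    latency comparisons).
    """
    for i, (n_nl, n_lt) in enumerate(_pair_spike_counts(cell, **detect_kwargs)):
        if n_nl >= 1 and n_lt >= 1:
            return i
    raise AnalysisError(f"cell {cell.cell_id}: no step spikes in both conditions")


def select_isi_low_depol_sweep(cell: CellRecording, **detect_kwargs) -> int:
    """One step above the latency sweep, so trains hold multiple APs."""
    i = select_latency_sweep(cell, **detect_kwargs) + 1
    if i >= len(cell.fi_pairs()):
        raise AnalysisError(f"cell {cell.cell_id}: latency sweep is the last recorded step")
    return i


def select_high_depol_sweep(
    cell: CellRecording,
    block: BlockResult | None = None,
    **detect_kwargs,
) -> int:
    """The no-light depolarization-block sweep, anchor of every
    high-depolarization measurement for both conditions.

    Raises AnalysisError when the cell has no detected block (unimodal
    height distribution or never half-attenuated).
    """
    if block is None:
        block = detect_block_sweep(cell, "no_light", **detect_kwargs)
    if block.block_sweep_index is None:
        raise AnalysisError(f"cell {cell.cell_id}: no depolarization block detected")
    return block.block_sweep_index


def _first_spike_step(cell: CellRecording, **detect_kwargs) -> int | None:
    """First paired step with >=1 AP in either condition."""
    for i, (n_nl, n_lt) in enumerate(_pair_spike_counts(cell, **detect_kwargs)):
        if n_nl >= 1 or n_lt >= 1:
            return i
    return None


def build_io_curve(
    cells: list[CellRecording],
    alignment: str = "first_spike_anchor",
    min_cells: int = 3,
    **detect_kwargs,
) -> IOCurve:
    """Build the group f-I curve under one alignment anchor.

    Every contributing cell supplies paired frequencies from the same
    absolute sweep pair; relative index 0 is the anchor step. Aggregates
    with fewer than ``min_cells`` cells are dropped from ``curve`` but kept
    in ``table``.
    """
    if alignment not in ("first_spike_anchor", "max_current_anchor"):
        raise AnalysisError(f"unknown alignment {alignment!r}")
    rows = []
    for cell in cells:
        pairs = cell.fi_pairs()
        if not pairs:
            continue
        if alignment == "first_spike_anchor":
            anchor = _first_spike_step(cell, **detect_kwargs)
            if anchor is None:
                continue
        else:
            anchor = len(pairs) - 1
        for i, (nl, lt) in enumerate(pairs):
            f_nl = train_features(nl, detect_aps(nl, **detect_kwargs)).frequency_hz
            f_lt = train_features(lt, detect_aps(lt, **detect_kwargs)).frequency_hz
            rows.append({
                "cell_id": cell.cell_id,
                "relative_index": i - anchor,
                "step_amplitude_pA": nl.step_amplitude_pA,
                "frequency_no_light_hz": f_nl,
                "frequency_light_hz": f_lt,
            })
    long = pd.DataFrame(rows)
    if long.empty:
        table = pd.DataFrame(columns=[
            "relative_index", "mean_frequency_no_light_hz", "sem_no_light",
            "mean_frequency_light_hz", "sem_light", "n_cells"])
        return IOCurve(alignment=alignment, min_cells=min_cells, table=table, long=long)
    g = long.groupby("relative_index")
    table = pd.DataFrame({
        "mean_frequency_no_light_hz": g["frequency_no_light_hz"].mean(),
        "sem_no_light": g["frequency_no_light_hz"].sem(ddof=1),
        "mean_frequency_light_hz": g["frequency_light_hz"].mean(),
        "sem_light": g["frequency_light_hz"].sem(ddof=1),
        "n_cells": g["cell_id"].nunique(),
    }).reset_index()
    return IOCurve(alignment=alignment, min_cells=min_cells, table=table, long=long)


def io_curve_tidy(curve: IOCurve) -> pd.DataFrame:
    """Tidy (long) export of a group curve: one row per index and condition."""
    rows = []
    for rec in curve.table.to_dict("records"):
        for cond in ("no_light", "light"):
            rows.append({
                "alignment": curve.alignment,
                "relative_index": rec["relative_index"],
                "condition": cond,
                "mean_frequency_hz": rec[f"mean_frequency_{cond}_hz"],
                "sem": rec["sem_no_light" if cond == "no_light" else "sem_light"],
                "n_cells": rec["n_cells"],
            })
    return pd.DataFrame(rows)


def _feature_value(sweep, feature: str, **detect_kwargs) -> float:
    aps = detect_aps(sweep, **detect_kwargs)
    if feature in ("height", "half_width", "rise_time"):
        aps = extract_ap_features(sweep, aps)
    tf = train_features(sweep, aps)
    if feature in ("latency_ms", "mean_isi_ms", "frequency_hz"):
        return getattr(tf, feature)
    first = tf.first_spike
    if first is None:
        return math.nan
    return {"height": first.height_mV,
            "half_width": first.half_width_ms,
            "rise_time": first.rise_time_ms}[feature]


def paired_deltas(
    cells: list[CellRecording],
    feature: str,
    state: str,
    **detect_kwargs,
) -> tuple[list[PairedDelta], list[CellExclusion]]:
    """Per-cell paired (light - no light) differences of one feature.

    ``state`` selects the designated sweep: ``"low_depol"`` uses the
    latency sweep (or, for the ISI, one step above it); ``"high_depol"``
    uses the no-light block sweep for every feature. Both values of a delta
    always come from the same sweep pair. Ineligible cells are returned in
    the exclusion log, never silently dropped.
    """
    if feature not in FEATURES:
        raise AnalysisError(f"unknown feature {feature!r}")
    if state not in ("low_depol", "high_depol"):
        raise AnalysisError(f"unknown state {state!r}")
    deltas: list[PairedDelta] = []
    excluded: list[CellExclusion] = []
    for cell in cells:
        try:
            if state == "low_depol":
                if feature == "mean_isi_ms":
                    step = select_isi_low_depol_sweep(cell, **detect_kwargs)
                else:
                    step = select_latency_sweep(cell, **detect_kwargs)
            else:
                step = select_high_depol_sweep(cell)
        except AnalysisError as exc:
            excluded.append(CellExclusion(cell.cell_id, str(exc)))
            continue
        pairs = cell.fi_pairs()
        if step >= len(pairs):
            excluded.append(CellExclusion(cell.cell_id, "designated sweep not recorded"))
            continue
        nl, lt = pairs[step]
        v_nl = _feature_value(nl, feature, **detect_kwargs)
        v_lt = _feature_value(lt, feature, **detect_kwargs)
        if math.isnan(v_nl) or math.isnan(v_lt):
            excluded.append(CellExclusion(cell.cell_id, f"{feature} undefined at designated sweep"))
            continue
        deltas.append(PairedDelta(
            cell_id=cell.cell_id, feature=feature, state=state,
            sweep_step_index=step, value_no_light=v_nl, value_light=v_lt))
    return deltas, excluded
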