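"""Depolarization-block detection from the bimodal AP-height histogram.

At high depolarization, medium spiny neurons fail to recover from sodium
channel inactivation and their action potentials shrink. Pooling all AP
heights of a cell yields a bimodal histogram: the upper mode is the height
of full APs, the lower mode the height of attenuated APs. A sweep whose
spike train has at least half of its APs *below the lower mode* marks the
onset of depolarization block; the first such sweep is the block sweep and
anchors every high-depolarization measurement.

Peak positions are reported as the upper edge of the modal bin (ties
between adjacent bins resolve to the lower bin). Reporting the upper edge
rather than the bin center makes "below the lower peak" include the
attenuated cluster that forms the peak itself; with a center convention
roughly half of a tight attenuated cluster would sit above its own mode and
the rule could never fire on it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import AnalysisError, CellRecording
from .spikes import detect_aps

__all__ = [
    "Histogram",
    "BlockResult",
    "height_histogram",
    "find_bimodal_peaks",
    "classify_heights",
    "detect_block_sweep",
]


@dataclass(frozen=True)
class Histogram:
    """AP-height histogram: ``edges`` has one more entry than ``counts``."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class BlockResult:
    """Outcome of block detection for one cell and condition.

    ``block_sweep_index`` is the first sweep (position in the ascending
    f-I ladder) whose attenuated-AP fraction reaches 0.5, or None when no
    sweep qualifies or the height distribution is unimodal.
    """

    condition: str
    lower_peak_mV: float | None
    upper_peak_mV: float | None
    bin_width_mV: float
    per_sweep_attenuated_fraction: list[float]
    block_sweep_index: int | None

    @property
    def bimodal(self) -> bool:
        return self.lower_peak_mV is not None and self.upper_peak_mV is not None


def height_histogram(heights_mV, bin_width_mV: float = 2.0) -> Histogram:
    """Histogram of AP heights with fixed-width bins covering [min, max].

    Counts conserve the number of heights. Raises AnalysisError on empty
    input.
    """
    heights = np.asarray(heights_mV, dtype=float)
    if heights.size == 0:
        raise AnalysisError("cannot build a height histogram from zero APs")
    if bin_width_mV <= 0:
        raise AnalysisError("bin_width_mV must be > 0")
    lo, hi = float(heights.min()), float(heights.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width_mV)))
    edges = lo + bin_width_mV * np.arange(n_bins + 1)
    # np.histogram's final bin is closed, so max lands inside
    counts, _ = np.histogram(heights, bins=edges)
    return Histogram(edges=edges, counts=counts)


def find_bimodal_peaks(
    hist: Histogram,
    min_separation_mV: float = 10.0,
    smooth_bins: int = 3,
) -> tuple[float, float] | None:
    """Locate the two modes of an AP-height histogram.

    Counts are smoothed with a ``smooth_bins``-wide moving average, local
    maxima are found, and the two largest maxima at least
    ``min_separation_mV`` apart are returned as (lower, upper) positions
    (upper edge of the modal bin; adjacent-bin ties resolve to the lower
    bin). Returns None when the distribution is unimodal by this rule.
    """
    counts = hist.counts.astype(float)
    if counts.size == 0:
        return None
    if smooth_bins > 1 and counts.size >= smooth_bins:
        kernel = np.ones(smooth_bins) / smooth_bins
        smooth = np.convolve(counts, kernel, mode="same")
    else:
        smooth = counts
    # local maxima, plateau edges included; exact-tie plateaus contribute
    # their edge bins and the tie-break below prefers the lower bin
    maxima = []
    for i in range(smooth.size):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < smooth.size - 1 else -np.inf
        is_max = smooth[i] >= left and smooth[i] >= right and (smooth[i] > left or smooth[i] > right)
        if smooth.size == 1:
            is_max = True
        if is_max and counts[i] > 0:
            maxima.append(i)
    if len(maxima) < 2:
        return None
    # order candidate modes by smoothed mass, then scan for a separated pair
    maxima.sort(key=lambda i: (-smooth[i], i))
    positions = hist.edges[1:]  # upper edge per bin
    for a in range(len(maxima)):
        for b in range(a + 1, len(maxima)):
            i, j = maxima[a], maxima[b]
            if abs(positions[i] - positions[j]) >= min_separation_mV:
                lo, hi = sorted((positions[i], positions[j]))
                return float(lo), float(hi)
    return None


def classify_heights(heights_mV, lower_peak_mV: float) -> np.ndarray:
    """Label APs attenuated (True) iff height falls strictly below the lower peak."""
    heights = np.asarray(heights_mV, dtype=float)
    return heights < lower_peak_mV


def detect_block_sweep(
    cell: CellRecording,
    condition: str = "no_light",
    bin_width_mV: float = 2.0,
    min_separation_mV: float = 10.0,
    pool: str = "cell",
    half_fraction: float = 0.5,
    height_smooth_ms: float = 0.3,
    **detect_kwargs,
) -> BlockResult:
    """Find the depolarization-block sweep of one cell in one condition.

    AP heights are pooled across all of the cell's sweeps in the condition
    (``pool="sweep"`` recomputes the histogram per sweep instead); the block
    sweep is the first position in the ascending current ladder whose
    attenuated fraction reaches ``half_fraction`` (at least half, boundary
    included). Unimodal cells return an explicit no-block outcome and are
    excluded from high-depolarization comparisons downstream.

    Heights are measured on a copy of the trace smoothed with a
    ``height_smooth_ms`` boxcar (well under the AP half-width): the
    full/attenuated separation is what matters here, and the smoothing
    tightens each height cluster so single-sample noise extremes cannot
    leak APs across the lower-mode boundary. Feature exports elsewhere
    keep raw-trace geometry.

    Raises AnalysisError when the cell has no spiking sweep in the
    condition.
    """
    sweeps = cell.fi_sweeps(condition)
    per_sweep_heights = []
    for sweep in sweeps:
        measured = sweep
        smooth_n = int(round(height_smooth_ms / 1000.0 * sweep.sample_rate_hz))
        if smooth_n >= 2:
            measured = dataclasses.replace(sweep, vm=uniform_filter1d(sweep.vm, smooth_n))
        aps = detect_aps(measured, **detect_kwargs)
        per_sweep_heights.append(np.array([a.height_mV for a in aps]))
    pooled = np.concatenate(per_sweep_heights) if per_sweep_heights else np.empty(0)
    if pooled.size == 0:
        raise AnalysisError(f"cell {cell.cell_id}: no spiking sweeps in condition {condition!r}")

    def _result(lower, upper, fractions):
        block = None
        for i, f in enumerate(fractions):
            if not np.isnan(f) and f >= half_fraction:
                block = i
                break
        return BlockResult(
            condition=condition,
            lower_peak_mV=lower,
            upper_peak_mV=upper,
            bin_width_mV=bin_width_mV,
            per_sweep_attenuated_fraction=[float(f) for f in fractions],
            block_sweep_index=block,
        )

    if pool == "cell":
        peaks = find_bimodal_peaks(height_histogram(pooled, bin_width_mV), min_separation_mV)
        if peaks is None:
            return _result(None, None, [np.nan] * len(sweeps))
        lower, upper = peaks
        fractions = [
            float(np.mean(classify_heights(h, lower))) if h.size else np.nan
            for h in per_sweep_heights
        ]
        return _result(lower, upper, fractions)
    if pool == "sweep":
        fractions = []
        lower = upper = None
        for h in per_sweep_heights:
            if h.size == 0:
                fractions.append(np.nan)
                continue
            peaks = find_bimodal_peaks(height_histogram(h, bin_width_mV), min_separation_mV)
            if peaks is None:
                fractions.append(0.0)
                continue
            lower, upper = peaks
            fractions.append(float(np.mean(classify_heights(h, lower))))
        return _result(lower, upper, fractions)
    raise AnalysisError(f"unknown pooling scope {pool!r}")
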