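import numpy as np
import pytest

from tsephys import (
    build_io_curve,
    paired_deltas,
    select_high_depol_sweep,
    select_isi_low_depol_sweep,
    select_latency_sweep,
)
from tsephys.io import AnalysisError, CellRecording, Sweep
from tsephys.iocurves import io_curve_tidy
from tsephys.stats import wilcoxon_signed_rank
from tsephys.synth import FICellParams, generate_fi_cell

from conftest import build_fi_cell


def _times(n, start=0.2, isi=0.05):
    return [start + k * isi for k in range(n)]


class TestSweepSelection:
    def test_latency_sweep_needs_both_conditions(self):
        """No-light spikes first at step 4, light at step 3 -> step 4."""
        cell = build_fi_cell([
            ([], []), ([], []), ([], []),
            ([], _times(1)),          # light only
            (_times(1), _times(2)),   # both
            (_times(3), _times(3)),
        ])
        assert select_latency_sweep(cell) == 4

    def test_latency_sweep_same_step(self):
        cell = build_fi_cell([([], []), ([], []), (_times(1), _times(1))])
        assert select_latency_sweep(cell) == 2

    def test_light_never_spiking_excludes(self):
        cell = build_fi_cell([(_times(2), []), (_times(3), [])])
        with pytest.raises(AnalysisError):
            select_latency_sweep(cell)

    def test_isi_sweep_is_one_above(self):
        cell = build_fi_cell([([], []), (_times(1), _times(1)),
                              (_times(3), _times(3))])
        assert select_isi_low_depol_sweep(cell) == 2

    def test_isi_sweep_missing_when_latency_is_last(self):
        cell = build_fi_cell([([], []), (_times(1), _times(1))])
        with pytest.raises(AnalysisError):
            select_isi_low_depol_sweep(cell)

    def test_isi_sweep_has_multiple_aps_in_cohort(self):
        """The step above first spikes holds >= 2 APs in both conditions."""
        from tsephys import detect_aps

        ok = 0
        for seed in range(10):
            cell, _ = generate_fi_cell(seed=300 + seed)
            step = select_isi_low_depol_sweep(cell)
            nl, lt = cell.fi_pairs()[step]
            if len(detect_aps(nl)) >= 2 and len(detect_aps(lt)) >= 2:
                ok += 1
        assert ok >= 9

    def test_high_depol_is_block_sweep(self, default_fi_cell):
        cell, truth = default_fi_cell
        assert select_high_depol_sweep(cell) == truth.block_step["no_light"]

    def test_unimodal_cell_excluded_from_high_depol(self):
        cell = build_fi_cell([(_times(2), _times(2)), (_times(4), _times(4))])
        with pytest.raises(AnalysisError):
            select_high_depol_sweep(cell)


class TestIOCurve:
    def test_single_cell_curve_is_its_frequencies(self, noiseless_fi_cell):
        cell, _ = noiseless_fi_cell
        curve = build_io_curve([cell], "first_spike_anchor", min_cells=1)
        assert (curve.table["n_cells"] == 1).all()
        row0 = curve.table[curve.table["relative_index"] == 0].iloc[0]
        assert row0["mean_frequency_no_light_hz"] > 0

    def test_rheobase_offset_cells_align(self):
        """Two identical cells whose rheobase differs by one step collapse
        onto the same first-spike-anchored curve."""
        a, _ = generate_fi_cell(FICellParams(noise_sd_mV=0.0), seed=1, cell_id="a")
        b, _ = generate_fi_cell(
            FICellParams(noise_sd_mV=0.0, rheobase_pA=250.0,
                         block_onset_step_index=7),
            n_steps=10, seed=1, cell_id="b")
        ca = build_io_curve([a], "first_spike_anchor", min_cells=1)
        cb = build_io_curve([b], "first_spike_anchor", min_cells=1)
        merged = ca.table.merge(cb.table, on="relative_index", suffixes=("_a", "_b"))
        assert len(merged) > 3
        np.testing.assert_allclose(merged["mean_frequency_no_light_hz_a"],
                                   merged["mean_frequency_no_light_hz_b"])

    def test_anchor_invariant_to_amplitude_shift(self, noiseless_fi_cell):
        cell, _ = noiseless_fi_cell
        shifted_sweeps = [
            Sweep(cell_id=s.cell_id, sweep_index=s.sweep_index,
                  sample_rate_hz=s.sample_rate_hz, vm=s.vm,
                  step_amplitude_pA=s.step_amplitude_pA + 100.0,
                  step_onset_s=s.step_onset_s, step_offset_s=s.step_offset_s,
                  condition=s.condition, protocol=s.protocol)
            for s in cell.sweeps
        ]
        shifted = CellRecording(cell_id="shifted", access_resistance_MOhm=10.0,
                                sweeps=shifted_sweeps)
        c1 = build_io_curve([cell], "first_spike_anchor", min_cells=1)
        c2 = build_io_curve([shifted], "first_spike_anchor", min_cells=1)
        np.testing.assert_allclose(c1.table["mean_frequency_light_hz"],
                                   c2.table["mean_frequency_light_hz"])

    def test_light_maintains_firing_at_max_current(self):
        """With later block under light, light frequency exceeds no-light
        at the highest completed step."""
        cells = [generate_fi_cell(seed=400 + s, cell_id=f"m{s}")[0] for s in range(5)]
        curve = build_io_curve(cells, "max_current_anchor")
        row0 = curve.curve[curve.curve["relative_index"] == 0].iloc[0]
        assert row0["mean_frequency_light_hz"] > row0["mean_frequency_no_light_hz"]

    def test_empty_input_gives_empty_curve(self):
        curve = build_io_curve([], "first_spike_anchor")
        assert curve.table.empty and curve.curve.empty

    def test_tidy_export_shape(self, noiseless_fi_cell):
        curve = build_io_curve([noiseless_fi_cell[0]], "max_current_anchor", min_cells=1)
        tidy = io_curve_tidy(curve)
        assert set(tidy["condition"]) == {"no_light", "light"}
        assert len(tidy) == 2 * len(curve.table)


class TestPairedDeltas:
    def test_injected_latency_effect_recovered_exactly(self, noiseless_cohort):
        cells, _ = noiseless_cohort
        deltas, excluded = paired_deltas(cells, "latency_ms", "low_depol")
        assert not excluded
        assert [d.delta for d in deltas] == pytest.approx([-10.0] * len(cells), abs=1e-6)

    def test_injected_isi_effect_recovered_exactly(self, noiseless_cohort):
        cells, _ = noiseless_cohort
        deltas, _ = paired_deltas(cells, "mean_isi_ms", "low_depol")
        assert [d.delta for d in deltas] == pytest.approx([-5.0] * len(cells), abs=1e-6)

    def test_zero_effect_cohort_centers_on_zero(self):
        params = FICellParams(light_latency_delta_ms=0.0, light_isi_delta_ms=0.0,
                              light_extra_full_steps=0)
        cells = [generate_fi_cell(params, seed=500 + s, cell_id=f"z{s}")[0]
                 for s in range(12)]
        deltas, _ = paired_deltas(cells, "latency_ms", "low_depol")
        res = wilcoxon_signed_rank([d.delta for d in deltas])
        assert res.p_value > 0.05

    def test_deltas_never_mix_sweeps(self, noiseless_cohort):
        cells, _ = noiseless_cohort
        for state in ("low_depol", "high_depol"):
            deltas, _ = paired_deltas(cells, "frequency_hz", state)
            for d in deltas:
                cell = next(c for c in cells if c.cell_id == d.cell_id)
                nl, lt = cell.fi_pairs()[d.sweep_step_index]
                assert nl.step_amplitude_pA == lt.step_amplitude_pA

    def test_cell_without_light_aps_logged(self):
        spiking = build_fi_cell([([], []), (_times(2), _times(2)),
                                 (_times(4), _times(4))], cell_id="good")
        silent = build_fi_cell([(_times(2), []), (_times(4), [])], cell_id="nolight")
        deltas, excluded = paired_deltas([spiking, silent], "latency_ms", "low_depol")
        assert {d.cell_id for d in deltas} == {"good"}
        assert excluded[0].cell_id == "nolight"
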