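import numpy as np
import pytest

from tsephys import (
    baseline_vm,
    breakdown,
    classify_response,
    delta_vm_window,
    transition_table,
    washon_effect,
)
from tsephys.io import AnalysisError, Sweep
from tsephys.psp import ResponseCall, round_half_away
from tsephys.synth import (
    PROTOCOL_10MS,
    PROTOCOL_20HZ,
    PROTOCOL_500MS,
    PSPKernelParams,
    generate_psp_cell,
    generate_psp_sweep,
    noise_free_psp,
)

RATE = 50_000.0


def _sweep_from(vm, protocol=PROTOCOL_500MS):
    return Sweep(cell_id="w", sweep_index=0, sample_rate_hz=RATE, vm=vm,
                 step_amplitude_pA=0.0, step_onset_s=protocol.pulse_onset_s,
                 step_offset_s=protocol.offset_s, condition="light",
                 protocol=protocol)


def _call(cls, cell="c", proto="single_pulse_500ms", subtype="unknown"):
    return ResponseCall(cell_id=cell, protocol_kind=proto, response_class=cls,
                        baseline_vm_mV=-78.0, peak_depol_mV=0.0,
                        peak_hyperpol_mV=0.0, delta_vm_200_300_mV=0.0,
                        threshold_mV=0.3, threshold_rule="test", n_sweeps=1,
                        subtype=subtype)


class TestWindowMetrics:
    def test_constant_baseline(self):
        sweep = _sweep_from(np.full(60_000, -78.0))
        assert baseline_vm(sweep) == pytest.approx(-78.0)

    def test_ramp_baseline_is_window_midpoint(self):
        """Linear drift of 1 mV/s averages to the midpoint of the window."""
        t = np.arange(60_000) / RATE
        sweep = _sweep_from(-80.0 + 1.0 * t)
        mid = PROTOCOL_500MS.pulse_onset_s - 0.05
        assert baseline_vm(sweep, window_ms=100.0) == pytest.approx(-80.0 + mid, abs=1e-4)

    def test_flat_trace_zero_delta(self):
        sweep = _sweep_from(np.full(60_000, -70.0))
        assert delta_vm_window(sweep) == pytest.approx(0.0)

    def test_plateau_delta(self):
        vm = np.full(60_000, -78.0)
        t0 = PROTOCOL_500MS.pulse_onset_s
        vm[int((t0 + 0.15) * RATE): int((t0 + 0.35) * RATE)] = -79.5
        assert delta_vm_window(_sweep_from(vm)) == pytest.approx(-1.5)

    def test_window_outside_sweep_raises(self):
        sweep = _sweep_from(np.full(12_000, -78.0))
        with pytest.raises(AnalysisError):
            delta_vm_window(sweep)

    def test_matches_analytic_kernel_sum(self):
        kern = PSPKernelParams(epsp_amplitude_mV=2.0, ipsp_amplitude_mV=1.5)
        sweep, _ = generate_psp_sweep(PROTOCOL_500MS, kern, noise_sd_mV=0.0)
        t0 = PROTOCOL_500MS.pulse_onset_s
        t = np.arange(int((t0 + 0.2) * RATE), int((t0 + 0.3) * RATE)) / RATE
        expected = float(np.mean(noise_free_psp(PROTOCOL_500MS, kern, t)))
        assert delta_vm_window(sweep) == pytest.approx(expected, abs=1e-6)


class TestClassification:
    def test_flat_traces_are_none(self):
        call = classify_response([_sweep_from(np.full(60_000, -78.0))])
        assert call.response_class == "none"

    @pytest.mark.parametrize("true_class", ["excitatory", "mixed", "inhibitory"])
    @pytest.mark.parametrize("protocol", [PROTOCOL_10MS, PROTOCOL_20HZ, PROTOCOL_500MS],
                             ids=["10ms", "20hz", "500ms"])
    def test_ground_truth_class_recovered(self, true_class, protocol):
        kern = PSPKernelParams.for_class(true_class)
        sweeps = [generate_psp_sweep(protocol, kern, noise_sd_mV=0.1,
                                     seed=i, sweep_index=i)[0] for i in range(3)]
        assert classify_response(sweeps).response_class == true_class

    def test_mixed_protocols_rejected(self):
        a, _ = generate_psp_sweep(PROTOCOL_10MS, PSPKernelParams.for_class("excitatory"))
        b, _ = generate_psp_sweep(PROTOCOL_500MS, PSPKernelParams.for_class("excitatory"))
        with pytest.raises(AnalysisError):
            classify_response([a, b])

    def test_dc_shift_changes_only_baseline(self):
        kern = PSPKernelParams.for_class("mixed")
        sweep, _ = generate_psp_sweep(PROTOCOL_500MS, kern, noise_sd_mV=0.1, seed=3)
        shifted = _sweep_from(sweep.vm + 12.0)
        a = classify_response([sweep])
        b = classify_response([shifted])
        assert a.response_class == b.response_class
        assert a.peak_depol_mV == pytest.approx(b.peak_depol_mV, abs=1e-9)
        assert a.delta_vm_200_300_mV == pytest.approx(b.delta_vm_200_300_mV, abs=1e-9)
        assert b.baseline_vm_mV == pytest.approx(a.baseline_vm_mV + 12.0, abs=1e-9)

    def test_growing_ipsp_never_moves_toward_excitatory(self):
        """Class order exc > mixed > inh on a hyperpolarization axis."""
        order = {"excitatory": 0, "mixed": 1, "inhibitory": 2, "none": 1}
        prev = -1
        for ipsp in (0.0, 0.5, 1.5, 4.0):
            cls = "excitatory" if ipsp == 0 else "mixed"
            kern = PSPKernelParams.for_class(cls, ipsp_amplitude_mV=ipsp)
            sweep, _ = generate_psp_sweep(PROTOCOL_500MS, kern, noise_sd_mV=0.0)
            rank = order[classify_response([sweep]).response_class]
            assert rank >= prev
            prev = rank


class TestBreakdown:
    def test_printed_percentages_for_train(self):
        """41 excitatory + 21 mixed of 63 cells -> 65% / 33%."""
        calls = [_call("excitatory", f"e{i}") for i in range(41)]
        calls += [_call("mixed", f"m{i}") for i in range(21)]
        calls += [_call("inhibitory", "i0")]
        bd = breakdown(calls).set_index("response_class")
        assert bd.loc["excitatory", "percent"] == 65
        assert bd.loc["mixed", "percent"] == 33

    def test_single_cell_is_100_percent(self):
        bd = breakdown([_call("inhibitory")])
        assert bd.iloc[0]["percent"] == 100

    def test_subtype_grouping(self):
        calls = [_call("excitatory", "a", subtype="D1"),
                 _call("mixed", "b", subtype="D2"),
                 _call("mixed", "c", subtype="D2")]
        bd = breakdown(calls, by_subtype=True)
        d2 = bd[bd["group"] == "D2"]
        assert d2.iloc[0]["percent"] == 100 and d2.iloc[0]["count"] == 2

    @pytest.mark.parametrize("x,expected", [(17.5, 18), (37.5, 38), (2.5, 3),
                                            (-2.5, -3), (17.4, 17)])
    def test_rounding_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestTransitions:
    def _calls_for(self, cell, classes):
        return [
            _call(classes[0], cell, "single_pulse_10ms"),
            _call(classes[1], cell, "pulse_train_20hz"),
            _call(classes[2], cell, "single_pulse_500ms"),
        ]

    def test_long_pulse_inhibition_was_mixed_at_train(self):
        """Cells inhibited by the long pulse respond mixed to the train."""
        calls = []
        for i in range(4):
            calls += self._calls_for(f"c{i}", ("excitatory", "mixed", "inhibitory"))
        for i in range(4, 10):
            calls += self._calls_for(f"c{i}", ("excitatory", "excitatory", "mixed"))
        table = transition_table(calls)
        assert table.total == 10
        bad = [combo for combo in table.counts
               if combo[2] == "inhibitory" and combo[1] != "mixed"]
        assert not bad

    def test_partial_cells_excluded_and_marginals_conserved(self):
        calls = self._calls_for("full", ("excitatory", "mixed", "mixed"))
        calls.append(_call("excitatory", "partial", "single_pulse_10ms"))
        table = transition_table(calls)
        assert table.total == 1
        assert table.marginal("pulse_train_20hz")["mixed"] == 1
        edges = table.to_edge_list()
        assert edges["n_cells"].sum() == 2  # one edge per consecutive pair

    def test_single_cell_unit_entry(self):
        table = transition_table(self._calls_for("solo", ("mixed",) * 3))
        assert table.counts == {("mixed", "mixed", "mixed"): 1}


class TestWashon:
    def _cell(self, seed, true_class="mixed"):
        cell, _ = generate_psp_cell({PROTOCOL_500MS: true_class},
                                    noise_sd_mV=0.1, n_sweeps=3, seed=seed,
                                    cell_id=f"w{seed}", washon=True)
        pre = [s for s in cell.sweeps if "cgp_pre" in s.pharmacology]
        post = [s for s in cell.sweeps if "cgp_post" in s.pharmacology]
        return pre, post

    def test_blockade_abolishes_slow_hyperpolarization(self):
        """Across 9 cells the pre window is hyperpolarized, the post window
        near zero, and the paired signed-rank test rejects at alpha 0.05."""
        from tsephys.stats import wilcoxon_signed_rank

        pre_vals, post_vals = [], []
        for seed in range(9):
            pre, post = self._cell(seed)
            dv_pre, dv_post = washon_effect(pre, post)
            pre_vals.append(dv_pre)
            post_vals.append(dv_post)
        assert all(p < -0.5 for p in pre_vals)
        assert all(abs(p) < 0.3 for p in post_vals)
        assert wilcoxon_signed_rank(pre_vals, post_vals).p_value < 0.05

    def test_identical_phases_give_equal_deltas(self):
        pre, _ = self._cell(1)
        dv_a, dv_b = washon_effect(pre, pre)
        assert dv_a == pytest.approx(dv_b)

    def test_dc_offset_between_phases_ignored(self):
        pre, post = self._cell(2)
        shifted_post = [_sweep_from(s.vm + 5.0) for s in post]
        dv1 = washon_effect(pre, post)
        dv2 = washon_effect(pre, shifted_post)
        assert dv1[1] == pytest.approx(dv2[1], abs=1e-9)

    def test_empty_phase_rejected(self):
        pre, _ = self._cell(3)
        with pytest.raises(AnalysisError):
            washon_effect(pre, [])
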