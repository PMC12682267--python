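import numpy as np
import pytest

from tsephys.io import ParameterError
from tsephys.synth import (
    CohortConfig,
    FICellParams,
    PROTOCOL_10MS,
    PROTOCOL_20HZ,
    PROTOCOL_500MS,
    PSPKernelParams,
    _allocate,
    generate_cohort,
    generate_fi_cell,
    generate_psp_sweep,
    noise_free_psp,
    psp_kernel,
    read_ground_truth,
)


class TestFICell:
    def test_same_seed_bit_identical(self):
        a, _ = generate_fi_cell(seed=9)
        b, _ = generate_fi_cell(seed=9)
        for sa, sb in zip(a.sweeps, b.sweeps):
            np.testing.assert_array_equal(sa.vm, sb.vm)

    def test_closed_form_spike_count(self):
        """gain 0.1 Hz/pA, rheobase 200 pA -> 10 spikes at 400 pA."""
        params = FICellParams(noise_sd_mV=0.0, rheobase_pA=200.0,
                              gain_hz_per_pA=0.1, block_onset_step_index=8,
                              light_extra_full_steps=0)
        cell, truth = generate_fi_cell(params, n_steps=9, seed=2)
        sweep_400 = [s for s in cell.fi_sweeps("no_light")
                     if s.step_amplitude_pA == 400.0][0]
        t = [s for s in truth.sweeps if s.sweep_index == sweep_400.sweep_index][0]
        assert len(t.spike_times_s) == 10
        from tsephys import detect_aps
        assert len(detect_aps(sweep_400)) == 10

    def test_subthreshold_step_returns_to_rest(self):
        params = FICellParams(noise_sd_mV=0.0)
        cell, truth = generate_fi_cell(params, seed=0)
        sweep = cell.fi_sweeps("no_light")[0]  # 50 pA, below 200 pA rheobase
        t = [s for s in truth.sweeps if s.sweep_index == sweep.sweep_index][0]
        assert t.spike_times_s == ()
        assert sweep.vm[-1] == pytest.approx(params.resting_vm, abs=0.5)
        assert sweep.vm.max() < -45.0

    def test_ground_truth_consistency(self, default_fi_cell):
        """Spike times inside the step; attenuated >= 0.5 from block onward."""
        cell, truth = default_fi_cell
        by_index = {s.sweep_index: s for s in cell.sweeps}
        for st in truth.sweeps:
            sweep = by_index[st.sweep_index]
            times = np.array(st.spike_times_s)
            assert np.all(np.diff(times) > 0)
            assert np.all((times >= sweep.step_onset_s) & (times <= sweep.step_offset_s))
            assert len(st.attenuated) == len(st.spike_times_s)
            block = truth.block_step[st.condition]
            if times.size:
                frac = np.mean(st.attenuated)
                if block is not None and st.step_index >= block:
                    assert frac >= 0.5
                else:
                    assert frac == 0.0

    def test_block_before_rheobase_rejected(self):
        with pytest.raises(ParameterError):
            generate_fi_cell(FICellParams(rheobase_pA=300.0,
                                          block_onset_step_index=2))

    def test_light_effects_are_exact_without_noise(self, noiseless_fi_cell):
        cell, truth = noiseless_fi_cell
        params = truth.params["fi"]
        for st_nl in truth.sweeps:
            if st_nl.condition != "no_light" or not st_nl.spike_times_s:
                continue
            st_lt = [s for s in truth.sweeps
                     if s.condition == "light" and s.step_index == st_nl.step_index][0]
            if not st_lt.spike_times_s:
                continue
            d_lat = (st_lt.spike_times_s[0] - st_nl.spike_times_s[0]) * 1000
            assert d_lat == pytest.approx(params["light_latency_delta_ms"], abs=1e-9)


class TestPSP:
    def test_kernel_unit_peak_and_causality(self):
        t = np.linspace(-0.1, 2.0, 20001)
        k = psp_kernel(t, 2.0, 20.0)
        assert k[t < 0].max() == 0.0
        assert k.max() == pytest.approx(1.0, abs=1e-4)

    def test_excitatory_single_pulse(self):
        kern = PSPKernelParams.for_class("excitatory")
        sweep, truth = generate_psp_sweep(PROTOCOL_10MS, kern, noise_sd_mV=0.0)
        dev = sweep.vm - (-78.0)
        assert dev.max() > 1.0
        assert dev.min() >= -1e-9
        assert truth.psp_class["single_pulse_10ms"] == "excitatory"

    def test_mixed_long_pulse_window_is_hyperpolarized(self):
        """Slow IPSP dominates the 200-300 ms window of a mixed response."""
        kern = PSPKernelParams(epsp_amplitude_mV=2.0, ipsp_amplitude_mV=1.5,
                               true_class="mixed")
        sweep, _ = generate_psp_sweep(PROTOCOL_500MS, kern, noise_sd_mV=0.0)
        t0 = PROTOCOL_500MS.pulse_onset_s
        i0, i1 = int((t0 + 0.2) * 50_000), int((t0 + 0.3) * 50_000)
        assert np.mean(sweep.vm[i0:i1] - (-78.0)) < 0
        # trace equals the analytic kernel sum
        t = np.arange(sweep.vm.size) / 50_000
        np.testing.assert_allclose(sweep.vm, -78.0 + noise_free_psp(PROTOCOL_500MS, kern, t))

    def test_train_pulses_barely_summate(self):
        """The EPSP decays by ~90% within one 50 ms inter-pulse interval
        (2.5 decay constants), so a 20 Hz train barely summates; the
        sampled remnant equals the kernel's closed form."""
        kern = PSPKernelParams.for_class("excitatory")
        tr, td = kern.epsp_tau_rise_ms / 1000, kern.epsp_tau_decay_ms / 1000
        t = np.arange(0, 0.5, 2e-5)
        k = psp_kernel(t, kern.epsp_tau_rise_ms, kern.epsp_tau_decay_ms)
        i_peak = int(np.argmax(k))
        remnant = k[i_peak + int(0.05 / 2e-5)] / k[i_peak]
        t_probe = t[i_peak] + 0.05
        t_pk = tr * td / (td - tr) * np.log(td / tr)
        closed = ((np.exp(-t_probe / td) - np.exp(-t_probe / tr))
                  / (np.exp(-t_pk / td) - np.exp(-t_pk / tr)))
        assert remnant == pytest.approx(closed / k[i_peak], abs=1e-3)
        assert remnant <= 0.10

    def test_kernel_linearity(self):
        base = PSPKernelParams.for_class("excitatory", epsp_amplitude_mV=1.0)
        double = PSPKernelParams.for_class("excitatory", epsp_amplitude_mV=2.0)
        t = np.arange(0, 1.0, 1e-4)
        np.testing.assert_allclose(
            2 * noise_free_psp(PROTOCOL_20HZ, base, t),
            noise_free_psp(PROTOCOL_20HZ, double, t), atol=1e-12)

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            generate_psp_sweep(PROTOCOL_10MS, noise_sd_mV=-1.0)

    def test_class_amplitude_consistency_enforced(self):
        with pytest.raises(ParameterError):
            PSPKernelParams(epsp_amplitude_mV=0.0, ipsp_amplitude_mV=0.0,
                            true_class="mixed")


class TestCohort:
    def test_mixture_realized_exactly(self, tmp_path):
        cfg = CohortConfig(
            n_fi_cells={}, n_psp_cells=56,
            psp_mixture={"single_pulse_500ms":
                         {"excitatory": 10 / 56, "mixed": 34 / 56, "inhibitory": 12 / 56}},
            n_psp_sweeps=1)
        _, truths = generate_cohort(cfg, seed=4, out_dir=tmp_path / "b")
        labels = [t.psp_class["single_pulse_500ms"] for t in truths]
        assert labels.count("excitatory") == 10
        assert labels.count("mixed") == 34
        assert labels.count("inhibitory") == 12
        back = read_ground_truth(tmp_path / "b")
        assert [t.psp_class for t in back] == [t.psp_class for t in truths]

    def test_bad_mixture_rejected(self):
        with pytest.raises(ParameterError):
            _allocate({"excitatory": 0.5, "mixed": 0.3}, 10)

    def test_empty_cohort_is_valid(self, tmp_path):
        from tsephys import read_sweep_bundle

        cells, truths = generate_cohort(CohortConfig(n_fi_cells={}), seed=0,
                                        out_dir=tmp_path / "b")
        assert cells == [] and truths == []
        assert read_sweep_bundle(tmp_path / "b") == []

    def test_seed_changes_noise_not_labels(self):
        cfg = CohortConfig(
            n_fi_cells={}, n_psp_cells=6,
            psp_mixture={"single_pulse_500ms":
                         {"excitatory": 0.5, "mixed": 0.5}},
            n_psp_sweeps=1)
        cells1, truths1 = generate_cohort(cfg, seed=1)
        cells2, truths2 = generate_cohort(cfg, seed=2)
        assert [t.psp_class for t in truths1] == [t.psp_class for t in truths2]
        assert not np.array_equal(cells1[0].sweeps[0].vm, cells2[0].sweeps[0].vm)
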