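"""Synthetic current-clamp data with exact ground truth.

The generator emulates the two recording protocols the analysis pipeline
targets:

* **f-I ladders** — 500 ms depolarizing current steps at 50 pA increments,
  each recorded as a (no-light, light) pair, where spike trains attenuate
  past a configurable depolarization-block onset and the light condition
  delays block and shifts latency / inter-spike interval by configured
  amounts;
* **PSP sweeps** — optogenetically evoked postsynaptic potentials under a
  10 ms single pulse, a 20 Hz pulse train of 5 ms pulses, or a 500 ms
  single pulse, built from a fast EPSP kernel and a slow, delayed IPSP
  kernel (the GABA_B timescale, hundreds of milliseconds) plus Gaussian
  noise.

Spike waveforms are stereotyped piecewise-linear templates inserted onto a
passive RC step response rather than an ODE neuron model: templates give
exact, closed-form ground truth for detector and feature tests, which a
dynamical model would blur. Per-step randomness (latency and ISI jitter) is
drawn from a substream shared between the no-light and light sweep of a
pair, so configured light effects survive to the paired deltas exactly when
trace noise is off; trace noise uses per-sweep substreams. All output is a
pure function of (parameters, seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .io import CellRecording, ParameterError, StimProtocol, Sweep, write_sweep_bundle

__all__ = [
    "APTemplateParams",
    "FICellParams",
    "PSPKernelParams",
    "SweepTruth",
    "GroundTruth",
    "CohortConfig",
    "ap_template_waveform",
    "make_spike_train_sweep",
    "generate_fi_cell",
    "psp_kernel",
    "generate_psp_sweep",
    "generate_psp_cell",
    "generate_cohort",
    "read_ground_truth",
    "PROTOCOL_10MS",
    "PROTOCOL_20HZ",
    "PROTOCOL_500MS",
]

PULSE_ONSET_S = 0.2
PROTOCOL_10MS = StimProtocol("single_pulse", PULSE_ONSET_S, 10.0, 1)
PROTOCOL_20HZ = StimProtocol("pulse_train", PULSE_ONSET_S, 5.0, 10, 20.0)
PROTOCOL_500MS = StimProtocol("single_pulse", PULSE_ONSET_S, 500.0, 1)


@dataclass(frozen=True)
class APTemplateParams:
    """Stereotyped action-potential template.

    The waveform is a piecewise-linear rise/fall added on top of the local
    baseline: a linear ramp of amplitude ``full_height`` whose 10-90% rise
    time is ``rise_time_ms`` followed by a linear repolarization sized so
    the full width at half height equals ``half_width_ms`` exactly.
    Attenuated APs scale the height by ``attenuated_height_fraction``.
    """

    threshold_vm: float = -45.0
    full_height: float = 80.0
    attenuated_height_fraction: float = 0.45
    half_width_ms: float = 1.5
    rise_time_ms: float = 0.4

    def __post_init__(self) -> None:
        if not 0 < self.attenuated_height_fraction < 1:
            raise ParameterError("attenuated_height_fraction must be in (0, 1)")
        if self.half_width_ms <= 0 or self.rise_time_ms <= 0:
            raise ParameterError("half_width_ms and rise_time_ms must be > 0")
        if self.rise_up_ms / 2 >= self.half_width_ms:
            raise ParameterError("half_width_ms too small for the requested rise time")

    @property
    def rise_up_ms(self) -> float:
        """Total threshold-to-peak rise duration (10-90% of a ramp is 0.8 of it)."""
        return self.rise_time_ms / 0.8

    @property
    def fall_ms(self) -> float:
        """Peak-to-baseline fall sized so FWHM == half_width_ms."""
        return 2.0 * self.half_width_ms - self.rise_up_ms


def ap_template_waveform(ap: APTemplateParams, sample_rate_hz: float,
                         height_mV: float | None = None) -> tuple[np.ndarray, int]:
    """Sampled template (additive mV) and the index of its peak sample.

    The waveform is evaluated on the sample grid of an AP whose peak falls
    exactly on a sample; linear segments stay exactly linear after
    sampling, so interpolation-based feature extraction recovers the
    template geometry to within one sample period.
    """
    h = ap.full_height if height_mV is None else height_mV
    dt_ms = 1000.0 / sample_rate_hz
    n_up = int(round(ap.rise_up_ms / dt_ms))
    n_down = int(round(ap.fall_ms / dt_ms))
    up = np.linspace(0.0, h, n_up + 1)
    down = np.linspace(h, 0.0, n_down + 1)[1:]
    return np.concatenate([up, down]), n_up


@dataclass(frozen=True)
class FICellParams:
    """Parameters of one synthetic f-I cell.

    ``block_onset_step_index`` is the 0-based position in the step ladder
    at which at least half the APs become attenuated in the no-light
    condition; the light condition blocks ``light_extra_full_steps`` steps
    later and shifts latency / mean ISI by the signed deltas (ms). The
    spike count above rheobase is round(gain * (I - rheobase) * step
    duration) and declines geometrically once the sweep is blocked.
    """

    resting_vm: float = -80.0
    rheobase_pA: float = 200.0
    gain_hz_per_pA: float = 0.1
    block_onset_step_index: int = 6
    light_extra_full_steps: int = 2
    light_latency_delta_ms: float = -10.0
    light_isi_delta_ms: float = -5.0
    noise_sd_mV: float = 0.2
    input_resistance_MOhm: float = 80.0
    membrane_tau_ms: float = 15.0
    base_latency_ms: float = 100.0
    latency_step_slope_ms: float = 15.0
    latency_jitter_ms: float = 3.0
    isi_jitter_ms: float = 1.5
    blocked_count_decline: float = 0.6
    blocked_fraction_start: float = 0.6
    blocked_fraction_slope: float = 0.2
    dropout_steps: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.rheobase_pA <= 0:
            raise ParameterError("rheobase_pA must be > 0")
        if self.noise_sd_mV < 0:
            raise ParameterError("noise_sd_mV must be >= 0")
        if not 0.5 <= self.blocked_fraction_start <= 1.0:
            raise ParameterError("blocked_fraction_start must be in [0.5, 1]")


@dataclass(frozen=True)
class SweepTruth:
    """Ground truth for one generated sweep."""

    condition: str
    step_index: int
    sweep_index: int
    spike_times_s: tuple[float, ...]
    attenuated: tuple[bool, ...]


@dataclass
class GroundTruth:
    """Everything the generator knows about one synthetic cell."""

    cell_id: str
    seed: int
    params: dict
    sweeps: list[SweepTruth] = field(default_factory=list)
    block_step: dict = field(default_factory=dict)
    psp_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweeps"] = [asdict(s) for s in self.sweeps]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        sweeps = [SweepTruth(
            condition=s["condition"], step_index=s["step_index"],
            sweep_index=s["sweep_index"],
            spike_times_s=tuple(s["spike_times_s"]),
            attenuated=tuple(s["attenuated"]),
        ) for s in d.get("sweeps", [])]
        return cls(cell_id=d["cell_id"], seed=d["seed"], params=d.get("params", {}),
                   sweeps=sweeps, block_step=d.get("block_step", {}),
                   psp_class=d.get("psp_class", {}))


def _passive_step(n: int, rate: float, onset_s: float, offset_s: float,
                  resting: float, plateau: float, tau_ms: float) -> np.ndarray:
    """Resting trace with an RC charge/discharge to a subthreshold plateau."""
    t = np.arange(n) / rate
    vm = np.full(n, resting)
    tau = tau_ms / 1000.0
    during = (t >= onset_s) & (t < offset_s)
    vm[during] = resting + (plateau - resting) * (1.0 - np.exp(-(t[during] - onset_s) / tau))
    after = t >= offset_s
    v_end = resting + (plateau - resting) * (1.0 - math.exp(-(offset_s - onset_s) / tau))
    vm[after] = resting + (v_end - resting) * np.exp(-(t[after] - offset_s) / tau)
    return vm


def make_spike_train_sweep(
    spike_peak_times_s,
    ap: APTemplateParams = APTemplateParams(),
    heights_mV=None,
    resting_vm: float = -80.0,
    plateau_vm: float | None = None,
    step_amplitude_pA: float = 300.0,
    step_onset_s: float = 0.1,
    step_offset_s: float = 0.6,
    duration_s: float = 0.75,
    sample_rate_hz: float = 50_000.0,
    noise_sd_mV: float = 0.0,
    rng: np.random.Generator | None = None,
    **sweep_kwargs,
) -> Sweep:
    """Render a sweep with AP templates peaking at the given times.

    A building block for tests and for :func:`generate_fi_cell`; spike
    peaks land on the nearest sample of the 50 kHz grid.
    """
    n = int(round(duration_s * sample_rate_hz))
    plateau = resting_vm + 15.0 if plateau_vm is None else plateau_vm
    vm = _passive_step(n, sample_rate_hz, step_onset_s, step_offset_s,
                       resting_vm, plateau, ap_tau_ms(ap))
    times = np.atleast_1d(np.asarray(spike_peak_times_s, dtype=float))
    if heights_mV is None:
        heights_mV = [ap.full_height] * times.size
    for t_peak, h in zip(times, heights_mV):
        wave, i_peak = ap_template_waveform(ap, sample_rate_hz, h)
        i0 = int(round(t_peak * sample_rate_hz)) - i_peak
        if i0 < 0 or i0 + wave.size > n:
            raise ParameterError(f"spike at {t_peak:g} s does not fit in the sweep")
        vm[i0:i0 + wave.size] += wave
    if noise_sd_mV > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        vm = vm + rng.normal(0.0, noise_sd_mV, size=n)
    defaults = dict(cell_id="synthetic", sweep_index=0)
    defaults.update(sweep_kwargs)
    return Sweep(
        sample_rate_hz=sample_rate_hz, vm=vm,
        step_amplitude_pA=step_amplitude_pA,
        step_onset_s=step_onset_s, step_offset_s=step_offset_s,
        **defaults,
    )


def ap_tau_ms(ap: APTemplateParams) -> float:  # noqa: ARG001 - uniform default
    """Membrane time constant used for the passive response (ms)."""
    return 15.0


def generate_fi_cell(
    params: FICellParams = FICellParams(),
    ap: APTemplateParams = APTemplateParams(),
    n_steps: int = 9,
    step_increment_pA: float = 50.0,
    seed: int = 0,
    cell_id: str = "cell0",
    subtype: str = "unknown",
    access_resistance_MOhm: float = 12.0,
    sample_rate_hz: float = 50_000.0,
    step_onset_s: float = 0.1,
    step_duration_s: float = 0.5,
    tail_s: float = 0.15,
) -> tuple[CellRecording, GroundTruth]:
    """Generate one cell's paired f-I ladder with ground truth.

    Steps run from ``step_increment_pA`` upward in equal increments; each
    step yields a no-light sweep and a light sweep (500 ms light pulse
    coincident with the step, even sweep indices no-light). Identical seeds
    give bit-identical output.
    """
    i_first = next((i for i in range(n_steps)
                    if step_increment_pA * (i + 1) > params.rheobase_pA), None)
    if i_first is None:
        raise ParameterError("no step in the ladder exceeds rheobase")
    if params.block_onset_step_index < i_first:
        raise ParameterError(
            f"block_onset_step_index {params.block_onset_step_index} precedes the "
            f"first suprathreshold step {i_first}"
        )
    if n_steps < params.block_onset_step_index:
        raise ParameterError("n_steps must reach block_onset_step_index")

    step_offset_s = step_onset_s + step_duration_s
    duration_s = step_offset_s + tail_s
    dur_ms = step_duration_s * 1000.0
    truth = GroundTruth(cell_id=cell_id, seed=seed,
                        params={"fi": asdict(params), "ap": asdict(ap)})
    sweeps: list[Sweep] = []
    onset_by_cond = {
        "no_light": params.block_onset_step_index,
        "light": params.block_onset_step_index + params.light_extra_full_steps,
    }
    truth.block_step = {c: (o if o < n_steps else None) for c, o in onset_by_cond.items()}

    for i in range(n_steps):
        current = step_increment_pA * (i + 1)
        base_count = 0
        if current > params.rheobase_pA:
            base_count = int(round(params.gain_hz_per_pA * (current - params.rheobase_pA)
                                   * step_duration_s))
        # latency/ISI jitter shared by the two conditions of the pair
        rng_pair = np.random.default_rng([seed % 2**31, 101, i])
        lat_jit = rng_pair.uniform(-params.latency_jitter_ms, params.latency_jitter_ms)
        isi_jit = rng_pair.uniform(-params.isi_jitter_ms, params.isi_jitter_ms,
                                   size=max(base_count - 1, 0))
        base_latency = max(20.0, params.base_latency_ms
                           - params.latency_step_slope_ms * (i - i_first)) + lat_jit

        for cond, code in (("no_light", 0), ("light", 1)):
            onset_i = onset_by_cond[cond]
            blocked = i >= onset_i
            n_spk = base_count
            if i in params.dropout_steps and cond == "no_light":
                n_spk = 0
            elif blocked and base_count > 0:
                n_spk = max(1, int(round(base_count
                                         * params.blocked_count_decline ** (i - onset_i + 1))))
            latency = base_latency + (params.light_latency_delta_ms if cond == "light" else 0.0)
            if latency < 5.0:
                raise ParameterError("configured latency effects push latency below 5 ms")
            spike_times: list[float] = []
            att: list[bool] = []
            if n_spk >= 1:
                base_isi = (dur_ms - base_latency - 30.0) / max(base_count - 1, 1)
                isis = base_isi + isi_jit[:max(n_spk - 1, 0)]
                if cond == "light":
                    isis = isis + params.light_isi_delta_ms
                t_ms = step_onset_s * 1000.0 + latency + np.concatenate([[0.0], np.cumsum(isis)])
                if t_ms[-1] > step_offset_s * 1000.0 - 2.0:
                    raise ParameterError("spike train does not fit inside the current step")
                spike_times = list(t_ms / 1000.0)
                n_att = int(math.ceil(
                    min(1.0, params.blocked_fraction_start
                        + params.blocked_fraction_slope * (i - onset_i)) * n_spk)) if blocked else 0
                att = [k >= n_spk - n_att for k in range(n_spk)]
            heights = [ap.full_height * (ap.attenuated_height_fraction if a else 1.0)
                       for a in att]
            plateau = params.resting_vm + min(
                params.input_resistance_MOhm * current / 1000.0,
                ap.threshold_vm - 4.0 - params.resting_vm,
            )
            rng_noise = np.random.default_rng([seed % 2**31, 202, i, code])
            sweep_index = 2 * i + code
            sweep = make_spike_train_sweep(
                spike_times, ap, heights,
                resting_vm=params.resting_vm, plateau_vm=plateau,
                step_amplitude_pA=current,
                step_onset_s=step_onset_s, step_offset_s=step_offset_s,
                duration_s=duration_s, sample_rate_hz=sample_rate_hz,
                noise_sd_mV=params.noise_sd_mV, rng=rng_noise,
                cell_id=cell_id, sweep_index=sweep_index,
                condition=cond,
                protocol=(StimProtocol("single_pulse", step_onset_s, 500.0, 1)
                          if cond == "light" else StimProtocol()),
            )
            sweeps.append(sweep)
            truth.sweeps.append(SweepTruth(
                condition=cond, step_index=i, sweep_index=sweep_index,
                spike_times_s=tuple(spike_times), attenuated=tuple(att),
            ))

    cell = CellRecording(cell_id=cell_id, subtype=subtype,
                         access_resistance_MOhm=access_resistance_MOhm, sweeps=sweeps)
    return cell, truth


# ---------------------------------------------------------------------------
# PSP generation

@dataclass(frozen=True)
class PSPKernelParams:
    """EPSP/IPSP kernel parameters and the intended response class.

    Kernels are differences of exponentials normalized to unit peak and
    scaled by the amplitudes; the IPSP is subtracted with an onset lag
    (default 30 ms) and its time constants put the hyperpolarization on the
    slow GABA_B scale of hundreds of milliseconds. Amplitudes are
    placeholders chosen for clear class separation — the source recordings
    report no population amplitude statistics.
    """

    epsp_amplitude_mV: float = 2.0
    epsp_tau_rise_ms: float = 2.0
    epsp_tau_decay_ms: float = 20.0
    ipsp_amplitude_mV: float = 1.5
    ipsp_tau_rise_ms: float = 60.0
    ipsp_tau_decay_ms: float = 250.0
    ipsp_lag_ms: float = 30.0
    long_pulse_scale: float = 1.5
    long_pulse_threshold_ms: float = 100.0
    sustained_epsp: bool = False
    true_class: str = "mixed"

    def __post_init__(self) -> None:
        if self.epsp_amplitude_mV < 0 or self.ipsp_amplitude_mV < 0:
            raise ParameterError("kernel amplitudes must be >= 0")
        if self.epsp_tau_decay_ms <= self.epsp_tau_rise_ms:
            raise ParameterError("EPSP decay must exceed rise")
        if self.ipsp_tau_decay_ms <= self.ipsp_tau_rise_ms:
            raise ParameterError("IPSP decay must exceed rise")
        if self.true_class not in ("excitatory", "mixed", "inhibitory"):
            raise ParameterError(f"unknown true_class {self.true_class!r}")
        want_e = self.true_class in ("excitatory", "mixed")
        want_i = self.true_class in ("inhibitory", "mixed")
        if want_e != (self.epsp_amplitude_mV > 0) or want_i != (self.ipsp_amplitude_mV > 0):
            raise ParameterError(
                f"true_class {self.true_class!r} inconsistent with amplitudes "
                f"(epsp={self.epsp_amplitude_mV}, ipsp={self.ipsp_amplitude_mV})"
            )

    @classmethod
    def for_class(cls, true_class: str, epsp_amplitude_mV: float = 2.0,
                  ipsp_amplitude_mV: float = 1.5, **kwargs) -> "PSPKernelParams":
        """Kernel parameters realizing a class by zeroing the other amplitude."""
        e = epsp_amplitude_mV if true_class in ("excitatory", "mixed") else 0.0
        i = ipsp_amplitude_mV if true_class in ("inhibitory", "mixed") else 0.0
        return cls(epsp_amplitude_mV=e, ipsp_amplitude_mV=i,
                   true_class=true_class, **kwargs)


def psp_kernel(t_s: np.ndarray, tau_rise_ms: float, tau_decay_ms: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t < 0."""
    tr, td = tau_rise_ms / 1000.0, tau_decay_ms / 1000.0
    t = np.asarray(t_s, dtype=float)
    out = np.where(t >= 0, np.exp(-np.maximum(t, 0) / td) - np.exp(-np.maximum(t, 0) / tr), 0.0)
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return out / peak


def noise_free_psp(protocol: StimProtocol, kernels: PSPKernelParams,
                   t_s: np.ndarray) -> np.ndarray:
    """Deviation from rest (mV) of the noise-free PSP response at times t_s.

    Superposition of one EPSP kernel per pulse and one delayed IPSP kernel
    per pulse; for pulses longer than ``long_pulse_threshold_ms`` both
    amplitudes are scaled by ``long_pulse_scale`` (or, with
    ``sustained_epsp``, the EPSP drive is integrated over the pulse). This
    closed form is the analytic oracle for window metrics.
    """
    t = np.asarray(t_s, dtype=float)
    dev = np.zeros_like(t)
    long_pulse = protocol.pulse_duration_ms >= kernels.long_pulse_threshold_ms
    scale = kernels.long_pulse_scale if long_pulse else 1.0
    for onset in protocol.pulse_onsets_s():
        if kernels.epsp_amplitude_mV > 0:
            if long_pulse and kernels.sustained_epsp:
                dev += _sustained_epsp(t - onset, protocol.pulse_duration_ms, kernels)
            else:
                dev += scale * kernels.epsp_amplitude_mV * psp_kernel(
                    t - onset, kernels.epsp_tau_rise_ms, kernels.epsp_tau_decay_ms)
        if kernels.ipsp_amplitude_mV > 0:
            dev -= scale * kernels.ipsp_amplitude_mV * psp_kernel(
                t - onset - kernels.ipsp_lag_ms / 1000.0,
                kernels.ipsp_tau_rise_ms, kernels.ipsp_tau_decay_ms)
    return dev


def _sustained_epsp(t_rel_s: np.ndarray, pulse_ms: float, kernels: PSPKernelParams) -> np.ndarray:
    """EPSP drive integrated over the light pulse, normalized to unit peak."""
    dt = float(t_rel_s[1] - t_rel_s[0]) if t_rel_s.size > 1 else 2e-5
    kernel_t = np.arange(0.0, 5 * kernels.epsp_tau_decay_ms / 1000.0, dt)
    k = psp_kernel(kernel_t, kernels.epsp_tau_rise_ms, kernels.epsp_tau_decay_ms)
    box = np.ones(max(1, int(round(pulse_ms / 1000.0 / dt))))
    drive = fftconvolve(box, k)[:t_rel_s.size]
    drive = drive / drive.max()
    out = np.zeros_like(t_rel_s)
    pos = t_rel_s >= 0
    n = int(pos.sum())
    out[pos] = kernels.epsp_amplitude_mV * drive[:n]
    return out


def generate_psp_sweep(
    protocol: StimProtocol,
    kernels: PSPKernelParams = PSPKernelParams(),
    noise_sd_mV: float = 0.1,
    seed: int = 0,
    resting_vm: float = -78.0,
    sample_rate_hz: float = 50_000.0,
    duration_s: float | None = None,
    cell_id: str = "psp0",
    sweep_index: int = 0,
    pharmacology: frozenset[str] = frozenset(),
) -> tuple[Sweep, GroundTruth]:
    """Generate one PSP sweep under a light protocol, with ground truth."""
    if protocol.kind == "none":
        raise ParameterError("generate_psp_sweep requires a light protocol")
    if noise_sd_mV < 0:
        raise ParameterError("noise_sd_mV must be >= 0")
    if duration_s is None:
        duration_s = max(1.0, protocol.offset_s + 0.45)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    vm = resting_vm + noise_free_psp(protocol, kernels, t)
    if noise_sd_mV > 0:
        rng = np.random.default_rng([seed % 2**31, 303, sweep_index])
        vm = vm + rng.normal(0.0, noise_sd_mV, size=n)
    sweep = Sweep(
        cell_id=cell_id, sweep_index=sweep_index, sample_rate_hz=sample_rate_hz,
        vm=vm, step_amplitude_pA=0.0,
        step_onset_s=protocol.pulse_onset_s,
        step_offset_s=max(protocol.offset_s, protocol.pulse_onset_s + 1e-3),
        condition="light", protocol=protocol, pharmacology=pharmacology,
    )
    truth = GroundTruth(cell_id=cell_id, seed=seed,
                        params={"kernels": asdict(kernels)},
                        psp_class={protocol.key: kernels.true_class})
    return sweep, truth


def generate_psp_cell(
    classes_by_protocol: dict,
    noise_sd_mV: float = 0.1,
    n_sweeps: int = 3,
    seed: int = 0,
    cell_id: str = "psp0",
    subtype: str = "unknown",
    kernel_kwargs: dict | None = None,
    washon: bool = False,
) -> tuple[CellRecording, GroundTruth]:
    """Generate one PSP cell recorded under several light protocols.

    ``classes_by_protocol`` maps a :class:`StimProtocol` to the cell's true
    class under it. With ``washon``, 500 ms sweeps are generated twice —
    tagged ``cgp_pre`` with the IPSP present and ``cgp_post`` with the IPSP
    removed, emulating GABA_B receptor blockade.
    """
    kernel_kwargs = dict(kernel_kwargs or {})
    sweeps: list[Sweep] = []
    truth = GroundTruth(cell_id=cell_id, seed=seed, params={"kernel_kwargs": kernel_kwargs})
    idx = 0
    for protocol, true_class in classes_by_protocol.items():
        kern = PSPKernelParams.for_class(true_class, **kernel_kwargs)
        phases = [(frozenset(), kern)]
        if washon and protocol.pulse_duration_ms >= kern.long_pulse_threshold_ms:
            # GABA_B blockade removes the slow IPSP and leaves the EPSP;
            # a purely inhibitory cell keeps a small residual EPSP so the
            # post-blockade response stays a valid (excitatory) PSP
            post_epsp = kern.epsp_amplitude_mV if kern.epsp_amplitude_mV > 0 else 0.5
            post = PSPKernelParams.for_class(
                "excitatory", epsp_amplitude_mV=post_epsp,
                **{k: v for k, v in kernel_kwargs.items()
                   if k not in ("ipsp_amplitude_mV", "epsp_amplitude_mV")})
            phases = [(frozenset({"cgp_pre"}), kern), (frozenset({"cgp_post"}), post)]
        for tags, k in phases:
            for _ in range(n_sweeps):
                sweep, _ = generate_psp_sweep(
                    protocol, k, noise_sd_mV=noise_sd_mV,
                    seed=seed, cell_id=cell_id, sweep_index=idx, pharmacology=tags)
                sweeps.append(sweep)
                idx += 1
        truth.psp_class[protocol.key] = true_class
    cell = CellRecording(cell_id=cell_id, subtype=subtype,
                         access_resistance_MOhm=10.0, sweeps=sweeps)
    return cell, truth


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortConfig:
    """Configuration of a full synthetic cohort.

    ``psp_mixture`` maps protocol kind -> class fractions; fractions per
    protocol must sum to 1 and are realized exactly by deterministic
    largest-remainder allocation over the ordered cell list (never
    sampled), so printed-count checks are exact. Because allocation is by
    position, stacking the inhibitory fraction at the end of the 500 ms
    mixture while the train mixture ends in "mixed" reproduces the nested
    structure in which long-pulse-inhibited cells respond mixed to the
    train.
    """

    n_fi_cells: dict = field(default_factory=lambda: {"D1": 3, "D2": 2})
    fi: FICellParams = field(default_factory=FICellParams)
    # cells cycle through these rheobase offsets (pA) for between-cell
    # excitability heterogeneity, as in a real cohort
    fi_rheobase_cycle_pA: tuple = (-50.0, 0.0, 50.0)
    ap: APTemplateParams = field(default_factory=APTemplateParams)
    n_steps: int = 9
    step_increment_pA: float = 50.0
    n_psp_cells: int = 0
    psp_mixture: dict = field(default_factory=dict)
    psp_noise_sd_mV: float = 0.1
    n_psp_sweeps: int = 3
    n_washon_cells: int = 0
    psp_kernel_kwargs: dict = field(default_factory=dict)


def _allocate(mixture: dict, n: int) -> list[str]:
    """Largest-remainder allocation of class labels over n ordered cells."""
    classes = list(mixture)
    fracs = np.array([float(mixture[c]) for c in classes])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"mixture fractions sum to {fracs.sum():g}, not 1")
    ideal = fracs * n
    counts = np.floor(ideal).astype(int)
    order = np.argsort(-(ideal - counts))
    for i in order[: n - counts.sum()]:
        counts[i] += 1
    labels: list[str] = []
    for c, k in zip(classes, counts):
        labels.extend([c] * int(k))
    return labels


def generate_cohort(
    config: CohortConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[CellRecording], list[GroundTruth]]:
    """Generate a full cohort; optionally write bundle + ground-truth sidecar.

    Output is a pure function of (config, seed). Changing the seed changes
    noise realizations but never the deterministic class labels.
    """
    cells: list[CellRecording] = []
    truths: list[GroundTruth] = []
    idx = 0
    cycle = tuple(config.fi_rheobase_cycle_pA) or (0.0,)
    for subtype, n_sub in config.n_fi_cells.items():
        for _ in range(int(n_sub)):
            fi = dataclasses.replace(
                config.fi,
                rheobase_pA=config.fi.rheobase_pA + cycle[idx % len(cycle)])
            cell, truth = generate_fi_cell(
                fi, config.ap, n_steps=config.n_steps,
                step_increment_pA=config.step_increment_pA,
                seed=(seed * 1009 + idx) % 2**31,
                cell_id=f"fi{idx:03d}", subtype=subtype)
            cells.append(cell)
            truths.append(truth)
            idx += 1

    if config.n_psp_cells:
        protocols = {"single_pulse_10ms": PROTOCOL_10MS,
                     "pulse_train_20hz": PROTOCOL_20HZ,
                     "single_pulse_500ms": PROTOCOL_500MS}
        labels = {}
        for key, mixture in config.psp_mixture.items():
            labels[key] = _allocate(mixture, config.n_psp_cells)
        for j in range(config.n_psp_cells):
            classes = {}
            for key, protocol in protocols.items():
                if key in labels:
                    classes[protocol] = labels[key][j]
            if not classes:
                break
            cell, truth = generate_psp_cell(
                classes, noise_sd_mV=config.psp_noise_sd_mV,
                n_sweeps=config.n_psp_sweeps,
                seed=(seed * 2003 + j) % 2**31,
                cell_id=f"psp{j:03d}",
                subtype="D1" if j % 2 == 0 else "D2",
                kernel_kwargs=config.psp_kernel_kwargs,
                washon=j < config.n_washon_cells)
            cells.append(cell)
            truths.append(truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        write_sweep_bundle(cells, out_dir)
        sidecar = [t.to_dict() for t in truths]
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump({"seed": seed, "cells": sidecar}, fh, indent=1)
    return cells, truths


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    """Read the ground-truth sidecar written by :func:`generate_cohort`."""
    with open(Path(path) / "ground_truth.json") as fh:
        data = json.load(fh)
    return [GroundTruth.from_dict(d) for d in data["cells"]]
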