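# tsephys

Whole-cell current-clamp analysis of how auditory-thalamic (medial
geniculate body, MGB) input modulates medium spiny neurons (MSNs) in the
tail of striatum. The package is written for slice electrophysiologists
who record paired optogenetic protocols: it extracts spike-train features
with the first-spike / train-mean conventions, detects depolarization
block from the bimodal action-potential height histogram, builds paired
light / no-light input–output (f–I) curves, classifies optogenetically
evoked postsynaptic potentials (oPSPs), and runs the accompanying
nonparametric statistics. A synthetic-data generator produces cohorts
with exact ground truth, so every stage ships with parameter-recovery
tests.

## The analysis in brief

**Depolarization block.** MSNs driven with 500 ms depolarizing steps at
50 pA increments eventually fail to sustain full-height firing. Pooling
all AP heights of a cell gives a bimodal histogram — an upper mode for
full APs and a lower mode for attenuated ones. The block sweep is the
first sweep in which at least half the APs fall below the lower mode:

> block = min { sweep i : #(heights < lower mode) / n_i ≥ ½ }

Every current step is recorded twice, without and (5 s later) with a
500 ms light pulse driving MGB terminals, so all light effects are
paired within a sweep pair. Latency is compared at the first step that
spikes in both conditions; the low-depolarization inter-spike interval
one step above it; every high-depolarization measurement at the no-light
block sweep.

**oPSP classification.** Responses to a 10 ms pulse, a 20 Hz train of
5 ms pulses, and a 500 ms pulse are averaged per cell, and peak
depolarization / hyperpolarization relative to the pre-pulse baseline are
compared to θ = max(3·SD_baseline, 0.3 mV): excitatory (only
depolarization exceeds θ), inhibitory (only hyperpolarization), or mixed
(both). Slow GABA_B inhibition is quantified as the mean V_m change
200–300 ms after pulse onset, and the wash-on comparison (before/after
GABA_B blockade) pairs that metric per cell.

**Statistics.** Wilcoxon signed-rank for paired comparisons (exact null
up to n = 25, Bonferroni across a declared family), Mann-Whitney U for
D1-MSN vs D2-MSN contrasts, a two-way OLS ANOVA (light × step, Type II
sums of squares) for I/O curves, and a chi-squared test of independence
for response-class distributions across protocols.

## Worked example

```python
from tsephys import build_io_curve, detect_block_sweep, paired_deltas, wilcoxon_signed_rank
from tsephys.synth import FICellParams, generate_fi_cell

params = FICellParams(noise_sd_mV=0.2)
cells = [generate_fi_cell(params, seed=s, cell_id=f"cell{s}")[0] for s in range(8)]

nl = detect_block_sweep(cells[0], "no_light")
lt = detect_block_sweep(cells[0], "light")
print(nl.block_sweep_index, lt.block_sweep_index)      # 6 8

deltas, _ = paired_deltas(cells, "latency_ms", "low_depol")
print(wilcoxon_signed_rank([d.delta for d in deltas]).p_value)
```

Running `python examples/fi_curves_and_block.py` prints:

```
cell0: no-light block at step 6, light at step 8 (AP-height modes 35.2 / 77.2 mV)
...
 relative_index  mean_frequency_no_light_hz  mean_frequency_light_hz  n_cells
             -1                         8.0                     20.0        8
              0                         6.0                     14.0        8
latency_ms (low_depol): mean light-minus-no-light = -10.00 ms over n=8 cells, signed-rank p = 0.0132
```

Light delays depolarization block by two steps, keeps the mean firing
frequency higher at the highest completed current step (14 vs 6 Hz), and
shortens the first-spike latency — the "resilient spiking" signature.
The other scripts in `examples/` walk through oPSP classification with
cross-protocol transition tables and the GABA_B wash-on comparison, and
`examples/run_pipeline.sh` drives the same stages through the
`tsephys simulate / analyze / stats` command line.

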