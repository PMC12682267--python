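# Methods

## Scope and data model

The package analyzes episodic whole-cell current-clamp recordings from
striatal medium spiny neurons under two protocol families:

* **f–I ladders** — 500 ms depolarizing current steps at 50 pA
  increments, each step recorded as a pair: first without, then with a
  coincident 500 ms optogenetic light pulse driving thalamic (MGB) axon
  terminals. Pairing makes every light effect a within-sweep-pair
  comparison.
* **oPSP protocols** — postsynaptic potentials evoked by a 10 ms single
  pulse, a 20 Hz train of 5 ms pulses, or a 500 ms single pulse, with
  optional pharmacology phases (GABA_B blockade wash-on tagged
  `cgp_pre` / `cgp_post`; monosynaptic isolation tagged `ttx_4ap_zd`).

Units are fixed package-wide: mV for membrane potential, pA for current,
ms for reported durations, seconds for sample timestamps. Traces are
stored at native rate (nominally 50 kHz) and never resampled on ingest.

The interchange format is a plain-text sweep bundle: `cells.csv` and
`sweeps.csv` manifests plus one `time_s,vm_mV` CSV per sweep. Samples are
written with 9 significant digits (≥ 6 preserved through a round trip).
Vendor binary (ABF) ingestion is an adapter contract behind the optional
`pyabf` dependency so the core carries no binary-format logic.

### Quality control

Cells with access resistance strictly above 30 MΩ are discarded
(R_a = 30 MΩ exactly is kept — the criterion is "larger than"); cells
with no recorded R_a are discarded with their own reason rather than
silently kept. "Continuous spike train" is operationalized as: no
zero-AP sweep between the first and last spiking no-light sweeps of the
ladder. R_a is treated as supplied metadata; it is not re-estimated from
test pulses.

## Spike detection and train features

Peaks are found by prominence (default 10 mV) on the raw trace; each
peak's threshold is the first sample before it where the smoothed dV/dt
(5-point quadratic Savitzky–Golay derivative) crosses 20 mV/ms. Two
guards matter in practice: the upstroke must lie within 5 ms of the
peak (this also keeps boundary artifacts of the smoothed derivative out
of reach), and the threshold-to-peak height must itself exceed the
prominence criterion — otherwise noise bumps riding a subthreshold
plateau, whose prominence is inflated by the step itself, are accepted
as spikes. Events closer than 1 ms merge to the larger peak; detection
is restricted to the current-step window when one is defined. The
detector is translation-invariant by construction.

Per-AP geometry: height is threshold-to-peak; half-width is the full
width at half height with linear interpolation between samples (no
splines); rise time spans the 10–90 % height crossings of the rising
limb. Non-measurable features are carried as NaN, never fabricated.

Train conventions: "first spike" refers to the first AP; "train mean"
averages all APs excluding the first; the mean ISI always averages all
successive peak-time differences, hence equals
(t_last − t_first)/(n − 1). Frequency is n_APs over the step duration.
Latency runs from step onset to the first AP's threshold crossing
(onset semantics; `latency_reference="peak"` switches to the peak —
on the synthetic templates the two differ by exactly one template rise,
0.5 ms at defaults).

## Depolarization block

All AP heights of a cell in one condition are pooled (per-sweep pooling
is available behind `pool="sweep"`, but single sweeps rarely give a
usable histogram); a fixed-width histogram (2 mV bins from the observed
minimum) is smoothed with a 3-bin moving average and searched for two
local maxima at least 10 mV apart. The block sweep is the first sweep
whose fraction of APs strictly below the lower mode reaches 0.5
("at least half", boundary included). Unimodal cells yield an explicit
no-block outcome and are excluded from high-depolarization comparisons.

Two deliberate conventions:

* **Peak position = upper edge of the modal bin** (ties between adjacent
  bins resolve to the lower bin). The classification boundary "below the
  lower peak" must include the attenuated cluster that forms the peak;
  with a bin-center convention roughly half of a tight attenuated
  cluster would sit above its own mode and the rule could never fire.
  The reported position still lies within one bin width of the true
  mode.
* **Heights for block detection are measured on a 0.3 ms boxcar-smoothed
  copy of the trace.** Only the full/attenuated separation matters here,
  and smoothing tightens each height cluster about five-fold so
  single-sample noise extremes cannot leak APs across the lower-mode
  boundary. Feature exports elsewhere keep raw-trace geometry.

Attenuated APs still count as APs for frequency and ISI.

## Designated comparison sweeps and I/O curves

* latency: first step with ≥ 1 AP in both conditions;
* low-depolarization ISI: one step above the latency sweep (so trains
  hold multiple APs);
* high depolarization (all features): the **no-light** block sweep, used
  for both conditions so the pair never mixes sweeps.

Group I/O curves are built under two anchors: `first_spike_anchor`
re-indexes each cell's steps relative to its first step with recorded
spikes (in either condition — the source does not specify which; this
reads "first recorded spikes" literally), and `max_current_anchor`
relative to the highest completed paired step (cells stop at block).
"Normalized to" is read as re-indexing, not amplitude scaling: the
y-axis stays mean frequency. Aggregates with fewer than `min_cells`
(default 3) contributing cells are dropped from the curve but retained
in the export.

## oPSP quantification

Sweeps of one protocol are averaged (mean-of-sweeps, matching how such
responses are presented), low-pass filtered with a 2 ms boxcar — short
against the PSP kernels but enough that peak measurements read the
synaptic envelope rather than single-sample noise extremes at 50 kHz —
and measured against the mean of the 100 ms pre-pulse baseline. Within
the response window (pulse onset → pulse offset + 300 ms, long enough
for slow GABA_B hyperpolarization) the peak depolarization and peak
hyperpolarization are compared to

    θ = max(k · SD_baseline, floor),  k = 3, floor = 0.3 mV.

The class is excitatory / inhibitory / mixed / none according to which
peaks exceed θ. The source reports classes without a millivolt
criterion, so this rule is the package's own decision; it is stored in
every `ResponseCall`, and both the peak metrics and the window-mean
metric are always computed so alternative rules can be audited.
Percentages in breakdowns round to the nearest integer, halves away
from zero. The slow-inhibition magnitude is the mean V_m change
200–300 ms after pulse onset; the wash-on comparison pairs that metric
per cell across the `cgp_pre` / `cgp_post` phases (baseline-relative,
so holding-current offsets between phases do not bias it).

## Statistics

* **Wilcoxon signed-rank** (paired): two-sided; zero differences dropped
  before ranking (Wilcoxon's original rule — recorded in the result
  because the convention matters at these sample sizes); exact null
  distribution up to 25 informative, tie-free pairs, else a
  continuity-corrected normal approximation. All-zero inputs give a
  defined p = 1 with a flag.
* **Mann-Whitney U** (unpaired, D1 vs D2): exact when the smaller group
  has ≤ 8 tie-free observations, else tie-corrected normal
  approximation with continuity correction.
* **Bonferroni**: adjusted p = min(1, m·p) over a declared comparison
  family; m defaults to the family size and may not be smaller.
* **Two-way OLS ANOVA** on I/O curves: treatment coding, Type II sums of
  squares, F and p per main effect and interaction. Rows are treated as
  independent — the conventional curve comparison — although cells
  contribute several steps; a repeated-measures warning is emitted and a
  cell-clustered covariance variant is available. Saturated or
  rank-deficient designs raise instead of returning garbage.
* **Chi-squared independence** on response-class contingency tables,
  no continuity correction by default.

The implementations delegate to scipy.stats and statsmodels (the
standard tools for these tests); the test suite verifies the exact
branches against independent brute-force enumeration of all sign
assignments / group assignments, and the ANOVA against hand-computed
sums of squares and a 1000-replicate null calibration.

## Synthetic data generator

The generator's purpose is exact ground truth, not biophysics:

* **APs are stereotyped piecewise-linear templates** (default 80 mV
  threshold-to-peak, 1.5 ms half-width, 0.4 ms 10–90 % rise) inserted on
  a passive RC step response (τ = 15 ms) toward a subthreshold plateau.
  Linear segments survive sampling exactly, so feature extraction can be
  tested to within one sample period. Attenuated APs scale the height by
  0.45.
* **f–I cells**: spike count = round(gain·(I − rheobase)·step duration)
  above rheobase (defaults: rheobase 200 pA, gain 0.1 Hz/pA). From the
  configured block-onset step the count declines geometrically (×0.6 per
  step) and the attenuated fraction starts at 0.6, growing by 0.2 per
  step. The light condition blocks `light_extra_full_steps` (default 2)
  steps later and shifts latency and each ISI by configured signed
  deltas (defaults −10 ms, −5 ms). Latency/ISI jitter is drawn from a
  substream shared between the two sweeps of a pair, so with trace noise
  off the configured deltas reach the paired-delta stage exactly.
  Cohorts cycle cells through rheobase offsets (−50/0/+50 pA) for
  realistic between-cell heterogeneity — without it all cells would have
  identical deterministic spike counts and group-level variance would be
  degenerate.
* **oPSPs** are difference-of-exponential kernels normalized to unit
  peak: EPSP τ_rise 2 ms / τ_decay 20 ms; IPSP τ_rise 60 ms / τ_decay
  250 ms, subtracted with a 30 ms onset lag — inside the
  hundreds-of-milliseconds envelope of slow GABA_B inhibition. Long
  (≥ 100 ms) pulses scale both kernels by 1.5 (an integrated-drive EPSP
  option exists). Amplitude defaults (EPSP 2 mV, IPSP 1.5 mV) are
  placeholders chosen for clear class separation: the source reports no
  population amplitude statistics, and these numbers should not be read
  as empirical. Class mixtures in cohorts are realized exactly by
  largest-remainder allocation over the ordered cell list, never
  sampled, so count-based checks are deterministic.
* Trace noise is white Gaussian per sample (default 0.2 mV for f–I,
  0.1 mV for PSPs). Everything is a pure function of (config, seed).

**What passing tests do and do not show.** Recovery tests demonstrate
that the pipeline's conventions are implemented consistently and that
the detectors are robust to white noise at realistic amplitudes. Real
recordings add what the generator omits: correlated (1/f, line)
noise, baseline drift, spike-shape adaptation within trains, graded
rather than bimodal attenuation, stochastic synaptic amplitudes, and
trial-to-trial latency variability beyond the modeled jitter. Threshold
choices validated here (k·SD rule, smoothing windows) should be
re-examined on vendor data before quantitative claims.

## Numerical choices and degenerate inputs

* dV/dt needs ≥ 10 kHz sampling; lower rates raise a capability error.
* Histogram bins start at the observed minimum height; the final bin is
  closed so the maximum is counted.
* Half-fraction comparisons use ≥ (boundary included); height
  classification uses strict < ("fell below").
* Empty bundles, empty cohorts and all-zero difference vectors are valid
  inputs with defined outputs; empty histograms, saturated ANOVA designs
  and windows outside a sweep raise typed errors.
* CLI exit codes: 0 success (including empty results), 2 validation
  error, 3 data-integrity error.

## Known limitations

* No conductance-based dynamics: the generator cannot probe detector
  behaviour on realistic spike-shape adaptation or partial block.
* The OLS ANOVA reproduces the conventional independence assumption
  across (cell, step) rows; the clustered variant is a mitigation, not a
  mixed model.
* Block detection assumes the attenuated mode is at least the mode
  separation (10 mV) below the full mode; gradual attenuation without
  bimodality is reported as "no block", by design.
* Voltage-clamp analysis, liquid-junction correction and online R_a
  estimation are out of scope; pharmacology is metadata only.
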