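#!/bin/sh
# End-to-end pipeline through the CLI: simulate a cohort bundle with its
# ground-truth sidecar, analyze it (QC, spike features, block detection,
# I/O curves, PSP calls), then run the declared statistics families.
set -e
out=${1:-/tmp/tsephys_demo}

cat > "$out.yaml" <<'EOF'
seed: 11
simulation:
  n_fi_cells: {D1: 4, D2: 3}
  n_psp_cells: 12
  psp_mixture:
    single_pulse_10ms: {excitatory: 0.75, mixed: 0.25}
    pulse_train_20hz: {excitatory: 0.5, mixed: 0.5}
    single_pulse_500ms: {excitatory: 0.25, mixed: 0.5, inhibitory: 0.25}
  n_washon_cells: 3
EOF

tsephys simulate --config "$out.yaml" --out "$out/bundle"
tsephys analyze  --config "$out.yaml" --bundle "$out/bundle" --out "$out/analysis"
tsephys stats    --config "$out.yaml" --analysis "$out/analysis" --out "$out/stats"

echo "--- stats report ---"
cat "$out/stats/stats_report.txt"
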