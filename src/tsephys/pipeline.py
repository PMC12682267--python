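"""End-to-end orchestration: simulate, analyze, stats.

A run is configured by a YAML file whose sections expose every tunable
decision of the analysis modules (QC thresholds, detector and classifier
parameters, histogram settings, comparison families); a config hash, the
package version and the seed are embedded in every report so outputs are
traceable. The three stages are plain functions — the command-line
interface in :mod:`tsephys.cli` is a thin wrapper.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .block import detect_block_sweep
from .io import AnalysisError, ParameterError, qc_filter, read_sweep_bundle
from .iocurves import build_io_curve, io_curve_tidy, paired_deltas
from .psp import breakdown, calls_table, classify_response, transition_table, washon_effect
from .spikes import feature_table
from .stats import (
    StatResult,
    anova_io_curves,
    bonferroni,
    chi_squared_independence,
    mann_whitney_u,
    wilcoxon_signed_rank,
)
from .synth import APTemplateParams, CohortConfig, FICellParams, generate_cohort

logger = logging.getLogger("tsephys")

DEFAULT_DELTAS = (
    ("latency_ms", "low_depol"),
    ("latency_ms", "high_depol"),
    ("mean_isi_ms", "low_depol"),
    ("mean_isi_ms", "high_depol"),
    ("frequency_hz", "high_depol"),
)

FAMILY_KINDS = ("wilcoxon_paired", "mann_whitney_subtype", "anova_io", "chi_squared_protocols")


@dataclass
class RunConfig:
    """Validated run configuration (one key per tunable design decision)."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=lambda: {
        "ra_max_MOhm": 30.0, "require_continuous_trains": True})
    detector: dict = field(default_factory=lambda: {
        "dvdt_threshold_mV_per_ms": 20.0, "min_peak_prominence_mV": 10.0,
        "refractory_ms": 1.0})
    block: dict = field(default_factory=lambda: {
        "bin_width_mV": 2.0, "min_separation_mV": 10.0, "pool": "cell",
        "half_fraction": 0.5})
    classifier: dict = field(default_factory=lambda: {
        "k_sd": 3.0, "floor_mV": 0.3, "window_after_offset_ms": 300.0,
        "baseline_window_ms": 100.0})
    io_curve: dict = field(default_factory=lambda: {"min_cells": 3})
    deltas: list = field(default_factory=lambda: [list(d) for d in DEFAULT_DELTAS])
    families: list = field(default_factory=list)
    raw: dict = field(default_factory=dict, repr=False)

    def hash(self) -> str:
        payload = {k: getattr(self, k) for k in
                   ("seed", "simulation", "qc", "detector", "block",
                    "classifier", "io_curve", "deltas", "families")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def default_families() -> list[dict]:
    """The declared comparison families of a standard run."""
    fams: list[dict] = [{
        "name": f"light_{feature}_{state}",
        "kind": "wilcoxon_paired",
        "feature": feature,
        "state": state,
        "group": "light_vs_no_light",
    } for feature, state in DEFAULT_DELTAS]
    fams.append({"name": "anova_io_max_current", "kind": "anova_io",
                 "alignment": "max_current_anchor"})
    fams.append({"name": "chi2_short_vs_long", "kind": "chi_squared_protocols",
                 "protocols": ["single_pulse_10ms", "single_pulse_500ms"]})
    return fams


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; None gives defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(raw=raw)
    for key in ("seed",):
        if key in raw:
            cfg.seed = int(raw[key])
    for key in ("simulation", "qc", "detector", "block", "classifier", "io_curve"):
        if key in raw:
            getattr(cfg, key).update(raw[key] or {})
    if "deltas" in raw:
        cfg.deltas = [list(d) for d in raw["deltas"]]
    cfg.families = list(raw.get("families") or default_families())
    errors = validate_config(cfg)
    if errors:
        raise ParameterError("invalid config: " + "; ".join(errors))
    return cfg


def validate_config(cfg: RunConfig) -> list[str]:
    """Collect validation errors (empty list = valid)."""
    errors = []
    sim = cfg.simulation
    for key, mixture in (sim.get("psp_mixture") or {}).items():
        total = sum(float(v) for v in mixture.values())
        if abs(total - 1.0) > 1e-9:
            errors.append(f"simulation.psp_mixture.{key} sums to {total:g}, not 1")
    if cfg.qc.get("ra_max_MOhm", 30.0) <= 0:
        errors.append("qc.ra_max_MOhm must be > 0")
    if cfg.block.get("bin_width_mV", 2.0) <= 0:
        errors.append("block.bin_width_mV must be > 0")
    for fam in cfg.families:
        kind = fam.get("kind")
        if kind not in FAMILY_KINDS:
            errors.append(f"families.{fam.get('name', '?')}.kind {kind!r} not one of {FAMILY_KINDS}")
    for item in cfg.deltas:
        if len(item) != 2:
            errors.append(f"deltas entry {item!r} must be [feature, state]")
    return errors


def cohort_config_from(cfg: RunConfig) -> CohortConfig:
    sim = dict(cfg.simulation)
    cohort = CohortConfig()
    if "fi" in sim:
        cohort.fi = FICellParams(**{**dataclasses.asdict(cohort.fi), **sim.pop("fi")})
    if "ap" in sim:
        cohort.ap = APTemplateParams(**{**dataclasses.asdict(cohort.ap), **sim.pop("ap")})
    for key, value in sim.items():
        if not hasattr(cohort, key):
            raise ParameterError(f"unknown simulation key {key!r}")
        setattr(cohort, key, value)
    return cohort


# ---------------------------------------------------------------------------
# stages

def cmd_simulate(cfg: RunConfig, out_dir: str | Path, seed: int | None = None) -> Path:
    """Generate the configured cohort bundle + ground-truth sidecar."""
    seed = cfg.seed if seed is None else seed
    out_dir = Path(out_dir)
    cohort = cohort_config_from(cfg)
    generate_cohort(cohort, seed=seed, out_dir=out_dir)
    manifest = {"seed": seed, "config_hash": cfg.hash(), "version": _version}
    (out_dir / "simulation_manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("simulated cohort -> %s (seed=%d)", out_dir, seed)
    return out_dir


def _detect_kwargs(cfg: RunConfig) -> dict:
    return dict(cfg.detector)


def cmd_analyze(cfg: RunConfig, bundle_dir: str | Path, out_dir: str | Path) -> dict:
    """Run every analysis stage on a bundle and write the output tables.

    Writes feature tables, per-cell block results, both group I/O curves
    (full long table + tidy aggregates), paired deltas, PSP response calls
    with breakdowns and the transition table, the per-cell exclusion log,
    and a machine-parsable run report. An empty bundle yields a report with
    zero cells and success.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = read_sweep_bundle(bundle_dir)
    detect = _detect_kwargs(cfg)
    kept, discarded = qc_filter(
        cells, ra_max_MOhm=cfg.qc.get("ra_max_MOhm", 30.0),
        require_continuous_trains=cfg.qc.get("require_continuous_trains", True))
    exclusions = [{"cell_id": d.cell.cell_id, "stage": "qc", "reason": d.reason}
                  for d in discarded]

    fi_cells = [c for c in kept if c.fi_pairs()]
    psp_cells = [c for c in kept if any(s.step_amplitude_pA == 0 and s.condition == "light"
                                        for s in c.sweeps)]

    features = feature_table(fi_cells, **detect)
    features.to_csv(out_dir / "features.csv", index=False)

    block_rows = []
    blocks = {}
    for cell in fi_cells:
        for condition in ("no_light", "light"):
            try:
                res = detect_block_sweep(cell, condition, **cfg.block, **detect)
            except AnalysisError as exc:
                exclusions.append({"cell_id": cell.cell_id, "stage": "block",
                                   "reason": str(exc)})
                continue
            blocks[(cell.cell_id, condition)] = res
            block_rows.append({
                "cell_id": cell.cell_id, "condition": condition,
                "lower_peak_mV": res.lower_peak_mV, "upper_peak_mV": res.upper_peak_mV,
                "block_sweep_index": res.block_sweep_index,
            })
    pd.DataFrame(block_rows).to_csv(out_dir / "block_results.csv", index=False)

    delta_rows = []
    for feature, state in cfg.deltas:
        deltas, excluded = paired_deltas(fi_cells, feature, state, **detect)
        subtype = {c.cell_id: c.subtype for c in fi_cells}
        delta_rows += [{
            "cell_id": d.cell_id, "subtype": subtype.get(d.cell_id, "unknown"),
            "feature": d.feature, "state": d.state,
            "sweep_step_index": d.sweep_step_index,
            "value_no_light": d.value_no_light, "value_light": d.value_light,
            "delta": d.delta,
        } for d in deltas]
        exclusions += [{"cell_id": e.cell_id, "stage": f"delta_{feature}_{state}",
                        "reason": e.reason} for e in excluded]
    pd.DataFrame(delta_rows).to_csv(out_dir / "paired_deltas.csv", index=False)

    curves = {}
    for alignment in ("first_spike_anchor", "max_current_anchor"):
        curve = build_io_curve(fi_cells, alignment,
                               min_cells=cfg.io_curve.get("min_cells", 3), **detect)
        curves[alignment] = curve
        io_curve_tidy(curve).to_csv(out_dir / f"io_curve_{alignment}.csv", index=False)
        curve.long.to_csv(out_dir / f"io_long_{alignment}.csv", index=False)

    calls = []
    washon_rows = []
    for cell in psp_cells:
        kinds = {s.protocol.kind if s.protocol.kind != "pulse_train"
                 else "pulse_train" for s in cell.sweeps}
        seen = {}
        for s in cell.sweeps:
            if s.step_amplitude_pA == 0 and s.condition == "light" and not s.pharmacology:
                seen.setdefault((s.protocol.kind, s.protocol.pulse_duration_ms,
                                 s.protocol.train_rate_hz), []).append(s)
        for group in seen.values():
            try:
                call = classify_response(group, **cfg.classifier)
            except AnalysisError as exc:
                exclusions.append({"cell_id": cell.cell_id, "stage": "psp",
                                   "reason": str(exc)})
                continue
            call.subtype = cell.subtype
            calls.append(call)
        pre = [s for s in cell.sweeps if "cgp_pre" in s.pharmacology]
        post = [s for s in cell.sweeps if "cgp_post" in s.pharmacology]
        if pre and post:
            dv_pre, dv_post = washon_effect(pre, post)
            washon_rows.append({"cell_id": cell.cell_id, "subtype": cell.subtype,
                                "delta_vm_pre_mV": dv_pre, "delta_vm_post_mV": dv_post})
        del kinds

    if calls:
        calls_table(calls).to_csv(out_dir / "response_calls.csv", index=False)
        breakdown_frames = []
        for kind in sorted({c.protocol_kind for c in calls}):
            sub = [c for c in calls if c.protocol_kind == kind]
            for by_subtype in (False, True):
                bd = breakdown(sub, by_subtype=by_subtype)
                bd.insert(0, "protocol", kind)
                breakdown_frames.append(bd)
        pd.concat(breakdown_frames).to_csv(out_dir / "breakdowns.csv", index=False)
        tt = transition_table(calls)
        tt.to_edge_list().to_csv(out_dir / "transitions.csv", index=False)
    else:
        pd.DataFrame().to_csv(out_dir / "response_calls.csv", index=False)
    pd.DataFrame(washon_rows).to_csv(out_dir / "washon.csv", index=False)
    pd.DataFrame(exclusions).to_csv(out_dir / "exclusions.csv", index=False)

    report = {
        "run": {"version": _version, "config_hash": cfg.hash(), "seed": cfg.seed,
                "n_cells_read": len(cells), "n_cells_kept": len(kept),
                "n_fi_cells": len(fi_cells), "n_psp_cells": len(psp_cells),
                "n_excluded": len({e['cell_id'] for e in exclusions})},
        "block": {f"{r['cell_id']}_{r['condition']}": r["block_sweep_index"]
                  for r in block_rows},
    }
    _write_report(report, out_dir / "run_report.txt")
    logger.info("analysis complete: %d cells kept of %d", len(kept), len(cells))
    return {"cells": cells, "kept": kept, "features": features, "blocks": blocks,
            "curves": curves, "calls": calls, "exclusions": exclusions}


def cmd_stats(cfg: RunConfig, analysis_dir: str | Path, out_dir: str | Path) -> list[StatResult]:
    """Run the declared comparison families on analysis outputs."""
    analysis_dir, out_dir = Path(analysis_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    deltas = _read_csv(analysis_dir / "paired_deltas.csv")
    calls = _read_csv(analysis_dir / "response_calls.csv")

    results: list[StatResult] = []
    groups: dict[str, list[StatResult]] = {}
    for fam in cfg.families:
        kind = fam.get("kind")
        if kind not in FAMILY_KINDS:
            raise ParameterError(f"undeclared family kind {kind!r}")
        name = fam.get("name", kind)
        res: StatResult | None = None
        try:
            res = _run_family(kind, fam, deltas, calls, analysis_dir)
        except ParameterError as exc:
            logger.warning("family %s skipped: %s", name, exc)
            continue
        if res is not None:
            res.notes["family"] = name
            results.append(res)
            groups.setdefault(fam.get("group", name), []).append(res)

    for members in groups.values():
        if len(members) > 1:
            bonferroni(members)

    report = {"run": {"version": _version, "config_hash": cfg.hash(), "seed": cfg.seed}}
    for res in results:
        report[res.notes["family"]] = {
            "test": res.test_name, "statistic": res.statistic,
            "p_value": res.p_value, "n": res.n, "df": res.df,
            "correction": res.correction, "adjusted_p": res.adjusted_p,
        }
    _write_report(report, out_dir / "stats_report.txt")
    rows = [{"family": r.notes["family"], "test": r.test_name, "statistic": r.statistic,
             "p_value": r.p_value, "adjusted_p": r.adjusted_p, "correction": r.correction,
             "n": str(r.n), "df": r.df} for r in results]
    pd.DataFrame(rows).to_csv(out_dir / "stats_results.csv", index=False)
    return results


def _run_family(kind, fam, deltas, calls, analysis_dir) -> StatResult | None:
    """Compute one declared comparison; None when the data carry no such
    comparison (raises ParameterError when the test itself cannot run)."""
    if kind == "wilcoxon_paired":
        if deltas.empty:
            return None
        sub = deltas[(deltas["feature"] == fam["feature"])
                     & (deltas["state"] == fam["state"])]
        if sub.empty:
            return None
        return wilcoxon_signed_rank(sub["value_light"], sub["value_no_light"])
    if kind == "mann_whitney_subtype":
        if deltas.empty:
            return None
        sub = deltas[(deltas["feature"] == fam["feature"])
                     & (deltas["state"] == fam["state"])]
        d1 = sub[sub["subtype"] == "D1"]["delta"]
        d2 = sub[sub["subtype"] == "D2"]["delta"]
        if len(d1) == 0 or len(d2) == 0:
            return None
        return mann_whitney_u(d1, d2)
    if kind == "anova_io":
        alignment = fam.get("alignment", "max_current_anchor")
        long = _read_csv(analysis_dir / f"io_long_{alignment}.csv")
        if long.empty:
            return None
        melted = long.melt(
            id_vars=["cell_id", "relative_index"],
            value_vars=["frequency_no_light_hz", "frequency_light_hz"],
            var_name="condition", value_name="frequency_hz")
        melted["condition"] = melted["condition"].str.replace(
            "frequency_", "").str.replace("_hz", "")
        return anova_io_curves(
            melted, cluster_robust=fam.get("cluster_robust", False))["light"]
    if kind == "chi_squared_protocols":
        if calls.empty:
            return None
        classes = sorted(calls["response_class"].unique())
        table = []
        for p in fam["protocols"]:
            sub = calls[calls["protocol_kind"] == p]
            if sub.empty:
                return None
            table.append([int((sub["response_class"] == c).sum()) for c in classes])
        arr = np.array(table)
        arr = arr[:, arr.sum(axis=0) > 0]
        if arr.shape[1] < 2:
            return None
        return chi_squared_independence(arr)
    return None



def _read_csv(path: Path) -> pd.DataFrame:
    if not path.is_file():
        return pd.DataFrame()
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def _write_report(sections: dict, path: Path) -> None:
    """Key-value report: one [section] per result, machine-parsable."""
    lines = []
    for section, payload in sections.items():
        lines.append(f"[{section}]")
        for key, value in payload.items():
            lines.append(f"{key} = {value}")
        lines.append("")
    path.write_text("\n".join(lines))
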