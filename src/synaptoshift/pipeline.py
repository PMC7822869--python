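"""End-to-end orchestration: detection/DE per fraction, ratio shift,
optional qPCR validation and gene-set enrichment, with a machine-readable
run report.

A run is driven by a YAML configuration with these blocks::

    simulation: {...}            # SimulationConfig fields; OR
    inputs: {expression: path, samples: path}
    thresholds: {detection_min_mean_fpkm: 0.5, fc_threshold: 1.3,
                 alpha: 0.05, log_pseudocount: 1.0, ratio_pseudocount: 0.0}
    qpcr: {ct: path}             # optional
    enrichment: {gmt: path, query: shift}   # optional; query one of
                                 # shift, total_up, total_down,
                                 # synaptic_up, synaptic_down
    validate_table: {fixture: null, tolerance: 1e-4}  # validate-only mode
    output_dir: path

Stage order: total fraction -> synaptic fraction -> ratio shift ->
validation -> enrichment. Identical config and seed give identical
outputs and an identical report body (timestamps aside).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .detection import AnalysisConfig, DetectionSummary, classify_and_summarize, de_test, detect_genes
from .enrichment import fisher_enrichment
from .errors import ConfigurationError
from .qpcr import cross_platform_correlation, delta_delta_ct, read_ct_table
from .ratios import (
    EnrichmentClassSummary,
    classify_enrichment,
    shift_test,
    subject_ratios,
    top_bottom,
    validate_ratio_table,
)
from .simulate import SimulationConfig, simulate_study, write_fixtures

log = logging.getLogger(__name__)

FRACTIONS = ("total", "synaptic")


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    detection: dict[str, DetectionSummary] = field(default_factory=dict)
    ratio_summary: dict[str, EnrichmentClassSummary] = field(default_factory=dict)
    n_ratio_genes: int = 0
    n_shift_genes: int = 0
    qpcr_correlation: dict[str, dict] = field(default_factory=dict)
    table_validation: dict | None = None
    outputs: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(config_path) -> dict:
    config_path = Path(config_path)
    if not config_path.exists():
        raise FileNotFoundError(f"configuration file not found: {config_path}")
    with open(config_path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def analysis_config(config: dict) -> AnalysisConfig:
    cfg = AnalysisConfig(**(config.get("thresholds") or {}))
    cfg.validate()
    return cfg


def validate_table(fixture=None, tolerance: float = 1e-4):
    """Validate a ratio table (the packaged reference by default)."""
    table = io.read_ratio_table(fixture) if fixture else io.load_reference_ratio_table()
    return validate_ratio_table(table, tolerance=tolerance), table


def _acquire(config: dict, outdir: Path):
    """Load or simulate the study; returns (matrix, samples, seed)."""
    if "simulation" in config:
        sim = SimulationConfig(**(config["simulation"] or {}))
        study = simulate_study(sim)
        write_fixtures(study, outdir / "simulated")
        return study.expression, study.samples, sim.seed
    inputs = config.get("inputs")
    if not inputs:
        raise ConfigurationError("config needs either a 'simulation' or an 'inputs' block")
    for key in ("expression", "samples"):
        path = inputs.get(key)
        if not path:
            raise ConfigurationError(f"inputs.{key} is required")
        if not Path(path).exists():
            raise FileNotFoundError(f"inputs.{key}: file not found: {path}")
    matrix = io.read_expression(inputs["expression"])
    samples = io.read_sample_sheet(inputs["samples"])
    return matrix, samples, None


def _fraction_matrix(matrix: pd.DataFrame, samples: pd.DataFrame, fraction: str) -> pd.DataFrame:
    ids = samples.loc[samples["fraction"] == fraction, "sample_id"]
    cols = [s for s in matrix.columns if s in set(ids)]
    if not cols:
        raise ConfigurationError(f"no samples of fraction {fraction!r} found in the matrix")
    return matrix[cols]


def run_pipeline(config_path=None, config: dict | None = None, output_dir=None) -> RunReport:
    """Execute the full analysis; returns the run report (also written to disk)."""
    if config is None:
        config = load_config(config_path)
    outdir = Path(output_dir or config.get("output_dir") or "synaptoshift_run")
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.provenance = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    if "validate_table" in config and "simulation" not in config and "inputs" not in config:
        block = config["validate_table"] or {}
        vr, table = validate_table(block.get("fixture"), float(block.get("tolerance", 1e-4)))
        report.table_validation = {
            "n_rows": vr.n_rows,
            "n_pass": vr.n_pass,
            "n_fail": vr.n_fail,
            "max_discrepancy": vr.max_discrepancy,
        }
        make_report(report, outdir)
        return report

    matrix, samples, seed = _acquire(config, outdir)
    report.provenance["seed"] = seed
    cfg = analysis_config(config)

    detected: dict[str, list[str]] = {}
    de_results: dict[str, pd.DataFrame] = {}
    for fraction in FRACTIONS:
        sub = _fraction_matrix(matrix, samples, fraction)
        keep = detect_genes(sub, samples, cfg)
        detected[fraction] = [g for g in sub.index if g in keep]
        results = de_test(sub.loc[detected[fraction]], samples, cfg)
        de_results[fraction] = results
        path = outdir / f"de_{fraction}.tsv"
        results.to_csv(path, sep="\t")
        report.outputs[f"de_{fraction}"] = str(path)
        report.detection[fraction] = classify_and_summarize(results, cfg)

    universe = [g for g in matrix.index if g in set(detected["total"]) & set(detected["synaptic"])]
    log.info("ratio universe: %d genes (intersection of detected sets)", len(universe))
    report.n_ratio_genes = len(universe)

    sr = subject_ratios(matrix.loc[universe], samples, pseudocount=cfg.ratio_pseudocount)
    shift = shift_test(sr, alpha=cfg.alpha)
    report.n_shift_genes = int(shift["significant"].sum())
    shift_path = outdir / "ratio_shift.tsv"
    shift.to_csv(shift_path, sep="\t")
    report.outputs["ratio_shift"] = str(shift_path)
    ratios_path = outdir / "subject_ratios.tsv"
    sr.ratios.to_csv(ratios_path, sep="\t")
    report.outputs["subject_ratios"] = str(ratios_path)
    for group in ("control", "MDD"):
        report.ratio_summary[group] = classify_enrichment(shift, group)
    n_rank = min(20, len(shift))
    top, bottom = top_bottom(shift, n_rank, group="control")
    pd.DataFrame({"top": top, "bottom": bottom}).to_csv(
        outdir / "top_bottom_ratios.tsv", sep="\t", index=False
    )
    report.outputs["top_bottom_ratios"] = str(outdir / "top_bottom_ratios.tsv")

    if config.get("qpcr"):
        ct_path = config["qpcr"].get("ct")
        if not ct_path or not Path(ct_path).exists():
            raise FileNotFoundError(f"qpcr.ct: file not found: {ct_path}")
        qres = delta_delta_ct(read_ct_table(ct_path), samples)
        qpath = outdir / "qpcr.tsv"
        qres.to_csv(qpath, sep="\t")
        report.outputs["qpcr"] = str(qpath)
        for fraction in FRACTIONS:
            fc = de_results[fraction]["fold_change"].dropna()
            shared = qres.index.intersection(fc.index)
            if len(shared) >= 3:
                r, p, n = cross_platform_correlation(fc[shared], qres.loc[shared, "fold_change"])
                report.qpcr_correlation[fraction] = {"r": r, "p": p, "n": n}
            else:
                log.info("qPCR correlation for %s skipped: %d shared genes", fraction, len(shared))

    if config.get("enrichment"):
        block = config["enrichment"]
        sets = io.read_gene_sets(block["gmt"])
        query_key = block.get("query", "shift")
        if query_key == "shift":
            query = set(shift.index[shift["significant"]])
            bg = set(shift.index)
        else:
            fraction, direction = query_key.rsplit("_", 1)
            results = de_results[fraction]
            query = set(results.index[results["class"] == direction])
            bg = set(results.index)
        if query:
            enr = fisher_enrichment(query, sets, bg, alpha=cfg.alpha)
            epath = outdir / "enrichment.tsv"
            enr.to_csv(epath, sep="\t", index=False)
            report.outputs["enrichment"] = str(epath)
        else:
            log.info("enrichment skipped: empty query %r", query_key)

    make_report(report, outdir)
    return report


def make_report(report: RunReport, outdir) -> tuple[Path, Path]:
    """Write report.json (machine-readable) and report.txt (human summary)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    txt_path = outdir / "report.txt"
    txt_path.write_text(format_report(report))
    report.outputs.setdefault("report_json", str(json_path))
    return json_path, txt_path


def format_report(report: RunReport) -> str:
    """Human-readable run summary; every number also appears in a stage TSV."""
    lines = ["synaptoshift run summary", "========================"]
    for fraction, s in report.detection.items():
        lines.append(
            f"{fraction} fraction: {s.n_detected} genes detected; "
            f"{s.n_sig_up} ({s.pct_sig_up}%) up and {s.n_sig_down} ({s.pct_sig_down}%) down "
            f"at p < alpha; {s.n_up_fc} up / {s.n_down_fc} down beyond the fold threshold"
        )
    if report.n_ratio_genes:
        lines.append(f"ratio universe: {report.n_ratio_genes} genes; "
                     f"{report.n_shift_genes} with a significant ratio shift")
    for group, s in report.ratio_summary.items():
        lines.append(
            f"{group} ratios: median {s.median_ratio:.6g}; >1: {s.n_above_1}, <1: {s.n_below_1}; "
            f"enriched >1.5x: {s.pct_enriched_1p5}% (>2x: {s.pct_enriched_2}%); "
            f"depleted >1.5x: {s.pct_depleted_1p5}% (>2x: {s.pct_depleted_2}%)"
        )
    for fraction, c in report.qpcr_correlation.items():
        lines.append(
            f"qPCR vs RNA-seq fold changes ({fraction}): r = {c['r']:.3f}, "
            f"p = {c['p']:.3g}, n = {c['n']}"
        )
    if report.table_validation:
        tv = report.table_validation
        lines.append(
            f"ratio-table validation: {tv['n_rows']} rows, {tv['n_fail']} failures "
            f"(max discrepancy {tv['max_discrepancy']:.3g})"
        )
    return "\n".join(lines) + "\n"
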