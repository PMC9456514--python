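"""End-to-end orchestration: run the analysis stages from one config and
write a reproducible report bundle (JSON report, manifest, small HTML view).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .conservation import clade_profiles, map_columns_to_reference
from .divergence import classify_columns, find_strong_change_runs
from .ibaq import DigestConfig, compute_ibaq, estimate_stoichiometry
from .io import read_alignment
from .registry import load_registry
from .synthetic import ComplexSpec, simulate_intensities
from .xlms import build_graph, bundled_dipeptide_table, filter_records, parse_crosslink_table

log = logging.getLogger("pepmap")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Stage toggles select which analyses execute; unset input paths fall back
    to the bundled fixtures where one exists (the printed dipeptide table)
    or to synthetic data (intensities).
    """

    outdir: str = "pepmap_run"
    seed: int = 0
    run_conserve: bool = False
    run_xlms: bool = False
    run_ibaq: bool = False
    alignment_path: str | None = None
    alignment_format: str = "fasta"
    clade_map: dict[str, str] = field(default_factory=dict)
    clades: list[str] = field(default_factory=list)
    reference_taxon: str | None = None
    crosslink_path: str | None = None  # None -> bundled printed table
    window_size: int = 11
    min_run: int = 3
    min_score: float = 30.0
    max_distance: float = 30.0
    exposure_threshold: float = 0.25
    len_range: tuple[int, int] = (6, 30)
    alpha_id: str = "alpha"
    restrict_to_members: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.alignment_path, self.crosslink_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 1")
        if not (self.min_score >= 0 and self.max_distance > 0):
            raise ValueError("min_score must be >= 0 and max_distance > 0")
        if not 0 <= self.exposure_threshold <= 1:
            raise ValueError("exposure_threshold must be in [0, 1]")
        lo, hi = self.len_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid len_range")


def _stage_conserve(cfg: RunConfig) -> dict:
    aln = read_alignment(cfg.alignment_path, cfg.alignment_format,
                         cfg.clade_map or None)
    profiles = clade_profiles(aln, cfg.clades, cfg.window_size)
    out: dict = {"n_taxa": aln.n_taxa, "n_columns": aln.n_columns, "profiles": {}}
    for prof in profiles:
        out["profiles"][prof.subset_label] = {
            "rolling_identity": [round(v, 4) for v in prof.rolling_identity],
            "rolling_homology": [round(v, 4) for v in prof.rolling_homology],
        }
    if cfg.reference_taxon and len(cfg.clades) >= 2:
        ref_map = map_columns_to_reference(aln, cfg.reference_taxon)
        clade_a = aln.taxa_in_clade(cfg.clades[0])
        clade_b = aln.taxa_in_clade(cfg.clades[1])
        classes = classify_columns(aln, clade_a, clade_b)
        runs = find_strong_change_runs(classes, ref_map, cfg.min_run)
        out["class_counts"] = {
            cls: sum(1 for c in classes if c.cls == cls)
            for cls in ("homologous", "nonhomologous", "gap")
        }
        out["strong_change_runs"] = [
            {"start": r.start_residue, "end": r.end_residue, "length": r.length}
            for r in runs
        ]
    return out


def _stage_xlms(cfg: RunConfig) -> dict:
    path = Path(cfg.crosslink_path) if cfg.crosslink_path else bundled_dipeptide_table()
    records = parse_crosslink_table(path)
    log.info("xlms: parsed %d records from %s", len(records), path)
    kept, dropped = filter_records(records, cfg.min_score)
    log.info("xlms: %d records pass filters, %d dropped", len(kept), len(dropped))
    registry = load_registry()
    graph = build_graph(kept, registry, restrict_to_members=cfg.restrict_to_members)
    links = [
        {
            "protein_1": r.protein_1, "protein_2": r.protein_2,
            "score": r.score, "absolute_1": r.absolute_1,
            "absolute_2": r.absolute_2, "flags": r.flags,
        }
        for r in kept
    ]
    return {
        "n_parsed": len(records),
        "n_kept": len(kept),
        "n_dropped": len(dropped),
        "clusters": graph.clusters,
        "n_clusters": graph.n_clusters,
        "links": links,
    }


def _stage_ibaq(cfg: RunConfig) -> dict:
    # demo stage: quantify a synthetic PEP-like complex at the canonical
    # 2:1:1:1 core copy numbers under multiplicative noise
    spec = ComplexSpec(
        subunits=(("alpha", 330, 2), ("beta", 1070, 1),
                  ("beta_prime", 680, 1), ("beta_double_prime", 1380, 1)),
        noise_sigma=0.3, n_replicates=3, seed=cfg.seed,
    )
    table, sequences = simulate_intensities(spec)
    lo, hi = cfg.len_range
    config = DigestConfig(min_length=lo, max_length=hi)
    result = compute_ibaq(table, sequences, config, alpha_id=cfg.alpha_id)
    est = estimate_stoichiometry(result, [(cfg.alpha_id, "beta")], seed=cfg.seed)[0]
    return {
        "ibaqr": {pid: round(float(v), 4) for pid, v in result.ibaqr.items()},
        "alpha_beta_ratio": round(est.ratio, 4),
        "alpha_beta_ci": [est.ci_low, est.ci_high],
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns the report dict; writes report.json, manifest.json and
    report.html under ``cfg.outdir``.  A stage failure is recorded and halts
    only that stage's dependents.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "errors": {}}
    stages = []
    if cfg.run_conserve:
        stages.append(("conserve", _stage_conserve))
    if cfg.run_xlms:
        stages.append(("xlms", _stage_xlms))
    if cfg.run_ibaq:
        stages.append(("ibaq", _stage_ibaq))
    for name, fn in stages:
        try:
            report["stages"][name] = fn(cfg)
            log.info("stage %s finished", name)
        except Exception as exc:  # halt this stage, report, continue others
            log.error("stage %s failed: %s", name, exc)
            report["errors"][name] = str(exc)
    manifest = {"pepmap_version": __version__, "config": asdict(cfg)}
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_html(report, outdir / "report.html")
    return report


def _write_html(report: dict, path: Path) -> None:
    parts = ["<html><head><title>pepmap report</title></head><body>",
             "<h1>pepmap report</h1>"]
    for name, payload in report["stages"].items():
        parts.append(f"<h2>{name}</h2><pre>{json.dumps(payload, indent=2)}</pre>")
    for name, err in report["errors"].items():
        parts.append(f"<h2>{name} (failed)</h2><pre>{err}</pre>")
    parts.append("</body></html>")
    path.write_text("\n".join(parts))


def ibaq_report_frame(report: dict) -> pd.DataFrame:
    """Tabular view of the ibaq stage of a report."""
    stage = report["stages"]["ibaq"]
    return pd.DataFrame({"ibaqr": pd.Series(stage["ibaqr"])})
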