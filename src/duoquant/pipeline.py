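"""End-to-end orchestration: simulate/load -> filter -> quantify -> test ->
consolidate -> enrich, with a run manifest.

The manifest records every effective parameter, per-stage row/protein counts
(the analysis funnel) and accumulated warnings, so each output file is
derivable from manifest + inputs with no hidden state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .consolidate import ConsolidationResult, consolidate_lists
from .diffexp import apply_detection_filter, diffexp_table
from .enrichment import enrich_table
from .io import (
    SampleDesign,
    read_design,
    read_evidence,
    read_fasta,
    read_gmt,
    read_mapping,
    write_results,
)
from .psm_filter import FilterConfig, decoy_fdr_threshold, filter_engine_a
from .quantify import build_digest_index, build_quant_matrix
from .simulate import SimulationConfig, recovery_metrics, simulate_evidence, simulate_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either ``simulation`` is set (hermetic run on synthetic data) or the
    four input paths are.  ``gmt_path`` switches enrichment on.
    """

    simulation: SimulationConfig | None = None
    evidence_a_path: str | None = None
    evidence_b_path: str | None = None
    design_path: str | None = None
    fasta_path: str | None = None
    gmt_path: str | None = None
    mapping_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.05
    detect_fraction: float = 0.6
    min_fold: float = 1.5
    min_overlap: int = 3
    seed: int = 0
    out_dir: str | None = None

    def effective_parameters(self) -> dict:
        out = {
            "alpha": self.alpha,
            "detect_fraction": self.detect_fraction,
            "min_fold": self.min_fold,
            "min_overlap": self.min_overlap,
            "seed": self.seed,
            "max_ppm": self.filter.max_ppm,
            "xcorr_thresholds": list(self.filter.xcorr_thresholds),
            "fdr_max": self.filter.fdr_max,
            "version": __version__,
        }
        if self.simulation is not None:
            out["simulation"] = dataclasses.asdict(self.simulation)
        return out


@dataclass
class RunResult:
    manifest: dict
    quant: dict  # engine -> QuantMatrix
    diffexp: dict  # engine -> DataFrame
    consolidation: ConsolidationResult
    enrichment: pd.DataFrame | None = None
    truth: object | None = None
    metrics: dict | None = None


_FUNNEL_STAGES = [
    "evidence_rows_in",
    "evidence_rows_filtered",
    "proteins_quantified",
    "proteins_detected_60pct",
    "proteins_significant",
]


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_all(cfg: RunConfig) -> RunResult:
    """Execute every stage in order; any failure aborts naming the stage."""
    manifest: dict = {
        "parameters": cfg.effective_parameters(),
        "counts": {"A": {}, "B": {}},
        "warnings": [],
        "inputs": {},
    }
    counts = manifest["counts"]

    # ---- stage: inputs ----
    truth = None
    try:
        if cfg.simulation is not None:
            sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
            truth = simulate_truth(sim)
            ev_a, ev_b, design, fasta = simulate_evidence(truth, sim)
            manifest["inputs"]["source"] = "simulated"
        else:
            for name, p in (
                ("evidence_a_path", cfg.evidence_a_path),
                ("evidence_b_path", cfg.evidence_b_path),
                ("design_path", cfg.design_path),
                ("fasta_path", cfg.fasta_path),
            ):
                if p is None:
                    raise ValueError(f"{name} required when no simulation is configured")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: no such file {p}")
                manifest["inputs"][name] = {"path": str(p), "sha256_16": _checksum(p)}
            ev_a, err_a = read_evidence(cfg.evidence_a_path, "A")
            ev_b, err_b = read_evidence(cfg.evidence_b_path, "B")
            manifest["warnings"] += err_a + err_b
            design = read_design(cfg.design_path)
            fasta = read_fasta(cfg.fasta_path)
        if cfg.gmt_path is not None and not Path(cfg.gmt_path).exists():
            raise FileNotFoundError(f"gmt_path: no such file {cfg.gmt_path}")
    except Exception as exc:
        raise StageError(f"stage 'inputs' failed: {exc}") from exc
    counts["A"]["evidence_rows_in"] = len(ev_a)
    counts["B"]["evidence_rows_in"] = len(ev_b)
    manifest["design"] = {"n_control": design.n_control, "n_case": design.n_case}

    # ---- stage: psm_filter ----
    try:
        kept_a, removed_a = filter_engine_a(ev_a, cfg.filter)
        cutoff, kept_b = decoy_fdr_threshold(ev_b, cfg.filter)
    except Exception as exc:
        raise StageError(f"stage 'psm_filter' failed: {exc}") from exc
    counts["A"]["evidence_rows_filtered"] = len(kept_a)
    counts["B"]["evidence_rows_filtered"] = len(kept_b)
    manifest["filter"] = {"removed_A": removed_a, "fdr_score_cutoff_B": cutoff}

    # ---- stage: quantify ----
    try:
        digest = build_digest_index(fasta)
        quant = {
            "A": build_quant_matrix(kept_a, design),
            "B": build_quant_matrix(kept_b, design, digest_index=digest),
        }
    except Exception as exc:
        raise StageError(f"stage 'quantify' failed: {exc}") from exc
    for e in "AB":
        counts[e]["proteins_quantified"] = len(quant[e].proteins)
        manifest["warnings"] += [f"engine {e}: {w}" for w in quant[e].warnings]

    # ---- stage: diffexp ----
    try:
        de = {e: diffexp_table(quant[e], design, alpha=cfg.alpha, fraction=cfg.detect_fraction) for e in "AB"}
    except Exception as exc:
        raise StageError(f"stage 'diffexp' failed: {exc}") from exc
    for e in "AB":
        counts[e]["proteins_detected_60pct"] = len(de[e])
        counts[e]["proteins_significant"] = int(de[e]["significant"].sum()) if len(de[e]) else 0

    # ---- stage: consolidate ----
    try:
        cons = consolidate_lists(de["A"], de["B"], min_fold=cfg.min_fold)
    except Exception as exc:
        raise StageError(f"stage 'consolidate' failed: {exc}") from exc
    manifest["tiers"] = {
        "tier1": len(cons.tier1),
        "tier2": len(cons.tier2),
        "conflicts": len(cons.conflicts),
        "single_engine": len(cons.single_engine),
    }
    if cons.conflicts:
        manifest["warnings"].append(f"{len(cons.conflicts)} both-significant direction-conflict protein(s)")

    # ---- stage: enrich (optional) ----
    enrich = None
    if cfg.gmt_path is not None:
        try:
            gene_sets = read_gmt(cfg.gmt_path)
            mapping = read_mapping(cfg.mapping_path) if cfg.mapping_path else None
            universe = set(de["A"]["protein"]) | set(de["B"]["protein"])
            directions = {
                row["protein"]: row["direction"]
                for _, row in cons.table.iterrows()
                if row["protein"] in cons.tier2
            }
            enrich = enrich_table(
                directions, gene_sets, universe, alpha=cfg.alpha, min_overlap=cfg.min_overlap, mapping=mapping
            )
        except Exception as exc:
            raise StageError(f"stage 'enrich' failed: {exc}") from exc
        manifest["enrichment"] = {
            "sets_tested": len(enrich),
            "sets_significant": int(enrich["significant"].sum()) if len(enrich) else 0,
        }

    # ---- stage: recovery (simulation only) ----
    metrics = None
    if truth is not None:
        metrics = recovery_metrics(truth, cons)
        manifest["recovery"] = metrics

    result = RunResult(
        manifest=manifest, quant=quant, diffexp=de, consolidation=cons, enrichment=enrich, truth=truth, metrics=metrics
    )
    if cfg.out_dir is not None:
        _write_outputs(result, cfg)
    return result


def _write_outputs(result: RunResult, cfg: RunConfig) -> None:
    cons = result.consolidation
    tables = {
        "diffexp_A": result.diffexp["A"],
        "diffexp_B": result.diffexp["B"],
        "consolidation": cons.table,
        "tier1": pd.DataFrame({"protein": sorted(cons.tier1)}),
        "tier2": pd.DataFrame({"protein": sorted(cons.tier2)}),
        "conflicts": pd.DataFrame({"protein": sorted(cons.conflicts)}),
        "single_engine": pd.DataFrame({"protein": sorted(cons.single_engine)}),
        "funnel": funnel_report(result.manifest),
    }
    if result.enrichment is not None:
        tables["enrichment"] = result.enrichment
    meta = {"seed": cfg.seed, "parameters": cfg.effective_parameters()}
    write_results(tables, cfg.out_dir, metadata=meta)
    import json

    Path(cfg.out_dir, "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))


def funnel_report(manifest: dict) -> pd.DataFrame:
    """Stage-by-stage count table (the workflow funnel) from a manifest."""
    if "counts" not in manifest or "tiers" not in manifest:
        raise ValueError("incomplete manifest: missing counts/tiers")
    rows = []
    for stage in _FUNNEL_STAGES:
        row = {"stage": stage}
        for e in "AB":
            if stage not in manifest["counts"][e]:
                raise ValueError(f"incomplete manifest: missing {stage!r} for engine {e}")
            row[f"engine_{e}"] = manifest["counts"][e][stage]
        rows.append(row)
    for tier in ("tier1", "tier2"):
        rows.append({"stage": tier, "engine_A": manifest["tiers"][tier], "engine_B": manifest["tiers"][tier]})
    return pd.DataFrame(rows, columns=["stage", "engine_A", "engine_B"])
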