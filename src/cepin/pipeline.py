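"""End-to-end comparative analysis: inputs to exclusive modules and reports.

Stages: score every static-PIN edge per condition -> build both CePINs
-> network overlap -> topology / differential-expression / hub analyses
-> gene- and dyad-level enrichment per condition -> candidate and
exclusive category sets (both directions) -> ontology-level filter ->
per-module classification, ROC/AUC, dynamics Z-scores and edge-dynamics
classes.  Every stage's output is serialized, and a run manifest records
the configuration hash and seed, so identical configurations produce
byte-identical result bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx
import pandas as pd

from . import __version__
from .correlation import (
    CePIN,
    build_cepin,
    network_overlap,
    score_network_edges,
    scores_to_records,
)
from .enrichment import dyad_enrichment, enrichment_table, gene_enrichment
from .evaluation import (
    classify_by_clustering,
    classify_edge_dynamics,
    module_dynamics_zscores,
)
from .io import (
    largest_connected_component,
    read_annotations,
    read_edge_list,
    read_expression_table,
    read_ontology_obo,
    read_sample_design,
    propagate_annotations,
    write_network,
)
from .model import AnnotationMap, ExpressionMatrix, OntologyDAG, SampleDesign
from .modules import discover_exclusive_modules
from .topology import (
    call_hubs,
    call_sdegs,
    compare_topology_by_group,
    compute_topology,
    sdeg_degree_association,
    topology_table,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds and paths of one comparative run."""

    expression: Optional[str] = None
    design: Optional[str] = None
    pin: Optional[str] = None
    ontology: Optional[str] = None
    annotations: Optional[str] = None
    annotation_format: str = "tsv"
    positive_condition: Optional[str] = None
    outdir: str = "cepin_results"
    alpha_edge: float = 0.05
    alpha_sdeg: float = 0.05
    alpha_enrich: float = 0.05
    min_go_level: int = 5
    hub_percentile: float = 1.0
    edge_dyn_threshold: float = 0.5
    n_null: int = 1000
    seed: int = 0
    linkage: str = "average"
    collapse: str = "mean"

    def __post_init__(self):
        for name in ("alpha_edge", "alpha_sdeg", "alpha_enrich"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_go_level < 1:
            raise ValueError("min_go_level must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cepins: Dict[str, CePIN]
    overlap: Dict[str, object]
    sdegs: Dict[str, object]
    hubs: Dict[str, object]
    enrichment: Dict[str, Dict[str, list]]
    modules: Dict[str, list]
    evaluations: Dict[str, dict]
    counters: Dict[str, object]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def load_inputs(cfg: PipelineConfig):
    expr = read_expression_table(cfg.expression, collapse=cfg.collapse)
    design = read_sample_design(cfg.design, positive_condition=cfg.positive_condition)
    pin = read_edge_list(cfg.pin)
    dag = read_ontology_obo(cfg.ontology)
    ann = propagate_annotations(
        read_annotations(cfg.annotations, dag, format=cfg.annotation_format), dag)
    return expr, design, pin, dag, ann


def run_full_comparison(
    cfg: PipelineConfig,
    inputs: Optional[Tuple[ExpressionMatrix, SampleDesign, nx.Graph,
                           OntologyDAG, AnnotationMap]] = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the whole comparative analysis.

    ``inputs`` may be passed directly (e.g. a synthetic dataset) instead
    of reading the configured paths.  With ``write`` the stage outputs
    and a run manifest land under ``cfg.outdir``.
    """
    outdir = Path(cfg.outdir)
    stage = "load_inputs"
    try:
        if inputs is None:
            inputs = load_inputs(cfg)
        expr, design, pin, dag, ann = inputs
        pos, neg = design.conditions
        background = set(expr.gene_ids) & set(pin.nodes()) & set(ann.genes)
        counters: Dict[str, object] = {
            "background_genes": len(background),
            "static_nodes": pin.number_of_nodes(),
            "static_edges": pin.number_of_edges(),
        }

        stage = "score_edges"
        scores, unscored = {}, {}
        for cond in (pos, neg):
            scores[cond], unscored[cond] = score_network_edges(pin, expr, design, cond)
        counters["edges_scored"] = {c: len(scores[c]) for c in scores}
        counters["edges_unscored"] = {c: len(unscored[c]) for c in unscored}

        stage = "build_cepin"
        cepins = {c: build_cepin(scores[c], cfg.alpha_edge, c) for c in (pos, neg)}
        counters["ceppis"] = {c: len(cepins[c].ceppis) for c in cepins}

        stage = "network_overlap"
        overlap = network_overlap(cepins[pos], cepins[neg], pin,
                                  scores[pos], scores[neg])

        stage = "sdeg"
        sdeg_table = call_sdegs(expr, design, cfg.alpha_sdeg)
        counters["sdegs"] = len(sdeg_table.sdegs)

        stage = "topology"
        topo_reports: Dict[str, object] = {}
        hubs: Dict[str, object] = {}
        for cond in (pos, neg):
            if cepins[cond].graph.number_of_nodes() == 0:
                topo_reports[cond] = None
                hubs[cond] = (set(), math.nan)
                continue
            topo = compute_topology(cepins[cond].graph)
            hub_set, hub_thr = call_hubs(cepins[cond], cfg.hub_percentile)
            hubs[cond] = (hub_set, hub_thr)
            sdeg_nodes = sdeg_table.sdegs & set(topo)
            non_sdeg_nodes = set(topo) - sdeg_nodes
            comparison = None
            if sdeg_nodes and non_sdeg_nodes:
                comparison = compare_topology_by_group(
                    topo, {"sdeg": sdeg_nodes, "non_sdeg": non_sdeg_nodes})
            association = None
            degrees = {cepins[cond].graph.degree(v) for v in cepins[cond].graph}
            if len(degrees) >= 2:
                association = sdeg_degree_association(cepins[cond], sdeg_table.sdegs)
            topo_reports[cond] = {"topology": topo, "comparison": comparison,
                                  "association": association}

        stage = "enrichment"
        enrichment: Dict[str, Dict[str, list]] = {}
        for cond in (pos, neg):
            g_enr = gene_enrichment(cepins[cond], ann, background)
            d_enr = dyad_enrichment(cepins[cond], ann, pin,
                                    [r.term for r in g_enr], background)
            enrichment[cond] = {"gene": g_enr, "dyad": d_enr}
            counters.setdefault("terms_tested", {})[cond] = len(g_enr)

        stage = "modules"
        modules = discover_exclusive_modules(
            cepins[pos], cepins[neg],
            enrichment[pos]["gene"], enrichment[pos]["dyad"],
            enrichment[neg]["gene"], enrichment[neg]["dyad"],
            ann, dag, alpha=cfg.alpha_enrich, min_level=cfg.min_go_level)
        counters["modules"] = {k: len(v) for k, v in modules.items()}

        stage = "evaluate"
        evaluations: Dict[str, dict] = {}
        for direction, mods in modules.items():
            for module in mods:
                key = f"{direction}:{module.term}"
                try:
                    report = classify_by_clustering(module, expr, design, cfg.linkage)
                except ValueError as exc:
                    report = None
                dynamics = None
                if len(module.member_genes) >= 2:
                    dynamics = module_dynamics_zscores(
                        module, expr, design, background_genes=background,
                        n_null=cfg.n_null, seed=cfg.seed)
                edge_classes = classify_edge_dynamics(
                    scores[pos], scores[neg], cfg.edge_dyn_threshold,
                    edges=module.member_ceppis)
                evaluations[key] = {"module": module, "classification": report,
                                    "dynamics": dynamics, "edge_classes": edge_classes}

        result = PipelineResult(
            config=cfg, cepins=cepins, overlap=overlap,
            sdegs={"table": sdeg_table},
            hubs=hubs, enrichment=enrichment, modules=modules,
            evaluations=evaluations, counters=counters)

        if write:
            stage = "write_outputs"
            _write_bundle(result, scores, topo_reports, outdir, dag)
        return result
    except StageError:
        raise
    except Exception as exc:
        if write:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc


def _round_floats(obj, digits=10):
    if isinstance(obj, float):
        return round(obj, digits) if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, set):
        return sorted(obj)
    return obj


def _dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_bundle(result: PipelineResult, scores, topo_reports, outdir: Path,
                  dag: OntologyDAG) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    pos, neg = list(result.cepins)
    for cond in (pos, neg):
        frame = scores_to_records(scores[cond], cfg.alpha_edge)
        frame.to_csv(outdir / f"edge_scores_{cond}.tsv", sep="\t", index=False,
                     float_format="%.8g")
        write_network(result.cepins[cond].graph, outdir / f"cepin_{cond}.tsv", "tsv")
        report = topo_reports.get(cond)
        if report:
            hubs, _thr = result.hubs[cond]
            tbl = topology_table(report["topology"],
                                 sdegs=result.sdegs["table"].sdegs, hubs=hubs)
            tbl.to_csv(outdir / f"topology_{cond}.tsv", sep="\t", index=False,
                       float_format="%.8g")
            if report["association"] is not None:
                _dump_json(report["association"], outdir / f"sdeg_association_{cond}.json")
            if report["comparison"] is not None:
                report["comparison"].to_csv(
                    outdir / f"topology_by_sdeg_{cond}.tsv", sep="\t", index=False,
                    float_format="%.8g")
        for family in ("gene", "dyad"):
            enrichment_table(result.enrichment[cond][family], dag).to_csv(
                outdir / f"enrichment_{family}_{cond}.tsv", sep="\t", index=False,
                float_format="%.8g")
    _dump_json(result.overlap, outdir / "overlap.json")
    result.sdegs["table"].table.to_csv(outdir / "sdeg.tsv", sep="\t",
                                       float_format="%.8g")
    module_summary = {}
    for direction, mods in result.modules.items():
        module_summary[direction] = [{
            "term": m.term, "name": m.name, "level": m.level,
            "condition": m.condition, "n_nodes": m.n_nodes, "n_edges": m.n_edges,
            "gene_p_adj": m.gene_p_adj, "dyad_p_adj": m.dyad_p_adj,
            "member_genes": sorted(m.member_genes),
            "member_ceppis": sorted(list(e) for e in m.member_ceppis),
        } for m in mods]
    _dump_json(module_summary, outdir / "modules.json")
    eval_summary = {}
    for key, ev in result.evaluations.items():
        entry: Dict[str, object] = {}
        rep = ev["classification"]
        if rep is not None:
            entry["classification"] = {
                "tp": rep.tp, "fp": rep.fp, "tn": rep.tn, "fn": rep.fn,
                "sensitivity": rep.sensitivity, "specificity": rep.specificity,
                "accuracy": rep.accuracy, "auc": rep.auc,
                "orientation": rep.orientation, "roc_points": rep.roc_points,
            }
        dyn = ev["dynamics"]
        if dyn is not None:
            entry["dynamics"] = {
                "mean_pcc": {c: dataclasses.asdict(s) for c, s in dyn.mean_pcc.items()},
                "expression_shift": dataclasses.asdict(dyn.expression_shift),
                "pcc_change": dataclasses.asdict(dyn.pcc_change),
                "seed": dyn.seed,
            }
        entry["edge_classes"] = [
            {"edge": list(c.edge), "pcc_a": c.pcc_a, "pcc_b": c.pcc_b,
             "label": c.label} for c in ev["edge_classes"]]
        eval_summary[key] = entry
    _dump_json(eval_summary, outdir / "evaluations.json")
    _dump_json(result.counters, outdir / "counters.json")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
    }
    _dump_json(manifest, outdir / "run_manifest.json")
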