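"""Comparative discovery of condition-exclusive functional modules.

A functional category is a *candidate* in a condition when it is
significant in that condition's CePIN at both levels — genes and
functional dyads — after FDR adjustment.  Categories candidate in one
condition but not the other are *exclusive* to it; after a minimum
ontology-level filter (specific enough categories only), each surviving
category is materialized as a module: its annotated genes in the CePIN
plus the CePPIs connecting them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .correlation import CePIN
from .enrichment import DyadEnrichment, GeneEnrichment
from .model import AnnotationMap, Edge, OntologyDAG


@dataclass
class FunctionalModule:
    """An exclusive category realized as a subnetwork of one CePIN."""

    term: str
    name: str
    level: int
    condition: str
    member_genes: Set[str]
    member_ceppis: Set[Edge]
    gene_p_adj: float
    dyad_p_adj: float
    no_edges: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.member_genes)

    @property
    def n_edges(self) -> int:
        return len(self.member_ceppis)


def candidate_functions(
    gene_enr: Iterable[GeneEnrichment],
    dyad_enr: Iterable[DyadEnrichment],
    alpha: float = 0.05,
) -> Set[str]:
    """Categories significant in BOTH families (adjusted p <= alpha)."""
    gene_sig = {r.term for r in gene_enr if r.p_adj <= alpha}
    dyad_sig = {r.term for r in dyad_enr if r.p_adj <= alpha}
    return gene_sig & dyad_sig


def exclusive_functions(cand_a: Set[str], cand_b: Set[str]) -> Set[str]:
    """Categories candidate in condition A but not in B (set difference)."""
    return set(cand_a) - set(cand_b)


def filter_by_level(terms: Set[str], dag: OntologyDAG, min_level: int = 5) -> Set[str]:
    """Keep categories at DAG level >= min_level (inclusive bound)."""
    out = set()
    for t in terms:
        level = dag.level(t)  # KeyError -> informative error for unknown terms
        if level >= min_level:
            out.add(t)
    return out


def assemble_module(
    term: str,
    cepin: CePIN,
    ann: AnnotationMap,
    dag: OntologyDAG,
    gene_record: Optional[GeneEnrichment] = None,
    dyad_record: Optional[DyadEnrichment] = None,
    use_propagated: bool = True,
) -> FunctionalModule:
    """Materialize a category as a module of one condition's CePIN.

    Member genes are the category-annotated genes among the CePIN's
    nodes; member CePPIs are CePIN edges with both endpoints annotated.
    An empty membership is an error; a membership without any internal
    CePPI is flagged, not an error.
    """
    term_genes = ann.genes_with(term, propagated=use_propagated)
    member_genes = term_genes & cepin.nodes
    if not member_genes:
        raise ValueError(f"category {term!r} has no member gene in the CePIN")
    member_ceppis = {e for e in cepin.ceppis
                     if e[0] in member_genes and e[1] in member_genes}
    return FunctionalModule(
        term=term,
        name=dag.name(term),
        level=dag.levels.get(term, 0),
        condition=cepin.condition,
        member_genes=member_genes,
        member_ceppis=member_ceppis,
        gene_p_adj=gene_record.p_adj if gene_record else math.nan,
        dyad_p_adj=dyad_record.p_adj if dyad_record else math.nan,
        no_edges=not member_ceppis,
    )


def discover_exclusive_modules(
    cepin_a: CePIN,
    cepin_b: CePIN,
    gene_enr_a: List[GeneEnrichment],
    dyad_enr_a: List[DyadEnrichment],
    gene_enr_b: List[GeneEnrichment],
    dyad_enr_b: List[DyadEnrichment],
    ann: AnnotationMap,
    dag: OntologyDAG,
    alpha: float = 0.05,
    min_level: int = 5,
    use_propagated: bool = True,
) -> Dict[str, List[FunctionalModule]]:
    """Both directions of exclusive-module discovery in one call.

    Returns {"a_exclusive": [...], "b_exclusive": [...]} with modules
    sorted by category id.  The level filter is applied after the
    exclusive set difference.
    """
    cand_a = candidate_functions(gene_enr_a, dyad_enr_a, alpha)
    cand_b = candidate_functions(gene_enr_b, dyad_enr_b, alpha)
    out: Dict[str, List[FunctionalModule]] = {}
    for key, cand, other, cepin, g_enr, d_enr in (
        ("a_exclusive", cand_a, cand_b, cepin_a, gene_enr_a, dyad_enr_a),
        ("b_exclusive", cand_b, cand_a, cepin_b, gene_enr_b, dyad_enr_b),
    ):
        kept = filter_by_level(exclusive_functions(cand, other), dag, min_level)
        g_map = {r.term: r for r in g_enr}
        d_map = {r.term: r for r in d_enr}
        out[key] = [
            assemble_module(t, cepin, ann, dag, g_map.get(t), d_map.get(t),
                            use_propagated=use_propagated)
            for t in sorted(kept)
        ]
    return out
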