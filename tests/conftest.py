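import numpy as np
import networkx as nx
import pandas as pd
import pytest

from cepin import (
    AnnotationMap,
    ExpressionMatrix,
    OntologyDAG,
    SampleDesign,
    SyntheticSpec,
    build_cepin,
    compute_levels,
    dyad_enrichment,
    gene_enrichment,
    generate_dataset,
    score_network_edges,
)
from cepin.modules import candidate_functions, exclusive_functions, filter_by_level


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic dataset (seed 42)."""
    return generate_dataset(SyntheticSpec(seed=42))


@pytest.fixture
def toy_dag():
    """Chain r -> a -> t plus a sibling branch r -> b."""
    terms = {t: {"name": t, "namespace": "biological_process"}
             for t in ("r", "a", "b", "t")}
    parents = {"r": set(), "a": {"r"}, "b": {"r"}, "t": {"a"}}
    return OntologyDAG(terms=terms, parents=parents,
                       levels=compute_levels(parents, set(terms)))


@pytest.fixture
def small_design():
    assignment = {f"a{i}": "A" for i in range(1, 5)}
    assignment.update({f"b{i}": "B" for i in range(1, 5)})
    return SampleDesign(assignment, positive_condition="A")


@pytest.fixture
def small_expr(small_design):
    rng = np.random.default_rng(7)
    samples = sorted(small_design.assignment)
    genes = [f"G{i}" for i in range(1, 7)]
    return ExpressionMatrix(pd.DataFrame(
        rng.standard_normal((len(genes), len(samples))),
        index=genes, columns=samples))


def discover_modules(dataset, alpha_edge=0.05, alpha_enrich=0.05, min_level=5):
    """Scoring -> CePINs -> both enrichment families -> exclusive terms.

    Shared helper for recovery / null-control tests; returns the
    per-direction exclusive term sets and the CePINs.
    """
    expr, design, pin, dag, ann = (dataset.expr, dataset.design, dataset.pin,
                                   dataset.dag, dataset.ann)
    pos, neg = design.conditions
    background = set(expr.gene_ids) & set(pin.nodes()) & set(ann.genes)
    cand = {}
    cepins = {}
    gene_records = {}
    for cond in (pos, neg):
        scores, _ = score_network_edges(pin, expr, design, cond)
        cep = build_cepin(scores, alpha_edge, cond)
        cepins[cond] = cep
        g_enr = gene_enrichment(cep, ann, background)
        d_enr = dyad_enrichment(cep, ann, pin, [r.term for r in g_enr], background)
        cand[cond] = candidate_functions(g_enr, d_enr, alpha_enrich)
        gene_records[cond] = g_enr
    excl = {
        "a_exclusive": filter_by_level(
            exclusive_functions(cand[pos], cand[neg]), dag, min_level),
        "b_exclusive": filter_by_level(
            exclusive_functions(cand[neg], cand[pos]), dag, min_level),
    }
    return excl, cepins, gene_records
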