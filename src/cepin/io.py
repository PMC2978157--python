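"""Readers and writers for expression tables, designs, networks, ontologies
and annotations.

All tabular inputs are plain tab-separated text.  Networks round-trip
through TSV, SIF and GraphML; ``read_edge_list(write_network(g, "tsv"))``
reproduces the node and edge sets exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .model import (
    AnnotationMap,
    ExpressionMatrix,
    OntologyDAG,
    SampleDesign,
    canonical_edge,
    compute_levels,
)

log = logging.getLogger(__name__)

_COLLAPSE_RULES = {"mean", "max", "first"}


def read_expression_table(
    path, collapse: str = "mean", sep: str = "\t"
) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (header = sample ids, first column = gene ids).

    Rows sharing a gene id are collapsed with ``collapse`` in {mean, max,
    first}.  Rows with no finite value are dropped with a warning.
    Non-numeric cells and duplicate sample ids are hard errors.
    """
    if collapse not in _COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {collapse!r}; use one of {_COLLAPSE_RULES}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen = [s for i, s in enumerate(header) if s in header[:i]]
    if seen:
        raise ValueError(f"{path}: duplicate sample ids {sorted(set(seen))}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        numeric[col] = converted
    all_missing = ~np.isfinite(numeric.to_numpy()).any(axis=1)
    if all_missing.any():
        dropped = numeric.index[all_missing].tolist()
        log.warning("%s: dropping %d all-missing rows (e.g. %s)", path, len(dropped), dropped[:3])
        numeric = numeric.loc[~all_missing]
    if numeric.shape[0] == 0:
        raise ValueError(f"{path}: no data rows after dropping all-missing rows")
    if numeric.index.duplicated().any():
        grouped = numeric.groupby(level=0, sort=False)
        if collapse == "mean":
            numeric = grouped.mean()
        elif collapse == "max":
            numeric = grouped.max()
        else:
            numeric = grouped.first()
    return ExpressionMatrix(numeric)


def read_sample_design(path, positive_condition: Optional[str] = None) -> SampleDesign:
    """Read a two-column TSV (sample_id, condition) into a SampleDesign.

    With ``positive_condition`` unset, the lexicographically smaller label
    is taken as positive (deterministic but usually worth overriding).
    """
    assignment: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            sample, cond = (f.strip() for f in fields)
            if sample in assignment and assignment[sample] != cond:
                raise ValueError(
                    f"{path}:{lineno}: sample {sample!r} listed with conflicting "
                    f"labels {assignment[sample]!r} and {cond!r}"
                )
            assignment[sample] = cond
    labels = sorted(set(assignment.values()))
    if len(labels) > 2:
        raise ValueError(f"{path}: expected two condition labels, found {labels}")
    if positive_condition is None:
        positive_condition = labels[0]
    return SampleDesign(assignment, positive_condition)


def read_edge_list(path) -> nx.Graph:
    """Read a two-column TSV of identifier pairs into a simple graph.

    Self-loops and duplicate (including reversed) edges are dropped; the
    removal counts are logged.
    """
    g = nx.Graph()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f for f in line.split("\t")]
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            u, v = (f.strip() for f in fields)
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
    if n_self or n_dup:
        log.info("%s: dropped %d self-loops and %d duplicate edges", path, n_self, n_dup)
    return g


def largest_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component.

    Ties in component size are broken deterministically by the
    lexicographically smallest member node.  The empty graph maps to
    itself.
    """
    if net.number_of_nodes() == 0:
        return net.copy()
    components = [set(c) for c in nx.connected_components(net)]
    best = max(components, key=lambda c: (len(c), _neg_key(min(c))))
    return net.subgraph(best).copy()


class _neg_key:
    """Order-reversing wrapper so max() prefers the smallest node label."""

    __slots__ = ("value",)

    def __init__(self, value):
        self.value = value

    def __lt__(self, other):
        return self.value > other.value

    def __eq__(self, other):
        return self.value == other.value


def read_ontology_obo(path, namespace: Optional[str] = "biological_process",
                      level_rule: str = "shortest") -> OntologyDAG:
    """Parse an OBO file into an :class:`OntologyDAG`.

    Restricted to one namespace (default biological_process; pass None to
    keep all).  Obsolete terms are dropped by the OBO parser.  Parent
    edges follow is_a and part_of.  Levels are computed with the given
    rule; a cycle raises with a witness.
    """
    graph = obonet.read_obo(path)
    terms: Dict[str, Dict[str, str]] = {}
    parents: Dict[str, Set[str]] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        if namespace is not None and ns != namespace:
            continue
        terms[node] = {"name": data.get("name", node), "namespace": ns}
    for node in terms:
        ps: Set[str] = set()
        data = graph.nodes[node]
        for parent in data.get("is_a", []):
            if parent in terms:
                ps.add(parent)
        for rel in data.get("relationship", []):
            fields = rel.split()
            if len(fields) == 2 and fields[0] == "part_of" and fields[1] in terms:
                ps.add(fields[1])
        parents[node] = ps
    levels = compute_levels(parents, set(terms), rule=level_rule)
    return OntologyDAG(terms=terms, parents=parents, levels=levels)


def read_annotations(
    path,
    dag: OntologyDAG,
    format: str = "tsv",
    evidence_exclude: Iterable[str] = (),
) -> AnnotationMap:
    """Read gene-to-term annotations from a two-column TSV or a GAF 2.x file.

    NOT-qualified GAF annotations are excluded; ``evidence_exclude`` lists
    evidence codes to drop (empty by default).  Annotations to terms absent
    from the DAG are dropped with a logged count; malformed GAF lines are
    skipped with a logged count.
    """
    direct: Dict[str, Set[str]] = {}
    n_unknown = 0
    n_malformed = 0
    evidence_exclude = set(evidence_exclude)
    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
                gene, term = (f.strip() for f in fields)
                if term not in dag.terms:
                    n_unknown += 1
                    continue
                direct.setdefault(gene, set()).add(term)
    elif format == "gaf":
        from Bio.UniProt import GOA

        with open(path) as fh:
            try:
                for rec in GOA.gafiterator(fh):
                    qualifiers = rec.get("Qualifier", [])
                    if any(q == "NOT" or q.startswith("NOT|") for q in qualifiers):
                        continue
                    if evidence_exclude and rec.get("Evidence") in evidence_exclude:
                        continue
                    gene = rec.get("DB_Object_Symbol") or rec.get("DB_Object_ID")
                    term = rec.get("GO_ID")
                    if not gene or not term:
                        n_malformed += 1
                        continue
                    if term not in dag.terms:
                        n_unknown += 1
                        continue
                    direct.setdefault(gene, set()).add(term)
            except (KeyError, IndexError, ValueError):
                n_malformed += 1
    else:
        raise ValueError(f"unknown annotation format {format!r}; use 'tsv' or 'gaf'")
    if n_unknown:
        log.warning("%s: dropped %d annotations to terms absent from the DAG", path, n_unknown)
    if n_malformed:
        log.warning("%s: skipped %d malformed annotation lines", path, n_malformed)
    return AnnotationMap(direct=direct)


def propagate_annotations(ann: AnnotationMap, dag: OntologyDAG) -> AnnotationMap:
    """Close direct annotations under the ancestor relation (true-path rule).

    Idempotent: propagating an already-propagated map changes nothing.
    """
    propagated: Dict[str, Set[str]] = {}
    ancestor_cache: Dict[str, Set[str]] = {}
    for gene, ts in ann.direct.items():
        closed: Set[str] = set(ts)
        for t in ts:
            if t not in ancestor_cache:
                ancestor_cache[t] = dag.ancestors(t)
            closed |= ancestor_cache[t]
        propagated[gene] = closed
    return AnnotationMap(direct={g: set(ts) for g, ts in ann.direct.items()},
                         propagated=propagated)


def apply_identifier_mapping(net_or_expr, mapping_path) -> object:
    """Relabel identifiers with a two-column (old, new) TSV mapping.

    The hook for probe-to-gene or protein-to-gene conversion.  Works on a
    graph (nodes relabelled; merged nodes keep the union of edges) or an
    ExpressionMatrix (rows relabelled then mean-collapsed).
    """
    mapping: Dict[str, str] = {}
    with open(mapping_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{mapping_path}:{lineno}: expected 2 fields")
            mapping[fields[0].strip()] = fields[1].strip()
    if isinstance(net_or_expr, nx.Graph):
        g = nx.Graph()
        for u, v in net_or_expr.edges():
            nu, nv = mapping.get(u, u), mapping.get(v, v)
            if nu != nv:
                g.add_edge(nu, nv)
        g.add_nodes_from(mapping.get(n, n) for n in net_or_expr.nodes())
        return g
    if isinstance(net_or_expr, ExpressionMatrix):
        df = net_or_expr.data.rename(index=mapping)
        if df.index.duplicated().any():
            df = df.groupby(level=0, sort=False).mean()
        return ExpressionMatrix(df)
    raise TypeError(f"cannot apply identifier mapping to {type(net_or_expr)!r}")


def write_network(
    net: nx.Graph,
    path,
    format: str = "tsv",
    node_attrs: Optional[Mapping[str, Mapping[str, object]]] = None,
    edge_attrs: Optional[Mapping[Tuple[str, str], Mapping[str, object]]] = None,
    sif_relation: str = "pp",
) -> None:
    """Write a graph as TSV edge list, SIF, or GraphML.

    Attribute maps must be keyed by existing nodes/edges.  TSV and SIF
    emit edges in sorted canonical order, so outputs are deterministic;
    singleton nodes are emitted as one-field lines (TSV/SIF convention).
    """
    node_attrs = dict(node_attrs or {})
    edge_attrs = {canonical_edge(*e): dict(v) for e, v in (edge_attrs or {}).items()}
    for n in node_attrs:
        if n not in net:
            raise ValueError(f"attribute on missing node {n!r}")
    for e in edge_attrs:
        if not net.has_edge(*e):
            raise ValueError(f"attribute on missing edge {e!r}")
    edges = sorted(canonical_edge(u, v) for u, v in net.edges())
    singletons = sorted(n for n in net.nodes() if net.degree(n) == 0)
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
            for n in singletons:
                fh.write(n + "\n")
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in edges:
                fh.write(f"{u}\t{sif_relation}\t{v}\n")
            for n in singletons:
                fh.write(n + "\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes())
        g.add_edges_from(edges)
        for n, attrs in node_attrs.items():
            g.nodes[n].update(attrs)
        for (u, v), attrs in edge_attrs.items():
            g.edges[u, v].update(attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "tsv") -> nx.Graph:
    """Read a graph written by :func:`write_network` (round-trip partner)."""
    if format == "tsv":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0]:
                    g.add_node(fields[0])
                elif len(fields) >= 2:
                    g.add_edge(fields[0], fields[1])
        return g
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) == 1 and fields[0]:
                    g.add_node(fields[0])
                elif len(fields) == 3:
                    g.add_edge(fields[0], fields[2])
        return g
    if format == "graphml":
        return nx.Graph(nx.read_graphml(path))
    raise ValueError(f"unknown network format {format!r}")
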