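"""Core data containers for the comparative co-expression network pipeline.

The pipeline couples three kinds of data: a genes-by-samples expression
table split across two biological conditions, a static protein interaction
network (PIN), and a Gene Ontology DAG with gene annotations.  Gene and
protein identifiers are treated as one namespace; any probe-to-gene or
protein-to-gene mapping is applied upstream (see
:func:`cepin.io.apply_identifier_mapping`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

Edge = Tuple[str, str]


def canonical_edge(u: str, v: str) -> Edge:
    """Return the unordered pair (u, v) in canonical (sorted) order."""
    return (u, v) if u <= v else (v, u)


@dataclass
class ExpressionMatrix:
    """A genes-by-samples real-valued expression table.

    Values are taken as provided (log-scale is assumed but not enforced).
    Missing values are NaN; downstream correlation uses pairwise-complete
    samples.
    """

    data: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.data.shape[0] == 0:
            raise ValueError("no data rows")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).any(axis=1).all():
            bad = self.data.index[~np.isfinite(values).any(axis=1)].tolist()
            raise ValueError(f"rows with no finite value: {bad[:5]}")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    def values_for(self, genes: Iterable[str], samples: Iterable[str]) -> np.ndarray:
        return self.data.loc[list(genes), list(samples)].to_numpy(dtype=float)


@dataclass
class SampleDesign:
    """Assignment of samples to exactly two condition labels.

    ``positive_condition`` names the condition treated as "positive" in
    classification reports (e.g. the disease state).
    """

    assignment: Dict[str, str]
    positive_condition: str

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if len(labels) != 2:
            raise ValueError(
                f"expected exactly two condition labels, got {len(labels)}: {labels}"
            )
        if self.positive_condition not in labels:
            raise ValueError(
                f"positive condition {self.positive_condition!r} not among {labels}"
            )
        for label in labels:
            n = sum(1 for c in self.assignment.values() if c == label)
            if n < 3:
                raise ValueError(
                    f"minimum 3 samples per condition; condition {label!r} has {n}"
                )

    @property
    def conditions(self) -> Tuple[str, str]:
        """The two labels, positive condition first."""
        labels = sorted(set(self.assignment.values()))
        other = [x for x in labels if x != self.positive_condition][0]
        return (self.positive_condition, other)

    @property
    def negative_condition(self) -> str:
        return self.conditions[1]

    def samples_of(self, condition: str) -> list:
        if condition not in set(self.assignment.values()):
            raise KeyError(f"unknown condition {condition!r}")
        return [s for s, c in self.assignment.items() if c == condition]


def as_simple_graph(edges: Iterable[Edge], nodes: Iterable[str] = ()) -> nx.Graph:
    """Build a simple undirected graph: self-loops and duplicates dropped."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u == v:
            continue
        g.add_edge(u, v)
    return g


@dataclass
class OntologyDAG:
    """An ontology term hierarchy with 1-based shortest-path levels.

    ``parents`` maps each term to its parents over is_a/part_of edges.
    ``levels`` follows the convention level(root) = 1 and
    level(t) = 1 + min over parents of level(parent); this matches the
    "level 5" / "level 6" usage of GO enrichment tools.  A longest-path
    variant is available via :func:`compute_levels`.
    """

    terms: Dict[str, Dict[str, str]]  # term id -> {"name": ..., "namespace": ...}
    parents: Dict[str, Set[str]]
    levels: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.levels and self.terms:
            self.levels = compute_levels(self.parents, set(self.terms))

    @property
    def roots(self) -> Set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def ancestors(self, term: str) -> Set[str]:
        """All proper ancestors of ``term`` via the parent relation."""
        out: Set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self.parents.get(p, ()))
        return out

    def level(self, term: str) -> int:
        if term not in self.levels:
            raise KeyError(f"term {term!r} has no level (not in DAG)")
        return self.levels[term]

    def name(self, term: str) -> str:
        return self.terms.get(term, {}).get("name", term)


def compute_levels(
    parents: Mapping[str, Set[str]],
    terms: Set[str],
    rule: str = "shortest",
) -> Dict[str, int]:
    """Compute 1-based depth of every term from the root(s).

    rule="shortest": level(t) = 1 + min over parents (the convention GO
    enrichment tools use when speaking of "level 5" terms);
    rule="longest":  level(t) = 1 + max over parents.
    Raises on cycles, with a witness.
    """
    if rule not in {"shortest", "longest"}:
        raise ValueError(f"unknown level rule {rule!r}")
    children: Dict[str, Set[str]] = {t: set() for t in terms}
    indeg: Dict[str, int] = {t: 0 for t in terms}
    for t in terms:
        for p in parents.get(t, ()):
            if p in children:
                children[p].add(t)
                indeg[t] += 1
    # Kahn topological order; leftover nodes witness a cycle.
    order = []
    queue = sorted(t for t in terms if indeg[t] == 0)
    indeg_work = dict(indeg)
    while queue:
        t = queue.pop()
        order.append(t)
        for c in sorted(children[t]):
            indeg_work[c] -= 1
            if indeg_work[c] == 0:
                queue.append(c)
    if len(order) != len(terms):
        cycle_members = sorted(t for t in terms if indeg_work[t] > 0)
        raise ValueError(f"ontology contains a cycle involving: {cycle_members[:10]}")
    pick = min if rule == "shortest" else max
    levels: Dict[str, int] = {}
    for t in order:
        ps = [p for p in parents.get(t, ()) if p in levels]
        levels[t] = 1 if not ps else 1 + pick(levels[p] for p in ps)
    return levels


@dataclass
class AnnotationMap:
    """Direct and ancestor-propagated gene-to-term annotations."""

    direct: Dict[str, Set[str]]
    propagated: Dict[str, Set[str]] = field(default_factory=dict)

    def genes_with(self, term: str, propagated: bool = True) -> Set[str]:
        source = self.propagated if (propagated and self.propagated) else self.direct
        return {g for g, ts in source.items() if term in ts}

    def term_index(self, propagated: bool = True) -> Dict[str, Set[str]]:
        """Invert to a term -> gene-set map."""
        source = self.propagated if (propagated and self.propagated) else self.direct
        index: Dict[str, Set[str]] = {}
        for g, ts in source.items():
            for t in ts:
                index.setdefault(t, set()).add(g)
        return index

    @property
    def genes(self) -> Set[str]:
        return set(self.direct)
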