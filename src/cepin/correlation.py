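"""Condition-specific edge scoring and CePIN construction.

Every edge of the static protein interaction network is assigned, per
condition, the Pearson correlation coefficient (PCC) of its two genes'
expression over that condition's samples, together with a two-sided
significance p-value.  Edges whose correlation is significant at the
chosen level form the condition's co-expressed protein interaction
network (CePIN); its edges are called CePPIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .model import Edge, ExpressionMatrix, SampleDesign, canonical_edge


@dataclass(frozen=True)
class EdgeScore:
    """Per-edge, per-condition Pearson correlation and significance."""

    edge: Edge
    condition: str
    pcc: float  # NaN when undefined (constant vector / too few samples)
    n_used: int
    p_value: float  # NaN when pcc undefined; 0 with degenerate flag at |pcc| = 1
    degenerate: bool = False

    @property
    def defined(self) -> bool:
        return math.isfinite(self.pcc)


@dataclass
class CePIN:
    """A condition's co-expressed protein interaction network."""

    condition: str
    graph: nx.Graph
    edge_scores: Dict[Edge, EdgeScore]
    alpha: float

    @property
    def ceppis(self) -> Set[Edge]:
        return {canonical_edge(u, v) for u, v in self.graph.edges()}

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes())


def pearson_cc(x: np.ndarray, y: np.ndarray) -> Tuple[float, int]:
    """Pearson correlation as the mean standardized cross-product.

    r = sum_i ((x_i - x̄)/s_x) * ((y_i - ȳ)/s_y) / (n - 1), with sample
    standard deviations, over the pairwise-complete entries; clipped to
    [-1, 1] against rounding.  Returns (r, n_used); r is NaN (score
    undefined, not an exception) when fewer than 3 complete pairs remain
    or either vector is constant on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return (math.nan, n)
    xv, yv = x[mask], y[mask]
    sx = xv.std(ddof=1)
    sy = yv.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return (math.nan, n)
    r = float(np.sum((xv - xv.mean()) / sx * ((yv - yv.mean()) / sy)) / (n - 1))
    return (min(1.0, max(-1.0, r)), n)


def pearson_pvalue(pcc: float, n_used: int) -> Tuple[float, bool]:
    """Two-sided p-value for a Pearson correlation via the t transform.

    t = r * sqrt(n-2) / sqrt(1-r^2) with n-2 degrees of freedom.  Returns
    (p, degenerate); |r| = 1 yields p = 0 with the degenerate flag set.
    """
    if not math.isfinite(pcc):
        return (math.nan, False)
    if n_used < 3:
        raise ValueError(f"n_used must be >= 3, got {n_used}")
    if abs(pcc) >= 1.0:
        return (0.0, True)
    df = n_used - 2
    t = pcc * math.sqrt(df) / math.sqrt(1.0 - pcc * pcc)
    return (2.0 * float(stats.t.sf(abs(t), df)), False)


def _score_edges_vectorized(
    values: np.ndarray, idx_u: np.ndarray, idx_v: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """PCC for many edges at once on a complete (finite) matrix.

    Rows are standardized once; each edge's r is a dot product of
    standardized rows over (n-1).
    """
    n = values.shape[1]
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    r = np.einsum("ij,ij->i", z[idx_u], z[idx_v]) / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    constant = (sd[:, 0] == 0.0) | ~np.isfinite(sd[:, 0])
    r[constant[idx_u] | constant[idx_v]] = np.nan
    return r, np.full(len(idx_u), n, dtype=int)


def score_network_edges(
    net: nx.Graph,
    expr: ExpressionMatrix,
    design: SampleDesign,
    condition: str,
) -> Tuple[Dict[Edge, EdgeScore], Set[Edge]]:
    """Score every static-PIN edge in one condition.

    Returns (scores, unscored): one EdgeScore per edge whose both
    endpoints have expression rows; edges with an unmeasured endpoint go
    to the ``unscored`` set.  Scores use exactly the condition's sample
    columns; pairwise-complete handling applies when values are missing.
    """
    samples = design.samples_of(condition)
    sub = expr.data[samples]
    gene_pos = {g: i for i, g in enumerate(sub.index)}
    values = sub.to_numpy(dtype=float)

    scored_edges = []
    unscored: Set[Edge] = set()
    for u, v in net.edges():
        e = canonical_edge(u, v)
        if u in gene_pos and v in gene_pos:
            scored_edges.append(e)
        else:
            unscored.add(e)
    scores: Dict[Edge, EdgeScore] = {}
    if not scored_edges:
        return scores, unscored

    idx_u = np.array([gene_pos[e[0]] for e in scored_edges])
    idx_v = np.array([gene_pos[e[1]] for e in scored_edges])
    used_rows = np.unique(np.concatenate([idx_u, idx_v]))
    complete = bool(np.isfinite(values[used_rows]).all())
    if complete:
        r_all, n_all = _score_edges_vectorized(values, idx_u, idx_v)
        for e, r, n in zip(scored_edges, r_all, n_all):
            p, degenerate = pearson_pvalue(float(r), int(n)) if math.isfinite(r) else (math.nan, False)
            scores[e] = EdgeScore(e, condition, float(r), int(n), p, degenerate)
    else:
        for e in scored_edges:
            r, n = pearson_cc(values[gene_pos[e[0]]], values[gene_pos[e[1]]])
            if math.isfinite(r):
                p, degenerate = pearson_pvalue(r, n)
            else:
                p, degenerate = math.nan, False
            scores[e] = EdgeScore(e, condition, r, n, p, degenerate)
    return scores, unscored


def build_cepin(
    scores: Dict[Edge, EdgeScore], alpha: float = 0.05, condition: Optional[str] = None
) -> CePIN:
    """Keep edges with p <= alpha (inclusive); nodes are their endpoints.

    Monotone in alpha: a larger alpha can only add edges.  Undefined
    scores (NaN) are never retained.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if condition is None:
        conditions = {s.condition for s in scores.values()}
        condition = conditions.pop() if len(conditions) == 1 else "?"
    g = nx.Graph()
    retained: Dict[Edge, EdgeScore] = {}
    for e, s in scores.items():
        if s.defined and s.p_value <= alpha:
            g.add_edge(*e, pcc=s.pcc, p_value=s.p_value, n_used=s.n_used)
            retained[e] = s
    return CePIN(condition=condition, graph=g, edge_scores=retained, alpha=alpha)


def network_overlap(a: CePIN, b: CePIN, static: nx.Graph,
                    scored_a: Optional[Dict[Edge, EdgeScore]] = None,
                    scored_b: Optional[Dict[Edge, EdgeScore]] = None) -> Dict[str, object]:
    """Structural comparison of two CePINs built from one static PIN.

    Reports per-condition protein counts, scored static-PPI counts, CePPI
    counts, and the pairwise intersections (the rewiring summary).
    """
    nodes_a, nodes_b = a.nodes, b.nodes
    ceppis_a, ceppis_b = a.ceppis, b.ceppis
    static_edges = {canonical_edge(u, v) for u, v in static.edges()}
    scored_edges_a = set(scored_a) if scored_a is not None else static_edges
    scored_edges_b = set(scored_b) if scored_b is not None else static_edges
    return {
        "condition_a": a.condition,
        "condition_b": b.condition,
        "proteins": {a.condition: len(nodes_a), b.condition: len(nodes_b),
                     "overlap": len(nodes_a & nodes_b)},
        "static_ppis_scored": {a.condition: len(scored_edges_a),
                               b.condition: len(scored_edges_b),
                               "overlap": len(scored_edges_a & scored_edges_b)},
        "ceppis": {a.condition: len(ceppis_a), b.condition: len(ceppis_b),
                   "overlap": len(ceppis_a & ceppis_b)},
    }


def scores_to_records(scores: Dict[Edge, EdgeScore], alpha: float) -> "pd.DataFrame":
    """Edge-score table: edge endpoints, condition, pcc, n_used, p, retained."""
    import pandas as pd

    rows = []
    for e in sorted(scores):
        s = scores[e]
        rows.append({
            "gene_a": e[0], "gene_b": e[1], "condition": s.condition,
            "pcc": s.pcc, "n_used": s.n_used, "p_value": s.p_value,
            "retained": bool(s.defined and s.p_value <= alpha),
        })
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "condition", "pcc",
                                       "n_used", "p_value", "retained"])


def records_to_scores(df) -> Dict[Edge, EdgeScore]:
    """Inverse of :func:`scores_to_records` (stage-isolation round trip)."""
    scores: Dict[Edge, EdgeScore] = {}
    for row in df.itertuples(index=False):
        e = canonical_edge(str(row.gene_a), str(row.gene_b))
        scores[e] = EdgeScore(e, str(row.condition), float(row.pcc),
                              int(row.n_used), float(row.p_value))
    return scores
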