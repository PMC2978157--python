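"""Hypergeometric enrichment of genes and functional dyads, with BH-FDR.

Two tests drive module discovery.  The gene-level test asks whether a
functional category's genes are over-represented among a CePIN's nodes,
relative to the annotated background (genes measured in the expression
data and present in the static PIN).  The dyad-level test repeats the
question at the edge level: a *functional dyad* is an edge whose two
endpoints share the category; the test compares the category's dyads
among CePPIs against its dyads among background static-PIN edges.

Both use the exact hypergeometric upper tail computed in log space, and
each family of raw p-values is adjusted with the Benjamini-Hochberg
step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .correlation import CePIN
from .model import AnnotationMap, Edge, canonical_edge


@dataclass(frozen=True)
class GeneEnrichment:
    """Gene-level record: category with n of N background genes, k of the
    CePIN's m genes."""

    term: str
    N: int
    m: int
    n: int
    k: int
    p_raw: float
    p_adj: float = math.nan


@dataclass(frozen=True)
class DyadEnrichment:
    """Dyad-level record: category with ne of Ne background edges as
    dyads, ke of the me CePPIs."""

    term: str
    Ne: int
    me: int
    ne: int
    ke: int
    p_raw: float
    p_adj: float = math.nan
    no_dyads: bool = False


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def hypergeometric_pmf(N: int, m: int, n: int, k: int) -> float:
    """P(X = k) drawing n from N of which m are marked (log-space exact)."""
    if k < 0 or k > n or k > m or n - k > N - m:
        return 0.0
    return math.exp(_log_comb(m, k) + _log_comb(N - m, n - k) - _log_comb(N, n))


def hypergeometric_tail(N: int, m: int, n: int, k: int, point_mass: bool = False) -> float:
    """Upper-tail P(X >= k) of the hypergeometric distribution.

    X counts marked elements in a draw of n from a population of N
    containing m marked elements.  Computed exactly by log-space
    summation of the point masses.  ``point_mass=True`` returns P(X = k)
    instead (for forensic comparison with tools that print the mass).
    """
    if not (0 <= k <= n <= N and 0 <= m <= N):
        raise ValueError(f"violated bounds: N={N}, m={m}, n={n}, k={k}")
    if point_mass:
        return hypergeometric_pmf(N, m, n, k)
    if k <= max(0, n + m - N):
        return 1.0
    terms = []
    for j in range(k, min(m, n) + 1):
        if n - j > N - m:
            continue
        terms.append(_log_comb(m, j) + _log_comb(N - m, n - j) - _log_comb(N, n))
    if not terms:
        return 0.0
    hi = max(terms)
    return float(min(1.0, math.exp(hi) * sum(math.exp(t - hi) for t in terms)))


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the probabilities of all tables with the same margins whose
    hypergeometric mass does not exceed the observed one (the standard
    two-sided convention).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in {table}")
    N = a + b + c + d
    m = a + b        # row-1 total (marked)
    n = a + c        # column-1 total (draw)
    p_obs = hypergeometric_pmf(N, m, n, a)
    total = 0.0
    for j in range(max(0, n + m - N), min(m, n) + 1):
        pj = hypergeometric_pmf(N, m, n, j)
        if pj <= p_obs * (1.0 + 1e-7):
            total += pj
    return float(min(1.0, total))


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * M / j, capped at 1, where p_(1) <= ...
    <= p_(M) is the sorted input.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    M = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(M, dtype=float)
    running = 1.0
    for rank in range(M, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * M / rank)
        adjusted[idx] = running
    return adjusted.tolist()


def gene_enrichment(
    cepin: CePIN,
    ann: AnnotationMap,
    background: Set[str],
    use_propagated: bool = True,
) -> List[GeneEnrichment]:
    """Gene-level hypergeometric enrichment of every category over a CePIN.

    ``background`` is the annotated gene universe (genes in both the
    expression data and the static PIN).  One record is produced per
    category with at least one background gene; BH adjustment is applied
    across all tested categories.
    """
    if not background:
        raise ValueError("empty background gene set")
    index = ann.term_index(propagated=use_propagated)
    cepin_genes = cepin.nodes & background
    N = len(background)
    m = len(cepin_genes)
    records = []
    for term in sorted(index):
        term_genes = index[term] & background
        n = len(term_genes)
        if n == 0:
            continue
        k = len(term_genes & cepin_genes)
        p = hypergeometric_tail(N, m, n, k)
        records.append(GeneEnrichment(term=term, N=N, m=m, n=n, k=k, p_raw=p))
    adj = bh_adjust([r.p_raw for r in records])
    return [GeneEnrichment(r.term, r.N, r.m, r.n, r.k, r.p_raw, q)
            for r, q in zip(records, adj)]


def _term_dyads(edges: Iterable[Edge], term_genes: Set[str]) -> int:
    return sum(1 for u, v in edges if u in term_genes and v in term_genes)


def dyad_enrichment(
    cepin: CePIN,
    ann: AnnotationMap,
    static: nx.Graph,
    terms: Iterable[str],
    background: Set[str],
    use_propagated: bool = True,
) -> List[DyadEnrichment]:
    """Dyad-level hypergeometric enrichment for the given categories.

    The edge universe is the static PIN restricted to the annotated
    background (Ne edges, of which me are CePPIs).  For a category, ne
    counts background edges whose both endpoints carry it and ke counts
    such CePPIs.  A category with no background dyad (ne = 0) gets
    p_raw = 1 with the ``no_dyads`` flag.  BH adjustment runs across the
    tested categories.
    """
    index = ann.term_index(propagated=use_propagated)
    bg_edges = [canonical_edge(u, v) for u, v in static.edges()
                if u in background and v in background]
    ceppi_edges = [e for e in cepin.ceppis if e[0] in background and e[1] in background]
    Ne, me = len(bg_edges), len(ceppi_edges)
    records = []
    for term in sorted(set(terms)):
        term_genes = index.get(term, set()) & background
        ne = _term_dyads(bg_edges, term_genes)
        if ne == 0:
            records.append(DyadEnrichment(term, Ne, me, 0, 0, 1.0, no_dyads=True))
            continue
        ke = _term_dyads(ceppi_edges, term_genes)
        p = hypergeometric_tail(Ne, me, ne, ke)
        records.append(DyadEnrichment(term, Ne, me, ne, ke, p))
    adj = bh_adjust([r.p_raw for r in records])
    return [DyadEnrichment(r.term, r.Ne, r.me, r.ne, r.ke, r.p_raw, q, r.no_dyads)
            for r, q in zip(records, adj)]


def enrichment_table(records, dag=None):
    """Flat table of enrichment records (either family) for export."""
    import pandas as pd

    rows = []
    for r in records:
        row = {"term": r.term}
        if dag is not None:
            row["name"] = dag.name(r.term)
            row["level"] = dag.levels.get(r.term, math.nan)
        if isinstance(r, GeneEnrichment):
            row.update({"N": r.N, "m": r.m, "n": r.n, "k": r.k})
        else:
            row.update({"Ne": r.Ne, "me": r.me, "ne": r.ne, "ke": r.ke})
        row.update({"p_raw": r.p_raw, "p_adj": r.p_adj})
        rows.append(row)
    return pd.DataFrame(rows)
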