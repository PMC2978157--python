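"""Network topology, differential-expression calls, hubs, and their association.

Four node-level measures are used throughout: degree, betweenness
centrality (fraction of shortest-path pair incidences routed through the
node, normalized by C(N,2)), closeness centrality (reciprocal mean
shortest-path length), and the local clustering coefficient.  Betweenness
and closeness are only defined within the largest connected component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .correlation import CePIN
from .io import largest_connected_component
from .model import ExpressionMatrix, SampleDesign


@dataclass(frozen=True)
class NodeTopology:
    node: str
    degree: int
    betweenness: float  # NaN outside the LCC
    closeness: float    # NaN outside the LCC
    clustering: float   # 0 with flag for degree < 2
    in_lcc: bool
    clustering_defined: bool


def compute_topology(net: nx.Graph) -> Dict[str, NodeTopology]:
    """All four measures for every node of a non-empty graph.

    Degree and clustering are computed on the full graph; betweenness and
    closeness within the largest connected component only (nodes outside
    it carry NaN).  Betweenness uses fractional shortest-path counting —
    each source-target pair contributes the fraction of its shortest
    paths passing through the node — normalized by C(N,2) over the LCC's
    N nodes.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    lcc = largest_connected_component(net)
    n_lcc = lcc.number_of_nodes()
    pairs = n_lcc * (n_lcc - 1) / 2
    raw_bc = nx.betweenness_centrality(lcc, normalized=False)
    bc = {v: (raw_bc[v] / pairs if pairs > 0 else 0.0) for v in lcc}
    cc = nx.closeness_centrality(lcc) if n_lcc > 1 else {v: 0.0 for v in lcc}
    clustering = nx.clustering(net)
    out: Dict[str, NodeTopology] = {}
    for v in net.nodes():
        in_lcc = v in lcc
        deg = net.degree(v)
        out[v] = NodeTopology(
            node=v,
            degree=deg,
            betweenness=bc[v] if in_lcc else math.nan,
            closeness=cc[v] if in_lcc else math.nan,
            clustering=float(clustering[v]),
            in_lcc=in_lcc,
            clustering_defined=deg >= 2,
        )
    return out


def wilcoxon_exact(
    x: Sequence[float], y: Sequence[float], max_enumeration: int = 1_000_000
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration over all C(nx+ny, nx) group assignments of
    the pooled midranks when that count is at most ``max_enumeration``;
    otherwise the normal approximation with midrank tie correction (no
    continuity correction).  All values tied across both groups gives
    p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    nx_, ny_ = x.size, y.size
    n = nx_ + ny_
    w_obs = float(ranks[:nx_].sum())
    mu = nx_ * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    if math.comb(n, nx_) <= max_enumeration:
        count = 0
        total = 0
        for combo in combinations(range(n), nx_):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mu) >= dev - 1e-9:
                count += 1
        return count / total
    # Normal approximation with tie correction on the rank variance.
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx_ * ny_ / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = dev / math.sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.sf(z)))


@dataclass
class SdegTable:
    """Per-gene rank-sum p-values, directions, and SDEG flags."""

    table: pd.DataFrame  # index gene; columns p_value, direction, is_sdeg
    alpha: float
    skipped: List[str]

    @property
    def sdegs(self) -> Set[str]:
        return set(self.table.index[self.table["is_sdeg"]])

    def is_sdeg(self, gene: str) -> bool:
        return gene in self.table.index and bool(self.table.loc[gene, "is_sdeg"])


def call_sdegs(
    expr: ExpressionMatrix, design: SampleDesign, alpha: float = 0.05
) -> SdegTable:
    """Call significantly differentially expressed genes between conditions.

    A gene is an SDEG when its two-sided rank-sum p-value (positive
    condition against the other) is at most ``alpha``; its direction (up
    or down in the positive condition) comes from the condition means.
    Genes without a finite value in either condition are skipped and
    reported.
    """
    pos, neg = design.conditions
    cols_pos = design.samples_of(pos)
    cols_neg = design.samples_of(neg)
    rows = []
    skipped: List[str] = []
    vp_all = expr.data[cols_pos].to_numpy(dtype=float)
    vn_all = expr.data[cols_neg].to_numpy(dtype=float)
    for i, gene in enumerate(expr.gene_ids):
        vp = vp_all[i][np.isfinite(vp_all[i])]
        vn = vn_all[i][np.isfinite(vn_all[i])]
        if vp.size == 0 or vn.size == 0:
            skipped.append(gene)
            continue
        p = wilcoxon_exact(vp, vn)
        flag = p <= alpha
        direction = ""
        if flag:
            direction = "up" if vp.mean() > vn.mean() else "down"
        rows.append({"gene": gene, "p_value": p, "direction": direction, "is_sdeg": flag})
    table = pd.DataFrame(rows, columns=["gene", "p_value", "direction", "is_sdeg"])
    table = table.set_index("gene") if len(rows) else pd.DataFrame(
        columns=["p_value", "direction", "is_sdeg"])
    return SdegTable(table=table, alpha=alpha, skipped=skipped)


def compare_topology_by_group(
    topo: Mapping[str, NodeTopology], groups: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Group means and rank-sum p-value per topological property.

    ``groups`` maps two group names (e.g. SDEG / non-SDEG) to node sets.
    Betweenness/closeness rows use only nodes where the measure is
    defined (inside the LCC).
    """
    names = list(groups)
    if len(names) != 2:
        raise ValueError(f"expected exactly two groups, got {names}")
    sets = {name: [n for n in members if n in topo] for name, members in groups.items()}
    for name, members in sets.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    for prop in ("degree", "betweenness", "closeness", "clustering"):
        vals = {}
        for name in names:
            v = np.array([getattr(topo[n], prop) for n in sets[name]], dtype=float)
            vals[name] = v[np.isfinite(v)]
        if vals[names[0]].size == 0 or vals[names[1]].size == 0:
            # e.g. a group entirely outside the LCC: the measure is undefined
            rows.append({
                "property": prop,
                f"mean_{names[0]}": float(vals[names[0]].mean()) if vals[names[0]].size else math.nan,
                f"mean_{names[1]}": float(vals[names[1]].mean()) if vals[names[1]].size else math.nan,
                "p_value": math.nan,
            })
            continue
        p = wilcoxon_exact(vals[names[0]], vals[names[1]])
        rows.append({
            "property": prop,
            f"mean_{names[0]}": float(vals[names[0]].mean()),
            f"mean_{names[1]}": float(vals[names[1]].mean()),
            "p_value": p,
        })
    return pd.DataFrame(rows)


def call_hubs(cepin: CePIN, percentile: float = 1.0) -> Tuple[Set[str], float]:
    """Nodes in the top ``percentile`` of the CePIN degree distribution.

    The threshold is the (100 - percentile)-th degree quantile (linear
    interpolation between order statistics); hubs have degree strictly
    greater than it, so an all-equal degree distribution yields no hubs.
    Returns (hub set, realized threshold).
    """
    if not (0.0 < percentile < 100.0):
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    nodes = list(cepin.graph.nodes())
    if not nodes:
        return set(), math.nan
    degrees = np.array([cepin.graph.degree(v) for v in nodes], dtype=float)
    threshold = float(np.percentile(degrees, 100.0 - percentile))
    hubs = {v for v, d in zip(nodes, degrees) if d > threshold}
    return hubs, threshold


def sdeg_degree_association(
    cepin_or_net,
    sdegs: Set[str],
    bin_edges: Optional[Sequence[float]] = None,
) -> Dict[str, object]:
    """Association between CePIN degree and differential expression.

    Splits nodes at the median degree into high (degree > median) and low
    halves, reports the SDEG proportion in each, and a two-sided Fisher
    exact p-value on the 2x2 table; also a binned degree-versus-SDEG-
    proportion curve with configurable bin edges.
    """
    from .enrichment import fisher_exact_2x2

    graph = cepin_or_net.graph if isinstance(cepin_or_net, CePIN) else cepin_or_net
    nodes = list(graph.nodes())
    degrees = np.array([graph.degree(v) for v in nodes], dtype=float)
    if len(set(degrees.tolist())) < 2:
        raise ValueError("fewer than 2 distinct degrees; median split undefined")
    median = float(np.median(degrees))
    high = [v for v, d in zip(nodes, degrees) if d > median]
    low = [v for v, d in zip(nodes, degrees) if d <= median]
    h_s = sum(1 for v in high if v in sdegs)
    l_s = sum(1 for v in low if v in sdegs)
    table = [[h_s, len(high) - h_s], [l_s, len(low) - l_s]]
    p = fisher_exact_2x2(table)
    if bin_edges is None:
        top = degrees.max()
        bin_edges = list(np.arange(1, min(top, 10) + 1)) + ([top + 1] if top >= 10 else [])
    bin_edges = sorted(set(float(b) for b in bin_edges))
    curve = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        members = [v for v, d in zip(nodes, degrees) if lo <= d < hi]
        if members:
            prop = sum(1 for v in members if v in sdegs) / len(members)
            curve.append({"degree_min": lo, "degree_max": hi,
                          "n_nodes": len(members), "sdeg_proportion": prop})
    return {
        "median_degree": median,
        "n_high": len(high),
        "n_low": len(low),
        "sdeg_proportion_high": h_s / len(high) if high else math.nan,
        "sdeg_proportion_low": l_s / len(low) if low else math.nan,
        "fisher_table": table,
        "fisher_p": p,
        "degree_curve": curve,
    }


def topology_table(
    topo: Mapping[str, NodeTopology],
    sdegs: Optional[Set[str]] = None,
    hubs: Optional[Set[str]] = None,
) -> pd.DataFrame:
    """Flat per-node table (node, degree, bc, cc, clustering, flags)."""
    rows = []
    for v in sorted(topo):
        t = topo[v]
        rows.append({
            "node": v, "degree": t.degree, "betweenness": t.betweenness,
            "closeness": t.closeness, "clustering": t.clustering,
            "in_lcc": t.in_lcc,
            "is_sdeg": (v in sdegs) if sdegs is not None else False,
            "is_hub": (v in hubs) if hubs is not None else False,
        })
    return pd.DataFrame(rows, columns=["node", "degree", "betweenness", "closeness",
                                       "clustering", "in_lcc", "is_sdeg", "is_hub"])
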