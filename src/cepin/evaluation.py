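"""Module evaluation: sample classification, ROC, dynamics nulls, rewiring.

A module is judged three ways.  (1) Classification: samples are
hierarchically clustered on the module's gene expression and the tree is
cut at the root; the branch with more positive-condition samples is the
predicted positive class.  A per-sample *module activity score* (mean
expression over member genes) feeds a ROC curve.  (2) Dynamics: the
module's within-condition co-expression, between-condition expression
shift, and between-condition correlation change are compared against
random gene sets of equal size (Z-scores and add-one empirical
p-values).  (3) Edge rewiring: each scored edge is classed by whether
its correlation magnitude clears a threshold in either condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .correlation import CePIN, EdgeScore, build_cepin, pearson_cc, score_network_edges
from .model import Edge, ExpressionMatrix, SampleDesign, canonical_edge
from .modules import FunctionalModule

_LINKAGES = {"single", "complete", "average", "ward"}


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    roc_points: List[Tuple[float, float]]
    auc: float
    orientation: int = 1
    tie_broken: bool = False

    def __post_init__(self) -> None:
        # The three rates must match their defining counts exactly.
        assert self.tp + self.fn > 0 and self.tn + self.fp > 0
        assert abs(self.sensitivity - self.tp / (self.tp + self.fn)) < 1e-12
        assert abs(self.specificity - self.tn / (self.fp + self.tn)) < 1e-12
        total = self.tp + self.fp + self.tn + self.fn
        assert abs(self.accuracy - (self.tp + self.tn) / total) < 1e-12


@dataclass
class DynamicsStat:
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when null sd is 0
    p_empirical: float
    n_null: int


@dataclass
class DynamicsReport:
    module: str
    mean_pcc: Dict[str, DynamicsStat]      # per condition
    expression_shift: DynamicsStat
    pcc_change: DynamicsStat
    seed: int


@dataclass(frozen=True)
class EdgeDynamicsClass:
    edge: Edge
    pcc_a: float
    pcc_b: float
    label: str  # "a_specific" | "b_specific" | "both" | "neither"
    missing: bool = False


def module_activity(
    module_or_genes, expr: ExpressionMatrix
) -> Dict[str, float]:
    """Per-sample mean expression over the module's member genes.

    Samples where a member is missing average over the remaining
    members.  No measured member at all is an error.
    """
    genes = (module_or_genes.member_genes
             if isinstance(module_or_genes, FunctionalModule) else set(module_or_genes))
    measured = [g for g in genes if g in expr.data.index]
    if not measured:
        raise ValueError("no module member gene measured in the expression matrix")
    values = expr.data.loc[sorted(measured)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        scores = np.nanmean(values, axis=0)
    return {s: float(v) for s, v in zip(expr.sample_ids, scores)}


def roc_auc(
    scores: Mapping[str, float], design: SampleDesign
) -> Tuple[List[Tuple[float, float]], float, int]:
    """ROC points and AUC for per-sample scores against the design.

    AUC is the pairwise-concordance (Mann-Whitney) statistic with
    half-credit for ties, identical to the trapezoid area under the
    threshold-sweep ROC.  The score orientation is auto-selected so that
    AUC >= 0.5; the returned orientation is +1 (higher score = positive)
    or -1.  Returns (roc_points, auc, orientation).
    """
    pos_label, neg_label = design.conditions
    pos = [scores[s] for s in design.samples_of(pos_label) if s in scores]
    neg = [scores[s] for s in design.samples_of(neg_label) if s in scores]
    if not pos or not neg:
        raise ValueError("both conditions must have scored samples")

    def _auc(pos_v, neg_v):
        wins = sum((p > q) + 0.5 * (p == q) for p in pos_v for q in neg_v)
        return wins / (len(pos_v) * len(neg_v))

    auc = _auc(pos, neg)
    orientation = 1
    if auc < 0.5:
        orientation = -1
        pos = [-v for v in pos]
        neg = [-v for v in neg]
        auc = _auc(pos, neg)
    # Threshold sweep from high to low over the oriented scores.
    points = [(0.0, 0.0)]
    for thr in sorted(set(pos) | set(neg), reverse=True):
        tpr = sum(1 for v in pos if v >= thr) / len(pos)
        fpr = sum(1 for v in neg if v >= thr) / len(neg)
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, float(auc), orientation


def classify_by_clustering(
    module_or_genes,
    expr: ExpressionMatrix,
    design: SampleDesign,
    linkage_method: str = "average",
) -> ClassificationReport:
    """Root-split classification of samples on module gene expression.

    Samples are clustered with the chosen linkage on Euclidean distance
    over member-gene expression; the dendrogram is cut at the root into
    two groups.  The group with more positive-condition samples is the
    predicted positive class; an exact tie goes to the group whose
    lexicographically smallest sample id is smaller (flagged).  The
    report also carries the activity-score ROC/AUC.
    """
    if linkage_method not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage_method!r}; use one of {_LINKAGES}")
    genes = (module_or_genes.member_genes
             if isinstance(module_or_genes, FunctionalModule) else set(module_or_genes))
    measured = sorted(g for g in genes if g in expr.data.index)
    if not measured:
        raise ValueError("no module member gene measured")
    samples = expr.sample_ids
    X = expr.data.loc[measured].to_numpy(dtype=float).T  # samples x genes
    if np.allclose(X, X[0], equal_nan=True):
        raise ValueError("degenerate clustering: all samples identical")
    X = np.nan_to_num(X, nan=0.0)
    Z = linkage(X, method=linkage_method, metric="euclidean")
    labels = fcluster(Z, t=2, criterion="maxclust")
    group1 = [s for s, l in zip(samples, labels) if l == 1]
    group2 = [s for s, l in zip(samples, labels) if l == 2]
    pos_label = design.positive_condition
    n1 = sum(1 for s in group1 if design.assignment.get(s) == pos_label)
    n2 = sum(1 for s in group2 if design.assignment.get(s) == pos_label)
    tie = n1 == n2
    if tie:
        positive_group = group1 if min(group1) < min(group2) else group2
    else:
        positive_group = group1 if n1 > n2 else group2
    pos_set = set(positive_group)
    tp = sum(1 for s in samples
             if s in pos_set and design.assignment[s] == pos_label)
    fp = sum(1 for s in samples
             if s in pos_set and design.assignment[s] != pos_label)
    fn = sum(1 for s in samples
             if s not in pos_set and design.assignment[s] == pos_label)
    tn = sum(1 for s in samples
             if s not in pos_set and design.assignment[s] != pos_label)
    points, auc, orientation = roc_auc(module_activity(measured, expr), design)
    return ClassificationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (fp + tn),
        accuracy=(tp + tn) / len(samples),
        roc_points=points, auc=auc, orientation=orientation, tie_broken=tie,
    )


def literal_accuracy(sensitivity: float, specificity: float, n_samples: int) -> float:
    """(sensitivity + specificity) / n_samples — forensic-only variant."""
    return (sensitivity + specificity) / n_samples


# ---------------------------------------------------------------------------
# Dynamics statistics and random-gene-set nulls
# ---------------------------------------------------------------------------

def _condition_matrix(expr: ExpressionMatrix, design: SampleDesign, condition: str,
                      genes: Sequence[str]) -> np.ndarray:
    cols = design.samples_of(condition)
    return expr.data.loc[list(genes), cols].to_numpy(dtype=float)


def mean_pairwise_pcc(genes: Iterable[str], expr: ExpressionMatrix,
                      design: SampleDesign, condition: str) -> float:
    """Mean pairwise gene-gene PCC within one condition (NaN pairs skipped)."""
    genes = sorted(g for g in set(genes) if g in expr.data.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 measured genes")
    V = _condition_matrix(expr, design, condition, genes)
    if np.isfinite(V).all():
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(V)
        iu = np.triu_indices(len(genes), k=1)
        vals = C[iu]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else math.nan
    vals = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r, _ = pearson_cc(V[i], V[j])
            if math.isfinite(r):
                vals.append(r)
    return float(np.mean(vals)) if vals else math.nan


def mean_expression_shift(genes: Iterable[str], expr: ExpressionMatrix,
                          design: SampleDesign) -> float:
    """Mean absolute difference of per-gene condition means."""
    genes = sorted(g for g in set(genes) if g in expr.data.index)
    if not genes:
        raise ValueError("no measured genes")
    a, b = design.conditions
    va = np.nanmean(_condition_matrix(expr, design, a, genes), axis=1)
    vb = np.nanmean(_condition_matrix(expr, design, b, genes), axis=1)
    return float(np.mean(np.abs(va - vb)))


def mean_pcc_change(pairs: Iterable[Edge], expr: ExpressionMatrix,
                    design: SampleDesign) -> float:
    """Mean |PCC_A - PCC_B| over the given gene pairs (undefined pairs skipped)."""
    a, b = design.conditions
    pairs = [(u, v) for u, v in pairs
             if u in expr.data.index and v in expr.data.index]
    if not pairs:
        return math.nan
    genes = sorted({g for p in pairs for g in p})
    pos = {g: i for i, g in enumerate(genes)}
    Va = _condition_matrix(expr, design, a, genes)
    Vb = _condition_matrix(expr, design, b, genes)
    if np.isfinite(Va).all() and np.isfinite(Vb).all():
        with np.errstate(invalid="ignore"):
            Ca = np.corrcoef(Va)
            Cb = np.corrcoef(Vb)
        if len(genes) == 1:
            return math.nan
        vals = [abs(Ca[pos[u], pos[v]] - Cb[pos[u], pos[v]]) for u, v in pairs
                if math.isfinite(Ca[pos[u], pos[v]]) and math.isfinite(Cb[pos[u], pos[v]])]
    else:
        vals = []
        for u, v in pairs:
            ra, _ = pearson_cc(Va[pos[u]], Va[pos[v]])
            rb, _ = pearson_cc(Vb[pos[u]], Vb[pos[v]])
            if math.isfinite(ra) and math.isfinite(rb):
                vals.append(abs(ra - rb))
    if not vals:
        return math.nan
    return float(np.mean(vals))


def _all_pairs(genes: Sequence[str]) -> List[Edge]:
    return [(genes[i], genes[j]) for i in range(len(genes))
            for j in range(i + 1, len(genes))]


def random_subnetwork_null(
    net_or_genes,
    size: int,
    n_null: int,
    seed: int,
    statistic: Callable[[Sequence[str]], float],
    mode: str = "gene_set",
) -> np.ndarray:
    """Null sample of a statistic over random gene sets of a fixed size.

    mode="gene_set" draws uniform random gene sets from the measured
    network genes (degree-agnostic); mode="connected" grows a random
    connected induced subgraph by frontier expansion (requires a graph).
    Bit-reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(net_or_genes, nx.Graph):
        genes = sorted(net_or_genes.nodes())
        graph = net_or_genes
    else:
        genes = sorted(net_or_genes)
        graph = None
    if size > len(genes):
        raise ValueError(f"size {size} exceeds available genes ({len(genes)})")
    out = np.empty(n_null, dtype=float)
    for i in range(n_null):
        if mode == "gene_set":
            draw = rng.choice(genes, size=size, replace=False)
        elif mode == "connected":
            if graph is None:
                raise ValueError("connected mode requires a graph")
            draw = _grow_connected(graph, size, rng)
        else:
            raise ValueError(f"unknown null mode {mode!r}")
        out[i] = statistic(list(draw))
    return out


def _grow_connected(graph: nx.Graph, size: int, rng) -> List[str]:
    nodes = sorted(graph.nodes())
    for _ in range(100):
        start = nodes[rng.integers(len(nodes))]
        chosen = {start}
        frontier = sorted(set(graph.neighbors(start)))
        while frontier and len(chosen) < size:
            nxt = frontier[rng.integers(len(frontier))]
            chosen.add(nxt)
            frontier = sorted((set(frontier) | set(graph.neighbors(nxt))) - chosen)
        if len(chosen) == size:
            return sorted(chosen)
    raise ValueError(f"could not grow a connected subgraph of size {size}")


def _stat_summary(observed: float, null: np.ndarray, n_null: int) -> DynamicsStat:
    null = null[np.isfinite(null)]
    mu = float(null.mean()) if null.size else math.nan
    sd = float(null.std(ddof=1)) if null.size > 1 else math.nan
    z = (observed - mu) / sd if (sd and math.isfinite(sd) and sd > 0) else math.nan
    p = (1 + int(np.sum(null >= observed))) / (1 + null.size) if null.size else math.nan
    return DynamicsStat(observed=observed, null_mean=mu, null_sd=sd, z=z,
                        p_empirical=p, n_null=n_null)


def module_dynamics_zscores(
    module: FunctionalModule,
    expr: ExpressionMatrix,
    design: SampleDesign,
    background_genes: Optional[Iterable[str]] = None,
    n_null: int = 1000,
    seed: int = 0,
    null_mode: str = "gene_set",
) -> DynamicsReport:
    """Observed-versus-null dynamics statistics for a module.

    Three observables: (a) mean pairwise within-condition PCC of member
    genes, per condition; (b) mean absolute per-gene condition-mean
    difference; (c) mean |PCC change| over member CePPIs.  Nulls draw
    random gene sets of equal size from ``background_genes`` (default:
    all measured genes); for (c) the null statistic runs over all pairs
    of the drawn set, since a random gene set carries no edges of its
    own.  Z = (observed - null mean) / null sd; empirical p uses the
    add-one estimator.
    """
    genes = sorted(g for g in module.member_genes if g in expr.data.index)
    if len(genes) < 2:
        raise ValueError("module needs at least 2 measured member genes")
    if background_genes is None:
        background_genes = expr.gene_ids
    pool = sorted(set(background_genes) & set(expr.gene_ids))
    size = len(genes)
    a, b = design.conditions

    mean_pcc: Dict[str, DynamicsStat] = {}
    for offset, cond in enumerate((a, b)):
        obs = mean_pairwise_pcc(genes, expr, design, cond)
        null = random_subnetwork_null(
            pool, size, n_null, seed + offset,
            lambda gs, c=cond: mean_pairwise_pcc(gs, expr, design, c),
            mode="gene_set" if null_mode == "gene_set" else null_mode)
        mean_pcc[cond] = _stat_summary(obs, null, n_null)

    obs_shift = mean_expression_shift(genes, expr, design)
    null_shift = random_subnetwork_null(
        pool, size, n_null, seed + 2,
        lambda gs: mean_expression_shift(gs, expr, design))
    shift = _stat_summary(obs_shift, null_shift, n_null)

    edge_pairs = sorted(module.member_ceppis) or _all_pairs(genes)
    obs_change = mean_pcc_change(edge_pairs, expr, design)
    null_change = random_subnetwork_null(
        pool, size, n_null, seed + 3,
        lambda gs: mean_pcc_change(_all_pairs(sorted(gs)), expr, design))
    change = _stat_summary(obs_change, null_change, n_null)

    return DynamicsReport(module=module.term, mean_pcc=mean_pcc,
                          expression_shift=shift, pcc_change=change, seed=seed)


def classify_edge_dynamics(
    scores_a: Mapping[Edge, EdgeScore],
    scores_b: Mapping[Edge, EdgeScore],
    threshold: float = 0.5,
    edges: Optional[Iterable[Edge]] = None,
) -> List[EdgeDynamicsClass]:
    """Class per edge from |PCC| >= threshold in each condition.

    Labels: a_specific, b_specific, both, neither.  An edge missing a
    defined score in either condition is "neither" with the missing
    flag.
    """
    if edges is None:
        edges = set(scores_a) | set(scores_b)
    out = []
    for e in sorted(canonical_edge(*x) for x in edges):
        sa, sb = scores_a.get(e), scores_b.get(e)
        pa = sa.pcc if sa is not None else math.nan
        pb = sb.pcc if sb is not None else math.nan
        if not (math.isfinite(pa) and math.isfinite(pb)):
            out.append(EdgeDynamicsClass(e, pa, pb, "neither", missing=True))
            continue
        in_a = abs(pa) >= threshold
        in_b = abs(pb) >= threshold
        label = ("both" if in_a and in_b else
                 "a_specific" if in_a else
                 "b_specific" if in_b else "neither")
        out.append(EdgeDynamicsClass(e, pa, pb, label))
    return out


def resample_robustness(
    expr: ExpressionMatrix,
    design: SampleDesign,
    static: nx.Graph,
    ann,
    dag,
    subsample_sizes: Sequence[int],
    n_repeat: int = 5,
    seed: int = 0,
    alpha_edge: float = 0.05,
    alpha_enrich: float = 0.05,
    min_level: int = 5,
    track_terms: Optional[Iterable[str]] = None,
) -> Dict[str, object]:
    """Re-sampling robustness of CePPIs and module identification.

    For each subsample size and repeat, samples are drawn without
    replacement within each condition, the CePINs are rebuilt and module
    discovery is re-run.  Reports, per size: the mean fraction of
    full-data CePPIs recovered (per condition and combined) and, for
    each tracked category (default: the full-data exclusive categories),
    the fraction of repeats in which it is re-identified as exclusive to
    the positive condition.
    """
    from .enrichment import dyad_enrichment, gene_enrichment
    from .modules import candidate_functions, exclusive_functions, filter_by_level

    pos, neg = design.conditions
    for size in subsample_sizes:
        if size < 3:
            raise ValueError(f"subsample size {size} < 3 (correlation needs >= 3 samples)")
        if size > len(design.samples_of(pos)) or size > len(design.samples_of(neg)):
            raise ValueError(f"subsample size {size} exceeds a condition's sample count")

    background = set(expr.gene_ids) & set(static.nodes()) & set(ann.genes)

    def _discover(e: ExpressionMatrix, d: SampleDesign):
        ceppis = {}
        cand = {}
        for cond in d.conditions:
            scores, _ = score_network_edges(static, e, d, cond)
            cep = build_cepin(scores, alpha_edge, cond)
            ceppis[cond] = cep.ceppis
            g_enr = gene_enrichment(cep, ann, background)
            d_enr = dyad_enrichment(cep, ann, static, [r.term for r in g_enr], background)
            cand[cond] = candidate_functions(g_enr, d_enr, alpha_enrich)
        excl = filter_by_level(exclusive_functions(cand[pos], cand[neg]), dag, min_level)
        return ceppis, excl

    full_ceppis, full_excl = _discover(expr, design)
    tracked = sorted(set(track_terms)) if track_terms is not None else sorted(full_excl)

    rng = np.random.default_rng(seed)
    curves = []
    for size in subsample_sizes:
        recov = {pos: [], neg: [], "combined": []}
        ident = {t: 0 for t in tracked}
        for _ in range(n_repeat):
            keep = []
            for cond in (pos, neg):
                cols = design.samples_of(cond)
                keep.extend(sorted(rng.choice(cols, size=size, replace=False)))
            sub_expr = ExpressionMatrix(expr.data[keep])
            sub_design = SampleDesign(
                {s: design.assignment[s] for s in keep}, design.positive_condition)
            ceppis, excl = _discover(sub_expr, sub_design)
            for cond in (pos, neg):
                full = full_ceppis[cond]
                recov[cond].append(len(ceppis[cond] & full) / len(full) if full else math.nan)
            all_full = full_ceppis[pos] | full_ceppis[neg]
            all_sub = ceppis[pos] | ceppis[neg]
            recov["combined"].append(
                len(all_sub & all_full) / len(all_full) if all_full else math.nan)
            for t in tracked:
                if t in excl:
                    ident[t] += 1
        curves.append({
            "size": int(size),
            "recovery_rate": {k: float(np.nanmean(v)) for k, v in recov.items()},
            "identification_rate": {t: ident[t] / n_repeat for t in tracked},
        })
    return {"tracked_terms": tracked, "full_exclusive": sorted(full_excl),
            "n_repeat": n_repeat, "seed": seed, "curves": curves}
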