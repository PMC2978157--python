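"""Synthetic two-condition datasets with planted co-expression structure.

The generator emulates the statistical structure the pipeline assumes: a
static interaction network, a shallow ontology with computed levels,
gene annotations, and a two-condition expression matrix in which chosen
annotated gene sets are co-expressed through a one-factor Gaussian model.
For a planted category with target correlations (rho_a, rho_b), member
gene g in condition c follows

    x_g = sqrt(rho_c) * f_sample + sqrt(1 - rho_c) * noise_sd * eps,

so the expected within-condition pairwise Pearson correlation is close
to rho_c.  Members of condition-exclusive categories (rho_a != rho_b)
additionally receive a mean shift of ``sdeg_shift`` in the positive
condition, making them differentially expressed.  Background genes are
i.i.d. standard normal and are annotated to decoy categories of matched
size, so enrichment statistics see a realistic null.

Everything is a pure function of the spec (including its seed): the same
spec always yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .io import propagate_annotations
from .model import (
    AnnotationMap,
    ExpressionMatrix,
    OntologyDAG,
    SampleDesign,
    compute_levels,
)

ROOT_TERM = "GO:0000001"


@dataclass(frozen=True)
class PlantedTerm:
    """A functional category planted into the synthetic data.

    ``shift`` is the per-gene mean shift in the positive condition; left
    unset, it defaults to the dataset-level ``sdeg_shift`` for
    condition-exclusive categories (rho_a != rho_b) and 0 otherwise.
    """

    term: str
    n_members: int
    rho_a: float  # target within-condition pairwise PCC, condition A
    rho_b: float  # same for condition B
    level: int = 6
    shift: Optional[float] = None

    def __post_init__(self):
        for rho in (self.rho_a, self.rho_b):
            if not (0.0 <= rho < 1.0):
                raise ValueError(f"rho must be in [0, 1), got {rho}")

    def effective_shift(self, sdeg_shift: float) -> float:
        if self.shift is not None:
            return self.shift
        return sdeg_shift if self.rho_a != self.rho_b else 0.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults describe the desk-scale reference fixture: 300 genes, 800
    interactions, 15 samples per condition, one A-exclusive co-expressed
    category (rho 0.8 vs 0) whose members are also mean-shifted, and one
    category co-expressed in both conditions.
    """

    n_genes: int = 300
    n_edges: int = 800
    samples_per_condition: Tuple[int, int] = (15, 15)
    planted_terms: Tuple[PlantedTerm, ...] = (
        PlantedTerm("GO:9000001", 20, 0.8, 0.0),
        PlantedTerm("GO:9000002", 20, 0.8, 0.8),
    )
    sdeg_shift: float = 1.0
    noise_sd: float = 1.0
    ontology_depth: int = 6
    decoy_size: int = 20
    seed: int = 0
    condition_a: str = "A"
    condition_b: str = "B"

    def __post_init__(self):
        if sum(t.n_members for t in self.planted_terms) > self.n_genes:
            raise ValueError("planted members exceed the gene count")
        if min(self.samples_per_condition) < 3:
            raise ValueError("need at least 3 samples per condition")
        for t in self.planted_terms:
            if t.level > self.ontology_depth:
                raise ValueError(f"term level {t.level} exceeds ontology depth")

    @property
    def gene_ids(self) -> List[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def members_of(self, term: PlantedTerm) -> List[str]:
        """Planted members are allocated in spec order from the gene list."""
        start = 0
        for t in self.planted_terms:
            if t.term == term.term:
                return self.gene_ids[start:start + t.n_members]
            start += t.n_members
        raise KeyError(term.term)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    expr: ExpressionMatrix
    design: SampleDesign
    pin: nx.Graph
    dag: OntologyDAG
    ann: AnnotationMap
    n_forced_edges: int = 0


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), stream])


def generate_pin(spec: SyntheticSpec) -> Tuple[nx.Graph, int]:
    """Random connected simple graph with planted members pre-wired.

    A random spanning tree guarantees one connected component over all
    genes; each planted category's members get their own spanning tree
    (so the category induces a connected subgraph); remaining edges are
    uniform random pairs.  Returns (graph, count of planted edges added
    beyond the global tree).
    """
    n = spec.n_genes
    max_edges = n * (n - 1) // 2
    if spec.n_edges > max_edges or spec.n_edges < n - 1:
        raise ValueError(
            f"infeasible edge budget {spec.n_edges} for {n} genes "
            f"(need between {n - 1} and {max_edges})")
    rng = _rng(spec, 1)
    genes = spec.gene_ids
    g = nx.Graph()
    g.add_nodes_from(genes)
    order = list(rng.permutation(n))
    for i in range(1, n):
        j = order[int(rng.integers(i))]
        g.add_edge(genes[order[i]], genes[j])
    forced = 0
    for term in spec.planted_terms:
        members = spec.members_of(term)
        for i in range(1, len(members)):
            j = int(rng.integers(i))
            if not g.has_edge(members[i], members[j]):
                g.add_edge(members[i], members[j])
                forced += 1
    while g.number_of_edges() < spec.n_edges:
        u, v = (genes[int(k)] for k in rng.integers(n, size=2))
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v)
    return g, forced


def generate_annotations(spec: SyntheticSpec) -> Tuple[OntologyDAG, AnnotationMap]:
    """Chain-plus-branches ontology and direct gene annotations.

    A single chain runs from the root down to level ``ontology_depth - 1``.
    Planted categories hang off the chain at their configured level
    (default 6).  Background genes are partitioned into decoy categories
    of ``decoy_size`` at the same default level, and two shallow decoys
    at level 3 re-annotate the first background genes so the level
    filter has something to reject.  Direct annotations are returned
    un-propagated (propagate with :func:`cepin.io.propagate_annotations`).
    """
    depth = spec.ontology_depth
    terms: Dict[str, Dict[str, str]] = {}
    parents: Dict[str, Set[str]] = {}

    chain = [ROOT_TERM] + [f"GO:{i + 1:07d}" for i in range(1, depth - 1)]
    for i, t in enumerate(chain):
        terms[t] = {"name": f"chain level {i + 1}" if i else "root process",
                    "namespace": "biological_process"}
        parents[t] = {chain[i - 1]} if i else set()

    def attach(term_id: str, name: str, level: int) -> None:
        if not (2 <= level <= depth):
            raise ValueError(f"cannot place term at level {level} (depth {depth})")
        terms[term_id] = {"name": name, "namespace": "biological_process"}
        parents[term_id] = {chain[level - 2]}

    direct: Dict[str, Set[str]] = {g: set() for g in spec.gene_ids}
    cursor = 0
    for idx, t in enumerate(spec.planted_terms, 1):
        attach(t.term, f"planted process {idx}", t.level)
        for g in spec.members_of(t):
            direct[g].add(t.term)
        cursor += t.n_members

    background = spec.gene_ids[cursor:]
    for i in range(0, len(background), spec.decoy_size):
        chunk = background[i:i + spec.decoy_size]
        term_id = f"GO:{7000001 + i // spec.decoy_size:07d}"
        attach(term_id, f"decoy process {i // spec.decoy_size + 1}", depth)
        for g in chunk:
            direct[g].add(term_id)

    # Shallow decoys (level 3): too generic to pass the level filter.
    if depth >= 3 and background:
        for j, chunk in enumerate([background[:spec.decoy_size],
                                   background[spec.decoy_size:2 * spec.decoy_size]]):
            if chunk:
                term_id = f"GO:{8000001 + j:07d}"
                attach(term_id, f"shallow decoy {j + 1}", 3)
                for g in chunk:
                    direct[g].add(term_id)

    dag = OntologyDAG(terms=terms, parents=parents,
                      levels=compute_levels(parents, set(terms)))
    ann = propagate_annotations(AnnotationMap(direct=direct), dag)
    return dag, ann


def generate_expression(
    spec: SyntheticSpec, pin: Optional[nx.Graph] = None
) -> Tuple[ExpressionMatrix, SampleDesign]:
    """Two-condition expression matrix from the one-factor model."""
    na, nb = spec.samples_per_condition
    samples_a = [f"{spec.condition_a}{i:02d}" for i in range(1, na + 1)]
    samples_b = [f"{spec.condition_b}{i:02d}" for i in range(1, nb + 1)]
    rng = _rng(spec, 2)
    values = rng.standard_normal((spec.n_genes, na + nb))
    genes = spec.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    col_slices = {spec.condition_a: slice(0, na), spec.condition_b: slice(na, na + nb)}
    for t in spec.planted_terms:
        members = [gene_pos[g] for g in spec.members_of(t)]
        shift = t.effective_shift(spec.sdeg_shift)
        for cond, rho in ((spec.condition_a, t.rho_a), (spec.condition_b, t.rho_b)):
            cols = col_slices[cond]
            n_cols = cols.stop - cols.start
            factor = rng.standard_normal(n_cols)
            eps = rng.standard_normal((len(members), n_cols))
            block = (np.sqrt(rho) * factor[None, :]
                     + np.sqrt(1.0 - rho) * spec.noise_sd * eps)
            if shift and cond == spec.condition_a:
                block = block + shift
            values[members, cols] = block
    df = pd.DataFrame(values, index=genes, columns=samples_a + samples_b)
    assignment = {s: spec.condition_a for s in samples_a}
    assignment.update({s: spec.condition_b for s in samples_b})
    design = SampleDesign(assignment, positive_condition=spec.condition_a)
    return ExpressionMatrix(df), design


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """All pipeline inputs for one spec, in memory."""
    pin, forced = generate_pin(spec)
    dag, ann = generate_annotations(spec)
    expr, design = generate_expression(spec, pin)
    return SyntheticDataset(spec=spec, expr=expr, design=design, pin=pin,
                            dag=dag, ann=ann, n_forced_edges=forced)


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A spec with no planted structure (pure null) at the default scale."""
    defaults = dict(planted_terms=(), sdeg_shift=0.0, seed=seed)
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def activity_shift_spec(seed: int = 0, delta: float = 1.5,
                        n_members: int = 20, **overrides) -> SyntheticSpec:
    """Classification-power fixture: one module with a pure activity shift.

    The planted module's genes each gain ``delta`` in the positive
    condition but share no co-expression factor, so the per-sample
    activity score isolates the shift (the quantity classification is
    meant to detect).
    """
    defaults = dict(
        planted_terms=(PlantedTerm("GO:9000001", n_members, 0.0, 0.0,
                                   shift=delta),),
        seed=seed)
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


# ---------------------------------------------------------------------------
# On-disk fixture bundles
# ---------------------------------------------------------------------------

_FILES = ("expression.tsv", "design.tsv", "pin.tsv", "ontology.obo",
          "annotations.tsv", "manifest.json")


def write_obo(dag: OntologyDAG, path) -> None:
    """Write a minimal OBO 1.2 file (id/name/namespace/is_a stanzas)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for t in sorted(dag.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.terms[t]['name']}\n")
            fh.write(f"namespace: {dag.terms[t]['namespace']}\n")
            for p in sorted(dag.parents.get(t, ())):
                fh.write(f"is_a: {p} ! {dag.terms[p]['name']}\n")


def generate_fixture(spec: SyntheticSpec, outdir, overwrite: bool = False) -> Path:
    """Write the full input bundle (5 data files + manifest) to ``outdir``.

    The manifest records the spec, so the bundle can be regenerated
    identically.  Existing bundle files are an error unless
    ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not overwrite:
        clashes = [f for f in _FILES if (outdir / f).exists()]
        if clashes:
            raise FileExistsError(f"{outdir}: bundle files already exist: {clashes}")
    ds = generate_dataset(spec)
    ds.expr.data.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.8g")
    with open(outdir / "design.tsv", "w") as fh:
        for s in ds.expr.sample_ids:
            fh.write(f"{s}\t{ds.design.assignment[s]}\n")
    with open(outdir / "pin.tsv", "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in ds.pin.edges()):
            fh.write(f"{u}\t{v}\n")
    write_obo(ds.dag, outdir / "ontology.obo")
    with open(outdir / "annotations.tsv", "w") as fh:
        for g in sorted(ds.ann.direct):
            for t in sorted(ds.ann.direct[g]):
                fh.write(f"{g}\t{t}\n")
    manifest = {
        "spec": _spec_to_dict(spec),
        "seed": spec.seed,
        "files": list(_FILES[:-1]),
        "n_forced_edges": ds.n_forced_edges,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["planted_terms"] = [dataclasses.asdict(t) for t in spec.planted_terms]
    d["samples_per_condition"] = list(spec.samples_per_condition)
    return d


def spec_from_manifest(path) -> SyntheticSpec:
    """Rebuild the spec recorded in a bundle manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    d = dict(manifest["spec"])
    d["planted_terms"] = tuple(PlantedTerm(**t) for t in d["planted_terms"])
    d["samples_per_condition"] = tuple(d["samples_per_condition"])
    return SyntheticSpec(**d)
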