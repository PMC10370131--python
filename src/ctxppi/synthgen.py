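"""Synthetic data with the statistical structure the method assumes.

Three generators emulate the pipeline's inputs at desk scale:

* ``gen_expression`` — a cell-type-structured count atlas.  Each cell
  type has a planted set of activated genes whose negative-binomial mean
  is ``activation_fold`` times the baseline inside the type; the planted
  map is returned so recovery can be scored exactly.
* ``gen_multiscale_graph`` — per-context stochastic-block-model protein
  networks with a configurable fraction of protein names shared across
  contexts, a random tissue tree, cell-tissue attachments and a sparse
  ligand-receptor table linking contexts that sit under the same subtree.
* ``gen_target_labels`` — positive druggability labels concentrated in
  one planted community of chosen contexts, negatives uniform elsewhere.

All draws flow from a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as _io
from .netcon import ContextNetwork, ExpressionMatrix, Metagraph, canonical_edge

__all__ = [
    "SyntheticAtlasSpec",
    "SyntheticGraphSpec",
    "SyntheticAtlas",
    "SyntheticMultiScaleGraph",
    "TargetLabelTable",
    "gen_expression",
    "gen_multiscale_graph",
    "gen_target_labels",
]


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Shape and noise of the synthetic count atlas.

    Defaults are sized so every downstream stage (gene calling, network
    induction, pretraining) runs in seconds while keeping realistic
    overdispersion: 5 cell types x 60 cells, 400 genes, 40 planted genes
    per type with a 6-fold activation over a baseline mean of 1 count,
    and negative-binomial dispersion 2 (variance well above the mean).
    """

    n_cell_types: int = 5
    cells_per_type: int = 60
    n_genes: int = 400
    activated_genes_per_type: int = 40
    baseline_mean: float = 1.0
    activation_fold: float = 6.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cell_types", "cells_per_type", "n_genes", "activated_genes_per_type"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.activation_fold <= 1:
            raise ValueError("activation_fold must be > 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be nonnegative")


@dataclass(frozen=True)
class SyntheticGraphSpec:
    """Shape of the synthetic multi-scale graph.

    Context networks are stochastic block models whose planted blocks
    stand in for functional modules; the default edge probabilities
    (0.15 within, 0.02 between) give sparse but connected networks at
    200 proteins.  The tissue tree is random with the stated depth and
    a branching factor of 3, giving 13 tissues at depth 3.
    """

    n_contexts: int = 3
    proteins_per_context: int = 200
    shared_fraction: float = 0.5
    within_block_p: float = 0.15
    between_block_p: float = 0.02
    n_blocks: int = 4
    tissue_tree_depth: int = 3
    branching: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shared_fraction <= 1:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.within_block_p <= self.between_block_p:
            raise ValueError("within_block_p must exceed between_block_p")
        for name in ("n_contexts", "proteins_per_context", "n_blocks", "tissue_tree_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticAtlas:
    expression: ExpressionMatrix
    planted: dict[str, set[str]]  # cell type -> activated gene set

    def to_dir(self, outdir) -> None:
        self.expression.to_dir(outdir)
        rows = [(ct, g) for ct, genes in sorted(self.planted.items()) for g in sorted(genes)]
        pd.DataFrame(rows, columns=["cell_type", "gene"]).to_csv(
            os.path.join(outdir, "planted_genes.tsv"), sep="\t", index=False
        )


@dataclass
class SyntheticMultiScaleGraph:
    contexts: list[ContextNetwork]
    metagraph: Metagraph
    planted_blocks: dict[str, int]  # protein -> block index (shared across contexts)
    context_tissue: dict[str, str]  # context id -> leaf tissue
    lr_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    ontology_edges: list[tuple[str, str]] = field(default_factory=list)

    def to_dir(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        for net in self.contexts:
            net.to_tsv(os.path.join(outdir, f"{net.context_id}.edges.tsv"))
        self.metagraph.to_tsv(os.path.join(outdir, "metagraph.tsv"))
        _io.write_edge_list(
            os.path.join(outdir, "ontology.tsv"), self.ontology_edges, ("child", "parent")
        )
        self.lr_table.to_csv(os.path.join(outdir, "lr_table.tsv"), sep="\t", index=False)


@dataclass
class TargetLabelTable:
    labels: dict[str, int]  # protein -> {0, 1}
    planted_context: str
    planted_block: int

    def to_tsv(self, path) -> None:
        _io.write_labels(path, self.labels)


def gen_expression(spec: SyntheticAtlasSpec) -> SyntheticAtlas:
    """Draw the synthetic count atlas described by `spec`.

    Planted gene sets are disjoint across cell types, which requires
    ``activated_genes_per_type * n_cell_types <= n_genes``.  Counts are
    negative-binomial with shape `dispersion` so the rank-sum screen
    faces realistic overdispersion rather than Poisson noise.
    """
    if spec.activated_genes_per_type * spec.n_cell_types > spec.n_genes:
        raise ValueError(
            "cannot plant disjoint activated sets: "
            f"{spec.activated_genes_per_type} x {spec.n_cell_types} > {spec.n_genes} genes"
        )
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    types = [f"ct{i}" for i in range(spec.n_cell_types)]
    perm = rng.permutation(spec.n_genes)
    planted: dict[str, set[str]] = {}
    mean = np.full((spec.n_genes, spec.n_cell_types), spec.baseline_mean)
    for j, ct in enumerate(types):
        idx = perm[j * spec.activated_genes_per_type : (j + 1) * spec.activated_genes_per_type]
        planted[ct] = {genes[i] for i in idx}
        # With baseline_mean=0 (the infinite-fold degenerate case) the fold
        # itself serves as the planted mean, so planted genes stay expressed
        # in their type while being exactly zero everywhere else.
        mean[idx, j] = (
            spec.baseline_mean * spec.activation_fold
            if spec.baseline_mean > 0
            else spec.activation_fold
        )

    n_cells = spec.n_cell_types * spec.cells_per_type
    counts = np.empty((spec.n_genes, n_cells), dtype=np.int64)
    cell_type, tissue, cell_ids = [], [], []
    for j, ct in enumerate(types):
        cols = slice(j * spec.cells_per_type, (j + 1) * spec.cells_per_type)
        m = mean[:, [j]]
        # NB parametrized by shape r and success prob p = r / (r + mean).
        p = spec.dispersion / (spec.dispersion + np.maximum(m, 1e-12))
        draw = rng.negative_binomial(spec.dispersion, p, size=(spec.n_genes, spec.cells_per_type))
        draw[(m == 0).ravel(), :] = 0
        counts[:, cols] = draw
        cell_type += [ct] * spec.cells_per_type
        tissue += [f"tissue_{ct}"] * spec.cells_per_type
        cell_ids += [f"{ct}_cell{i:03d}" for i in range(spec.cells_per_type)]

    expr = ExpressionMatrix(
        values=sp.csr_matrix(counts),
        gene_ids=genes,
        cell_ids=cell_ids,
        cell_type=cell_type,
        tissue=tissue,
    )
    return SyntheticAtlas(expression=expr, planted=planted)


def _random_tree(depth: int, branching: int, rng: np.random.Generator) -> nx.DiGraph:
    """Random rooted tree: each node at depth k picks a uniform parent at k-1.

    Level widths grow linearly (branching, branching+1, ...), giving 13
    tissues at the default depth 3 / branching 3 — large enough for
    lowest-common-ancestor distances of varied magnitude without dwarfing
    the handful of cell-type contexts attached to the leaves.
    """
    tree = nx.DiGraph()
    tree.add_node("T_root", depth=0)
    levels = [["T_root"]]
    counter = 0
    for d in range(1, depth + 1):
        n_level = branching + (d - 1)
        level = []
        for _ in range(n_level):
            name = f"T{counter:03d}"
            counter += 1
            parent = levels[d - 1][rng.integers(len(levels[d - 1]))]
            tree.add_node(name, depth=d)
            tree.add_edge(name, parent)  # child -> parent
            level.append(name)
        levels.append(level)
    return tree


def gen_multiscale_graph(spec: SyntheticGraphSpec) -> SyntheticMultiScaleGraph:
    """Draw SBM context networks, a tissue tree and an LR table.

    A ``shared_fraction`` of each context's protein names comes from a
    global shared pool; a shared protein keeps the same planted block
    index in every context, so cross-context similarity structure is
    well defined.  Each context attaches to one leaf tissue; pairs of
    contexts under a common depth-1 subtree get a significant LR row.
    """
    rng = np.random.default_rng(spec.seed)
    n_shared = int(round(spec.shared_fraction * spec.proteins_per_context))
    # Each context draws its shared proteins from a common pool of
    # `proteins_per_context` names, so a pool protein lands in a varying
    # number of contexts and the context-multiplicity axis is non-degenerate.
    pool_size = spec.proteins_per_context if n_shared else 0
    shared_pool = [f"P_sh{i:04d}" for i in range(pool_size)]
    block_of: dict[str, int] = {
        p: int(rng.integers(spec.n_blocks)) for p in shared_pool
    }

    contexts = []
    context_ids = [f"C{i}" for i in range(spec.n_contexts)]
    for cid in context_ids:
        shared = (
            sorted(rng.choice(shared_pool, size=n_shared, replace=False))
            if n_shared
            else []
        )
        private = [
            f"P_{cid}_{i:04d}" for i in range(spec.proteins_per_context - n_shared)
        ]
        for p in private:
            block_of[p] = int(rng.integers(spec.n_blocks))
        proteins = shared + private
        blocks = np.array([block_of[p] for p in proteins])
        n = len(proteins)
        # Upper-triangular Bernoulli draw at block-dependent probability.
        iu, ju = np.triu_indices(n, k=1)
        same = blocks[iu] == blocks[ju]
        p_edge = np.where(same, spec.within_block_p, spec.between_block_p)
        keep = rng.random(p_edge.size) < p_edge
        g = nx.Graph()
        g.add_nodes_from(proteins)
        g.add_edges_from(
            (proteins[i], proteins[j]) for i, j in zip(iu[keep], ju[keep])
        )
        component = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        sub = g.subgraph(component)
        contexts.append(
            ContextNetwork(
                context_id=cid,
                nodes=sorted(component),
                edges={canonical_edge(u, v) for u, v in sub.edges()},
            )
        )

    tree = _random_tree(spec.tissue_tree_depth, spec.branching, rng)
    leaves = sorted(n for n in tree.nodes if tree.nodes[n]["depth"] == spec.tissue_tree_depth)
    leaf_of = {
        cid: leaves[int(rng.integers(len(leaves)))] for cid in context_ids
    }
    ontology_edges = sorted(tree.edges())  # (child, parent)

    # Significant LR rows among context pairs sharing a depth-1 ancestor.
    def top_ancestor(leaf):
        node = leaf
        while tree.nodes[node]["depth"] > 1:
            node = next(iter(tree.successors(node)))
        return node

    lr_rows = []
    for i, a in enumerate(context_ids):
        for b in context_ids[i + 1 :]:
            if top_ancestor(leaf_of[a]) == top_ancestor(leaf_of[b]):
                lr_rows.append((a, b, float(rng.uniform(0, 5e-4))))
            else:
                lr_rows.append((a, b, float(rng.uniform(0.01, 1.0))))
    lr_table = pd.DataFrame(lr_rows, columns=["cell_type_a", "cell_type_b", "p_value"])

    cc_edges = {
        canonical_edge(a, b)
        for a, b, p in lr_rows
        if p < 0.001
    }
    tt_edges = {canonical_edge(c, p) for c, p in ontology_edges}
    metagraph = Metagraph(
        cell_types=context_ids,
        tissues=sorted(tree.nodes),
        cc_edges=cc_edges,
        ct_edges={(cid, leaf_of[cid]) for cid in context_ids},
        tt_edges=tt_edges,
    )
    retained = {p for net in contexts for p in net.nodes}
    planted = {p: b for p, b in block_of.items() if p in retained}
    return SyntheticMultiScaleGraph(
        contexts=contexts,
        metagraph=metagraph,
        planted_blocks=planted,
        context_tissue=leaf_of,
        lr_table=lr_table,
        ontology_edges=ontology_edges,
    )


def gen_target_labels(
    graph: SyntheticMultiScaleGraph,
    planted_contexts: list[str],
    n_pos: int = 20,
    n_neg: int = 60,
    seed: int = 0,
    block: int | None = None,
    purity: float = 0.9,
) -> TargetLabelTable:
    """Plant positive target labels in one community of chosen contexts.

    A fraction `purity` of positives comes from the planted block
    (default: block 0) restricted to proteins present in
    `planted_contexts`; the rest of the positives, and all negatives,
    are drawn uniformly from the remaining proteins.  Every labeled
    protein appears in at least one context network by construction.
    """
    if not planted_contexts:
        raise ValueError("planted_contexts must be nonempty")
    rng = np.random.default_rng(seed)
    block = 0 if block is None else block
    nets = {net.context_id: set(net.nodes) for net in graph.contexts}
    in_planted = sorted(
        p
        for cid in planted_contexts
        for p in nets[cid]
        if graph.planted_blocks.get(p) == block
    )
    all_proteins = sorted({p for nodes in nets.values() for p in nodes})
    if n_pos + n_neg > len(all_proteins):
        raise ValueError("n_pos + n_neg exceeds number of available proteins")

    n_from_block = min(int(round(purity * n_pos)), len(in_planted))
    positives = list(rng.choice(in_planted, size=n_from_block, replace=False)) if n_from_block else []
    rest_pool = sorted(set(all_proteins) - set(positives))
    extra = n_pos - len(positives)
    if extra:
        positives += list(rng.choice(rest_pool, size=extra, replace=False))
    neg_pool = sorted(set(all_proteins) - set(positives))
    negatives = list(rng.choice(neg_pool, size=n_neg, replace=False)) if n_neg else []

    labels = {str(p): 1 for p in positives}
    labels.update({str(p): 0 for p in negatives})
    return TargetLabelTable(
        labels=labels,
        planted_context=planted_contexts[0],
        planted_block=block,
    )
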