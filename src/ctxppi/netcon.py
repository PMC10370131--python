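"""Construction of cell-type-specific protein networks and the metagraph.

Starting from a single-cell expression matrix, a reference protein
interaction network, a ligand-receptor significance table and a tissue
ontology, this module (i) calls the genes activated in each cell type by
a repeated subsampled Wilcoxon rank-sum screen, (ii) induces each cell
type's protein network on the reference interactome and keeps the
largest connected component, and (iii) assembles the metagraph of
cell-cell communication, cell-tissue provenance and the ancestor-closed
tissue hierarchy.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from . import io as _io

__all__ = [
    "ExpressionMatrix",
    "ReferenceNetwork",
    "ContextNetwork",
    "Metagraph",
    "NetworkRejection",
    "passes_frequency",
    "call_activated_genes",
    "build_context_network",
    "build_metagraph",
]


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells counts with per-cell type and tissue labels."""

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_type: list[str]
    tissue: list[str]

    def __post_init__(self):
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        for name in ("cell_ids", "cell_type", "tissue"):
            if len(getattr(self, name)) != n_cells:
                raise ValueError(f"{name} length does not match matrix columns")

    @classmethod
    def from_dir(cls, indir) -> "ExpressionMatrix":
        matrix, genes, cells = _io.read_expression(indir)
        return cls(
            values=matrix,
            gene_ids=genes,
            cell_ids=cells["cell_id"].tolist(),
            cell_type=cells["cell_type"].tolist(),
            tissue=cells["tissue"].tolist(),
        )

    def to_dir(self, outdir) -> None:
        meta = pd.DataFrame(
            {"cell_id": self.cell_ids, "cell_type": self.cell_type, "tissue": self.tissue}
        )
        _io.write_expression(outdir, self.values, self.gene_ids, meta)


@dataclass
class ReferenceNetwork:
    """Undirected reference interactome; edges stored canonically."""

    edges: set[tuple[str, str]]

    def __post_init__(self):
        clean = set()
        for u, v in self.edges:
            if u == v:
                continue
            clean.add(canonical_edge(u, v))
        self.edges = clean

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    @classmethod
    def from_tsv(cls, path) -> "ReferenceNetwork":
        return cls(edges=set(_io.read_edge_list(path)))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass
class ContextNetwork:
    """One cell type's protein interaction subgraph (connected)."""

    context_id: str
    nodes: list[str]
    edges: set[tuple[str, str]]

    def __post_init__(self):
        self.edges = {canonical_edge(u, v) for u, v in self.edges if u != v}
        self.nodes = sorted(set(self.nodes))
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u},{v}) has endpoint outside node set")

    def is_connected(self) -> bool:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return nx.is_connected(g)

    def to_tsv(self, path) -> None:
        _io.write_edge_list(path, self.edges)

    @classmethod
    def from_tsv(cls, path, context_id: str) -> "ContextNetwork":
        edges = set(_io.read_edge_list(path))
        nodes = sorted({n for e in edges for n in e})
        return cls(context_id=context_id, nodes=nodes, edges=edges)


@dataclass
class Metagraph:
    """Typed graph over cell-type and tissue nodes.

    cc edges join communicating cell types, ct edges join a cell type to
    the tissue it was sampled from, and tt edges are parent-child links
    of the ancestor-closed tissue hierarchy.
    """

    cell_types: list[str]
    tissues: list[str]
    cc_edges: set[tuple[str, str]] = field(default_factory=set)
    ct_edges: set[tuple[str, str]] = field(default_factory=set)
    tt_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        self.cell_types = sorted(set(self.cell_types))
        self.tissues = sorted(set(self.tissues))
        cset, tset = set(self.cell_types), set(self.tissues)
        self.cc_edges = {canonical_edge(*e) for e in self.cc_edges}
        self.tt_edges = {canonical_edge(*e) for e in self.tt_edges}
        self.ct_edges = set(self.ct_edges)
        for c, t in self.ct_edges:
            if c not in cset or t not in tset:
                raise ValueError(f"ct edge ({c},{t}) endpoints not typed correctly")

    def to_tsv(self, path) -> None:
        rows = (
            [(u, v, "cc") for u, v in sorted(self.cc_edges)]
            + [(c, t, "ct") for c, t in sorted(self.ct_edges)]
            + [(u, v, "tt") for u, v in sorted(self.tt_edges)]
        )
        pd.DataFrame(rows, columns=["src", "dst", "edge_type"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "Metagraph":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cc = {(r.src, r.dst) for r in df.itertuples() if r.edge_type == "cc"}
        ct = {(r.src, r.dst) for r in df.itertuples() if r.edge_type == "ct"}
        tt = {(r.src, r.dst) for r in df.itertuples() if r.edge_type == "tt"}
        cells = sorted({c for c, _ in ct} | {n for e in cc for n in e})
        tissues = sorted({t for _, t in ct} | {n for e in tt for n in e})
        return cls(cell_types=cells, tissues=tissues, cc_edges=cc, ct_edges=ct, tt_edges=tt)


@dataclass
class NetworkRejection:
    """A context whose induced network did not meet quality criteria."""

    context_id: str
    reason: str


def _ranksum_z(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorized one-sided Wilcoxon rank-sum z per gene (rows of `values`).

    Positive z means higher expression inside the group.  No tie
    correction, matching the plain large-sample rank-sum statistic.
    """
    n1 = int(in_group.sum())
    n2 = values.shape[1] - n1
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, in_group].sum(axis=1)
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    return (r1 - mu) / sigma


def passes_frequency(count: int, n_iter: int, freq_threshold: float) -> bool:
    """A gene is kept when it appears in at least `freq_threshold` of the
    iterations (e.g. 89/100 fails a 0.9 threshold; 90/100 passes)."""
    return count > 0 and count >= freq_threshold * n_iter - 1e-9


def call_activated_genes(
    expr: ExpressionMatrix,
    context: str,
    top_k: int = 4000,
    n_iter: int = 10,
    freq_threshold: float = 0.9,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> list[str]:
    """Genes with significantly higher expression in `context` than the rest.

    Each iteration subsamples `subsample_fraction` of all cells without
    replacement, ranks genes by the one-sided Wilcoxon rank-sum statistic
    (context cells vs all other cells in the subsample) and keeps the
    `top_k` most activated.  Genes appearing in at least `freq_threshold`
    of iterations are returned, ordered by mean rank (ties by mean
    statistic, then symbol).
    """
    if not 0 < freq_threshold <= 1:
        raise ValueError("freq_threshold must be in (0, 1]")
    labels = np.asarray(expr.cell_type)
    members = np.flatnonzero(labels == context)
    if members.size < 2:
        raise ValueError(f"context {context!r} has fewer than 2 cells")
    n_genes, n_cells = expr.values.shape
    if top_k > n_genes:
        warnings.warn(f"top_k={top_k} exceeds n_genes={n_genes}; clamping")
        top_k = n_genes
    dense = np.asarray(expr.values.todense(), dtype=np.float64)
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_fraction * n_cells)))
    genes = np.asarray(expr.gene_ids)

    counts = np.zeros(n_genes, dtype=np.int64)
    rank_sums = np.zeros(n_genes, dtype=np.float64)
    stat_sums = np.zeros(n_genes, dtype=np.float64)
    for _ in range(n_iter):
        # Cells are chosen by sorted id so the draw is invariant to column order.
        order = np.argsort(np.asarray(expr.cell_ids))
        chosen = np.sort(order[rng.choice(n_cells, size=n_sub, replace=False)])
        in_group = labels[chosen] == context
        if in_group.sum() < 1 or (~in_group).sum() < 1:
            continue
        z = _ranksum_z(dense[:, chosen], in_group)
        # Rank genes by decreasing statistic; deterministic tie-break by symbol.
        order_idx = np.lexsort((genes, -z))
        top = order_idx[:top_k]
        counts[top] += 1
        rank_sums[top] += np.arange(top_k)
        stat_sums[top] += z[top]

    keep = np.asarray([passes_frequency(c, n_iter, freq_threshold) for c in counts])
    idx = np.flatnonzero(keep)
    mean_rank = rank_sums[idx] / counts[idx]
    mean_stat = stat_sums[idx] / counts[idx]
    order_idx = np.lexsort((genes[idx], -mean_stat, mean_rank))
    return [genes[idx[i]] for i in order_idx]


def build_context_network(
    genes: list[str], ref: ReferenceNetwork, min_size: int = 1000, context_id: str = ""
) -> ContextNetwork | NetworkRejection:
    """Induce the reference network on `genes`; keep the largest component.

    Returns a NetworkRejection when no gene maps into the reference
    network or the largest component falls below `min_size` proteins.
    """
    if not genes:
        raise ValueError("gene list is empty")
    gene_set = set(genes)
    sub = nx.Graph()
    sub.add_nodes_from(gene_set & ref.nodes)
    sub.add_edges_from(
        (u, v) for u, v in ref.edges if u in gene_set and v in gene_set
    )
    if sub.number_of_nodes() == 0:
        return NetworkRejection(context_id, "no overlap")
    component = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
    if len(component) < min_size:
        return NetworkRejection(
            context_id, f"largest component has {len(component)} < {min_size} proteins"
        )
    g = sub.subgraph(component)
    return ContextNetwork(
        context_id=context_id,
        nodes=sorted(component),
        edges={canonical_edge(u, v) for u, v in g.edges()},
    )


def build_metagraph(
    lr_table: pd.DataFrame,
    cell_meta: pd.DataFrame,
    ontology_edges: list[tuple[str, str]],
    p_cutoff: float = 0.001,
) -> Metagraph:
    """Assemble the cell/tissue metagraph.

    A cc edge joins two cell types with at least one ligand-receptor row
    below `p_cutoff`; a ct edge joins each cell type to the tissue(s) its
    cells were sampled from; the tissue node set is the sampled tissues
    closed under ancestors up to the ontology root, with the parent-child
    links among retained tissues as tt edges.  `ontology_edges` are
    (child, parent) pairs forming a rooted tree or DAG.
    """
    parents: dict[str, set[str]] = {}
    onto = nx.DiGraph()
    for child, parent in ontology_edges:
        onto.add_edge(child, parent)
        parents.setdefault(child, set()).add(parent)
    if onto.number_of_nodes() and not nx.is_directed_acyclic_graph(onto):
        raise ValueError("cycle in tissue ontology")

    cell_types = sorted(set(cell_meta["cell_type"]))
    ct_edges = set()
    sampled_tissues = set()
    known = set(onto.nodes)
    for ct, tissue in (
        cell_meta[["cell_type", "tissue"]].drop_duplicates().itertuples(index=False)
    ):
        if known and tissue not in known:
            raise ValueError(f"cell type {ct!r} maps to unknown tissue {tissue!r}")
        ct_edges.add((ct, tissue))
        sampled_tissues.add(tissue)

    # Ancestor closure up to the root(s).
    tissues = set(sampled_tissues)
    frontier = list(sampled_tissues)
    while frontier:
        node = frontier.pop()
        for parent in parents.get(node, ()):
            if parent not in tissues:
                tissues.add(parent)
                frontier.append(parent)
    tt_edges = {
        canonical_edge(child, parent)
        for child, ps in parents.items()
        if child in tissues
        for parent in ps
        if parent in tissues
    }

    cc_edges = set()
    if len(lr_table):
        sig = lr_table[lr_table["p_value"].astype(float) < p_cutoff]
        for a, b in sig[["cell_type_a", "cell_type_b"]].itertuples(index=False):
            if a in cell_types and b in cell_types and a != b:
                cc_edges.add(canonical_edge(a, b))

    return Metagraph(
        cell_types=cell_types,
        tissues=sorted(tissues),
        cc_edges=cc_edges,
        ct_edges=ct_edges,
        tt_edges=tt_edges,
    )


def write_context_networks(networks: list[ContextNetwork], outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    for net in networks:
        net.to_tsv(os.path.join(outdir, f"{net.context_id}.edges.tsv"))
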