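"""Assembly of the training-ready multi-scale graph.

A protein appearing in several context networks becomes several nodes —
one per (protein, context) pair — that share a single initial feature
vector, preserving protein identity while letting message passing
specialize each copy.  Protein-protein edges are split per context into
train/validation/test positives with matched non-edge negatives; the
metagraph is never split.  Message passing only ever sees the train
adjacency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .netcon import ContextNetwork, Metagraph

__all__ = ["MultiScaleGraph", "EdgeSplit", "init_protein_features", "split_edges", "sample_negatives"]


@dataclass
class MultiScaleGraph:
    """Union of context networks and metagraph with integer node ids.

    Protein node ids are global and contiguous, grouped by context; each
    node also carries the index of its protein identity into the shared
    feature matrix.
    """

    contexts: list[ContextNetwork]
    metagraph: Metagraph
    protein_index: dict[tuple[str, str], int] = field(init=False)  # (protein, context) -> id
    identities: list[str] = field(init=False)
    identity_of_node: np.ndarray = field(init=False)
    context_of_node: np.ndarray = field(init=False)  # context position per node
    features: np.ndarray | None = None  # per-identity rows, d_in columns

    def __post_init__(self):
        self.identities = sorted({p for net in self.contexts for p in net.nodes})
        ident_pos = {p: i for i, p in enumerate(self.identities)}
        self.protein_index = {}
        ident_of, ctx_of = [], []
        for ci, net in enumerate(self.contexts):
            for p in net.nodes:
                self.protein_index[(p, net.context_id)] = len(ident_of)
                ident_of.append(ident_pos[p])
                ctx_of.append(ci)
        self.identity_of_node = np.asarray(ident_of, dtype=np.intp)
        self.context_of_node = np.asarray(ctx_of, dtype=np.intp)

    @property
    def n_nodes(self) -> int:
        return len(self.identity_of_node)

    @property
    def context_ids(self) -> list[str]:
        return [net.context_id for net in self.contexts]

    def context_nodes(self, context_id: str) -> np.ndarray:
        ci = self.context_ids.index(context_id)
        return np.flatnonzero(self.context_of_node == ci)

    def edge_array(self, net: ContextNetwork) -> np.ndarray:
        """Edges of one context as an (m, 2) array of global node ids."""
        cid = net.context_id
        return np.asarray(
            [[self.protein_index[(u, cid)], self.protein_index[(v, cid)]] for u, v in sorted(net.edges)],
            dtype=np.intp,
        ).reshape(-1, 2)


def init_protein_features(graph: MultiScaleGraph, d_in: int = 1024, seed: int = 0) -> np.ndarray:
    """One standard-normal vector per protein identity, shared across contexts."""
    if d_in < 1:
        raise ValueError("d_in must be >= 1")
    rng = np.random.default_rng(seed)
    graph.features = rng.standard_normal((len(graph.identities), d_in))
    return graph.features


@dataclass
class EdgeSplit:
    """Per-context partition of positive pp edges plus frozen negatives.

    ``positives[cid][name]`` and ``negatives[cid][name]`` are (m, 2)
    arrays of global node ids for name in {train, val, test}; negatives
    for val/test are frozen so reported metrics are stable, while train
    negatives are resampled each epoch by the trainer.
    """

    positives: dict[str, dict[str, np.ndarray]]
    negatives: dict[str, dict[str, np.ndarray]]

    def to_tsv(self, path, graph: MultiScaleGraph) -> None:
        id_to_name = {v: k for k, v in graph.protein_index.items()}
        rows = []
        for cid, splits in self.positives.items():
            for split, arr in splits.items():
                for u, v in arr:
                    rows.append((id_to_name[u][0], id_to_name[v][0], cid, split, 1))
        for cid, splits in self.negatives.items():
            for split, arr in splits.items():
                for u, v in arr:
                    rows.append((id_to_name[u][0], id_to_name[v][0], cid, split, 0))
        pd.DataFrame(rows, columns=["src", "dst", "context", "split", "label"]).to_csv(
            path, sep="\t", index=False
        )


def split_edges(
    graph: MultiScaleGraph,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> EdgeSplit:
    """Uniform random train/val/test split of pp edges, per context.

    Counts follow the ratios with largest-remainder rounding, so 10
    edges at (0.8, 0.1, 0.1) give exactly (8, 1, 1).  Metagraph edges
    are never split.  A context with fewer edges than split parts keeps
    everything in train with a warning.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    positives: dict[str, dict[str, np.ndarray]] = {}
    for net in graph.contexts:
        edges = graph.edge_array(net)
        m = len(edges)
        if m < 3:
            warnings.warn(f"context {net.context_id}: only {m} edges; all assigned to train")
            positives[net.context_id] = {
                "train": edges,
                "val": edges[:0],
                "test": edges[:0],
            }
            continue
        perm = rng.permutation(m)
        raw = np.asarray(ratios) * m
        counts = np.floor(raw).astype(int)
        for _ in range(m - counts.sum()):  # largest remainders
            counts[np.argmax(raw - counts)] += 1
        n_tr, n_va, _ = counts
        positives[net.context_id] = {
            "train": edges[np.sort(perm[:n_tr])],
            "val": edges[np.sort(perm[n_tr : n_tr + n_va])],
            "test": edges[np.sort(perm[n_tr + n_va :])],
        }
    split = EdgeSplit(positives=positives, negatives={})
    split.negatives = {
        cid: {
            name: sample_negatives(graph, cid, arr, seed=seed + 1 + i)
            for i, (name, arr) in enumerate(splits.items())
        }
        for cid, splits in positives.items()
    }
    return split


def sample_negatives(
    graph: MultiScaleGraph,
    context_id: str,
    positives: np.ndarray,
    ratio: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Corrupt each positive (u, v) into `ratio` non-edges (u, w) by rejection.

    `w` is drawn within the same context and rejected while (u, w) is an
    observed edge or a self-pair.  Raises if the context network is
    complete (no negative exists).
    """
    net = next(n for n in graph.contexts if n.context_id == context_id)
    nodes = graph.context_nodes(context_id)
    n = len(nodes)
    if n * (n - 1) // 2 == len(net.edges):
        raise ValueError(f"context {context_id}: graph is complete, no negatives available")
    edge_set = set()
    for u, v in graph.edge_array(net):
        edge_set.add((u, v))
        edge_set.add((v, u))
    rng = np.random.default_rng(seed)

    def draw_for(u):
        for _ in range(100):  # rejection; falls through for saturated nodes
            w = nodes[rng.integers(n)]
            if w != u and (u, w) not in edge_set:
                return (u, w)
        candidates = [w for w in nodes if w != u and (u, w) not in edge_set]
        if not candidates:
            return None
        return (u, candidates[rng.integers(len(candidates))])

    out = np.empty((len(positives) * ratio, 2), dtype=np.intp)
    k = 0
    for u, v in positives:
        for _ in range(ratio):
            pair = draw_for(u)
            if pair is None:  # u saturated: corrupt the other endpoint
                pair = draw_for(v)
                if pair is None:
                    raise ValueError(
                        f"context {context_id}: no non-edge available for ({u},{v})"
                    )
            out[k] = pair
            k += 1
    return out


def metagraph_indices(graph: MultiScaleGraph):
    """Integer-id views of the metagraph: (cell ids, tissue ids, typed edges).

    Returns a dict with cell/tissue name lists and (m, 2) arrays for cc
    (cell, cell), ct (cell, tissue) and tt (tissue, tissue) edges.
    """
    mg = graph.metagraph
    cpos = {c: i for i, c in enumerate(mg.cell_types)}
    tpos = {t: i for i, t in enumerate(mg.tissues)}
    as_arr = lambda rows: np.asarray(rows, dtype=np.intp).reshape(-1, 2)
    return {
        "cells": mg.cell_types,
        "tissues": mg.tissues,
        "cc": as_arr([[cpos[a], cpos[b]] for a, b in sorted(mg.cc_edges)]),
        "ct": as_arr([[cpos[c], tpos[t]] for c, t in sorted(mg.ct_edges)]),
        "tt": as_arr([[tpos[a], tpos[b]] for a, b in sorted(mg.tt_edges)]),
    }


def sample_metagraph_negatives(n_a: int, n_b: int, edges: np.ndarray, same_class: bool, rng) -> np.ndarray:
    """1:1 non-edge negatives within a node-type pair of the metagraph.

    For same-class relations (cc, tt) both endpoints come from one node
    set and non-edges are undirected; for cross-class relations (ct, tc)
    the second endpoint is corrupted.  Falls back to fewer negatives when
    the bipartite/unipartite pair is saturated.
    """
    existing = {tuple(e) for e in edges}
    if same_class:
        existing |= {(b, a) for a, b in edges}
    out = []
    for a, _ in edges:
        for _ in range(40):
            w = int(rng.integers(n_b))
            if same_class and w == a:
                continue
            if (a, w) not in existing:
                out.append((a, w))
                break
    return np.asarray(out, dtype=np.intp).reshape(-1, 2)
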