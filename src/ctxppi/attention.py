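"""The multi-scale attention network.

Per layer, the model (i) runs GATv2-style attention inside every
cell-type-specific protein network, (ii) pools protein embeddings into
their cell-type node through learned importances gamma, (iii) propagates
cell-type and tissue embeddings over the metagraph with per-edge-type
attention combined by shared semantic attention weights beta, and
(iv) writes the updated cell-type embedding back onto each protein,
scaled by the same gamma.  Two layers: the hidden layer concatenates
attention heads, the output layer averages them so the output width is
head-independent.  Layer normalization follows the hidden layer and
batch normalization the output layer.

The attention score for an arc u -> v with edge type r is
``a_r^T LeakyReLU(W_l h_u + W_r h_v)``, normalized by softmax over the
in-neighborhood of v (self-loops included), the GATv2 form in which the
nonlinearity precedes the attention vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Tensor,
    batch_norm,
    concat,
    dropout,
    gather,
    layer_norm,
    segment_softmax,
    segment_sum,
)
from .graphdata import MultiScaleGraph, metagraph_indices

__all__ = [
    "ModelParams",
    "EmbeddingSet",
    "init_params",
    "protein_attention_layer",
    "metagraph_node_attention",
    "semantic_attention",
    "bridge_pool",
    "init_scale_embeddings",
    "forward",
]

RELATIONS = ("cc", "ct", "tc", "tt")


@dataclass
class EmbeddingSet:
    """Embeddings for every (protein, context) node, cell type and tissue."""

    graph: MultiScaleGraph
    protein_matrix: np.ndarray  # (n_nodes, d_out)
    cell_matrix: np.ndarray  # (n_cell_types, d_out)
    tissue_matrix: np.ndarray  # (n_tissues, d_out)

    @property
    def d_out(self) -> int:
        return self.protein_matrix.shape[1]

    def protein(self, protein: str, context: str) -> np.ndarray:
        return self.protein_matrix[self.graph.protein_index[(protein, context)]]

    def cell_type(self, context: str) -> np.ndarray:
        return self.cell_matrix[self.graph.metagraph.cell_types.index(context)]

    def tissue(self, tissue: str) -> np.ndarray:
        return self.tissue_matrix[self.graph.metagraph.tissues.index(tissue)]

    def contexts_of(self, protein: str) -> list[str]:
        return [c for (p, c) in self.graph.protein_index if p == protein]


def _glorot(rng, shape):
    fan = sum(shape) if len(shape) > 1 else shape[0] * 2
    limit = np.sqrt(6.0 / fan)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


@dataclass
class ModelParams:
    """All learnable arrays, keyed by a flat module path."""

    params: dict[str, Tensor]
    d_in: int
    d_out: int
    n_heads: int
    hidden_head_dim: int
    n_layers: int = 2
    context_ids: list[str] = field(default_factory=list)

    def layer_dims(self) -> list[tuple[int, int, int]]:
        """(d_prev, head_dim, d_out) per layer; heads concatenate on hidden
        layers and average on the final layer."""
        dims = []
        d_prev = self.d_in
        hidden = self.n_heads * self.hidden_head_dim
        for l in range(self.n_layers):
            if l < self.n_layers - 1:
                dims.append((d_prev, self.hidden_head_dim, hidden))
                d_prev = hidden
            else:
                dims.append((d_prev, self.d_out, self.d_out))
        return dims

    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if v.requires_grad}


def init_params(
    graph: MultiScaleGraph,
    d_in: int = 1024,
    d_out: int = 16,
    n_heads: int = 8,
    hidden_head_dim: int = 8,
    n_layers: int = 2,
    seed: int = 0,
) -> ModelParams:
    rng = np.random.default_rng(seed)
    mp = ModelParams(
        params={},
        d_in=d_in,
        d_out=d_out,
        n_heads=n_heads,
        hidden_head_dim=hidden_head_dim,
        n_layers=n_layers,
        context_ids=graph.context_ids,
    )
    p = mp.params
    for l, (d_prev, dh, d_l) in enumerate(mp.layer_dims()):
        for cid in graph.context_ids:
            p[f"pp{l}.{cid}.Wl"] = _glorot(rng, (d_prev, n_heads * dh))
            p[f"pp{l}.{cid}.Wr"] = _glorot(rng, (d_prev, n_heads * dh))
            p[f"pp{l}.{cid}.a"] = _glorot(rng, (n_heads, dh))
        for r in RELATIONS:
            p[f"mg{l}.{r}.Wl"] = _glorot(rng, (d_prev, n_heads * dh))
            p[f"mg{l}.{r}.Wr"] = _glorot(rng, (d_prev, n_heads * dh))
            p[f"mg{l}.{r}.a"] = _glorot(rng, (n_heads, dh))
        p[f"sem{l}.s"] = _glorot(rng, (d_l,))
        p[f"sem{l}.M"] = _glorot(rng, (d_l, d_l))
        p[f"sem{l}.b"] = Tensor(np.zeros(d_l), requires_grad=True)
        p[f"bridge{l}.q"] = _glorot(rng, (d_prev,))
        for scale in ("protein", "cell", "tissue"):
            p[f"norm{l}.{scale}.g"] = Tensor(np.ones(d_l), requires_grad=True)
            p[f"norm{l}.{scale}.b"] = Tensor(np.zeros(d_l), requires_grad=True)
    return mp


def _gatv2(
    h_src: Tensor,
    h_dst: Tensor,
    arcs: np.ndarray,
    Wl: Tensor,
    Wr: Tensor,
    a: Tensor,
    n_heads: int,
    head_dim: int,
    average_heads: bool,
    return_alpha: bool = False,
):
    """One GATv2 attention pass along `arcs` (src -> dst, global over rows).

    Output row v = ReLU(sum_u alpha_{u,v} W_l h_u), heads concatenated or
    averaged.  `arcs` must give every dst node at least one incoming arc
    (guaranteed by self-loops).
    """
    n_dst = h_dst.shape[0]
    src_proj = (h_src @ Wl).reshape(-1, n_heads, head_dim)
    dst_proj = (h_dst @ Wr).reshape(-1, n_heads, head_dim)
    z = (gather(src_proj, arcs[:, 0]) + gather(dst_proj, arcs[:, 1])).leaky_relu(0.2)
    scores = (z * a.reshape(1, n_heads, head_dim)).sum(axis=2)  # (E, H)
    alpha = segment_softmax(scores, arcs[:, 1], n_dst)
    msg = gather(src_proj, arcs[:, 0])
    agg = segment_sum(alpha.reshape(-1, n_heads, 1) * msg, arcs[:, 1], n_dst)
    out = agg.relu()
    out = out.mean(axis=1) if average_heads else out.reshape(n_dst, n_heads * head_dim)
    if return_alpha:
        return out, (alpha.data, arcs[:, 1])
    return out


def _context_arcs(graph: MultiScaleGraph, net, local_offset: int) -> np.ndarray:
    """Directed arcs (both orientations of each edge) plus self-loops,
    in context-local node ids."""
    edges = graph.edge_array(net) - local_offset
    n = len(net.nodes)
    self_loops = np.stack([np.arange(n)] * 2, axis=1)
    if len(edges) == 0:
        return self_loops
    return np.concatenate([edges, edges[:, ::-1], self_loops], axis=0)


def _arcs_for_training(split_edges: np.ndarray, n: int) -> np.ndarray:
    self_loops = np.stack([np.arange(n)] * 2, axis=1)
    if len(split_edges) == 0:
        return self_loops
    return np.concatenate([split_edges, split_edges[:, ::-1], self_loops], axis=0)


def protein_attention_layer(
    h: Tensor,
    arcs: np.ndarray,
    Wl: Tensor,
    Wr: Tensor,
    a: Tensor,
    n_heads: int,
    head_dim: int,
    average_heads: bool = False,
    return_alpha: bool = False,
):
    """Protein-level attention within one context network (arcs in local ids).

    `arcs` must include a self-loop for every node; an isolated node
    without one has an empty softmax and is rejected.
    """
    covered = np.zeros(h.shape[0], dtype=bool)
    covered[np.asarray(arcs)[:, 1]] = True
    if not covered.all():
        raise ValueError("every node needs at least one incoming arc (add self-loops)")
    return _gatv2(h, h, arcs, Wl, Wr, a, n_heads, head_dim, average_heads, return_alpha)


def metagraph_node_attention(
    cell_h: Tensor,
    tissue_h: Tensor,
    meta_idx: dict,
    params: dict[str, Tensor],
    layer: int,
    n_heads: int,
    head_dim: int,
    average_heads: bool,
    return_alpha: bool = False,
):
    """Per-edge-type attention vectors for cell and tissue nodes.

    Returns ({"cc": ..., "ct": ...}, {"tt": ..., "tc": ...}) where a
    cross-class relation (ct / tc) is absent when the metagraph has no
    cell-tissue edges; same-class relations always exist via self-loops.
    """
    n_cells, n_tissues = cell_h.shape[0], tissue_h.shape[0]

    def rel(name, h_src, h_dst, arcs):
        return _gatv2(
            h_src,
            h_dst,
            arcs,
            params[f"mg{layer}.{name}.Wl"],
            params[f"mg{layer}.{name}.Wr"],
            params[f"mg{layer}.{name}.a"],
            n_heads,
            head_dim,
            average_heads,
            return_alpha,
        )

    cc = meta_idx["cc"]
    cc_arcs = np.concatenate(
        [cc, cc[:, ::-1], np.stack([np.arange(n_cells)] * 2, axis=1)], axis=0
    )
    tt = meta_idx["tt"]
    tt_arcs = np.concatenate(
        [tt, tt[:, ::-1], np.stack([np.arange(n_tissues)] * 2, axis=1)], axis=0
    )
    cell_out = {"cc": rel("cc", cell_h, cell_h, cc_arcs)}
    tissue_out = {"tt": rel("tt", tissue_h, tissue_h, tt_arcs)}

    ct = meta_idx["ct"]
    if len(ct):
        uncovered_cells = ~np.isin(np.arange(n_cells), ct[:, 0])
        if uncovered_cells.any():
            warnings.warn("some cell types have no tissue edge; ct skips them")
        # tissue -> cell arcs; only cells with a tissue neighbor receive mass
        ct_arcs = ct[:, ::-1]
        h_ct = rel("ct", tissue_h, cell_h, ct_arcs)
        tc_arcs = ct
        h_tc = rel("tc", cell_h, tissue_h, tc_arcs)
        cell_out["ct"] = h_ct
        tissue_out["tc"] = h_tc
    else:
        warnings.warn("metagraph has no cell-tissue edges; ct/tc relations skipped")
    return cell_out, tissue_out


def semantic_attention(per_type: dict[str, Tensor], s: Tensor, M: Tensor, b: Tensor):
    """Combine per-edge-type vectors with shared attention weights beta.

    m_r = sum_u s^T tanh(M h_u^r + b) over the node class; beta is the
    softmax of the m_r over the available edge types; the output is the
    per-node convex combination sum_r beta_r h^r.
    """
    if not per_type:
        raise ValueError("at least one edge type is required")
    names = sorted(per_type)
    ms = []
    for r in names:
        h = per_type[r]
        ms.append(((h @ M.transpose() + b).tanh() @ s.reshape(-1, 1)).sum())
    m_vec = concat([m.reshape(1) for m in ms], axis=0)
    shift = Tensor(np.max(m_vec.data))
    e = (m_vec - shift).exp()
    beta = e / e.sum()
    combined = None
    for i, r in enumerate(names):
        term = gather(beta, [i]).reshape(1, 1) * per_type[r]
        combined = term if combined is None else combined + term
    return combined, {r: float(beta.data[i]) for i, r in enumerate(names)}


def bridge_pool(
    protein_h: Tensor,
    context_of_node: np.ndarray,
    cell_h: Tensor,
    q: Tensor,
):
    """Learned-importance pooling of proteins into their cell type.

    gamma_{c,u} = softmax over u in V_c of q^T tanh(h_u); the cell-type
    embedding is incremented by ReLU(sum_u gamma_{c,u} h_u).  Returns the
    updated cell embeddings and gamma (one weight per protein node) for
    the write-back step.
    """
    n_cells = cell_h.shape[0]
    scores = protein_h.tanh() @ q.reshape(-1, 1)
    gamma = segment_softmax(scores.reshape(-1), context_of_node, n_cells)
    pooled = segment_sum(gamma.reshape(-1, 1) * protein_h, context_of_node, n_cells)
    return cell_h + pooled.relu(), gamma


def neighbor_average(cell_h: Tensor, tissue_prov: Tensor, meta_idx: dict) -> Tensor:
    """Mean over each tissue's metagraph neighbors.

    Neighbors are adjacent tissues (using the vectors in `tissue_prov`)
    and attached cell types (using `cell_h`).  A tissue with no
    neighbors gets a zero vector with a warning.
    """
    n_tissues = tissue_prov.shape[0]
    d = cell_h.shape[1]
    src_t, dst_t = [], []
    for a, b in meta_idx["tt"]:
        src_t += [b, a]
        dst_t += [a, b]
    src_c = [c for c, _ in meta_idx["ct"]]
    dst_c = [t for _, t in meta_idx["ct"]]
    count = np.zeros(n_tissues)
    np.add.at(count, np.asarray(dst_t + dst_c, dtype=np.intp), 1.0)
    if (count == 0).any():
        warnings.warn("tissue(s) with no metagraph neighbors: zero initial embedding")
    total = Tensor(np.zeros((n_tissues, d)))
    if src_t:
        total = total + segment_sum(gather(tissue_prov, src_t), dst_t, n_tissues)
    if src_c:
        total = total + segment_sum(gather(cell_h, src_c), dst_c, n_tissues)
    return total * Tensor((1.0 / np.maximum(count, 1.0)).reshape(-1, 1))


def init_scale_embeddings(graph: MultiScaleGraph, protein_h: Tensor, meta_idx: dict):
    """Initial cell-type and tissue embeddings.

    Cell types start as the mean of their proteins' embeddings.  Tissues
    start as the mean over their metagraph neighbors (adjacent tissues
    and attached cell types); since tissues carry no intrinsic features,
    provisional tissue vectors are first filled bottom-up from attached
    cell types (a tissue without cells inherits the mean of its already
    filled tissue neighbors), then a single neighborhood-averaging sweep
    produces the final initialization.
    """
    n_cells = len(meta_idx["cells"])
    n_tissues = len(meta_idx["tissues"])
    counts = np.bincount(graph.context_of_node, minlength=n_cells).astype(float)
    cell_h = segment_sum(protein_h, graph.context_of_node, n_cells) * Tensor(
        (1.0 / np.maximum(counts, 1.0)).reshape(-1, 1)
    )

    # Stage 1: provisional tissue vectors, filled outward from attached cells.
    d = cell_h.shape[1]
    ct = meta_idx["ct"]
    ct_count = np.zeros(n_tissues)
    if len(ct):
        np.add.at(ct_count, ct[:, 1], 1.0)
        prov = segment_sum(gather(cell_h, ct[:, 0]), ct[:, 1], n_tissues) * Tensor(
            (1.0 / np.maximum(ct_count, 1.0)).reshape(-1, 1)
        )
    else:
        prov = Tensor(np.zeros((n_tissues, d)))
    filled = ct_count > 0
    for _ in range(n_tissues):
        if filled.all():
            break
        src, dst = [], []
        for a, b in meta_idx["tt"]:
            for u, v in ((a, b), (b, a)):
                if filled[u] and not filled[v]:
                    src.append(u)
                    dst.append(v)
        if not src:
            break
        cnt = np.zeros(n_tissues)
        np.add.at(cnt, dst, 1.0)
        scale = np.divide(1.0, cnt, out=np.zeros(n_tissues), where=cnt > 0)
        prov = prov + segment_sum(gather(prov, src), dst, n_tissues) * Tensor(
            scale.reshape(-1, 1)
        )
        filled |= cnt > 0

    # Stage 2: one neighborhood-averaging sweep over the metagraph.
    tissue_h = neighbor_average(cell_h, prov, meta_idx)
    return cell_h, tissue_h


def forward(
    graph: MultiScaleGraph,
    mp: ModelParams,
    train_edges: dict[str, np.ndarray] | None = None,
    training: bool = False,
    drop: float = 0.0,
    rng: np.random.Generator | None = None,
    use_metagraph: bool = True,
    collect: bool = False,
):
    """Full forward pass; returns (protein, cell, tissue) embedding tensors.

    `train_edges` maps context id to the (m, 2) positive edge array used
    for message passing (global ids); when None, each context's full
    edge set is used.  With `use_metagraph=False` the bridge and
    metagraph stages are skipped entirely and the pass reduces to
    independent per-context attention stacks.  `collect=True` also
    returns the attention weights (alpha per context/relation, beta,
    gamma) of every layer for invariant checks.
    """
    if graph.features is None:
        raise ValueError("graph.features not initialized (init_protein_features)")
    rng = rng or np.random.default_rng(0)
    meta_idx = metagraph_indices(graph)
    feats = Tensor(graph.features)
    P = gather(feats, graph.identity_of_node)
    cellH = tissueH = None
    record: dict = {"alpha": [], "beta": [], "gamma": []}

    offsets = {}
    off = 0
    for net in graph.contexts:
        offsets[net.context_id] = off
        off += len(net.nodes)

    dims = mp.layer_dims()
    for l, (d_prev, dh, d_l) in enumerate(dims):
        last = l == mp.n_layers - 1
        # --- protein attention per context ---
        outs = []
        layer_alphas = {}
        for net in graph.contexts:
            cid = net.context_id
            o = offsets[cid]
            n = len(net.nodes)
            local = gather(P, np.arange(o, o + n))
            if train_edges is not None:
                arcs = _arcs_for_training(train_edges[cid] - o, n)
            else:
                arcs = _context_arcs(graph, net, o)
            res = protein_attention_layer(
                local,
                arcs,
                mp.params[f"pp{l}.{cid}.Wl"],
                mp.params[f"pp{l}.{cid}.Wr"],
                mp.params[f"pp{l}.{cid}.a"],
                mp.n_heads,
                dh,
                average_heads=last,
                return_alpha=collect,
            )
            if collect:
                res, alpha = res
                layer_alphas[cid] = alpha
            outs.append(res)
        p_new = concat(outs, axis=0)

        beta_rec = {}
        gamma = None
        if use_metagraph:
            if l == 0:
                cellH, tissueH = init_scale_embeddings(graph, P, meta_idx)
            cell_pool, gamma = bridge_pool(
                P, graph.context_of_node, cellH, mp.params[f"bridge{l}.q"]
            )
            cell_per_type, tissue_per_type = metagraph_node_attention(
                cell_pool,
                tissueH,
                meta_idx,
                mp.params,
                l,
                mp.n_heads,
                dh,
                average_heads=last,
            )
            sem = (mp.params[f"sem{l}.s"], mp.params[f"sem{l}.M"], mp.params[f"sem{l}.b"])
            c_new, beta_c = semantic_attention(cell_per_type, *sem)
            t_new, beta_t = semantic_attention(tissue_per_type, *sem)
            beta_rec = {"cell": beta_c, "tissue": beta_t}
            # write the updated cell-type embedding back onto its proteins, same gamma
            p_new = p_new + gamma.reshape(-1, 1) * gather(c_new, graph.context_of_node)
        else:
            c_new = t_new = None

        # --- normalization (+ dropout on the hidden layer) ---
        norm = layer_norm if l == 0 else batch_norm
        p_new = norm(p_new, mp.params[f"norm{l}.protein.g"], mp.params[f"norm{l}.protein.b"])
        if use_metagraph:
            c_new = norm(c_new, mp.params[f"norm{l}.cell.g"], mp.params[f"norm{l}.cell.b"])
            t_new = norm(t_new, mp.params[f"norm{l}.tissue.g"], mp.params[f"norm{l}.tissue.b"])
        if not last:
            p_new = dropout(p_new, drop, rng, training)
            if use_metagraph:
                c_new = dropout(c_new, drop, rng, training)
                t_new = dropout(t_new, drop, rng, training)

        if collect:
            record["alpha"].append(layer_alphas)
            record["beta"].append(beta_rec)
            if gamma is not None:
                record["gamma"].append((gamma.data, graph.context_of_node))

        P = p_new
        if use_metagraph:
            cellH, tissueH = c_new, t_new

    if not use_metagraph:
        d_out = dims[-1][2]
        n_cells = len(meta_idx["cells"])
        n_tissues = len(meta_idx["tissues"])
        cellH = Tensor(np.zeros((n_cells, d_out)))
        tissueH = Tensor(np.zeros((n_tissues, d_out)))
    if collect:
        return P, cellH, tissueH, record
    return P, cellH, tissueH


def embeddings_from_forward(graph: MultiScaleGraph, P, cellH, tissueH) -> EmbeddingSet:
    return EmbeddingSet(
        graph=graph,
        protein_matrix=np.asarray(P.data, dtype=np.float64),
        cell_matrix=np.asarray(cellH.data, dtype=np.float64),
        tissue_matrix=np.asarray(tissueH.data, dtype=np.float64),
    )
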