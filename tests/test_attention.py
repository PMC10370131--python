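"""Attention mechanics against independent scalar-arithmetic oracles."""

import math

import numpy as np
import pytest

from ctxppi.attention import (
    bridge_pool,
    forward,
    init_params,
    init_scale_embeddings,
    metagraph_node_attention,
    neighbor_average,
    protein_attention_layer,
    semantic_attention,
)
from ctxppi.autodiff import Tensor, batch_norm, concat, gather, layer_norm
from ctxppi.graphdata import MultiScaleGraph, init_protein_features, metagraph_indices
from ctxppi.netcon import ContextNetwork, Metagraph


def leaky(x, s=0.2):
    return x if x > 0 else s * x


def test_single_node_self_loop_attention_is_identity_transform():
    """Softmax over one element gives alpha=1; output = relu(W h)."""
    h = Tensor([[2.0]])
    arcs = np.array([[0, 0]])
    Wl, Wr, a = Tensor([[1.5]]), Tensor([[0.3]]), Tensor([[4.0]])
    out, (alpha, _) = protein_attention_layer(
        h, arcs, Wl, Wr, a, n_heads=1, head_dim=1, return_alpha=True
    )
    np.testing.assert_allclose(alpha, 1.0)
    np.testing.assert_allclose(out.data, [[max(1.5 * 2.0, 0.0)]])


def test_two_node_toy_matches_scalar_oracle():
    """Hand evaluation of the attention update on a 2-node graph."""
    h1, h2 = 0.7, -0.4
    wl, wr, av = 1.1, -0.6, 0.9
    h = Tensor([[h1], [h2]])
    arcs = np.array([[0, 1], [1, 0], [0, 0], [1, 1]])
    out, (alpha, dst) = protein_attention_layer(
        h, arcs, Tensor([[wl]]), Tensor([[wr]]), Tensor([[av]]),
        n_heads=1, head_dim=1, return_alpha=True,
    )
    # scalar oracle, node 0: neighbors {1 (arc 1->0), 0 (self)}
    def score(hu, hv):
        return av * leaky(wl * hu + wr * hv)

    for v, neigh in ((0, [h2, h1]), (1, [h1, h2])):
        exps = [math.exp(score(hu, [h1, h2][v])) for hu in neigh]
        alphas = [e / sum(exps) for e in exps]
        expected = max(sum(al * wl * hu for al, hu in zip(alphas, neigh)), 0.0)
        np.testing.assert_allclose(out.data[v, 0], expected, rtol=1e-12)
    # attention weights sum to 1 per destination
    sums = np.zeros(2)
    np.add.at(sums, dst, alpha[:, 0])
    np.testing.assert_allclose(sums, 1.0)


def test_isolated_node_without_self_loop_rejected():
    h = Tensor([[1.0], [2.0]])
    arcs = np.array([[0, 0]])  # node 1 receives nothing
    with pytest.raises(ValueError, match="self-loop"):
        protein_attention_layer(h, arcs, Tensor([[1.0]]), Tensor([[1.0]]),
                                Tensor([[1.0]]), 1, 1)


def test_semantic_attention_singleton_and_oracle():
    d = 3
    rng = np.random.default_rng(5)
    hA = rng.standard_normal((4, d))
    hB = rng.standard_normal((4, d))
    s, M, b = rng.standard_normal(d), rng.standard_normal((d, d)), rng.standard_normal(d)

    combined, beta = semantic_attention({"cc": Tensor(hA)}, Tensor(s), Tensor(M), Tensor(b))
    assert beta == {"cc": 1.0}
    np.testing.assert_allclose(combined.data, hA)

    combined, beta = semantic_attention(
        {"cc": Tensor(hA), "ct": Tensor(hB)}, Tensor(s), Tensor(M), Tensor(b)
    )
    # independent numpy oracle
    m = {r: float(np.sum(np.tanh(h @ M.T + b) @ s)) for r, h in (("cc", hA), ("ct", hB))}
    zmax = max(m.values())
    Z = sum(math.exp(v - zmax) for v in m.values())
    beta_exp = {r: math.exp(v - zmax) / Z for r, v in m.items()}
    assert beta == pytest.approx(beta_exp, rel=1e-12)
    assert 0 < beta["cc"] < 1 and 0 < beta["ct"] < 1
    assert beta["cc"] + beta["ct"] == pytest.approx(1.0)
    np.testing.assert_allclose(
        combined.data, beta_exp["cc"] * hA + beta_exp["ct"] * hB, rtol=1e-12
    )


def test_bridge_pool_singleton_and_two_protein_oracle():
    d = 2
    # singleton context: gamma = 1, cell update adds relu(h_u)
    h = np.array([[0.5, -1.0]])
    cell = np.array([[0.1, 0.2]])
    q = np.array([0.7, -0.3])
    out, gamma = bridge_pool(Tensor(h), np.array([0]), Tensor(cell), Tensor(q))
    np.testing.assert_allclose(gamma.data, [1.0])
    np.testing.assert_allclose(out.data, cell + np.maximum(h, 0.0))

    # two proteins, scalar oracle for gamma and the pooled update
    h2 = np.array([[0.5, -1.0], [1.5, 0.3]])
    scores = [q @ np.tanh(row) for row in h2]
    exps = [math.exp(s) for s in scores]
    g_exp = np.array([e / sum(exps) for e in exps])
    out2, gamma2 = bridge_pool(Tensor(h2), np.array([0, 0]), Tensor(cell), Tensor(q))
    np.testing.assert_allclose(gamma2.data, g_exp, rtol=1e-12)
    pooled = np.maximum((g_exp[:, None] * h2).sum(axis=0), 0.0)
    np.testing.assert_allclose(out2.data, cell + pooled, rtol=1e-12)
    # write-back arithmetic with the same gamma
    wb = h2 + g_exp[:, None] * out2.data
    np.testing.assert_allclose(
        (Tensor(h2) + gamma2.reshape(-1, 1) * out2).data, wb, rtol=1e-12
    )


def two_context_graph():
    c1 = ContextNetwork("c1", ["P", "Q"], {("P", "Q")})
    c2 = ContextNetwork("c2", ["P", "R", "S"], {("P", "R"), ("R", "S")})
    mg = Metagraph(
        cell_types=["c1", "c2"],
        tissues=["ta", "tb", "root"],
        cc_edges={("c1", "c2")},
        ct_edges={("c1", "ta"), ("c2", "tb")},
        tt_edges={("ta", "root"), ("root", "tb")},
    )
    return MultiScaleGraph(contexts=[c1, c2], metagraph=mg)


def test_init_scale_embeddings_means():
    g = two_context_graph()
    meta_idx = metagraph_indices(g)
    d = 2
    P = np.zeros((g.n_nodes, d))
    x = np.array([1.0, 2.0])
    y = np.array([3.0, -1.0])
    # context c1 proteins share x -> cell mean = x
    for p in ("P", "Q"):
        P[g.protein_index[(p, "c1")]] = x
    # context c2: two distinct vectors and one zero
    P[g.protein_index[("P", "c2")]] = x
    P[g.protein_index[("R", "c2")]] = y
    P[g.protein_index[("S", "c2")]] = np.zeros(d)
    cell_h, tissue_h = init_scale_embeddings(g, Tensor(P), meta_idx)
    np.testing.assert_allclose(cell_h.data[0], x)
    np.testing.assert_allclose(cell_h.data[1], (x + y + 0) / 3)


def test_neighbor_average_matches_direct_mean():
    g = two_context_graph()
    meta_idx = metagraph_indices(g)
    rng = np.random.default_rng(1)
    cell_h = rng.standard_normal((2, 2))
    prov = rng.standard_normal((3, 2))
    out = neighbor_average(Tensor(cell_h), Tensor(prov), meta_idx)
    tissues = meta_idx["tissues"]
    # root: neighbors = tissues ta and tb only
    ta, tb, root = tissues.index("ta"), tissues.index("tb"), tissues.index("root")
    np.testing.assert_allclose(out.data[root], (prov[ta] + prov[tb]) / 2)
    # ta: neighbors = {root (tissue), c1 (cell)} -> mean of both
    np.testing.assert_allclose(out.data[ta], (prov[root] + cell_h[0]) / 2)


def test_metagraph_attention_weights_and_singleton():
    g = two_context_graph()
    meta_idx = metagraph_indices(g)
    mp = init_params(g, d_in=4, d_out=3, n_heads=2, hidden_head_dim=2, seed=0)
    rng = np.random.default_rng(0)
    cell_h = Tensor(rng.standard_normal((2, 4)))
    tissue_h = Tensor(rng.standard_normal((3, 4)))
    cell_out, tissue_out = metagraph_node_attention(
        cell_h, tissue_h, meta_idx, mp.params, 0, 2, 2,
        average_heads=False, return_alpha=True,
    )
    assert set(cell_out) == {"cc", "ct"}
    assert set(tissue_out) == {"tt", "tc"}
    # per (node, edge type) attention sums to 1 over incoming arcs
    for _out, (alpha, dst) in list(cell_out.values()) + list(tissue_out.values()):
        n = int(dst.max()) + 1
        sums = np.zeros((n, alpha.shape[1]))
        np.add.at(sums, dst, alpha)
        covered = np.unique(dst)
        np.testing.assert_allclose(sums[covered], 1.0, atol=1e-12)
    # a cell type with exactly one ct neighbor puts weight 1 on it
    _, (alpha_ct, dst_ct) = cell_out["ct"]
    np.testing.assert_allclose(alpha_ct, 1.0)


def test_forward_shapes_default_output_width_and_finiteness(small_graph):
    mp = init_params(small_graph, d_in=16, seed=0)
    assert mp.d_out == 16
    P, cellH, tissueH = forward(small_graph, mp)
    assert P.shape == (small_graph.n_nodes, 16)
    assert cellH.shape[1] == 16 and tissueH.shape[1] == 16
    for t in (P, cellH, tissueH):
        assert np.isfinite(t.data).all()


def test_forward_softmax_invariants(small_graph):
    """All alpha, beta, gamma weight sets are nonnegative and sum to 1."""
    mp = init_params(small_graph, d_in=16, d_out=8, n_heads=2, hidden_head_dim=4, seed=1)
    P, cellH, tissueH, rec = forward(small_graph, mp, collect=True)
    for layer_alphas in rec["alpha"]:
        for alpha, dst in layer_alphas.values():
            assert (alpha >= 0).all()
            sums = np.zeros((int(dst.max()) + 1, alpha.shape[1]))
            np.add.at(sums, dst, alpha)
            np.testing.assert_allclose(sums[np.unique(dst)], 1.0, atol=1e-10)
    for beta_rec in rec["beta"]:
        for betas in beta_rec.values():
            vals = np.asarray(list(betas.values()))
            assert (vals >= 0).all()
            np.testing.assert_allclose(vals.sum(), 1.0, atol=1e-12)
    for gamma, ctx in rec["gamma"]:
        assert (gamma >= 0).all()
        sums = np.zeros(int(ctx.max()) + 1)
        np.add.at(sums, ctx, gamma)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def test_ablated_forward_equals_plain_per_context_stack(small_graph):
    """With bridge and metagraph off, forward is independent per-context
    attention; verified against an explicit per-context run."""
    mp = init_params(small_graph, d_in=16, d_out=8, n_heads=2, hidden_head_dim=4, seed=2)
    P, _, _ = forward(small_graph, mp, use_metagraph=False)

    # explicit reconstruction
    feats = Tensor(small_graph.features)
    H = gather(feats, small_graph.identity_of_node)
    offsets, off = {}, 0
    for net in small_graph.contexts:
        offsets[net.context_id] = off
        off += len(net.nodes)
    for l, (d_prev, dh, d_l) in enumerate(mp.layer_dims()):
        outs = []
        for net in small_graph.contexts:
            o = offsets[net.context_id]
            n = len(net.nodes)
            local = gather(H, np.arange(o, o + n))
            edges = small_graph.edge_array(net) - o
            arcs = np.concatenate(
                [edges, edges[:, ::-1], np.stack([np.arange(n)] * 2, axis=1)], axis=0
            )
            outs.append(
                protein_attention_layer(
                    local, arcs,
                    mp.params[f"pp{l}.{net.context_id}.Wl"],
                    mp.params[f"pp{l}.{net.context_id}.Wr"],
                    mp.params[f"pp{l}.{net.context_id}.a"],
                    2, dh, average_heads=(l == 1),
                )
            )
        H = concat(outs, axis=0)
        norm = layer_norm if l == 0 else batch_norm
        H = norm(H, mp.params[f"norm{l}.protein.g"], mp.params[f"norm{l}.protein.b"])
    np.testing.assert_allclose(P.data, H.data, atol=1e-10)


def test_forward_permutation_equivariance(small_graph):
    """Renaming proteins (and permuting their shared features accordingly)
    permutes the outputs identically."""
    mp = init_params(small_graph, d_in=16, d_out=8, n_heads=2, hidden_head_dim=4, seed=3)
    P1, _, _ = forward(small_graph, mp)

    rename = {p: f"zz_{p[::-1]}" for p in small_graph.identities}
    contexts2 = [
        ContextNetwork(
            net.context_id,
            [rename[p] for p in net.nodes],
            {(rename[u], rename[v]) for u, v in net.edges},
        )
        for net in small_graph.contexts
    ]
    g2 = MultiScaleGraph(contexts=contexts2, metagraph=small_graph.metagraph)
    ident_pos1 = {p: i for i, p in enumerate(small_graph.identities)}
    g2.features = np.empty_like(small_graph.features)
    for j, p2 in enumerate(g2.identities):
        orig = next(p for p in rename if rename[p] == p2)
        g2.features[j] = small_graph.features[ident_pos1[orig]]
    P2, _, _ = forward(g2, mp)
    for (p, c), i in small_graph.protein_index.items():
        j = g2.protein_index[(rename[p], c)]
        np.testing.assert_allclose(P1.data[i], P2.data[j], atol=1e-8)
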