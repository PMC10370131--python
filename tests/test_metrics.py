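"""Evaluation metrics against independent brute-force oracles."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from ctxppi.attention import EmbeddingSet
from ctxppi.graphdata import MultiScaleGraph
from ctxppi.metrics import (
    OntologyTree,
    apr_at_k,
    contextualize_external,
    hierarchy_retrieval,
    median_pool_patches,
    multiplicity_correlation,
    score_gap_permutation_test,
    similarity_gap,
    spatial_enrichment,
    tissue_ontology_distance,
)
from ctxppi.netcon import ContextNetwork, Metagraph


# -- independent oracles -------------------------------------------------------


def apr_bruteforce(rel, k):
    rel = list(rel)[:k]
    r = sum(rel)
    if r == 0:
        return 0.0
    total = 0.0
    for j in range(1, k + 1):
        if rel[j - 1]:
            total += sum(rel[:j]) / j
    return total / r


def spearman_bruteforce(x, y):
    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        sv = np.asarray(v, dtype=float)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def test_apr_examples_and_bruteforce_property():
    assert apr_at_k([1, 1, 1], 3) == 1.0
    assert apr_at_k([1, 0, 1], 3) == pytest.approx((1 + 2 / 3) / 2)
    assert apr_at_k([0, 0, 0], 3) == 0.0
    with pytest.raises(ValueError):
        apr_at_k([1, 0], 3)
    rng = np.random.default_rng(0)
    for _ in range(1000):
        n = int(rng.integers(1, 12))
        rel = rng.integers(0, 2, size=n)
        k = int(rng.integers(1, n + 1))
        assert apr_at_k(rel, k) == pytest.approx(apr_bruteforce(rel, k))


def test_similarity_gap_trivial_and_constructed():
    ctx = ["a", "a", "b", "b"]
    same = np.tile([1.0, 2.0, 3.0], (4, 1))
    out = similarity_gap(same, ctx)
    assert out["median_within"] == pytest.approx(1.0)
    assert out["median_cross"] == pytest.approx(1.0)
    assert out["gap"] == pytest.approx(0.0)

    # within pairs colinear, cross pairs orthogonal
    emb = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
    out = similarity_gap(emb, ctx)
    assert out["median_within"] == pytest.approx(1.0)
    assert out["median_cross"] == pytest.approx(0.0)
    assert out["ks_statistic"] == pytest.approx(1.0)
    assert 0.0 <= out["ks_statistic"] <= 1.0
    with pytest.raises(ValueError):
        similarity_gap(emb, ["a"] * 4)


def embedding_set(vectors_by_key, contexts):
    """Build an EmbeddingSet over 1-edge contexts from (protein, context) vectors."""
    nets = []
    for cid in contexts:
        nodes = sorted({p for (p, c) in vectors_by_key if c == cid})
        edges = {(nodes[i], nodes[i + 1]) for i in range(len(nodes) - 1)}
        nets.append(ContextNetwork(cid, nodes, edges))
    mg = Metagraph(cell_types=list(contexts), tissues=["t"],
                   ct_edges={(c, "t") for c in contexts})
    g = MultiScaleGraph(contexts=nets, metagraph=mg)
    d = len(next(iter(vectors_by_key.values())))
    mat = np.zeros((g.n_nodes, d))
    for key, vec in vectors_by_key.items():
        mat[g.protein_index[key]] = vec
    return EmbeddingSet(graph=g, protein_matrix=mat,
                        cell_matrix=np.zeros((len(contexts), d)),
                        tissue_matrix=np.zeros((1, d)))


def test_multiplicity_correlation_cases():
    # perfect decreasing: more contexts -> lower self-similarity
    vecs = {}
    # protein A in 2 contexts, identical vectors (sim 1)
    vecs[("A", "c1")] = vecs[("A", "c2")] = np.array([1.0, 0.0, 0.0])
    vecs[("A", "c3")] = np.array([1.0, 0.0, 0.0])  # wait, 3 contexts
    del vecs[("A", "c3")]
    # protein B in 3 contexts, slightly rotated (sim ~0.9)
    vecs[("B", "c1")] = np.array([1.0, 0.0, 0.0])
    vecs[("B", "c2")] = np.array([0.9, 0.436, 0.0])
    vecs[("B", "c3")] = np.array([0.9, 0.0, 0.436])
    # protein C in 4 contexts, orthogonal-ish (low sim)
    for i, c in enumerate(["c1", "c2", "c3", "c4"]):
        v = np.zeros(3)
        v[i % 3] = 1.0
        vecs[("C", c)] = v + 0.01 * i
    emb = embedding_set(vecs, ["c1", "c2", "c3", "c4"])
    out = multiplicity_correlation(emb)
    assert not out["tied"]
    assert out["rho"] == pytest.approx(-1.0)

    # degenerate: identical similarities -> rho 0 with tie flag
    tied = {(p, c): np.array([1.0, 0.0]) for p in "ABC" for c in ("c1", "c2")}
    out2 = multiplicity_correlation(embedding_set(tied, ["c1", "c2"]))
    assert out2["tied"] and out2["rho"] == 0.0


def test_multiplicity_correlation_matches_independent_spearman():
    rng = np.random.default_rng(3)
    vecs = {}
    contexts = [f"c{i}" for i in range(5)]
    for i in range(8):
        k = int(rng.integers(2, 6))
        for c in rng.choice(contexts, size=k, replace=False):
            vecs[(f"P{i}", c)] = rng.standard_normal(4)
    emb = embedding_set(vecs, contexts)
    out = multiplicity_correlation(emb)
    assert out["rho"] == pytest.approx(
        spearman_bruteforce(out["counts"], out["mean_similarity"]), abs=1e-10
    )


def chain_tree():
    #        root
    #       /    \
    #      a      b
    #     / \      \
    #    c   d      e
    return OntologyTree.from_edges(
        [("a", "root"), ("b", "root"), ("c", "a"), ("d", "a"), ("e", "b")]
    )


def test_tissue_ontology_distance_cases():
    tree = chain_tree()
    assert tissue_ontology_distance("c", "c", tree) == 0
    assert tissue_ontology_distance("c", "a", tree) == 1
    assert tissue_ontology_distance("c", "d", tree) == 2
    assert tissue_ontology_distance("c", "e", tree) == 4
    with pytest.raises(ValueError):
        tissue_ontology_distance("c", "zz", tree)


def test_tissue_ontology_distance_matches_bfs_oracle():
    rng = np.random.default_rng(1)
    # random tree on 15 nodes
    parents = {}
    nodes = [f"n{i}" for i in range(15)]
    for i in range(1, 15):
        parents[nodes[i]] = nodes[int(rng.integers(i))]
    tree = OntologyTree(parent=parents, root="n0")
    g = nx.Graph([(c, p) for c, p in parents.items()])
    for a, b in combinations(nodes, 2):
        # oracle: min over common ancestors of both path lengths
        anc_a = set(tree.ancestors(a))
        anc_b = set(tree.ancestors(b))
        expected = min(
            nx.shortest_path_length(g, a, x) + nx.shortest_path_length(g, b, x)
            for x in anc_a & anc_b
        )
        assert tissue_ontology_distance(a, b, tree) == expected


def test_ontology_tree_validation():
    with pytest.raises(ValueError, match="two parents"):
        OntologyTree.from_edges([("a", "b"), ("a", "c")])
    with pytest.raises(ValueError, match="single root"):
        OntologyTree.from_edges([("a", "b"), ("c", "d")])


def test_hierarchy_retrieval_monotone_and_null():
    # On a chain hierarchy the ontology distance is the depth difference;
    # points on a circle at angle 0.3*depth make cosine distance a strictly
    # increasing function of it, so rho = 1 up to ties.
    chain = OntologyTree.from_edges(
        [("n1", "n0"), ("n2", "n1"), ("n3", "n2"), ("n4", "n3"), ("n5", "n4")]
    )
    names = sorted(chain.nodes)
    emb = np.stack(
        [[math.cos(0.3 * chain.depth(n)), math.sin(0.3 * chain.depth(n))] for n in names]
    )
    out = hierarchy_retrieval(emb, names, chain, n_shuffles=10, seed=0)
    assert len(out["null_rhos"]) == 10  # stated default count
    # rho = 1 up to ties; float jitter in the norm splits exactly tied
    # distances, which costs a few hundredths
    assert out["rho"] > 0.97
    with pytest.raises(ValueError):
        hierarchy_retrieval(emb[:3], names[:3], chain)


def test_hierarchy_null_is_centered_at_zero_for_random_embeddings():
    """Shuffled-identity null stays near zero on a 21-tissue tree."""
    rng = np.random.default_rng(0)
    nodes = [f"t{i}" for i in range(21)]
    parents = {nodes[i]: nodes[(i - 1) // 2] for i in range(1, 21)}
    tree = OntologyTree(parent=parents, root="t0")
    emb = rng.standard_normal((21, 8))
    out = hierarchy_retrieval(emb, nodes, tree, n_shuffles=10, seed=1)
    assert abs(np.mean(out["null_rhos"])) < 0.1


def test_permutation_test_two_values_exact_and_montecarlo():
    exact = score_gap_permutation_test([1.0], [0.0], exhaustive_max=8)
    assert exact["exact"] and exact["p"] == pytest.approx(0.5)
    mc = score_gap_permutation_test([1.0], [0.0], n_iter=100_000, seed=0)
    se = math.sqrt(0.5 * 0.5 / 100_000)
    assert abs(mc["p"] - 0.5) <= 3 * se


def test_permutation_test_counter_ordering_and_errors():
    out = score_gap_permutation_test([0.1, 0.2], [0.8, 0.9], n_iter=2000, seed=1)
    assert out["p"] > 0.95
    with pytest.raises(ValueError):
        score_gap_permutation_test([], [1.0])


def bh_stepup_oracle(pvals, alpha):
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = np.asarray(pvals)[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.nonzero(passed))
        reject[order[: kmax + 1]] = True
    return reject


def hypergeom_tail_oracle(k, N, K, n):
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


def test_spatial_enrichment_uniform_labels_nothing_enriched():
    rng = np.random.default_rng(0)
    emb = rng.standard_normal((30, 5))
    res = spatial_enrichment(emb, np.ones(30, dtype=int), sim_threshold=-1.0)
    assert res.n_enriched == 0
    assert res.alpha == 0.05  # stated default
    assert ((res.adjusted_p >= 0) & (res.adjusted_p <= 1)).all()
    np.testing.assert_array_equal(res.significant, res.adjusted_p <= res.alpha)


def test_spatial_enrichment_planted_cluster_significant():
    rng = np.random.default_rng(1)
    # tight labeled cluster + diffuse unlabeled background
    cluster = np.tile([5.0, 5.0, 5.0], (12, 1)) + 0.01 * rng.standard_normal((12, 3))
    rest = rng.standard_normal((40, 3))
    emb = np.vstack([cluster, rest])
    labels = np.array([1] * 12 + [0] * 40)
    res = spatial_enrichment(emb, labels, sim_threshold=0.5, radius=0.15, alpha=0.05)
    node_pos = {n: i for i, n in enumerate(res.nodes)}
    cluster_flags = [res.significant[node_pos[i]] for i in range(12) if i in node_pos]
    assert np.mean(cluster_flags) > 0.9
    # cross-check one neighborhood's p against a direct hypergeometric tail
    from scipy.stats import hypergeom

    assert hypergeom.sf(4, 52, 12, 10) == pytest.approx(
        hypergeom_tail_oracle(5, 52, 12, 10), rel=1e-10
    )


def test_bh_correction_matches_stepup_oracle():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(2)
    for _ in range(20):
        pvals = rng.uniform(size=int(rng.integers(3, 40)))
        reject, _, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, bh_stepup_oracle(pvals, 0.05))


def test_contextualize_external_concatenation():
    vecs = {("A", "c1"): np.array([1.0, 0.0]), ("A", "c2"): np.array([0.0, 1.0]),
            ("B", "c1"): np.array([2.0, 2.0])}
    emb = embedding_set(vecs, ["c1", "c2"])
    ext = np.array([9.0, 8.0, 7.0])
    ctx = contextualize_external(ext, emb, "A", "c1")
    assert len(ctx) == 3 + 2  # dims add
    np.testing.assert_array_equal(ctx, [9, 8, 7, 1, 0])
    free = contextualize_external(ext, emb, "A")
    np.testing.assert_array_equal(free, [9, 8, 7, 0.5, 0.5])  # mean across contexts
    with pytest.raises(ValueError):
        contextualize_external(ext, emb, "ZZ")
    # cosine of two combined vectors matches a direct computation
    other = contextualize_external(ext, emb, "A", "c2")
    cos = float(ctx @ other / (np.linalg.norm(ctx) * np.linalg.norm(other)))
    assert -1.0 <= cos <= 1.0


def test_median_pool_patches():
    const = np.full((5, 4), 3.3)
    np.testing.assert_array_equal(
        median_pool_patches(const, np.arange(5), k_select=5), np.full(5, 3.3)
    )
    mat = np.array([[1.0, 5.0, 2.0, 9.0], [0.0, 0.0, 1.0, 1.0], [7.0, 3.0, 3.0, 2.0]])
    scores = [0.5, 0.9, 0.1]
    out = median_pool_patches(mat, scores, k_select=3)
    # rows ordered by decreasing score; per-row median via explicit sort
    expected = [sorted(row)[1:3] for row in (mat[1], mat[0], mat[2])]
    np.testing.assert_array_equal(out, [np.mean(e) for e in expected])
    with pytest.raises(ValueError):
        median_pool_patches(mat, scores, k_select=4)
    import inspect

    assert inspect.signature(median_pool_patches).parameters["k_select"].default == 200
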