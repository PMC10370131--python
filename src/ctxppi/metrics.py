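"""Quantitative evaluation procedures.

APR@K ranking quality, embedding-similarity analyses (within- vs
cross-context cosine similarity, context-multiplicity correlation),
tissue-hierarchy retrieval against the ontology's lowest-common-ancestor
distance, one-sided permutation tests for score gaps, a simplified
SAFE-style spatial enrichment of labels over an embedding-similarity
graph, and helpers that contextualize external (e.g. structure-surface)
protein vectors by concatenation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.stats import hypergeom, ks_2samp, spearmanr
from statsmodels.stats.multitest import multipletests

from .attention import EmbeddingSet

__all__ = [
    "OntologyTree",
    "EnrichmentResult",
    "apr_at_k",
    "similarity_gap",
    "multiplicity_correlation",
    "tissue_ontology_distance",
    "hierarchy_retrieval",
    "score_gap_permutation_test",
    "spatial_enrichment",
    "contextualize_external",
    "median_pool_patches",
]


@dataclass
class OntologyTree:
    """Rooted tissue hierarchy as child -> parent pointers."""

    parent: dict[str, str]
    root: str

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "OntologyTree":
        parent = {}
        children = set()
        nodes = set()
        for child, par in edges:
            if child in parent:
                raise ValueError(f"node {child!r} has two parents; not a tree")
            parent[child] = par
            children.add(child)
            nodes.update((child, par))
        roots = nodes - children
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {sorted(roots)}")
        root = next(iter(roots))
        # Acyclicity: walking up from any node must terminate at the root.
        for node in nodes:
            seen = set()
            while node != root:
                if node in seen:
                    raise ValueError("cycle in ontology")
                seen.add(node)
                node = parent[node]
        return cls(parent=parent, root=root)

    @property
    def nodes(self) -> set[str]:
        return set(self.parent) | {self.root}

    def depth(self, node: str) -> int:
        d = 0
        while node != self.root:
            node = self.parent[node]
            d += 1
        return d

    def ancestors(self, node: str) -> list[str]:
        """Path from `node` to the root, inclusive."""
        path = [node]
        while node != self.root:
            node = self.parent[node]
            path.append(node)
        return path

    def relabel(self, mapping: dict[str, str]) -> "OntologyTree":
        return OntologyTree(
            parent={mapping[c]: mapping[p] for c, p in self.parent.items()},
            root=mapping[self.root],
        )


@dataclass
class EnrichmentResult:
    """Per-node neighborhood enrichment of a binary label."""

    nodes: list
    scores: np.ndarray  # -log10 adjusted p per node
    adjusted_p: np.ndarray
    significant: np.ndarray  # boolean at alpha
    n_enriched: int
    alpha: float


def apr_at_k(relevance, k: int) -> float:
    """Average precision-and-recall at K over a ranked binary list.

    (1/r) * sum_{j<=K} Precision@j * rel(j), where r is the number of
    relevant items among the top K; defined as 0 when r = 0.
    """
    rel = np.asarray(relevance, dtype=float)
    if k < 1 or k > len(rel):
        raise ValueError(f"K={k} out of range for list of length {len(rel)}")
    top = rel[:k]
    r = top.sum()
    if r == 0:
        return 0.0
    precision_at = np.cumsum(top) / np.arange(1, k + 1)
    return float((precision_at * top).sum() / r)


def _cosine_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    if (norms == 0).any():
        warnings.warn("zero vector in cosine computation; its similarities are 0")
    unit = x / safe[:, None]
    unit[norms == 0] = 0.0
    return unit @ unit.T


def similarity_gap(embeddings: np.ndarray, context_labels, protein_labels=None):
    """Within- vs cross-context cosine similarity distributions.

    Returns a dict with both samples, their medians, the gap of medians
    and the two-sample KS statistic/p-value.  Pairs of the same protein
    across contexts are excluded from the cross-context sample when
    `protein_labels` is given; singleton contexts contribute no
    within-context pairs.
    """
    ctx = np.asarray(context_labels)
    if len(np.unique(ctx)) < 2:
        raise ValueError("at least two contexts are required")
    sims = _cosine_matrix(np.asarray(embeddings, dtype=float))
    iu, ju = np.triu_indices(len(ctx), k=1)
    same_ctx = ctx[iu] == ctx[ju]
    cross = ~same_ctx
    if protein_labels is not None:
        prot = np.asarray(protein_labels)
        cross &= prot[iu] != prot[ju]
    within_vals = sims[iu[same_ctx], ju[same_ctx]]
    cross_vals = sims[iu[cross], ju[cross]]
    ks = ks_2samp(within_vals, cross_vals)
    return {
        "within": within_vals,
        "cross": cross_vals,
        "median_within": float(np.median(within_vals)),
        "median_cross": float(np.median(cross_vals)),
        "gap": float(np.median(within_vals) - np.median(cross_vals)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }


def multiplicity_correlation(embeddings: EmbeddingSet):
    """Spearman correlation between a protein's context count and the mean
    pairwise cosine similarity among its own context-specific vectors.

    Proteins present in a single context carry no self-similarity and
    are skipped.  When every protein has identical values on either
    axis the correlation is degenerate; 0 is reported with a tie flag.
    """
    by_protein: dict[str, list[int]] = {}
    for (p, _c), idx in embeddings.graph.protein_index.items():
        by_protein.setdefault(p, []).append(idx)
    counts, mean_sims = [], []
    for p, idxs in sorted(by_protein.items()):
        if len(idxs) < 2:
            continue
        vecs = embeddings.protein_matrix[idxs]
        sims = _cosine_matrix(vecs)
        iu, ju = np.triu_indices(len(idxs), k=1)
        counts.append(len(idxs))
        mean_sims.append(float(sims[iu, ju].mean()))
    if len(counts) < 3:
        raise ValueError("need >= 3 proteins appearing in >= 2 contexts")
    if len(set(counts)) == 1 or len(set(np.round(mean_sims, 12))) == 1:
        return {"rho": 0.0, "pvalue": np.nan, "tied": True,
                "counts": np.asarray(counts), "mean_similarity": np.asarray(mean_sims)}
    rho, p = spearmanr(counts, mean_sims)
    return {"rho": float(rho), "pvalue": float(p), "tied": False,
            "counts": np.asarray(counts), "mean_similarity": np.asarray(mean_sims)}


def tissue_ontology_distance(t1: str, t2: str, tree: OntologyTree) -> int:
    """Sum of both tissues' path lengths to their lowest common ancestor."""
    for t in (t1, t2):
        if t not in tree.nodes:
            raise ValueError(f"unknown tissue {t!r}")
    path1 = tree.ancestors(t1)
    path2 = set(tree.ancestors(t2))
    for d1, node in enumerate(path1):
        if node in path2:
            lca = node
            break
    d2 = tree.ancestors(t2).index(lca)
    return d1 + d2


def hierarchy_retrieval(
    tissue_embeddings: np.ndarray,
    tissue_names: list[str],
    tree: OntologyTree,
    n_shuffles: int = 10,
    seed: int = 0,
):
    """Zero-shot retrieval of the tissue hierarchy from embedding distances.

    Correlates pairwise cosine distance between tissue embeddings with
    the ontology (LCA) distance; compares the embedding-distance sample
    against distances of standard-normal random vectors of equal count
    and dimension (two-sample KS); and builds a null Spearman
    distribution from trees with shuffled node identities.
    """
    if len(tissue_names) < 4:
        raise ValueError("need at least 4 tissues")
    x = np.asarray(tissue_embeddings, dtype=float)
    rng = np.random.default_rng(seed)
    cos_dist = 1.0 - _cosine_matrix(x)
    iu, ju = np.triu_indices(len(tissue_names), k=1)
    emb_d = cos_dist[iu, ju]
    onto_d = np.asarray(
        [tissue_ontology_distance(tissue_names[i], tissue_names[j], tree) for i, j in zip(iu, ju)],
        dtype=float,
    )
    rho, p = spearmanr(emb_d, onto_d)

    rand = rng.standard_normal(x.shape)
    rand_d = (1.0 - _cosine_matrix(rand))[iu, ju]
    ks = ks_2samp(emb_d, rand_d)

    # Null: shuffle node identities of the hierarchy while the embeddings
    # stay put, i.e. the ontology distance of a pair is looked up at
    # permuted positions in the fixed tree.
    null_rhos = []
    names = list(tissue_names)
    all_nodes = sorted(tree.nodes)
    for _ in range(n_shuffles):
        perm = rng.permutation(len(all_nodes))
        mapping = {all_nodes[i]: all_nodes[perm[i]] for i in range(len(all_nodes))}
        null_d = np.asarray(
            [
                tissue_ontology_distance(mapping[names[i]], mapping[names[j]], tree)
                for i, j in zip(iu, ju)
            ],
            dtype=float,
        )
        r, _ = spearmanr(emb_d, null_d)
        null_rhos.append(float(r) if np.isfinite(r) else 0.0)
    return {
        "rho": float(rho),
        "pvalue": float(p),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "null_rhos": np.asarray(null_rhos),
    }


def score_gap_permutation_test(
    binding_scores,
    nonbinding_scores,
    n_iter: int = 100_000,
    seed: int = 0,
    exhaustive_max: int = 0,
    plus_one: bool = False,
):
    """One-sided permutation test for mean(binding) - mean(nonbinding).

    Monte-Carlo p is the raw fraction of label permutations whose gap
    is >= the observed gap (set `plus_one` for the (b+1)/(n+1)
    estimator).  With ``len(all scores) <= exhaustive_max`` every label
    assignment is enumerated instead and the p-value is exact.
    """
    b = np.asarray(binding_scores, dtype=float)
    nb = np.asarray(nonbinding_scores, dtype=float)
    if len(b) == 0 or len(nb) == 0:
        raise ValueError("both score sets must be nonempty")
    gap = float(b.mean() - nb.mean())
    pooled = np.concatenate([b, nb])
    n, n_b = len(pooled), len(b)
    if exhaustive_max and n <= exhaustive_max:
        hits = total = 0
        for idx in combinations(range(n), n_b):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            g = pooled[sel].mean() - pooled[~sel].mean()
            hits += g >= gap - 1e-12
            total += 1
        return {"gap": gap, "p": hits / total, "exact": True, "n_iter": total}
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 10_000
    done = 0
    while done < n_iter:
        m = min(batch, n_iter - done)
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :n_b]
        perm_b = pooled[idx].mean(axis=1)
        perm_nb = (pooled.sum() - pooled[idx].sum(axis=1)) / (n - n_b)
        hits += int(((perm_b - perm_nb) >= gap - 1e-12).sum())
        done += m
    p = (hits + 1) / (n_iter + 1) if plus_one else hits / n_iter
    return {"gap": gap, "p": float(p), "exact": False, "n_iter": n_iter}


def spatial_enrichment(
    embeddings: np.ndarray,
    labels,
    sim_threshold: float = 0.3,
    radius: float = 0.15,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """SAFE-style neighborhood enrichment of a binary label.

    An unweighted graph joins embedding pairs with cosine similarity
    above `sim_threshold`; only its largest connected component is
    analyzed.  Each node's neighborhood is the set of nodes within a
    shortest-path distance at or below the `radius` quantile of all
    finite pairwise distances (radius 0.15 reads as the 15th
    percentile).  Label over-representation per neighborhood uses the
    hypergeometric tail, corrected by Benjamini-Hochberg; the score is
    -log10 of the adjusted p.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("at least one labeled node is required")
    sims = _cosine_matrix(np.asarray(embeddings, dtype=float))
    n = len(y)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    keep = sims[iu, ju] >= sim_threshold
    g.add_edges_from(zip(iu[keep], ju[keep]))
    component = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    nodes = sorted(component)
    if len(nodes) == 0:
        raise ValueError("empty component")
    sub = g.subgraph(nodes)
    dist = dict(nx.all_pairs_shortest_path_length(sub))
    finite = [d for row in dist.values() for d in row.values() if d > 0]
    cutoff = np.quantile(finite, radius) if finite else 0

    y_sub = y[nodes]
    n_total = len(nodes)
    n_labeled = int(y_sub.sum())
    pvals = []
    for node in nodes:
        neigh = [m for m, d in dist[node].items() if d <= cutoff]
        k_lab = int(y[neigh].sum())
        # Over-representation: P[X >= k] under hypergeom(N, K, n_draw).
        pvals.append(float(hypergeom.sf(k_lab - 1, n_total, n_labeled, len(neigh))))
    pvals = np.asarray(pvals)
    reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    scores = -np.log10(np.maximum(adj, 1e-300))
    return EnrichmentResult(
        nodes=nodes,
        scores=scores,
        adjusted_p=adj,
        significant=reject,
        n_enriched=int(reject.sum()),
        alpha=alpha,
    )


def contextualize_external(
    external: np.ndarray,
    embeddings: EmbeddingSet,
    protein: str,
    context: str | None = None,
):
    """Concatenate an external protein vector with contextual embeddings.

    With a `context`, returns the single contextualized vector for that
    (protein, context).  Without one, returns the context-free baseline:
    concatenation with the elementwise mean across all of that protein's
    contexts.
    """
    contexts = embeddings.contexts_of(protein)
    if not contexts:
        raise ValueError(f"unknown protein {protein!r}")
    ext = np.asarray(external, dtype=float).ravel()
    if context is not None:
        if context not in contexts:
            raise ValueError(f"protein {protein!r} not embedded in context {context!r}")
        return np.concatenate([ext, embeddings.protein(protein, context)])
    mean = np.mean([embeddings.protein(protein, c) for c in contexts], axis=0)
    return np.concatenate([ext, mean])


def median_pool_patches(patches: np.ndarray, site_scores, k_select: int = 200) -> np.ndarray:
    """Pool a patches-by-features matrix into a fixed-length vector.

    Keeps the `k_select` rows with the highest site score, then takes
    each kept row's median across its feature columns, yielding a
    length-`k_select` vector (rows ordered by decreasing score).
    """
    x = np.asarray(patches, dtype=float)
    scores = np.asarray(site_scores, dtype=float)
    if x.ndim != 2 or len(scores) != x.shape[0]:
        raise ValueError("patches must be 2-D with one site score per row")
    if x.shape[0] < k_select:
        raise ValueError(f"only {x.shape[0]} patches available; need {k_select}")
    order = np.argsort(-scores, kind="stable")[:k_select]
    return np.median(x[order], axis=1)
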