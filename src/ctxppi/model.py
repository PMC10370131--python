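"""Model/Results facade over the multi-scale embedding pipeline.

``ContextualProteinModel`` is built from context networks and a
metagraph (or directly from a directory of constructed inputs); its
``fit`` runs self-supervised pretraining and returns
``ContextualProteinResults`` carrying the embeddings, the training log,
diagnostics and a ``summary()`` table.  Downstream analyses — the
within/cross-context similarity gap, context-multiplicity correlation
and zero-shot tissue-hierarchy retrieval — hang off the results object.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attention import EmbeddingSet
from .graphdata import MultiScaleGraph, init_protein_features, split_edges
from .metrics import OntologyTree, hierarchy_retrieval, multiplicity_correlation, similarity_gap
from .netcon import ContextNetwork, Metagraph
from .training import TrainConfig, TrainResult, export_embeddings, select_model, train

__all__ = ["ContextualProteinModel", "ContextualProteinResults"]


class ContextualProteinModel:
    """Multi-scale attention model over cell-type-specific protein networks.

    Parameters
    ----------
    contexts : list[ContextNetwork]
        One connected protein network per cell-type context.
    metagraph : Metagraph
        Cell-cell, cell-tissue and tissue-tissue relations.
    config : TrainConfig, optional
        Architecture and optimization settings; defaults follow the
        published hyperparameters.
    """

    def __init__(self, contexts: list[ContextNetwork], metagraph: Metagraph,
                 config: TrainConfig | None = None):
        if not contexts:
            raise ValueError("at least one context network is required")
        self.config = config or TrainConfig()
        self.graph = MultiScaleGraph(contexts=contexts, metagraph=metagraph)

    @classmethod
    def from_dir(cls, indir, config: TrainConfig | None = None) -> "ContextualProteinModel":
        """Load `<context>.edges.tsv` files plus `metagraph.tsv` from a directory."""
        metagraph = Metagraph.from_tsv(os.path.join(indir, "metagraph.tsv"))
        contexts = []
        for name in sorted(os.listdir(indir)):
            if name.endswith(".edges.tsv"):
                cid = name[: -len(".edges.tsv")]
                contexts.append(ContextNetwork.from_tsv(os.path.join(indir, name), cid))
        return cls(contexts, metagraph, config)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "ContextualProteinResults":
        """Split edges, pretrain, and return the best checkpoint's results."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        init_protein_features(self.graph, config.d_in, seed=config.seed)
        split = split_edges(self.graph, seed=config.seed)
        result = train(self.graph, split, config, verbose=verbose)
        return ContextualProteinResults(model=self, split=split, train_result=result)


@dataclass
class ContextualProteinResults:
    """Fitted embeddings plus diagnostics."""

    model: ContextualProteinModel
    split: object
    train_result: TrainResult
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def embeddings(self) -> EmbeddingSet:
        return self.train_result.embeddings

    @property
    def log(self) -> pd.DataFrame:
        return self.train_result.log

    @property
    def best_epoch(self) -> int:
        return self.train_result.best_epoch

    def test_auroc(self) -> float:
        """Held-out link-prediction AUROC on the frozen test split."""
        from sklearn.metrics import roc_auc_score

        from .autodiff import Tensor
        from .objectives import decode_pairs

        graph = self.model.graph
        z = Tensor(self.embeddings.protein_matrix)
        probs, labels = [], []
        rel = self.train_result.relations
        for cid in graph.context_ids:
            pos = self.split.positives[cid]["test"]
            neg = self.split.negatives[cid]["test"]
            if len(pos) == 0:
                continue
            key = f"pp.{cid}" if f"pp.{cid}" in rel.vectors else "pp"
            probs += [decode_pairs(z, pos, rel.vectors[key]).data,
                      decode_pairs(z, neg, rel.vectors[key]).data]
            labels += [np.ones(len(pos)), np.zeros(len(neg))]
        return float(roc_auc_score(np.concatenate(labels), np.concatenate(probs)))

    def similarity_gap(self):
        """Within- vs cross-context cosine similarity of protein embeddings."""
        graph = self.model.graph
        prot = [p for (p, _c) in sorted(graph.protein_index, key=graph.protein_index.get)]
        return similarity_gap(
            self.embeddings.protein_matrix,
            graph.context_of_node,
            protein_labels=prot,
        )

    def multiplicity_correlation(self):
        return multiplicity_correlation(self.embeddings)

    def hierarchy_retrieval(self, ontology_edges=None, n_shuffles: int = 10, seed: int = 0):
        """Zero-shot tissue-hierarchy retrieval from tissue embeddings."""
        mg = self.model.graph.metagraph
        edges = ontology_edges if ontology_edges is not None else sorted(mg.tt_edges)
        try:  # (child, parent) oriented input
            tree = OntologyTree.from_edges(edges)
        except ValueError:  # canonical undirected storage: recover an orientation
            tree = OntologyTree.from_edges(_orient_edges(edges))
        return hierarchy_retrieval(
            self.embeddings.tissue_matrix, mg.tissues, tree,
            n_shuffles=n_shuffles, seed=seed,
        )

    def export(self, outdir) -> dict[str, str]:
        return export_embeddings(self.embeddings, outdir)

    def summary(self) -> str:
        graph = self.model.graph
        cfg = self.train_result.config
        final = self.log.iloc[-1]
        best = self.log.iloc[select_model(self.log)]
        lines = [
            "Contextual protein embedding model",
            "==================================",
            f"contexts: {len(graph.contexts)}   protein nodes: {graph.n_nodes}   "
            f"identities: {len(graph.identities)}",
            f"metagraph: {len(graph.metagraph.cell_types)} cell types, "
            f"{len(graph.metagraph.tissues)} tissues "
            f"(cc={len(graph.metagraph.cc_edges)}, ct={len(graph.metagraph.ct_edges)}, "
            f"tt={len(graph.metagraph.tt_edges)})",
            f"architecture: d_in={cfg.d_in} d_out={cfg.d_out} heads={cfg.n_heads} "
            f"layers={cfg.n_layers} dropout={cfg.dropout}",
            f"objective: theta={cfg.theta} lambda={cfg.lambda_}",
            f"epochs: {cfg.epochs}   best epoch: {int(best['epoch'])}",
            f"best val AUROC: {best['val_auroc']:.4f}   "
            f"val CH score: {best['val_ch']:.1f}",
            f"final total loss: {final['total']:.4f}",
        ]
        return "\n".join(lines)


def _orient_edges(edges):
    """Recover a child->parent orientation for canonically stored tt
    edges by rooting the undirected tree at its center and orienting
    every edge away from it via BFS."""
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(edges)
    if g.number_of_nodes() == 0:
        raise ValueError("no tissue edges")
    # Root: the node minimizing eccentricity (tree center); ties by name.
    center = sorted(nx.center(g))[0]
    oriented = []
    for parent, child in nx.bfs_edges(g, center):
        oriented.append((child, parent))
    return oriented
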