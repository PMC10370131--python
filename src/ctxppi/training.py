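"""Pretraining loop, model selection and embedding export.

Full-graph gradient training of the multi-scale attention network on
the composite objective.  Two optimizer groups follow the two published
learning rates: all model parameters train at `lr_link`, while the
per-context center vectors of the cell-type-identification term train
at `lr_center` (the classic center-loss arrangement).  Per epoch the
trainer logs every loss component, the validation link-prediction AUROC
(frozen negatives) and a Calinski-Harabasz cluster-separation score of
the protein embeddings labeled by context; the checkpoint with the best
validation AUROC (ties broken by the cluster score) is returned.
"""

from __future__ import annotations

import os
import sys
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, roc_auc_score

from . import io as _io
from .attention import EmbeddingSet, ModelParams, embeddings_from_forward, forward, init_params
from .autodiff import Adam, Tensor
from .graphdata import (
    EdgeSplit,
    MultiScaleGraph,
    init_protein_features,
    metagraph_indices,
    sample_metagraph_negatives,
    sample_negatives,
)
from .objectives import (
    LossWeights,
    RelationEmbeddings,
    center_loss,
    decode_cross_pairs,
    decode_pairs,
    link_loss_pos_neg,
    total_loss,
)

__all__ = ["TrainConfig", "TrainResult", "train", "select_model", "export_embeddings"]


@dataclass(frozen=True)
class TrainConfig:
    """Pretraining hyperparameters.

    Defaults follow the published tuned values: input feature width
    1024, output width 16, 8 attention heads, dropout 0.6, weight decay
    1e-5, link-prediction learning rate 0.01, center learning rate 0.1,
    lambda 0.1, 250 epochs, two layers with layer normalization then
    batch normalization.  theta has no published default and is exposed
    here at 0.5.
    """

    d_in: int = 1024
    d_out: int = 16
    n_heads: int = 8
    hidden_head_dim: int = 16
    n_layers: int = 2
    epochs: int = 250
    dropout: float = 0.6
    weight_decay: float = 1e-5
    lr_link: float = 0.01
    lr_center: float = 0.1
    theta: float = 0.5
    lambda_: float = 0.1
    seed: int = 0
    normalization: tuple[str, ...] = ("layernorm", "batchnorm")
    use_metagraph: bool = True
    center_source: str = "parameter"  # or "embedding"
    per_context_pp_relation: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def weights(self) -> LossWeights:
        return LossWeights(theta=self.theta, lambda_=self.lambda_)


@dataclass
class TrainResult:
    params: ModelParams
    relations: RelationEmbeddings
    centers: Tensor
    embeddings: EmbeddingSet
    log: pd.DataFrame
    best_epoch: int
    config: TrainConfig


def _no_decay(name: str) -> bool:
    """Normalization parameters and relation embeddings skip weight decay."""
    return name.startswith(("norm", "rel.")) or name.endswith((".b",))


def build_optimizer(mp: ModelParams, relations: RelationEmbeddings, centers: Tensor, config: TrainConfig) -> Adam:
    model_params = {**mp.trainable(), **relations.trainable()}
    decayed = {k: v for k, v in model_params.items() if not _no_decay(k)}
    plain = {k: v for k, v in model_params.items() if _no_decay(k)}
    groups = [
        {"params": decayed, "lr": config.lr_link, "weight_decay": config.weight_decay},
        {"params": plain, "lr": config.lr_link, "weight_decay": 0.0},
        {"params": {"centers": centers}, "lr": config.lr_center, "weight_decay": 0.0},
    ]
    return Adam(groups)


def _rel(relations: RelationEmbeddings, name: str, cid: str | None = None) -> Tensor:
    if cid is not None and f"pp.{cid}" in relations.vectors:
        return relations.vectors[f"pp.{cid}"]
    return relations.vectors[name]


def _epoch_losses(
    graph: MultiScaleGraph,
    split: EdgeSplit,
    P: Tensor,
    cellH: Tensor,
    tissueH: Tensor,
    relations: RelationEmbeddings,
    centers: Tensor,
    config: TrainConfig,
    rng: np.random.Generator,
):
    """All loss components on the training split (fresh train negatives)."""
    meta_idx = metagraph_indices(graph)
    per_ctx = []
    train_nodes = []
    for net in graph.contexts:
        cid = net.context_id
        pos = split.positives[cid]["train"]
        neg = sample_negatives(graph, cid, pos, seed=int(rng.integers(2**31)))
        probs_pos = decode_pairs(P, pos, _rel(relations, "pp", cid))
        probs_neg = decode_pairs(P, neg, _rel(relations, "pp", cid))
        per_ctx.append(link_loss_pos_neg(probs_pos, probs_neg))
        train_nodes.append(np.unique(pos))
    l_ppi = per_ctx[0]
    for t in per_ctx[1:]:
        l_ppi = l_ppi + t
    l_ppi = l_ppi * (1.0 / len(per_ctx))

    zero = Tensor(0.0)
    if not config.use_metagraph:
        return {"l_ppi": l_ppi, "l_cellid": zero, "l_cc": zero, "l_ct": zero,
                "l_tt": zero, "l_tc": zero}

    nodes = np.concatenate(train_nodes)
    from .autodiff import gather  # local import to avoid cycle noise

    z_train = gather(P, nodes)
    ctx_train = graph.context_of_node[nodes]
    center_src = centers if config.center_source == "parameter" else cellH
    # Per-coordinate normalization keeps the quadratic identity term on the
    # same scale as the cross-entropy terms regardless of embedding width.
    l_cellid = center_loss(z_train, ctx_train, center_src) * (1.0 / config.d_out)

    n_cells, n_tissues = cellH.shape[0], tissueH.shape[0]

    def scale_loss(pos, z_a, z_b, name, n_b, same_class):
        if len(pos) == 0:
            return zero
        neg = sample_metagraph_negatives(z_a.shape[0], n_b, pos, same_class, rng)
        p_pos = decode_cross_pairs(z_a, z_b, pos, _rel(relations, name))
        if len(neg) == 0:  # saturated relation: positives only
            from .objectives import link_loss

            return link_loss(p_pos, np.ones(len(pos)))
        p_neg = decode_cross_pairs(z_a, z_b, neg, _rel(relations, name))
        return link_loss_pos_neg(p_pos, p_neg)

    l_cc = scale_loss(meta_idx["cc"], cellH, cellH, "cc", n_cells, True)
    l_ct = scale_loss(meta_idx["ct"], cellH, tissueH, "ct", n_tissues, False)
    l_tt = scale_loss(meta_idx["tt"], tissueH, tissueH, "tt", n_tissues, True)
    tc = meta_idx["ct"][:, ::-1] if len(meta_idx["ct"]) else meta_idx["ct"]
    l_tc = scale_loss(tc, tissueH, cellH, "tc", n_cells, False)
    return {"l_ppi": l_ppi, "l_cellid": l_cellid, "l_cc": l_cc, "l_ct": l_ct,
            "l_tt": l_tt, "l_tc": l_tc}


def _validation_metrics(graph, split, P, relations) -> tuple[float, float]:
    probs, labels = [], []
    for net in graph.contexts:
        cid = net.context_id
        pos = split.positives[cid]["val"]
        neg = split.negatives[cid]["val"]
        if len(pos) == 0:
            continue
        probs.append(decode_pairs(P, pos, _rel(relations, "pp", cid)).data)
        labels.append(np.ones(len(pos)))
        probs.append(decode_pairs(P, neg, _rel(relations, "pp", cid)).data)
        labels.append(np.zeros(len(neg)))
    auroc = np.nan
    if probs:
        y = np.concatenate(labels)
        if len(np.unique(y)) == 2:
            auroc = roc_auc_score(y, np.concatenate(probs))
    ch = np.nan
    labels_ctx = graph.context_of_node
    if len(np.unique(labels_ctx)) >= 2:
        try:
            ch = calinski_harabasz_score(P.data, labels_ctx)
        except ValueError:
            pass
    return float(auroc), float(ch)


def train(graph: MultiScaleGraph, split: EdgeSplit, config: TrainConfig, verbose: bool = False) -> TrainResult:
    """Pretrain on the multi-scale graph; returns the best checkpoint.

    Message passing uses only the train-split adjacency; validation and
    test edges stay invisible to the forward pass.  Raises on a
    non-finite loss with the epoch and the offending components.
    """
    if graph.features is None:
        init_protein_features(graph, config.d_in, seed=config.seed)
    mp = init_params(
        graph,
        d_in=config.d_in,
        d_out=config.d_out,
        n_heads=config.n_heads,
        hidden_head_dim=config.hidden_head_dim,
        n_layers=config.n_layers,
        seed=config.seed,
    )
    relations = RelationEmbeddings.init(
        config.d_out,
        seed=config.seed + 1,
        per_context_pp=graph.context_ids if config.per_context_pp_relation else None,
    )
    n_cells = len(graph.metagraph.cell_types)
    centers = Tensor(np.zeros((n_cells, config.d_out)), requires_grad=True)
    opt = build_optimizer(mp, relations, centers, config)
    train_edges = {cid: split.positives[cid]["train"] for cid in graph.context_ids}

    rows = []
    best: tuple[float, float] = (-np.inf, -np.inf)
    best_state = None
    best_epoch = -1
    for epoch in range(config.epochs):
        rng = np.random.default_rng((config.seed * 100003 + epoch) % (2**31))
        P, cellH, tissueH = forward(
            graph,
            mp,
            train_edges=train_edges,
            training=True,
            drop=config.dropout,
            rng=rng,
            use_metagraph=config.use_metagraph,
        )
        comps = _epoch_losses(graph, split, P, cellH, tissueH, relations, centers, config, rng)
        loss = total_loss(
            comps["l_ppi"],
            comps["l_cellid"],
            comps["l_cc"] + comps["l_ct"],
            comps["l_tt"] + comps["l_tc"],
            config.weights,
        )
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: "
                + ", ".join(f"{k}={float(v.data):.4g}" for k, v in comps.items())
            )
        opt.zero_grad()
        loss.backward()
        opt.step()

        # Evaluation pass: no dropout, same train adjacency.
        P_eval, cellH_eval, tissueH_eval = forward(
            graph, mp, train_edges=train_edges, training=False,
            use_metagraph=config.use_metagraph,
        )
        auroc, ch = _validation_metrics(graph, split, P_eval, relations)
        row = {"epoch": epoch, **{k: float(v.data) for k, v in comps.items()},
               "total": float(loss.data), "val_auroc": auroc, "val_ch": ch}
        rows.append(row)
        if verbose:
            print(
                f"epoch {epoch}: total={row['total']:.4f} val_auroc={auroc:.4f}",
                file=sys.stderr,
            )
        key = (auroc if np.isfinite(auroc) else -np.inf, ch if np.isfinite(ch) else -np.inf)
        if key > best:
            best = key
            best_epoch = epoch
            best_state = (
                {k: v.data.copy() for k, v in mp.params.items()},
                {k: v.data.copy() for k, v in relations.vectors.items()},
                centers.data.copy(),
                embeddings_from_forward(graph, P_eval, cellH_eval, tissueH_eval),
            )

    log = pd.DataFrame(rows)
    if best_state is not None:
        for k, v in best_state[0].items():
            mp.params[k].data = v
        for k, v in best_state[1].items():
            relations.vectors[k].data = v
        centers.data = best_state[2]
        embeddings = best_state[3]
    else:  # no usable validation signal; keep final state
        P_eval, cellH_eval, tissueH_eval = forward(
            graph, mp, train_edges=train_edges, training=False,
            use_metagraph=config.use_metagraph,
        )
        embeddings = embeddings_from_forward(graph, P_eval, cellH_eval, tissueH_eval)
        best_epoch = config.epochs - 1
    return TrainResult(
        params=mp,
        relations=relations,
        centers=centers,
        embeddings=embeddings,
        log=log,
        best_epoch=best_epoch,
        config=config,
    )


def select_model(log: pd.DataFrame) -> int:
    """Epoch with maximal validation AUROC; ties broken by the
    cluster-separation (Calinski-Harabasz) score."""
    if len(log) == 0:
        raise ValueError("empty training log")
    auroc = log["val_auroc"].to_numpy(dtype=float)
    ch = log["val_ch"].to_numpy(dtype=float)
    auroc = np.where(np.isfinite(auroc), auroc, -np.inf)
    ch = np.where(np.isfinite(ch), ch, -np.inf)
    order = np.lexsort((log["epoch"].to_numpy(), -ch, -auroc))
    return int(log["epoch"].iloc[order[0]])


def export_embeddings(embeddings: EmbeddingSet, outdir) -> dict[str, str]:
    """Write protein-context, cell-type and tissue embedding TSVs."""
    os.makedirs(outdir, exist_ok=True)
    graph = embeddings.graph
    names = sorted(graph.protein_index, key=graph.protein_index.get)
    paths = {
        "protein": os.path.join(outdir, "protein_embeddings.tsv"),
        "cell_type": os.path.join(outdir, "cell_type_embeddings.tsv"),
        "tissue": os.path.join(outdir, "tissue_embeddings.tsv"),
    }
    _io.write_embedding_tsv(paths["protein"], names, embeddings.protein_matrix, ("protein", "context"))
    _io.write_embedding_tsv(
        paths["cell_type"],
        [(c,) for c in graph.metagraph.cell_types],
        embeddings.cell_matrix,
        ("cell_type",),
    )
    _io.write_embedding_tsv(
        paths["tissue"],
        [(t,) for t in graph.metagraph.tissues],
        embeddings.tissue_matrix,
        ("tissue",),
    )
    return paths


def save_checkpoint(result: TrainResult, path) -> None:
    """Single .npz archive of parameter arrays plus a JSON hyperparameter sidecar."""
    import json

    arrays = {f"param:{k}": v.data for k, v in result.params.params.items()}
    arrays.update({f"rel:{k}": v.data for k, v in result.relations.vectors.items()})
    arrays["centers"] = result.centers.data
    np.savez(path, **arrays)
    cfg = asdict(result.config)
    cfg["normalization"] = list(cfg["normalization"])
    with open(str(path) + ".json", "w") as fh:
        json.dump(cfg, fh, indent=1)
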