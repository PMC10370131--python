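"""Target prioritization on top of pretrained contextual embeddings.

Labels live at the protein-identity level; a protein's context-specific
representations all inherit its train/val/test assignment so no
identity straddles two splits.  A small MLP head scores each
(protein, context) embedding; per-context APR@K over the test rows
ranks the cell-type contexts by predictive ability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .attention import EmbeddingSet
from .autodiff import Adam, Tensor, dropout, layer_norm
from .metrics import apr_at_k
from .objectives import link_loss

__all__ = [
    "TargetLabelSet",
    "PredictionTable",
    "HeadConfig",
    "split_targets",
    "train_head",
    "predict",
    "rank_contexts",
    "rank_contexts_for_protein",
    "TargetPrioritizationModel",
    "TargetPrioritizationResults",
]

SPLITS = ("train", "val", "test")


@dataclass
class TargetLabelSet:
    """Binary target labels with a leakage-free identity-level split."""

    labels: dict[str, int]
    split: dict[str, str]

    def __post_init__(self):
        for p, s in self.split.items():
            if s not in SPLITS:
                raise ValueError(f"bad split {s!r} for protein {p!r}")
            if p not in self.labels:
                raise ValueError(f"protein {p!r} has a split but no label")

    def proteins(self, split_name: str) -> list[str]:
        return sorted(p for p, s in self.split.items() if s == split_name)


@dataclass
class PredictionTable:
    """One scored row per labeled (protein, context) pair."""

    frame: pd.DataFrame  # columns: protein, context, score, label, split

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def split_targets(
    labels: dict[str, int],
    embeddings: EmbeddingSet,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> TargetLabelSet:
    """Assign labeled proteins to train/val/test at the identity level.

    Proteins absent from every context network are dropped with a
    warning.  After the uniform draw, a greedy repair (contexts visited
    by ascending positive count) moves positives between splits so each
    context with at least one positive per missing split can be covered;
    contexts with no positives at all are excluded from the coverage
    constraint.  Achieved fractions may therefore deviate from the
    requested ratios.
    """
    pos = [p for p, y in labels.items() if y == 1]
    neg = [p for p, y in labels.items() if y == 0]
    if not pos or not neg:
        raise ValueError("need at least one positive and one negative label")
    present = {p: embeddings.contexts_of(p) for p in labels}
    dropped = [p for p, ctxs in present.items() if not ctxs]
    if dropped:
        warnings.warn(f"{len(dropped)} labeled protein(s) not present in any context; dropped")
    usable = sorted(p for p in labels if present[p])

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(usable))
    m = len(order)
    raw = np.asarray(ratios) * m
    counts = np.floor(raw).astype(int)
    for _ in range(m - counts.sum()):
        counts[np.argmax(raw - counts)] += 1
    split: dict[str, str] = {}
    start = 0
    for name, c in zip(SPLITS, counts):
        for p in order[start : start + c]:
            split[p] = name
        start += c

    # Coverage repair: every context should see >= 1 positive per split
    # where it has enough positives to spare.
    ctx_pos: dict[str, list[str]] = {}
    for p in pos:
        for c in present.get(p, []):
            ctx_pos.setdefault(c, []).append(p)
    for c in sorted(ctx_pos, key=lambda c: (len(ctx_pos[c]), c)):
        members = sorted(ctx_pos[c])
        if len(members) < 2:
            continue
        have = {s: [p for p in members if split[p] == s] for s in SPLITS}
        feasible = SPLITS if len(members) >= 3 else SPLITS[:2]
        for missing in feasible:
            if have[missing]:
                continue
            donors = max(
                (s for s in SPLITS if s != missing),
                key=lambda s: len(have[s]),
            )
            if len(have[donors]) < 2:
                continue
            mover = have[donors].pop()  # deterministic: sorted order
            split[mover] = missing
            have[missing].append(mover)
    return TargetLabelSet(
        labels={p: labels[p] for p in usable},
        split=split,
    )


@dataclass(frozen=True)
class HeadConfig:
    """MLP head over contextual embeddings: input -> hidden -> output,
    with layer normalization then dropout between input and hidden."""

    hidden1: int = 32
    hidden2: int = 16
    lr: float = 0.001
    dropout: float = 0.5
    weight_decay: float = 1e-4
    epochs: int = 150


@dataclass
class MLPHead:
    params: dict[str, Tensor]
    config: HeadConfig

    @classmethod
    def init(cls, d_in: int, config: HeadConfig, seed: int) -> "MLPHead":
        rng = np.random.default_rng(seed)

        def glorot(shape):
            limit = np.sqrt(6.0 / sum(shape))
            return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

        params = {
            "W1": glorot((d_in, config.hidden1)),
            "b1": Tensor(np.zeros(config.hidden1), requires_grad=True),
            "W2": glorot((config.hidden1, config.hidden2)),
            "b2": Tensor(np.zeros(config.hidden2), requires_grad=True),
            "W3": glorot((config.hidden2, 1)),
            "b3": Tensor(np.zeros(1), requires_grad=True),
            "ln_g": Tensor(np.ones(config.hidden1), requires_grad=True),
            "ln_b": Tensor(np.zeros(config.hidden1), requires_grad=True),
        }
        return cls(params=params, config=config)

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> Tensor:
        p = self.params
        h = (Tensor(x) @ p["W1"] + p["b1"]).relu()
        h = layer_norm(h, p["ln_g"], p["ln_b"])
        h = dropout(h, self.config.dropout, rng or np.random.default_rng(0), training)
        h = (h @ p["W2"] + p["b2"]).relu()
        return (h @ p["W3"] + p["b3"]).sigmoid().reshape(-1)


def _rows(embeddings: EmbeddingSet, labelset: TargetLabelSet) -> pd.DataFrame:
    rows = []
    for p in sorted(labelset.labels):
        for c in embeddings.contexts_of(p):
            rows.append((p, c, labelset.labels[p], labelset.split[p]))
    return pd.DataFrame(rows, columns=["protein", "context", "label", "split"])


def train_head(
    embeddings: EmbeddingSet,
    labelset: TargetLabelSet,
    config: HeadConfig | None = None,
    seed: int = 0,
) -> tuple[MLPHead, PredictionTable]:
    """Fit the MLP head; early selection on validation average precision.

    Training rows are all (protein, context) representations of train
    proteins; the returned table scores every labeled representation
    with the selected checkpoint.
    """
    config = config or HeadConfig()
    table = _rows(embeddings, labelset)
    if not len(table[table["split"] == "train"]):
        raise ValueError("empty training split")
    feats = np.stack(
        [embeddings.protein(p, c) for p, c in zip(table["protein"], table["context"])]
    )
    y = table["label"].to_numpy(dtype=float)
    tr = (table["split"] == "train").to_numpy()
    va = (table["split"] == "val").to_numpy()

    head = MLPHead.init(feats.shape[1], config, seed)
    opt = Adam(
        [{"params": head.params, "lr": config.lr, "weight_decay": config.weight_decay}]
    )
    best_ap, best_state = -np.inf, None
    for epoch in range(config.epochs):
        rng = np.random.default_rng((seed * 9176 + epoch) % (2**31))
        probs = head.forward(feats[tr], training=True, rng=rng)
        loss = link_loss(probs, y[tr])
        opt.zero_grad()
        loss.backward()
        opt.step()
        if va.any() and len(np.unique(y[va])) == 2:
            ap = average_precision_score(y[va], head.forward(feats[va]).data)
        else:
            ap = -float(loss.data)
        if ap > best_ap:
            best_ap = ap
            best_state = {k: v.data.copy() for k, v in head.params.items()}
    if best_state is not None:
        for k, v in best_state.items():
            head.params[k].data = v

    table = table.copy()
    table["score"] = head.forward(feats).data
    table = table[["protein", "context", "score", "label", "split"]]
    return head, PredictionTable(frame=table)


def predict(head: MLPHead, embeddings: EmbeddingSet, labelset: TargetLabelSet) -> PredictionTable:
    table = _rows(embeddings, labelset)
    feats = np.stack(
        [embeddings.protein(p, c) for p, c in zip(table["protein"], table["context"])]
    )
    table["score"] = head.forward(feats).data
    return PredictionTable(frame=table[["protein", "context", "score", "label", "split"]])


def rank_contexts(predictions: PredictionTable | list[PredictionTable], k: int = 5) -> pd.DataFrame:
    """Rank contexts by APR@K over their test rows (descending).

    Within a context, test proteins are ordered by decreasing score
    (ties by protein symbol for determinism).  Contexts without test
    positives are omitted with a warning.  A list of tables (multiple
    seeds) is averaged per context before ranking.
    """
    tables = predictions if isinstance(predictions, list) else [predictions]
    per_context: dict[str, list[float]] = {}
    for tab in tables:
        test = tab.frame[tab.frame["split"] == "test"]
        for ctx, grp in test.groupby("context"):
            if grp["label"].sum() == 0:
                warnings.warn(f"context {ctx}: no test positives; omitted")
                continue
            grp = grp.sort_values(["score", "protein"], ascending=[False, True])
            rel = grp["label"].to_numpy()
            per_context.setdefault(ctx, []).append(apr_at_k(rel, min(k, len(rel))))
    rows = [
        (ctx, float(np.mean(vals)), len(vals)) for ctx, vals in sorted(per_context.items())
    ]
    out = pd.DataFrame(rows, columns=["context", "apr_at_k", "n_runs"])
    return out.sort_values(["apr_at_k", "context"], ascending=[False, True]).reset_index(drop=True)


def rank_contexts_for_protein(predictions: PredictionTable, protein: str) -> pd.DataFrame:
    """Order one protein's contexts by the head's score (descending)."""
    rows = predictions.frame[predictions.frame["protein"] == protein]
    if not len(rows):
        raise ValueError(f"unknown protein {protein!r}")
    return (
        rows.sort_values(["score", "context"], ascending=[False, True])
        .reset_index(drop=True)[["context", "score"]]
    )


# -- statsmodels-style facade --------------------------------------------------


class TargetPrioritizationModel:
    """Binary target-prioritization head over contextual embeddings.

    Parameters
    ----------
    embeddings : EmbeddingSet
        Pretrained (protein, context) embeddings.
    labels : dict[str, int]
        Protein -> {0, 1} druggability labels.
    config : HeadConfig, optional
    """

    def __init__(self, embeddings: EmbeddingSet, labels: dict[str, int],
                 config: HeadConfig | None = None):
        self.embeddings = embeddings
        self.labels = dict(labels)
        self.config = config or HeadConfig()

    @classmethod
    def from_tsv(cls, embeddings: EmbeddingSet, path, config: HeadConfig | None = None):
        from . import io as _io

        return cls(embeddings, _io.read_labels(path), config)

    def fit(self, seed: int = 0, ratios=(0.6, 0.2, 0.2)) -> "TargetPrioritizationResults":
        labelset = split_targets(self.labels, self.embeddings, ratios=ratios, seed=seed)
        head, predictions = train_head(self.embeddings, labelset, self.config, seed=seed)
        return TargetPrioritizationResults(self, head, labelset, predictions)


@dataclass
class TargetPrioritizationResults:
    model: TargetPrioritizationModel
    head: MLPHead
    labelset: TargetLabelSet
    predictions: PredictionTable
    _ranking: pd.DataFrame | None = field(default=None, repr=False)

    def rank_contexts(self, k: int = 5) -> pd.DataFrame:
        return rank_contexts(self.predictions, k=k)

    def rank_contexts_for_protein(self, protein: str) -> pd.DataFrame:
        return rank_contexts_for_protein(self.predictions, protein)

    def summary(self, k: int = 5) -> str:
        ranking = self.rank_contexts(k=k)
        test = self.predictions.frame[self.predictions.frame["split"] == "test"]
        lines = [
            "Target prioritization results",
            "=============================",
            f"labeled proteins: {len(self.labelset.labels)} "
            f"({sum(self.labelset.labels.values())} positive)",
            f"test rows: {len(test)}",
            "",
            f"context ranking by APR@{k}:",
        ]
        for _, row in ranking.iterrows():
            lines.append(f"  {row['context']:<12} {row['apr_at_k']:.4f}")
        return "\n".join(lines)
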