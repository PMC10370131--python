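"""The composite training objective.

Link prediction at every scale uses a diagonal bilinear (DistMult-style)
decoder: the score of an edge of type i between nodes u and v is
``sum_k z_u[k] * r_i[k] * z_v[k]``, mapped to a probability by the
logistic function and penalized with binary cross-entropy.  A center
loss pulls each protein embedding toward its cell type's center to
enforce cell-type identity.  The total loss combines the scales as

    L = theta * L_ppi + lambda * L_cellid + (1 - theta) * (L_cc + L_ct)
        + (L_tt + L_tc)

Each term is a mean rather than a raw sum so contexts of different
sizes contribute comparably; for fixed splits this is a monotone
rescaling that does not move the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather

__all__ = [
    "LossWeights",
    "RelationEmbeddings",
    "decode_edge",
    "link_loss",
    "center_loss",
    "total_loss",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """theta balances protein-level vs cell-type-level link prediction;
    lambda_ scales the cell-type-identification (center loss) term."""

    theta: float = 0.5
    lambda_: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError("lambda_ must lie in [0, 1]")


@dataclass
class RelationEmbeddings:
    """One vector per edge type; pp is shared across contexts by default."""

    vectors: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, d_out: int, seed: int = 0, per_context_pp: list[str] | None = None):
        rng = np.random.default_rng(seed)
        names = ["pp", "cc", "ct", "tc", "tt"]
        if per_context_pp is not None:
            names = [f"pp.{c}" for c in per_context_pp] + ["cc", "ct", "tc", "tt"]
        vecs = {
            n: Tensor(rng.standard_normal(d_out) / np.sqrt(d_out), requires_grad=True)
            for n in names
        }
        return cls(vectors=vecs)

    def trainable(self) -> dict[str, Tensor]:
        return {f"rel.{k}": v for k, v in self.vectors.items()}


def decode_edge(z_u: Tensor, r_i: Tensor, z_v: Tensor) -> Tensor:
    """Probability of an edge from the diagonal bilinear score.

    Accepts single vectors (d,) or batches (m, d); the score is the
    elementwise triple product summed over features, and the probability
    its logistic transform.  Symmetric in u and v.
    """
    if z_u.shape[-1] != r_i.shape[-1] or z_v.shape[-1] != r_i.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {z_u.shape[-1]}, {r_i.shape[-1]}, {z_v.shape[-1]}"
        )
    score = (z_u * r_i * z_v).sum(axis=-1)
    return score.sigmoid()


def link_loss(probabilities: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over an edge set.

    Probabilities are clipped away from {0, 1} by epsilon, so perfect
    predictions give a loss near (not exactly) zero.
    """
    y = np.asarray(labels, dtype=np.float64)
    clipped = probabilities * (1 - 2 * _EPS) + _EPS
    ll = Tensor(y) * clipped.log() + Tensor(1.0 - y) * (1.0 - clipped).log()
    return -ll.mean()


def center_loss(z: Tensor, context_of_node: np.ndarray, centers: Tensor) -> Tensor:
    """Mean squared distance of each protein embedding to its context center.

    ``centers`` has one row per context, indexed by `context_of_node`.
    A node whose context index falls outside `centers` is a caller error.
    """
    context_of_node = np.asarray(context_of_node, dtype=np.intp)
    if context_of_node.size and context_of_node.max() >= centers.shape[0]:
        raise ValueError("missing center for some context")
    diff = z - gather(centers, context_of_node)
    return (diff**2).sum(axis=-1).mean()


def total_loss(
    ppi: Tensor | float,
    cellid: Tensor | float,
    celltype: Tensor | float,
    tissue: Tensor | float,
    weights: LossWeights,
) -> Tensor:
    """Composite objective across the three biological scales.

    `celltype` is L_cc + L_ct and `tissue` is L_tt + L_tc, computed by
    the caller; the tissue term carries no (1 - theta) factor.
    """
    t = Tensor.as_tensor
    return (
        weights.theta * t(ppi)
        + weights.lambda_ * t(cellid)
        + (1.0 - weights.theta) * t(celltype)
        + t(tissue)
    )


def decode_pairs(z: Tensor, pairs: np.ndarray, r: Tensor) -> Tensor:
    """Decode a batch of (u, v) node-id pairs against relation vector r."""
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    return decode_edge(gather(z, pairs[:, 0]), r, gather(z, pairs[:, 1]))


def decode_cross_pairs(z_a: Tensor, z_b: Tensor, pairs: np.ndarray, r: Tensor) -> Tensor:
    """Decode (a, b) pairs whose endpoints live in two different node sets."""
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    return decode_edge(gather(z_a, pairs[:, 0]), r, gather(z_b, pairs[:, 1]))


def link_loss_pos_neg(probs_pos: Tensor, probs_neg: Tensor) -> Tensor:
    """BCE over a positive set and its matched negatives."""
    probs = concat([probs_pos, probs_neg], axis=0)
    labels = np.concatenate([np.ones(probs_pos.shape[0]), np.zeros(probs_neg.shape[0])])
    return link_loss(probs, labels)
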