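"""End-to-end training of the embedding with a negative-sampling loss.

The objective pulls known (positive) disease pairs toward high sigmoid
dot-product scores and pushes sampled non-associated pairs toward low
scores:

    L = - sum_{(d1,d2) in pos} log sigma(h_d1 . h_d2)
        - sum_{(d1,d2) in neg} log sigma(-h_d1 . h_d2)

Negatives are re-sampled every epoch from the complement of the positive
set (uniform over unordered disease pairs, seeded).  Optimisation is Adam
on every learnable tensor.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .graph import HeterogeneousGraph, NodeType
from .model import EmbeddingConfig, GraphIndex, forward_embed, init_params, \
    trainable

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _canon(pair) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def score_pair(h1: np.ndarray, h2: np.ndarray) -> float | np.ndarray:
    """Association probability sigma(h1 . h2); symmetric, in (0, 1)."""
    h1, h2 = np.asarray(h1, dtype=np.float64), np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError(f"embedding shapes differ: {h1.shape} vs {h2.shape}")
    dot = (h1 * h2).sum(axis=-1)
    out = 1.0 / (1.0 + np.exp(-np.clip(dot, -500, 500)))
    return float(out) if np.isscalar(dot) or dot.ndim == 0 else out


@dataclass
class PairSet:
    """Positive pairs (known associations) and sampled negatives.

    Invariants: disjoint, unordered, no self-pairs, all members disease
    nodes of the graph they were built against.
    """

    positives: list[Pair]
    negatives: list[Pair] = field(default_factory=list)

    def __post_init__(self):
        self.positives = [_canon(p) for p in self.positives]
        self.negatives = [_canon(p) for p in self.negatives]
        pos = set(self.positives)
        if any(a == b for a, b in itertools.chain(self.positives,
                                                  self.negatives)):
            raise ValueError("self-pairs are not allowed")
        if pos & set(self.negatives):
            raise ValueError("positive and negative sets overlap")


def _log_sigmoid_np(x: np.ndarray) -> np.ndarray:
    return np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))


def compute_loss(pairs: PairSet, embeddings: dict[str, np.ndarray]) -> float:
    """Numerically stable negative-sampling loss on fixed embeddings."""
    if not pairs.positives:
        raise ValueError("empty positive set")
    dots_pos = np.array([np.dot(embeddings[a], embeddings[b])
                         for a, b in pairs.positives])
    loss = -_log_sigmoid_np(dots_pos).sum()
    if pairs.negatives:
        dots_neg = np.array([np.dot(embeddings[a], embeddings[b])
                             for a, b in pairs.negatives])
        loss += -_log_sigmoid_np(-dots_neg).sum()
    return float(loss)


def loss_tensor(emb: Tensor, pos_idx: np.ndarray, neg_idx: np.ndarray,
                ) -> Tensor:
    """Differentiable loss on embedding rows indexed by pair arrays (n, 2)."""
    def dots(idx):
        h1 = ad.take_rows(emb, idx[:, 0])
        h2 = ad.take_rows(emb, idx[:, 1])
        return ad.tensor_sum(ad.mul(h1, h2), axis=1)

    loss = ad.neg(ad.tensor_sum(ad.log_sigmoid(dots(pos_idx))))
    if len(neg_idx):
        loss = ad.sub(loss, ad.tensor_sum(ad.log_sigmoid(ad.neg(dots(neg_idx)))))
    return loss


def all_disease_pairs(disease_ids: list[str]):
    return itertools.combinations(sorted(disease_ids), 2)


def sample_negatives(graph: HeterogeneousGraph, positives, ratio: float = 1.0,
                     seed: int = 0, exclude=()) -> list[Pair]:
    """Seeded uniform sample of non-positive unordered disease pairs.

    Draws ``ratio * len(positives)`` pairs from the complement of the
    positive set (minus `exclude`, e.g. held-out evaluation negatives),
    without replacement.  If the complement is smaller than requested, the
    whole complement is returned with a warning.
    """
    pos = {_canon(p) for p in positives}
    banned = pos | {_canon(p) for p in exclude}
    complement = [p for p in all_disease_pairs(
        graph.nodes_of_type(NodeType.DISEASE)) if p not in banned]
    want = int(round(ratio * len(pos)))
    rng = np.random.default_rng(seed)
    if want >= len(complement):
        if want > len(complement):
            logger.warning("requested %d negatives but complement has only "
                           "%d pairs; returning all", want, len(complement))
        return complement
    keep = np.sort(rng.choice(len(complement), size=want, replace=False))
    return [complement[i] for i in keep]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters.

    epochs: full-batch gradient steps.
    lr: Adam learning rate.
    neg_ratio: negatives sampled per positive per epoch (>= 1).
    patience: early-stopping patience on validation AUC (0 disables);
        validation pairs are carved from the training positives.
    val_fraction: share of positives held out for early stopping.
    seed: governs negative sampling, dropout and the validation split.
    """

    epochs: int = 100
    lr: float = 5e-3
    neg_ratio: float = 1.0
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.epochs <= 0 or self.lr < 0:
            raise ValueError("epochs must be positive and lr non-negative")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")


class Adam:
    """Adaptive-moment gradient descent over a list of tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


@dataclass
class TrainResult:
    params: dict[str, Tensor]
    disease_ids: list[str]
    embeddings: np.ndarray          # eval-mode, (n_diseases, out_dim)
    loss_trace: list[float]
    best_epoch: int


def _pairs_to_idx(pairs, local: dict[str, int]) -> np.ndarray:
    return np.asarray([[local[a], local[b]] for a, b in pairs],
                      dtype=np.intp).reshape(len(pairs), 2)


def _quick_auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    from .evaluation import auc
    scores = np.concatenate([scores_pos, scores_neg])
    labels = np.concatenate([np.ones(len(scores_pos)),
                             np.zeros(len(scores_neg))])
    return auc(scores, labels)


def train(graph: HeterogeneousGraph, positives,
          embed_config: EmbeddingConfig | None = None,
          train_config: TrainingConfig | None = None,
          exclude_negatives=(), index: GraphIndex | None = None,
          params: dict[str, Tensor] | None = None) -> TrainResult:
    """Fit all model parameters by full-batch Adam on the pair loss.

    `exclude_negatives` keeps held-out evaluation negatives out of the
    training negative samples.  A pre-built `index` (and optionally a warm
    `params` dict) may be supplied to reuse instance enumeration.
    """
    embed_config = embed_config or EmbeddingConfig()
    train_config = train_config or TrainingConfig()
    if index is None:
        index = GraphIndex(graph, embed_config)
    if index.n_diseases < 2:
        raise ValueError("training needs at least two disease nodes")
    positives = [_canon(p) for p in positives]
    if not positives:
        raise ValueError("empty positive set")
    local = {n: i for i, n in enumerate(index.disease_ids)}
    for a, b in positives:
        if a not in local or b not in local:
            raise ValueError(f"positive pair ({a}, {b}) references a node "
                             "that is not a disease in the graph")

    rng = np.random.default_rng(train_config.seed)
    # early-stopping split (only when there is enough signal to split)
    val_pos: list[Pair] = []
    train_pos = positives
    if train_config.patience > 0 and len(positives) >= 20:
        n_val = max(2, int(round(train_config.val_fraction * len(positives))))
        order = rng.permutation(len(positives))
        val_pos = [positives[i] for i in order[:n_val]]
        train_pos = [positives[i] for i in order[n_val:]]
        val_neg = sample_negatives(
            graph, positives, ratio=max(1.0, len(val_pos) / len(positives)),
            seed=train_config.seed + 7919, exclude=exclude_negatives)
        val_neg = val_neg[:max(2, len(val_pos))]

    if params is None:
        params = init_params(index, embed_config)
    opt = Adam(trainable(params), lr=train_config.lr)
    pos_idx = _pairs_to_idx(train_pos, local)
    loss_trace: list[float] = []
    best_auc, best_epoch, best_state, stall = -np.inf, 0, None, 0
    exclude_all = list(exclude_negatives) + val_pos
    for epoch in range(train_config.epochs):
        negs = sample_negatives(graph, positives,
                                ratio=train_config.neg_ratio,
                                seed=train_config.seed + 31 * epoch + 1,
                                exclude=exclude_all)
        neg_idx = _pairs_to_idx(negs, local)
        drop_rng = np.random.default_rng(
            np.random.SeedSequence([train_config.seed, 101, epoch]))
        emb = forward_embed(index, params, embed_config, training=True,
                            rng=drop_rng)
        loss = loss_tensor(emb, pos_idx, neg_idx)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {loss.data!r}; "
                f"lr={train_config.lr}, |pos|={len(train_pos)}, |neg|={len(negs)}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_trace.append(float(loss.data))
        if val_pos:
            emb_eval = forward_embed(index, params, embed_config,
                                     training=False).data
            def _score(pairs):
                return np.array([score_pair(emb_eval[local[a]],
                                            emb_eval[local[b]])
                                 for a, b in pairs])
            vauc = _quick_auc(_score(val_pos), _score(val_neg))
            if vauc > best_auc + 1e-9:
                best_auc, best_epoch, stall = vauc, epoch, 0
                best_state = {k: p.data.copy() for k, p in params.items()}
            else:
                stall += 1
                if stall >= train_config.patience:
                    break
        else:
            best_epoch = epoch
    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    final = forward_embed(index, params, embed_config, training=False)
    return TrainResult(params=params, disease_ids=index.disease_ids,
                       embeddings=final.data, loss_trace=loss_trace,
                       best_epoch=best_epoch)
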