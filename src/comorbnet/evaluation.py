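"""Metrics, repeated k-fold cross-validation, and ranked predictions.

AUC is the rank-based (Mann-Whitney, midranks for ties) area under the ROC
curve; AP is the step-sum area under the precision-recall curve.  Both are
delegated to scikit-learn after input validation.  Cross-validation
partitions the positive pair set into seeded folds, trains on nine folds
with sampled negatives, and evaluates each held-out fold against an
equal-sized held-out negative sample that the training negatives never see.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import HeterogeneousGraph
from .model import EmbeddingConfig, GraphIndex
from .training import TrainingConfig, _canon, sample_negatives, score_pair, \
    train

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midranks for ties; needs both classes."""
    scores, labels = _validate(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class present")
    return float(roc_auc_score(labels, scores))


def average_precision(scores, labels) -> float:
    """AP = sum_k (R_k - R_{k-1}) P_k over descending-score thresholds."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AP undefined without positives")
    return float(average_precision_score(labels, scores))


@dataclass
class EvaluationReport:
    """Per-fold, per-repeat and aggregate AUC/AP (fractions internally)."""

    folds: int
    repeats: int
    fold_auc: np.ndarray            # (repeats, folds)
    fold_ap: np.ndarray
    seeds: list[int] = field(default_factory=list)

    @property
    def repeat_auc(self) -> np.ndarray:
        return self.fold_auc.mean(axis=1)

    @property
    def repeat_ap(self) -> np.ndarray:
        return self.fold_ap.mean(axis=1)

    @property
    def mean_auc(self) -> float:
        return float(self.fold_auc.mean())

    @property
    def mean_ap(self) -> float:
        return float(self.fold_ap.mean())

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "repeats": self.repeats,
            "seeds": list(self.seeds),
            "fold_auc": self.fold_auc.tolist(),
            "fold_ap": self.fold_ap.tolist(),
            "repeat_auc": self.repeat_auc.tolist(),
            "repeat_ap": self.repeat_ap.tolist(),
            # reported as percentages, two decimals, table-style
            "mean_auc_pct": round(100 * self.mean_auc, 2),
            "mean_ap_pct": round(100 * self.mean_ap, 2),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        """One row per (repeat, fold) with AUC and AP."""
        with open(path, "w") as fh:
            fh.write("repeat,fold,auc,ap\n")
            for r in range(self.repeats):
                for k in range(self.folds):
                    fh.write(f"{r},{k},{self.fold_auc[r, k]:.6f},"
                             f"{self.fold_ap[r, k]:.6f}\n")


def make_folds(positives: list[Pair], folds: int, seed: int,
               ) -> list[list[Pair]]:
    """Seeded partition of the positive set into `folds` near-equal folds."""
    if len(positives) < folds:
        raise ValueError(f"{len(positives)} positives cannot fill {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    out: list[list[Pair]] = [[] for _ in range(folds)]
    for k, i in enumerate(order):
        out[k % folds].append(positives[i])
    return out


def cross_validate(graph: HeterogeneousGraph, positives,
                   embed_config: EmbeddingConfig | None = None,
                   train_config: TrainingConfig | None = None,
                   folds: int = 10, repeats: int = 10, seed: int = 0,
                   ) -> EvaluationReport:
    """Repeated stratified-by-pair k-fold evaluation of link prediction.

    Per fold: train on the other folds' positives (negatives re-sampled per
    epoch, excluding the held-out negatives), then score held-out positives
    against an equal-sized seeded negative sample disjoint from both the
    positive set and the training negatives.  Repeats rerun the whole
    procedure with distinct derived seeds and are averaged.
    """
    embed_config = embed_config or EmbeddingConfig()
    train_config = train_config or TrainingConfig()
    positives = [_canon(p) for p in positives]
    fold_auc = np.zeros((repeats, folds))
    fold_ap = np.zeros((repeats, folds))
    seeds = []
    for r in range(repeats):
        rseed = int(np.random.SeedSequence([seed, r]).generate_state(1)[0]
                    % (2 ** 31 - 1))
        seeds.append(rseed)
        parts = make_folds(positives, folds, rseed)
        ecfg = dataclasses.replace(embed_config, seed=rseed)
        index = GraphIndex(graph, ecfg)
        local = {n: i for i, n in enumerate(index.disease_ids)}
        for k, test_pos in enumerate(parts):
            if not test_pos:
                raise ValueError(f"fold {k} has zero positives")
            train_pos = [p for j, part in enumerate(parts) if j != k
                         for p in part]
            test_neg = sample_negatives(graph, positives,
                                        ratio=len(test_pos) / len(positives),
                                        seed=rseed + 13 * k + 5)
            tcfg = dataclasses.replace(train_config, seed=rseed + 977 * k)
            result = train(graph, train_pos, ecfg, tcfg,
                           exclude_negatives=test_neg, index=index)
            emb = result.embeddings

            def _scores(pairs):
                return np.array([score_pair(emb[local[a]], emb[local[b]])
                                 for a, b in pairs])

            s = np.concatenate([_scores(test_pos), _scores(test_neg)])
            y = np.concatenate([np.ones(len(test_pos)),
                                np.zeros(len(test_neg))])
            fold_auc[r, k] = auc(s, y)
            fold_ap[r, k] = average_precision(s, y)
        logger.info("repeat %d: AUC %.4f, AP %.4f", r,
                    fold_auc[r].mean(), fold_ap[r].mean())
    return EvaluationReport(folds=folds, repeats=repeats,
                            fold_auc=fold_auc, fold_ap=fold_ap, seeds=seeds)


def rank_predictions(disease_ids: list[str], embeddings: np.ndarray,
                     known_positives, top_k: int | None = None,
                     ) -> list[tuple[int, str, str, float]]:
    """Score every unordered disease pair not in `known_positives`.

    Returns (rank, disease_1, disease_2, score) rows sorted by descending
    score; ties break lexicographically on the pair ids.
    """
    local = {n: i for i, n in enumerate(disease_ids)}
    known = {_canon(p) for p in known_positives}
    rows = []
    for a, b in itertools.combinations(sorted(local), 2):
        if (a, b) in known:
            continue
        rows.append((a, b, score_pair(embeddings[local[a]],
                                      embeddings[local[b]])))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    if top_k is not None:
        rows = rows[:top_k]
    return [(i + 1, a, b, s) for i, (a, b, s) in enumerate(rows)]
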