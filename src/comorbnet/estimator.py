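"""Scikit-learn-style estimator wrapping the full pipeline.

`DiseaseAssociationPredictor` fits the meta-path attention embedding on a
typed heterogeneous graph plus a list of known disease-pair associations,
then scores arbitrary disease pairs with the sigmoid dot product of their
embeddings.  Hyperparameters follow sklearn conventions (settable in
``__init__``, introspectable via ``get_params``/``set_params``); fitted
state carries a trailing underscore.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .graph import HeterogeneousGraph
from .model import EmbeddingConfig
from .training import TrainingConfig, score_pair, train

__all__ = ["DiseaseAssociationPredictor"]


class DiseaseAssociationPredictor(BaseEstimator):
    """Link predictor for disease-disease associations.

    Parameters
    ----------
    hidden_dim, out_dim, heads, summary_dim, dropout, activation, metapaths,
    instance_cap
        Embedding model structure; see :class:`~comorbnet.model.EmbeddingConfig`.
    epochs, lr, neg_ratio, patience
        Optimisation; see :class:`~comorbnet.training.TrainingConfig`.
    random_state
        Master seed for initialisation, instance subsampling, negative
        sampling and dropout.

    Attributes
    ----------
    disease_ids_ : list of str
        Disease nodes in embedding-row order.
    embeddings_ : ndarray of shape (n_diseases, out_dim)
        Eval-mode embeddings after training.
    params_ : dict of named parameter tensors.
    loss_trace_ : list of per-epoch training losses.
    best_epoch_ : epoch whose parameters were kept (early stopping).
    """

    def __init__(self, hidden_dim: int = 64, out_dim: int = 64,
                 heads: int = 8, summary_dim: int = 128,
                 dropout: float = 0.5, activation: str = "elu",
                 metapaths: tuple[str, ...] = ("M1", "M2", "M3", "M4"),
                 instance_cap: int | None = 128, epochs: int = 100,
                 lr: float = 5e-3, neg_ratio: float = 1.0,
                 patience: int = 10, random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.out_dim = out_dim
        self.heads = heads
        self.summary_dim = summary_dim
        self.dropout = dropout
        self.activation = activation
        self.metapaths = metapaths
        self.instance_cap = instance_cap
        self.epochs = epochs
        self.lr = lr
        self.neg_ratio = neg_ratio
        self.patience = patience
        self.random_state = random_state

    # -- config adapters ---------------------------------------------------

    def _embed_config(self, seed: int | None = None) -> EmbeddingConfig:
        return EmbeddingConfig(
            hidden_dim=self.hidden_dim, out_dim=self.out_dim,
            heads=self.heads, summary_dim=self.summary_dim,
            dropout=self.dropout, activation=self.activation,
            metapaths=tuple(self.metapaths), instance_cap=self.instance_cap,
            seed=self.random_state if seed is None else seed)

    def _train_config(self, seed: int | None = None) -> TrainingConfig:
        return TrainingConfig(
            epochs=self.epochs, lr=self.lr, neg_ratio=self.neg_ratio,
            patience=self.patience,
            seed=self.random_state if seed is None else seed)

    # -- estimator API -----------------------------------------------------

    def fit(self, X: HeterogeneousGraph, y=None, exclude_negatives=()):
        """Train on a typed graph `X` and positive pair list `y`."""
        if y is None:
            raise ValueError("fit requires the positive disease-pair list y")
        result = train(X, list(y), self._embed_config(), self._train_config(),
                       exclude_negatives=exclude_negatives)
        self.graph_ = X
        self.disease_ids_ = result.disease_ids
        self._local = {n: i for i, n in enumerate(result.disease_ids)}
        self.embeddings_ = result.embeddings
        self.params_ = result.params
        self.loss_trace_ = result.loss_trace
        self.best_epoch_ = result.best_epoch
        return self

    def _check_fitted(self):
        if not hasattr(self, "embeddings_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict_proba(self, pairs) -> np.ndarray:
        """Association probability for each (disease, disease) pair."""
        self._check_fitted()
        out = np.empty(len(pairs))
        for i, (a, b) in enumerate(pairs):
            if a not in self._local or b not in self._local:
                raise ValueError(f"pair ({a!r}, {b!r}) contains an unknown "
                                 "disease node")
            out[i] = score_pair(self.embeddings_[self._local[a]],
                                self.embeddings_[self._local[b]])
        return out

    def predict(self, pairs, threshold: float = 0.5) -> np.ndarray:
        """Binary association call at the given probability threshold."""
        return (self.predict_proba(pairs) >= threshold).astype(int)

    def score(self, pairs, labels) -> float:
        """ROC AUC of the predicted probabilities against 0/1 labels."""
        from .evaluation import auc
        return auc(self.predict_proba(pairs), labels)

    def embedding_of(self, disease: str) -> np.ndarray:
        self._check_fitted()
        return self.embeddings_[self._local[disease]]
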