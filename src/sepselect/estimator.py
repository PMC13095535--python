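"""Scikit-learn-style estimator facade over the Actor-Critic pipeline.

:class:`ActorCriticSepsisClassifier` follows the sklearn contract
(``get_params``/``set_params``, ``fit``/``predict``/``predict_proba``,
trailing-underscore fitted attributes) so it composes with pipelines and
model selection. Because sklearn passes a single 2-D design matrix, the
temporal block is carried *flattened*: a row is

    [ static_1..static_{n_static} | signal_1 t_1..t_T | ... | signal_c t_1..t_T ]

and the estimator re-folds it into (n, c, T) internally. Use
:func:`pack_design` / :func:`unpack_design` to convert.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .cohort import CohortTable, TemporalSignals, _feature_names, _signal_names
from .explain import FeatureRanking, rank_selection_probabilities
from .networks import ModelBundle
from .training import TrainConfig, featurize, predict_baseline, predict_critic, train


def pack_design(X_s: np.ndarray, X_v: np.ndarray) -> np.ndarray:
    """Flatten (static, temporal) blocks into one sklearn design matrix."""
    n = X_s.shape[0]
    return np.concatenate([X_s, X_v.reshape(n, -1)], axis=1)


def unpack_design(X: np.ndarray, n_static: int,
                  n_signals: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_design`."""
    X = np.asarray(X, dtype=float)
    X_s = X[:, :n_static]
    rest = X[:, n_static:]
    if rest.shape[1] % n_signals:
        raise ValueError(
            f"temporal block of width {rest.shape[1]} does not divide "
            f"into {n_signals} signals")
    T = rest.shape[1] // n_signals
    return X_s, rest.reshape(X.shape[0], n_signals, T)


class ActorCriticSepsisClassifier(BaseEstimator, ClassifierMixin):
    """Instance-wise feature selection with an Actor-Critic objective.

    Parameters mirror the training protocol: 100 epochs of Adam at learning
    rate 0.01 with exponential decay, batch size 32, attention networks for
    both the selector and the predictor, a 10-layer TCN baseline, and an
    HSIC penalty tying the baseline's temporal embedding to carry
    information beyond the summary statistics.

    Examples
    --------
    >>> from sepselect import SynthConfig, generate_synthetic_cohort
    >>> cohort, signals = generate_synthetic_cohort(SynthConfig(n=200,
    ...     positive_count=10, T=16, seed=1))
    >>> clf = ActorCriticSepsisClassifier(epochs=2, random_state=0)
    >>> X = pack_design(cohort.X_s, signals.X_v)
    >>> probs = clf.fit(X, cohort.y).predict_proba(X)[:, 1]
    """

    def __init__(self, n_static: int = 20, n_signals: int = 5,
                 epochs: int = 100, lr: float = 0.01, lr_decay: float = 0.95,
                 decay_start: int = 50, batch_size: int = 32,
                 lam: float = 0.1, selector_kind: str = "attention",
                 predictor_kind: str = "attention", hidden: int = 64,
                 tcn_channels: int = 32, dropout: float = 0.5,
                 class_weight: bool = False, stratified_batches: bool = False,
                 reward_sign: float = 1.0, pretrain_baseline: int = 0,
                 optimizer: str = "adam", threshold: float = 0.5,
                 random_state: int = 0):
        self.n_static = n_static
        self.n_signals = n_signals
        self.epochs = epochs
        self.lr = lr
        self.lr_decay = lr_decay
        self.decay_start = decay_start
        self.batch_size = batch_size
        self.lam = lam
        self.selector_kind = selector_kind
        self.predictor_kind = predictor_kind
        self.hidden = hidden
        self.tcn_channels = tcn_channels
        self.dropout = dropout
        self.class_weight = class_weight
        self.stratified_batches = stratified_batches
        self.reward_sign = reward_sign
        self.pretrain_baseline = pretrain_baseline
        self.optimizer = optimizer
        self.threshold = threshold
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if not np.isin(classes, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        X_s, X_v = unpack_design(X, self.n_static, self.n_signals)
        ids = [f"P{i:06d}" for i in range(len(y))]
        cohort = CohortTable(ids, X_s, y.astype(int),
                             feature_names=_feature_names(self.n_static))
        signals = TemporalSignals(list(ids), X_v,
                                  signal_names=_signal_names(self.n_signals))

        bundle = ModelBundle.create(
            d=self.n_static + 2 * self.n_signals, n_signals=self.n_signals,
            seed=self.random_state, selector_kind=self.selector_kind,
            predictor_kind=self.predictor_kind, hidden=self.hidden,
            tcn_channels=self.tcn_channels, dropout=self.dropout)
        cfg = TrainConfig(
            epochs=self.epochs, lr=self.lr, lr_decay=self.lr_decay,
            decay_start=self.decay_start, batch_size=self.batch_size,
            lam=self.lam, seed=self.random_state,
            stratified_batches=self.stratified_batches,
            class_weight=self.class_weight, reward_sign=self.reward_sign,
            pretrain_baseline=self.pretrain_baseline,
            optimizer=self.optimizer)
        self.bundle_, self.history_ = train(bundle, cohort, signals, cfg)
        self.feature_names_ = self.history_["feature_names"]

        X_d = featurize(self.bundle_, cohort, signals)
        _, S_d, _ = predict_critic(self.bundle_, X_d)
        self.selection_probabilities_ = S_d
        self.mean_selection_prob_ = S_d.mean(axis=0)
        return self

    # ------------------------------------------------------------- predict
    def _featurize(self, X) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "bundle_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}")
        X_s, X_v = unpack_design(X, self.n_static, self.n_signals)
        ids = [f"Q{i:06d}" for i in range(X.shape[0])]
        cohort = CohortTable(ids, X_s, np.zeros(X.shape[0], dtype=int),
                             feature_names=_feature_names(self.n_static))
        signals = TemporalSignals(list(ids), X_v,
                                  signal_names=_signal_names(self.n_signals))
        return featurize(self.bundle_, cohort, signals), X_v

    def predict_proba(self, X) -> np.ndarray:
        X_d, _ = self._featurize(X)
        p, _, _ = predict_critic(self.bundle_, X_d)
        return np.c_[1.0 - p, p]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def predict_proba_baseline(self, X) -> np.ndarray:
        """Risk from the co-trained TCN baseline (uses the raw time series)."""
        X_d, X_v = self._featurize(X)
        p = predict_baseline(self.bundle_, X_d, X_v)
        return np.c_[1.0 - p, p]

    def selection_mask(self, X) -> np.ndarray:
        """Deterministic per-instance feature mask (threshold mode)."""
        X_d, _ = self._featurize(X)
        _, _, M = predict_critic(self.bundle_, X_d)
        return M

    def feature_ranking(self) -> FeatureRanking:
        """Training-cohort ranking of mean selection probabilities."""
        check_is_fitted(self, "selection_probabilities_")
        return rank_selection_probabilities(self.selection_probabilities_,
                                            self.feature_names_)
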