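"""Per-signal summary statistics and assembly of the combined feature vector.

Each monitoring series is summarised by its mean and its *population*
standard deviation (divisor N, not N-1):

    x_M = (1/N) sum_i x_i,    sigma = sqrt((1/N) sum_i (x_i - x_M)^2)

The dispersion term is the clinically loaded one — widely fluctuating vital
signs flag sepsis risk — and is what the planted synthetic cohorts encode.
The combined per-patient feature vector is the static block followed by the
signal means and then the signal standard deviations (columns ``HR_M``, ...,
``HR_S``, ...), z-scored with moments fitted on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, TemporalSignals

logger = logging.getLogger(__name__)


@dataclass
class StatFeatures:
    """Mean/sd summary block, columns ``[mean_1..mean_c, sd_1..sd_c]``."""

    X_m: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.X_m = np.asarray(self.X_m, dtype=float)
        c2 = self.X_m.shape[1]
        if len(self.names) != c2:
            raise ValueError("names must match column count")
        if (self.X_m[:, c2 // 2:] < 0).any():
            raise ValueError("standard deviations cannot be negative")


@dataclass
class FeatureVector:
    """Combined design matrix X_d = [static | means | sds]."""

    X_d: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X_d = np.asarray(self.X_d, dtype=float)
        if self.X_d.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must align with columns")


def compute_stat_features(signals: TemporalSignals) -> StatFeatures:
    """Mean and population standard deviation of every monitoring signal.

    Padded tails (when ``signals.lengths`` is set) are excluded: statistics
    use the observed samples only.
    """
    X_v = signals.X_v
    if np.isnan(X_v).any():
        raise ValueError("temporal signals contain NaN; impute upstream")
    n, c, T = X_v.shape
    if signals.lengths is None:
        means = X_v.mean(axis=2)
        sds = X_v.std(axis=2)          # numpy default ddof=0: population form
    else:
        t = np.arange(T)[None, None, :]
        mask = t < signals.lengths[:, None, None]
        L = signals.lengths[:, None].astype(float)
        means = np.where(mask, X_v, 0.0).sum(axis=2) / L
        dev = np.where(mask, X_v - means[:, :, None], 0.0)
        sds = np.sqrt((dev ** 2).sum(axis=2) / L)
    names = [f"{s}_M" for s in signals.signal_names] + \
            [f"{s}_S" for s in signals.signal_names]
    return StatFeatures(np.concatenate([means, sds], axis=1), names)


class FeatureScaler:
    """Column-wise z-scoring with zero-variance guard.

    Moments are fitted on the training design only; columns with (near-)zero
    spread get scale 1 so they pass through centred but unscaled, with a
    warning. ``identity=True`` disables scaling altogether.
    """

    def __init__(self, identity: bool = False):
        self.identity = identity
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        degenerate = scale < 1e-12
        if degenerate.any():
            logger.warning("zero-variance column(s) %s: scale clamped to 1",
                           np.flatnonzero(degenerate).tolist())
            scale = np.where(degenerate, 1.0, scale)
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.identity:
            return X.copy()
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        return (X - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def build_feature_vector(cohort: CohortTable, stats: StatFeatures,
                         scaler: FeatureScaler | None = None) -> FeatureVector:
    """Concatenate static and statistical blocks into X_d, optionally scaled.

    Column order: static indicators (table order), then signal means, then
    signal standard deviations. Pass a *fitted* scaler to standardize with
    training-set moments; ``None`` returns the raw concatenation.
    """
    if cohort.n != stats.X_m.shape[0]:
        raise ValueError("cohort and statistical block row counts differ")
    X_d = np.concatenate([cohort.X_s, stats.X_m], axis=1)
    if scaler is not None:
        X_d = scaler.transform(X_d)
    return FeatureVector(X_d, list(cohort.feature_names) + list(stats.names))
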