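"""scikit-learn-compatible estimators.

``FeatureExtractor`` is a stateless transformer turning a collection of raw
waveform records into the 27-column HRV feature matrix (preprocess -> beat
detection -> time/frequency/time-frequency features). ``AFDetector`` is a
binary classifier over such feature matrices, wrapping one of the supported
boosting models and restricting itself to a named feature group. Both
compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .containers import WaveformSignal
from .errors import ConfigurationError, PulseAFError
from .features import FEATURE_NAMES, extract_features
from .preprocess import PreprocessConfig, preprocess
from .select import get_feature_group

logger = logging.getLogger(__name__)

MODEL_REGISTRY = {
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "xgboost": lambda seed: XGBClassifier(random_state=seed, eval_metric="logloss"),
}


class FeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform raw ``WaveformSignal`` records into the HRV feature matrix.

    Parameters mirror the conditioning and extraction defaults; ``fit`` is a
    no-op (the transform is stateless), provided for pipeline compatibility.
    Records failing beat detection are dropped with a logged reason when
    ``errors='drop'`` (their positions are recorded in ``failed_indices_``
    after ``transform``), or raise when ``errors='raise'``.
    """

    def __init__(
        self,
        target_fs: float = 100.0,
        band_low: float = 0.5,
        band_high: float = 8.0,
        filter_order: int = 4,
        norm_percentile: float = 97.0,
        threshold_percentile: float = 88.0,
        min_distance: float = 0.25,
        sampen_m: int = 2,
        sampen_r_fraction: float = 0.2,
        she_bins: int = 16,
        fs_tach: float = 4.0,
        wavelet_name: str = "db4",
        errors: str = "drop",
    ):
        self.target_fs = target_fs
        self.band_low = band_low
        self.band_high = band_high
        self.filter_order = filter_order
        self.norm_percentile = norm_percentile
        self.threshold_percentile = threshold_percentile
        self.min_distance = min_distance
        self.sampen_m = sampen_m
        self.sampen_r_fraction = sampen_r_fraction
        self.she_bins = she_bins
        self.fs_tach = fs_tach
        self.wavelet_name = wavelet_name
        self.errors = errors

    def _preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            target_fs=self.target_fs,
            band_low=self.band_low,
            band_high=self.band_high,
            filter_order=self.filter_order,
            norm_percentile=self.norm_percentile,
        )

    def fit(self, X=None, y=None) -> "FeatureExtractor":
        self._preprocess_config()  # validate parameters
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Extract features for each record in ``X`` (iterable of signals)."""
        self.fit()
        config = self._preprocess_config()
        rows, index, failed = [], [], []
        for i, signal in enumerate(X):
            if not isinstance(signal, WaveformSignal):
                raise ConfigurationError(
                    f"record {i}: expected WaveformSignal, got {type(signal).__name__}"
                )
            try:
                conditioned = preprocess(signal, config)
                rows.append(
                    extract_features(
                        conditioned,
                        threshold_percentile=self.threshold_percentile,
                        min_distance=self.min_distance,
                        sampen_m=self.sampen_m,
                        sampen_r_fraction=self.sampen_r_fraction,
                        she_bins=self.she_bins,
                        fs_tach=self.fs_tach,
                        wavelet_name=self.wavelet_name,
                    )
                )
                index.append(signal.record_id or i)
            except PulseAFError as exc:
                if self.errors == "raise":
                    raise
                failed.append(i)
                logger.warning("dropping record %s: %s", signal.record_id or i, exc)
        self.failed_indices_ = failed
        return pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


class AFDetector(ClassifierMixin, BaseEstimator):
    """Binary AF classifier over an HRV feature matrix.

    Parameters
    ----------
    model : {'gradient_boosting', 'adaboost', 'xgboost'}
        Backing boosting classifier (library defaults, seeded).
    feature_group : str or None
        One of Group1..Group5; restricts fitting to that column subset when
        the input is a DataFrame. ``None`` uses all supplied columns.
    random_state : int
        Seed forwarded to the backing model.
    """

    def __init__(self, model: str = "gradient_boosting", feature_group: str | None = None,
                 random_state: int = 0):
        self.model = model
        self.feature_group = feature_group
        self.random_state = random_state

    def _columns(self, X):
        if self.feature_group is None or not isinstance(X, pd.DataFrame):
            return None
        members = get_feature_group(self.feature_group).members
        missing = [m for m in members if m not in X.columns]
        if missing:
            raise ConfigurationError(f"feature table lacks columns {missing}")
        return list(members)

    def _matrix(self, X) -> np.ndarray:
        cols = self._columns(X)
        if cols is not None:
            X = X[cols]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ConfigurationError("feature matrix must be 2-dimensional")
        return X

    def fit(self, X, y) -> "AFDetector":
        if self.model not in MODEL_REGISTRY:
            raise ConfigurationError(
                f"unknown model {self.model!r}; valid: {sorted(MODEL_REGISTRY)}"
            )
        mat = self._matrix(X)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ConfigurationError("AFDetector is a binary classifier; need exactly 2 classes")
        self.n_features_in_ = mat.shape[1]
        self.estimator_ = MODEL_REGISTRY[self.model](self.random_state)
        self.estimator_.fit(mat, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._matrix(X))

    def decision_scores(self, X) -> np.ndarray:
        """Probability of the AF (positive) class, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.classes_[(self.decision_scores(X) >= 0.5).astype(int)]

    def clone_unfitted(self) -> "AFDetector":
        return clone(self)
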