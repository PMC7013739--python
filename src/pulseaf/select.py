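"""Feature ranking and the Group 1-5 nested feature subsets.

Three transparent rankers (absolute Pearson correlation, information gain,
symmetric uncertainty) plus a greedy cross-validated forward-selection
wrapper cover the two selection behaviours: ranking all features versus
picking a subset. The groups themselves are fixed, curated constants nested
as Group2 c Group3 c Group4 c Group5 c Group1 with sizes 8/11/15/20/27.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError
from .features import FEATURE_NAMES, TARGET_NAME

_GROUP2 = ("Mean", "MAD", "RMSSD", "SD1", "SDRR", "MAVcA", "AEcA", "STDcA")
_GROUP3 = _GROUP2 + ("STD", "S", "SpEn")
_GROUP4 = _GROUP3 + ("MeanAD", "SD2", "AEcD", "STDcD")
_GROUP5 = _GROUP4 + ("SampEn", "CosEn", "ShE", "MaxPeak", "MAVcD")

FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "Group1": FEATURE_NAMES,
    "Group2": _GROUP2,
    "Group3": _GROUP3,
    "Group4": _GROUP4,
    "Group5": _GROUP5,
}

RANKING_METHODS = ("correlation", "info_gain", "symmetric_uncertainty")


@dataclass(frozen=True)
class FeatureGroup:
    """A named subset of the 27 canonical features."""

    name: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class RankingResult:
    """Scores per feature and the descending ordering (lexicographic ties)."""

    method: str
    scores: dict[str, float]
    ordering: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.ordering),
                "method": self.method,
                "score": [self.scores[f] for f in self.ordering],
                "rank": np.arange(1, len(self.ordering) + 1),
            }
        )


def get_feature_group(name: str) -> FeatureGroup:
    """Look up one of Group1..Group5 by name."""
    try:
        return FeatureGroup(name, FEATURE_GROUPS[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown feature group {name!r}; valid: {sorted(FEATURE_GROUPS)}"
        ) from None


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _discretize(x: pd.Series, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning with ties kept together.

    Features with at most ``n_bins`` distinct values get one bin per value;
    otherwise interior deciles of the values become bin edges (duplicate
    edges merged), so tied values always share a bin.
    """
    vals = x.to_numpy(dtype=float)
    uniq = np.unique(vals)
    if uniq.size <= n_bins:
        return np.searchsorted(uniq, vals)
    edges = np.unique(np.quantile(vals, np.linspace(0, 1, n_bins + 1))[1:-1])
    return np.searchsorted(edges, vals, side="right")


def _info_gain(bins: np.ndarray, y: np.ndarray) -> float:
    h_y = _entropy(np.bincount(y))
    h_cond = 0.0
    n = y.size
    for b in np.unique(bins):
        mask = bins == b
        h_cond += mask.sum() / n * _entropy(np.bincount(y[mask]))
    return max(h_y - h_cond, 0.0)


def _validate_table(table: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    if TARGET_NAME not in table.columns:
        raise ConfigurationError(f"feature table lacks the target column {TARGET_NAME!r}")
    y = table[TARGET_NAME].to_numpy().astype(int)
    if np.unique(y).size < 2:
        raise ConfigurationError("feature table contains a single class; ranking undefined")
    features = [c for c in table.columns if c != TARGET_NAME]
    return features, y


def rank_features(table: pd.DataFrame, method: str = "correlation") -> RankingResult:
    """Score every feature against the binary target Vt.

    * ``correlation``: absolute Pearson r (constant features score 0);
    * ``info_gain``: H(Vt) - H(Vt | feature), feature discretized into 10
      equal-frequency bins, entropies in nats;
    * ``symmetric_uncertainty``: 2*IG / (H(feature) + H(Vt)), in [0, 1].
    """
    if method not in RANKING_METHODS:
        raise ConfigurationError(f"unknown ranking method {method!r}; valid: {RANKING_METHODS}")
    features, y = _validate_table(table)
    scores: dict[str, float] = {}
    for name in features:
        col = table[name]
        if method == "correlation":
            sd = col.std(ddof=0)
            if sd == 0:
                scores[name] = 0.0
            else:
                r = np.corrcoef(col.to_numpy(), y)[0, 1]
                scores[name] = float(abs(r))
        else:
            bins = _discretize(col)
            ig = _info_gain(bins, y)
            if method == "info_gain":
                scores[name] = ig
            else:
                denom = _entropy(np.bincount(bins)) + _entropy(np.bincount(y))
                scores[name] = 2.0 * ig / denom if denom > 0 else 0.0
    ordering = tuple(sorted(scores, key=lambda f: (-scores[f], f)))
    return RankingResult(method, scores, ordering)


def greedy_wrapper_select(
    table: pd.DataFrame,
    max_features: int = 27,
    folds: int = 5,
    seed: int = 0,
    estimator=None,
) -> list[str]:
    """Forward selection maximizing cross-validated accuracy.

    At each step the feature whose addition most improves stratified
    ``folds``-fold CV accuracy of the configured classifier (default a
    depth-3 decision tree) is added; stops at ``max_features`` or when no
    candidate improves the score. Ties break lexicographically.
    """
    features, y = _validate_table(table)
    if estimator is None:
        estimator = DecisionTreeClassifier(max_depth=3, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    selected: list[str] = []
    best_score = -np.inf
    while len(selected) < max_features:
        candidates = sorted(set(features) - set(selected))
        if not candidates:
            break
        step_scores = []
        for cand in candidates:
            x = table[selected + [cand]].to_numpy()
            score = cross_val_score(clone(estimator), x, y, cv=cv, scoring="accuracy").mean()
            step_scores.append((score, cand))
        score, winner = min(step_scores, key=lambda sc: (-sc[0], sc[1]))
        if score < best_score:  # ties continue: plateaus are not degradation
            break
        best_score = score
        selected.append(winner)
    return selected
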