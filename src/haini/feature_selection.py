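"""Consensus feature selection over two rankings of the chemical features.

The chemical cross-product block is wide (3600 columns with the default
descriptor panel) and heavily redundant.  Two rankings are computed on
training data only — impurity-based random-forest importance and a
univariate one-way ANOVA F statistic per feature — and the selected set
is the consensus of the two: the smallest top-``m`` prefix of each
ranking whose intersection holds at least ``k`` features, truncated to
``k`` by mean rank.  The default ``k = 94`` chemical features are then
concatenated with the 12 CYP interaction features to form the 106-wide
hybrid row the classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

from .errors import SelectionError

DEFAULT_K = 94


@dataclass(frozen=True)
class FeatureRanking:
    """Descending ranking of feature names by a finite score."""

    method: str
    ordered: tuple[tuple[str, float], ...]

    def __post_init__(self):
        names = [n for n, _ in self.ordered]
        if len(names) != len(set(names)):
            raise SelectionError(f"{self.method}: duplicate feature names")
        scores = np.array([s for _, s in self.ordered])
        if not np.all(np.isfinite(scores)):
            raise SelectionError(f"{self.method}: non-finite scores")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.ordered]

    def rank_of(self) -> dict[str, int]:
        return {n: i for i, (n, _) in enumerate(self.ordered)}


def _as_ranking(method: str, names, scores) -> FeatureRanking:
    # descending score, lexicographic name as the deterministic tie-break
    order = sorted(zip(names, scores), key=lambda t: (-t[1], t[0]))
    return FeatureRanking(method, tuple(order))


def rank_by_forest_importance(X: pd.DataFrame, y, seed: int = 0,
                              n_estimators: int = 100) -> FeatureRanking:
    """Impurity-decrease importance from a random forest fit on (X, y)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("forest ranking needs at least 2 classes")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), y)
    return _as_ranking("forest_importance", X.columns, forest.feature_importances_)


def rank_by_univariate_score(X: pd.DataFrame, y) -> FeatureRanking:
    """One-way ANOVA F statistic per feature (the univariate fit score).

    Constant features have zero between-class variance and score 0.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise SelectionError("univariate ranking needs at least 2 classes")
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns are expected and score 0
        scores, _ = f_classif(X.to_numpy(), y)
    scores = np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)
    return _as_ranking("univariate_f", X.columns, scores)


def consensus_select(rankings: list[FeatureRanking], k: int = DEFAULT_K) -> list[str]:
    """Top-``k`` features agreed on by every ranking.

    Grows a shared prefix length ``m`` until the intersection of all
    top-``m`` lists holds at least ``k`` features, then truncates to
    ``k`` by mean rank across the rankings (ties broken by name).
    """
    if not rankings:
        raise SelectionError("no rankings supplied")
    universes = [set(r.names) for r in rankings]
    if any(u != universes[0] for u in universes[1:]):
        raise SelectionError("rankings cover different feature universes")
    n = len(universes[0])
    if k > n:
        raise SelectionError(f"k={k} exceeds the {n} available features")
    name_lists = [r.names for r in rankings]
    common: set[str] = set()
    for m in range(k, n + 1):
        common = set(name_lists[0][:m])
        for names in name_lists[1:]:
            common &= set(names[:m])
        if len(common) >= k:
            break
    ranks = [r.rank_of() for r in rankings]
    ordered = sorted(common, key=lambda f: (np.mean([r[f] for r in ranks]), f))
    return ordered[:k]


def selection_report(rankings: list[FeatureRanking], selected: list[str]) -> pd.DataFrame:
    """Per-feature table of every ranking's score plus the selected flag."""
    features = rankings[0].names
    data = {"feature": sorted(features)}
    for r in rankings:
        scores = dict(r.ordered)
        data[f"{r.method}_score"] = [scores[f] for f in data["feature"]]
    sel = set(selected)
    data["selected"] = [f in sel for f in data["feature"]]
    return pd.DataFrame(data)
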