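"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Greedy forward selection on the criterion

    score(S) = (1/|S|) sum_{f in S} I(f; c)
             - (1/|S|^2) sum_{f_i != f_j in S} I(f_i; f_j)

with I the plug-in mutual information (bits) on discretized features.
The first feature is the marginal-relevance argmax (for a singleton the
redundancy term vanishes, so this is the criterion maximizer too);
every later step adds the candidate maximizing the criterion of the
enlarged set.  Ties break by column order, never by dict-iteration
hazard.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information (bits) of two discrete sequences.

    Estimated from the empirical joint distribution; 0*log(0) terms are
    taken as 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("sequences must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def discretize_quartiles(x: Sequence[float], bins: int = 4) -> np.ndarray:
    """Equal-frequency discretization (quartiles by default).

    Degenerate columns (fewer distinct quantile edges than bins)
    collapse gracefully via duplicate-edge dropping.
    """
    codes = pd.qcut(np.asarray(x, dtype=float), q=bins,
                    labels=False, duplicates="drop")
    return np.nan_to_num(codes, nan=0.0).astype(int)


def _is_continuous(col: pd.Series) -> bool:
    return pd.api.types.is_float_dtype(col) and col.nunique() > 8


def _discretized(table: pd.DataFrame, continuous: Optional[Sequence[str]],
                 bins: int) -> dict[str, np.ndarray]:
    out = {}
    for name in table.columns:
        col = table[name]
        cont = (name in continuous) if continuous is not None else _is_continuous(col)
        out[name] = discretize_quartiles(col, bins) if cont else np.asarray(col)
    return out


def mrmr_criterion(features: Sequence[str], relevance: dict[str, float],
                   pair_mi) -> float:
    """Criterion value for a candidate feature set."""
    s = len(features)
    rel = sum(relevance[f] for f in features) / s
    red = 0.0
    for i, fi in enumerate(features):
        for fj in features[:i]:
            red += 2.0 * pair_mi(fi, fj)  # symmetric, ordered pairs i != j
    return rel - red / (s * s)


class MRMRSelector(BaseEstimator):
    """Greedy mRMR feature ranker with a scikit-learn interface.

    Parameters
    ----------
    k : int or None
        Number of features to rank; all of them when None.
    continuous : sequence of str or None
        Column names to quartile-discretize before MI estimation; when
        None, float columns with more than 8 distinct values are
        treated as continuous.
    bins : int
        Equal-frequency bin count for continuous features.

    Attributes
    ----------
    ranking_ : list of str
        Features in selection order.
    relevance_ : dict
        I(feature; label) in bits.
    scores_ : list of float
        Criterion value of the growing set after each addition.
    """

    def __init__(self, k: Optional[int] = None,
                 continuous: Optional[Sequence[str]] = None, bins: int = 4):
        self.k = k
        self.continuous = continuous
        self.bins = bins

    def fit(self, X: pd.DataFrame, y: Sequence) -> "MRMRSelector":
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        k = len(X.columns) if self.k is None else self.k
        if k > len(X.columns):
            raise ValueError(f"k={k} exceeds feature count {len(X.columns)}")
        cols = list(X.columns)
        disc = _discretized(X, self.continuous, self.bins)
        self.relevance_ = {f: mutual_information(disc[f], y) for f in cols}

        cache: dict[tuple[str, str], float] = {}

        def pair_mi(a: str, b: str) -> float:
            key = (a, b) if a <= b else (b, a)
            if key not in cache:
                cache[key] = mutual_information(disc[key[0]], disc[key[1]])
            return cache[key]

        ranking: list[str] = []
        scores: list[float] = []
        while len(ranking) < k:
            best, best_score = None, -np.inf
            for f in cols:  # column order is the tie rule
                if f in ranking:
                    continue
                sc = mrmr_criterion(ranking + [f], self.relevance_, pair_mi)
                if sc > best_score:
                    best, best_score = f, sc
            ranking.append(best)
            scores.append(best_score)
        self.ranking_ = ranking
        self.scores_ = scores
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.ranking_]


def mrmr_rank(table: pd.DataFrame, labels: Sequence, k: int,
              continuous: Optional[Sequence[str]] = None) -> list[str]:
    """Rank the top ``k`` features of ``table`` against ``labels``."""
    if k == 0:
        return []
    return MRMRSelector(k=k, continuous=continuous).fit(table, labels).ranking_
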