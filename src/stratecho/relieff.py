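"""ReliefF feature weighting and ranking.

Standard multi-class ReliefF (Kononenko / Robnik-Sikonja): for each sampled
reference instance the k nearest same-class hits and, per other class, the
k nearest misses (Euclidean distance over range-normalized features) update
each feature's weight — penalized for differing across hits, rewarded,
prior-weighted, for differing across misses.  Weights lie in [-1, 1]; a
positive weight marks a feature whose values separate the classes better
than chance among near neighbors.

`relieff_oracle` recomputes the same quantity by independent plain-Python
enumeration and exists for cross-checking on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class ReliefFError(ValueError):
    pass


@dataclass
class ReliefFResult:
    """Per-feature ReliefF weights and the induced ranking.

    ``ranking`` sorts feature names by descending weight, ties broken
    lexicographically.  ``m`` is the number of sampled reference instances;
    with m equal to the sample count the pass is exhaustive and
    seed-independent.
    """

    feature_names: list[str]
    weights: np.ndarray
    ranking: list[str]
    k: int
    m: int
    seed: int
    class_priors: dict[str, float]

    @property
    def weight_by_name(self) -> dict[str, float]:
        return dict(zip(self.feature_names, self.weights.tolist()))

    def to_dict(self) -> dict:
        wbn = self.weight_by_name
        return {
            "k": self.k,
            "m": self.m,
            "seed": self.seed,
            "class_priors": self.class_priors,
            "ranking": [
                {"rank": i + 1, "feature": f, "weight": wbn[f]}
                for i, f in enumerate(self.ranking)
            ],
        }


def _rank_names(feature_names, weights) -> list[str]:
    return [f for f, _ in sorted(zip(feature_names, weights), key=lambda t: (-t[1], t[0]))]


def relieff_weights(
    X: np.ndarray,
    y,
    feature_names: list[str] | None = None,
    k: int = 10,
    m: int | None = None,
    seed: int = 0,
) -> ReliefFResult:
    """ReliefF weights for a fully observed, comparably scaled matrix.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix; features should be on comparable ranges (the diff
        function normalizes by per-feature range over the full matrix, so
        min-max scaled input gives range ~1).
    y : length-n labels
    k : nearest hits/misses per reference instance (every class must have
        at least k+1 members)
    m : number of reference instances sampled without replacement; None or
        n means an exhaustive, seed-independent pass over all instances.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ReliefFError("X must be 2-D")
    n, p = X.shape
    if np.isnan(X).any():
        raise ReliefFError("X must be fully observed (impute first)")
    y = np.asarray(y, dtype=object)
    if y.shape != (n,):
        raise ReliefFError("y length must match X rows")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]
    if len(feature_names) != p:
        raise ReliefFError("feature_names length must match X columns")
    if k < 1:
        raise ReliefFError("k must be >= 1")

    classes, counts = np.unique(y, return_counts=True)
    too_small = [str(c) for c, cnt in zip(classes, counts) if cnt <= k]
    if too_small:
        raise ReliefFError(f"classes with <= k={k} members: {too_small}")
    priors = {str(c): cnt / n for c, cnt in zip(classes, counts)}

    span = X.max(axis=0) - X.min(axis=0)
    nonconst = span > 0
    # Constant features contribute 0 to both diffs and distances.
    Xn = np.zeros_like(X)
    Xn[:, nonconst] = X[:, nonconst] / span[nonconst]

    if m is None or m == n:
        refs = np.arange(n)
        m = n
    else:
        if not 1 <= m <= n:
            raise ReliefFError("m must be in [1, n]")
        rng = np.random.default_rng(seed)
        refs = np.sort(rng.choice(n, size=m, replace=False))

    # Pairwise Euclidean distances on range-normalized features.
    sq = (Xn**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Xn @ Xn.T)
    np.maximum(d2, 0.0, out=d2)
    dist = np.sqrt(d2)

    class_rows = {c: np.flatnonzero(y == c) for c in classes}
    W = np.zeros(p)
    denom = m * k
    for i in refs:
        ci = y[i]
        for c in classes:
            rows = class_rows[c]
            if c == ci:
                rows = rows[rows != i]
            # stable sort on distance -> ties broken by instance index
            order = rows[np.argsort(dist[i, rows], kind="stable")][:k]
            diffs = np.abs(Xn[order] - Xn[i]).sum(axis=0)
            if c == ci:
                W -= diffs / denom
            else:
                W += (priors[str(c)] / (1.0 - priors[str(ci)])) * diffs / denom

    return ReliefFResult(
        feature_names=list(feature_names),
        weights=W,
        ranking=_rank_names(feature_names, W),
        k=k,
        m=int(m),
        seed=seed,
        class_priors=priors,
    )


def select_relevant(result: ReliefFResult) -> list[str]:
    """Features with strictly positive weight, in ranking order."""
    wbn = result.weight_by_name
    return [f for f in result.ranking if wbn[f] > 0]


def select_top_k(result: ReliefFResult, top_k: int) -> list[str]:
    """The ``min(top_k, n_features)`` highest-ranked feature names."""
    if top_k < 1:
        raise ReliefFError("top_k must be >= 1")
    return result.ranking[: min(top_k, len(result.ranking))]


def relieff_oracle(X, y, k: int = 1) -> list[float]:
    """Exhaustive plain-Python ReliefF for cross-checking (n<=30, p<=10).

    Implements the same weight update by direct enumeration, sharing no
    neighbor-search code with :func:`relieff_weights`; every reference
    instance is visited (m = n).
    """
    rows = [list(map(float, r)) for r in X]
    labels = list(y)
    n = len(rows)
    p = len(rows[0]) if rows else 0
    if n > 30 or p > 10:
        raise ReliefFError("oracle limited to n<=30, p<=10")
    classes = sorted({str(c) for c in labels})
    counts = {c: sum(1 for lab in labels if str(lab) == c) for c in classes}
    if any(counts[c] <= k for c in classes):
        raise ReliefFError("each class needs > k members")

    spans = []
    for j in range(p):
        col = [r[j] for r in rows]
        spans.append(max(col) - min(col))

    def diff(j, a, b):
        if spans[j] == 0:
            return 0.0
        return abs(rows[a][j] - rows[b][j]) / spans[j]

    def distance(a, b):
        return math.sqrt(sum(diff(j, a, b) ** 2 for j in range(p)))

    weights = [0.0] * p
    for i in range(n):
        ci = str(labels[i])
        for c in classes:
            candidates = [o for o in range(n) if str(labels[o]) == c and o != i]
            candidates.sort(key=lambda o: (distance(i, o), o))
            nearest = candidates[:k]
            for j in range(p):
                contrib = sum(diff(j, i, o) for o in nearest) / (n * k)
                if c == ci:
                    weights[j] -= contrib
                else:
                    prior = counts[c] / n
                    weights[j] += prior / (1.0 - counts[ci] / n) * contrib
    return weights
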