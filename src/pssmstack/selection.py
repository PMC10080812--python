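"""Max-Relevance-Max-Distance (MRMD) feature ranking and subset selection.

MRMD scores each feature by two additive terms:

* **relevance** — how strongly the feature tracks the class label, measured
  as the absolute Pearson correlation |r(feature, label)|;
* **distance** — how far the feature sits from the other features, measured
  as its mean pairwise distance to all other standardized feature columns
  (higher = less redundant).

``score = relevance + weight * distance``; features are ranked by
descending score.  Euclidean distances are reported on the per-sample RMS
scale (divided by sqrt(n)), so for z-scored columns they lie in [0, 2] and
are commensurate with |r| in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureTable

METRICS = ("euclidean", "cosine", "tanimoto")


@dataclass
class MrmdRanking:
    """Per-feature relevance, distance, combined score and rank order.

    ``rank`` is a permutation of column indices, best feature first.
    Ties in score are broken by original column index (stable).
    """

    names: list[str]
    relevance: np.ndarray
    distance: np.ndarray
    weight: float
    metric: str

    @property
    def score(self) -> np.ndarray:
        return self.relevance + self.weight * self.distance

    @property
    def rank(self) -> np.ndarray:
        # stable mergesort on -score keeps original column order on ties
        return np.argsort(-self.score, kind="stable")

    def ranked_names(self) -> list[str]:
        return [self.names[i] for i in self.rank]

    def to_frame(self) -> pd.DataFrame:
        order = np.empty(len(self.names), dtype=int)
        order[self.rank] = np.arange(1, len(self.names) + 1)
        return pd.DataFrame(
            {
                "name": self.names,
                "relevance": self.relevance,
                "distance": self.distance,
                "score": self.score,
                "rank": order,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().sort_values("rank").to_csv(path, sep="\t", index=False)


def _require_labels(table: FeatureTable) -> np.ndarray:
    if table.labels is None:
        raise ValueError("feature table has no labels; relevance needs them")
    return table.labels.astype(float)


def relevance(table: FeatureTable) -> np.ndarray:
    """|Pearson correlation| of each feature column with the label vector.

    Constant features (and a constant label) get relevance 0, never NaN.
    """
    y = _require_labels(table)
    X = table.values
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(r)


def _zscore_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns (population std); constant columns become zero.

    Returns (Z, constant_mask).
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    Z = (X - mu) / np.where(constant, 1.0, sd)
    Z[:, constant] = 0.0
    return Z, constant


def distance(table: FeatureTable, metric: str = "euclidean") -> np.ndarray:
    """Mean pairwise distance from each feature to all other features.

    Columns are z-scored first so the measure is scale-free.  Constant
    columns contribute distance 0 and are excluded from the other
    features' means.

    Raises
    ------
    ValueError
        For single-feature tables or an unknown metric.
    """
    if table.d < 2:
        raise ValueError("distance needs at least 2 features")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    Z, constant = _zscore_columns(table.values)
    n, d = Z.shape

    if metric == "euclidean":
        # RMS scale: ||u - v|| / sqrt(n) = sqrt(2 (1 - r_uv)) for z-scored columns
        G = Z.T @ Z / n
        sq = np.add.outer(np.diag(G), np.diag(G)) - 2.0 * G
        D = np.sqrt(np.maximum(sq, 0.0))
    else:
        norms = np.sqrt((Z**2).sum(axis=0))
        dot = Z.T @ Z
        if metric == "cosine":
            denom = np.outer(norms, norms)
            with np.errstate(invalid="ignore", divide="ignore"):
                sim = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
            D = 1.0 - sim
        else:  # tanimoto
            denom = np.add.outer(norms**2, norms**2) - dot
            with np.errstate(invalid="ignore", divide="ignore"):
                sim = np.where(denom != 0, dot / np.where(denom != 0, denom, 1.0), 0.0)
            D = 1.0 - sim
    np.fill_diagonal(D, 0.0)

    valid = ~constant
    n_other = valid.sum() - valid.astype(int)  # valid peers, excluding self
    sums = D[:, valid].sum(axis=1)  # diagonal is 0, self term vanishes
    out = np.where(n_other > 0, sums / np.maximum(n_other, 1), 0.0)
    out[constant] = 0.0
    return out


def mrmd_rank(
    table: FeatureTable, weight: float = 1.0, metric: str = "euclidean"
) -> MrmdRanking:
    """Rank features by ``|r| + weight * mean_distance``, descending."""
    rel = relevance(table)
    dist = distance(table, metric=metric)
    return MrmdRanking(
        names=list(table.names), relevance=rel, distance=dist, weight=weight, metric=metric
    )


def select_top_k(table: FeatureTable, ranking: MrmdRanking, k: int) -> FeatureTable:
    """Restrict the table to the k best-ranked features.

    The original relative column order is preserved within the subset.
    """
    if not 1 <= k <= table.d:
        raise ValueError(f"k must be in [1, {table.d}], got {k}")
    top = set(ranking.rank[:k].tolist())
    keep = [name for j, name in enumerate(table.names) if j in top]
    return table.subset_columns(keep)


def select_auto(
    table: FeatureTable,
    ranking: MrmdRanking,
    estimator_factory: Callable[[], object],
    k_grid: Sequence[int],
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[int, FeatureTable]:
    """Pick the subset size by the one-standard-error rule.

    Cross-validated accuracy is measured at every k in ``k_grid``; the
    smallest k whose mean accuracy is within one standard error of the best
    mean wins.  Returns ``(k_star, reduced_table)``.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    ks = sorted(set(int(k) for k in k_grid))
    if ks[0] < 1 or ks[-1] > table.d:
        raise ValueError(f"k_grid values must lie in [1, {table.d}]")
    y = _require_labels(table).astype(int)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    means, ses = [], []
    for k in ks:
        sub = select_top_k(table, ranking, k)
        scores = cross_val_score(estimator_factory(), sub.values, y, cv=cv, scoring="accuracy")
        means.append(scores.mean())
        ses.append(scores.std(ddof=1) / np.sqrt(len(scores)))
    best = int(np.argmax(means))
    threshold = means[best] - ses[best]
    k_star = next(k for k, m in zip(ks, means) if m >= threshold)
    return k_star, select_top_k(table, ranking, k_star)
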