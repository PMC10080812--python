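"""Binary-classification evaluation: confusion metrics, ROC, CV, McNemar.

Metrics follow the standard confusion-matrix definitions: sensitivity
SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy ACC (reported in
percent), and the Matthews correlation coefficient with the four-factor
denominator.  Two AUC variants are reported side by side and labelled
distinctly:

* ``auc_rank`` — the area under the threshold-swept ROC curve (trapezoidal
  rule), equivalent to the Mann-Whitney rank statistic;
* ``auc_balanced`` — (SN + SP)/2, the balanced accuracy at a single
  operating point, which some studies print under the name "AUC".

Cross-validation reports per-fold values with their mean and sample
(n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable

METRIC_COLUMNS = ("acc", "sn", "sp", "mcc", "auc_rank", "auc_balanced")


@dataclass(frozen=True)
class ConfusionCounts:
    """The four confusion-matrix cells (positive class = 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN for 0/1 label vectors of equal length."""
    t = np.asarray(y_true).astype(int)
    p = np.asarray(y_pred).astype(int)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """SN, SP, ACC (percent) and MCC from confusion counts.

    Any zero factor in the MCC denominator yields MCC = 0 (the
    conventional limit).  Empty classes give SN or SP = 0.
    """
    if c.total == 0:
        raise ValueError("no samples to evaluate")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = ((c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom)) if denom else 0.0
    return {"sn": sn, "sp": sp, "acc": acc, "mcc": float(mcc)}


def auc_eq10(c: ConfusionCounts) -> float:
    """Single-operating-point AUC surrogate: (SN + SP) / 2.

    This is the balanced accuracy; it is reported alongside (never instead
    of) the rank-based ROC area.
    """
    m = metrics(c)
    return 0.5 * (m["sn"] + m["sp"])


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep over unique scores, plus its area.

    Tied scores are grouped at one threshold.  Returns
    ``(points, area)`` where points is an array of (FPR, TPR) pairs from
    (0, 0) to (1, 1) and area is the trapezoidal integral.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have the same shape")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # cumulative counts at each position; keep only the last index of each
    # tied-score group so ties share one threshold
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    last_of_group = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[last_of_group] / n_pos]
    fpr = np.r_[0.0, fps[last_of_group] / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), area


@dataclass
class EvaluationReport:
    """Aggregate metrics, optionally with per-fold values, mean and std."""

    acc: float
    sn: float
    sp: float
    mcc: float
    auc_rank: float
    auc_balanced: float
    roc_points: np.ndarray | None = None
    per_fold: pd.DataFrame | None = None

    @property
    def mean(self) -> pd.Series | None:
        return None if self.per_fold is None else self.per_fold.mean()

    @property
    def std(self) -> pd.Series | None:
        # sample (n-1) standard deviation, as in CV tables
        return None if self.per_fold is None else self.per_fold.std(ddof=1)

    def to_frame(self) -> pd.DataFrame:
        row = {k: getattr(self, k) for k in METRIC_COLUMNS}
        return pd.DataFrame([row])

    def to_tsv(self, path: str | Path) -> None:
        if self.per_fold is not None:
            out = self.per_fold.copy()
            out.loc["mean"] = self.per_fold.mean()
            out.loc["std"] = self.per_fold.std(ddof=1)
            out.to_csv(path, sep="\t", index_label="fold")
        else:
            self.to_frame().to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        """Human-readable block mirroring the usual table layout."""
        lines = [
            f"ACC (%)  {self.acc:7.2f}",
            f"SN       {self.sn:7.3f}",
            f"SP       {self.sp:7.3f}",
            f"MCC      {self.mcc:7.3f}",
            f"AUC(ROC) {self.auc_rank:7.3f}",
            f"AUC(bal) {self.auc_balanced:7.3f}",
        ]
        if self.per_fold is not None:
            std = self.per_fold.std(ddof=1)
            lines.append(
                "Std      "
                + "  ".join(f"{k}={std[k]:.3f}" for k in METRIC_COLUMNS if k in std)
            )
        return "\n".join(lines)


def evaluate_predictions(y_true, y_pred, scores=None) -> EvaluationReport:
    """Full report from labels, predictions and (optionally) scores."""
    c = confusion(y_true, y_pred)
    m = metrics(c)
    if scores is not None:
        roc_points, auc = roc_auc(y_true, scores)
    else:
        roc_points, auc = None, float("nan")
    return EvaluationReport(
        acc=m["acc"],
        sn=m["sn"],
        sp=m["sp"],
        mcc=m["mcc"],
        auc_rank=auc,
        auc_balanced=auc_eq10(c),
        roc_points=roc_points,
    )


def cross_validate(
    pipeline_factory: Callable[[], object],
    table: FeatureTable,
    k: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """k-fold cross-validation of any fit/predict_proba pipeline.

    ``pipeline_factory()`` must return a fresh estimator with ``fit(X, y)``
    and ``predict_proba(X)``.  Folds are stratified and deterministic under
    ``seed``.  The report's headline numbers are fold means; per-fold
    values, mean and sample std are attached.
    """
    from sklearn.model_selection import StratifiedKFold

    if table.labels is None:
        raise ValueError("cross_validate needs labels")
    if table.n < k:
        raise ValueError(f"need at least k={k} samples, got {table.n}")
    y = table.labels
    X = table.values
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for train, val in splitter.split(X, y):
        est = pipeline_factory()
        est.fit(X[train], y[train])
        proba = est.predict_proba(X[val])
        pos_col = list(getattr(est, "classes_", [0, 1])).index(1)
        s = proba[:, pos_col]
        pred = (s >= 0.5).astype(int)
        rep = evaluate_predictions(y[val], pred, s)
        rows.append({k_: getattr(rep, k_) for k_ in METRIC_COLUMNS})
    per_fold = pd.DataFrame(rows)
    mean = per_fold.mean()
    return EvaluationReport(
        acc=mean["acc"],
        sn=mean["sn"],
        sp=mean["sp"],
        mcc=mean["mcc"],
        auc_rank=mean["auc_rank"],
        auc_balanced=mean["auc_balanced"],
        per_fold=per_fold,
    )


@dataclass(frozen=True)
class McNemarResult:
    """Discordant-pair test between two classifiers on the same samples.

    ``b`` counts samples A got right and B got wrong; ``c`` the reverse.
    """

    b: int
    c: int
    statistic: float
    p_value: float
    method: str


def mcnemar(y_true, pred_a, pred_b, method: str = "auto") -> McNemarResult:
    """McNemar's paired test on two prediction vectors.

    ``method='auto'`` uses the exact two-sided binomial test when
    b + c < 25, otherwise the continuity-corrected chi-square
    (|b - c| - 1)^2 / (b + c) with 1 degree of freedom.
    """
    t = np.asarray(y_true).astype(int)
    a = np.asarray(pred_a).astype(int)
    bb = np.asarray(pred_b).astype(int)
    if not (t.shape == a.shape == bb.shape):
        raise ValueError("all three vectors must have the same shape")
    right_a = a == t
    right_b = bb == t
    b = int(np.sum(right_a & ~right_b))
    c = int(np.sum(~right_a & right_b))
    n = b + c
    if method == "auto":
        method = "exact-binomial" if n < 25 else "chi-square-corrected"
    if method == "exact-binomial":
        p = 1.0 if n == 0 else float(stats.binomtest(b, n, 0.5).pvalue)
        stat = float(min(b, c))
    elif method == "chi-square-corrected":
        if n == 0:
            stat, p = 0.0, 1.0
        else:
            stat = (abs(b - c) - 1) ** 2 / n
            p = float(stats.chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return McNemarResult(b=b, c=c, statistic=float(stat), p_value=min(p, 1.0), method=method)
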