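"""Two-layer stacked ensemble classifier.

Layer one trains three base learners — a gradient-boosting machine
(LightGBM), an RBF-kernel support vector machine, and extremely randomized
trees — and collects their out-of-fold (OOF) positive-class probabilities
over a k-fold partition of the training set.  Layer two fits a logistic
regression meta-model on the n x 3 OOF matrix.  Because each OOF entry
comes from a model that never saw that sample, the meta-model's inputs are
leakage-free.  For inference, the base learners are refit on the full
training set.

Hard- and soft-voting combiners over the same three bases are provided as
baselines, along with an exhaustive grid-search helper.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .features import FeatureTable

_ARCHIVE_VERSION = 1

#: OOF column order; fixed so serialized stacks are comparable.
BASE_ORDER = ("lightgbm", "svm_rbf", "extra_trees")


@dataclass(frozen=True)
class BaseConfig:
    """One base learner: family name plus hyperparameters.

    Families are restricted to the three the stack uses:
    ``lightgbm``, ``svm_rbf``, ``extra_trees``.
    """

    family: str
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in BASE_ORDER:
            raise ValueError(f"family must be one of {BASE_ORDER}, got {self.family!r}")
        object.__setattr__(self, "params", tuple(sorted(dict(self.params).items())))

    @property
    def param_dict(self) -> dict:
        return dict(self.params)


def default_base_configs() -> tuple[BaseConfig, BaseConfig, BaseConfig]:
    """The stack's fixed base hyperparameters, in OOF column order.

    GBM: learning rate 0.05, 400 boosting rounds, depth 7, row subsample
    0.8.  SVM: RBF kernel, gamma 0.018, C 19, probability outputs.  ERT:
    100 trees, min samples to split 2, min samples per leaf 1.
    """
    gbm = BaseConfig(
        "lightgbm",
        (
            ("learning_rate", 0.05),
            ("n_estimators", 400),
            ("max_depth", 7),
            ("subsample", 0.8),
        ),
    )
    svm = BaseConfig("svm_rbf", (("gamma", 0.018), ("C", 19.0)))
    ert = BaseConfig(
        "extra_trees",
        (("n_estimators", 100), ("min_samples_split", 2), ("min_samples_leaf", 1)),
    )
    return gbm, svm, ert


def build_estimator(config: BaseConfig, seed: int = 0):
    """Instantiate the scikit-learn/LightGBM estimator for a config.

    SVM probability outputs use the library's sigmoid (Platt) calibration;
    its internal CV is tied to ``seed``.
    """
    p = config.param_dict
    if config.family == "lightgbm":
        from lightgbm import LGBMClassifier

        kwargs = {
            "learning_rate": 0.05,
            "n_estimators": 400,
            "max_depth": 7,
            "subsample": 0.8,
            **p,
        }
        kwargs.setdefault("subsample_freq", 1 if kwargs["subsample"] < 1.0 else 0)
        return LGBMClassifier(**kwargs, random_state=seed, n_jobs=1, verbose=-1)
    if config.family == "svm_rbf":
        # Platt sigmoid calibration provides probability outputs; the
        # internal CV is tied to the global seed for determinism.
        from sklearn.calibration import CalibratedClassifierCV
        from sklearn.model_selection import StratifiedKFold

        svc = SVC(kernel="rbf", **{"gamma": 0.018, "C": 19.0, **p})
        return CalibratedClassifierCV(
            svc,
            method="sigmoid",
            ensemble=False,
            cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        )
    # extra_trees
    kwargs = {"n_estimators": 100, "min_samples_split": 2, "min_samples_leaf": 1, **p}
    return ExtraTreesClassifier(**kwargs, random_state=seed, n_jobs=1)


def make_folds(
    ids: Sequence[str],
    k: int = 10,
    seed: int = 0,
    labels: Sequence[int] | None = None,
) -> dict[str, int]:
    """Assign each sample ID to one of k disjoint, near-equal folds.

    With ``labels`` given, folds are stratified by class (the default used
    by the stack) so undersampled data cannot produce single-class folds by
    chance; without labels, folds are plain random partitions.
    Deterministic under ``seed``; fold sizes differ by at most 1.
    """
    n = len(ids)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if len(set(ids)) != n:
        raise ValueError("sample IDs must be unique")
    from sklearn.model_selection import KFold, StratifiedKFold

    idx = np.arange(n)
    assignment: dict[str, int] = {}
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx, np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(idx)
    for fold, (_, test) in enumerate(splits):
        for i in test:
            assignment[ids[i]] = fold
    return assignment


def generate_oof(
    table: FeatureTable,
    configs: Sequence[BaseConfig],
    folds: Mapping[str, int],
    seed: int = 0,
    hard_labels: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Out-of-fold base predictions: entry (i, m) is base m's positive-class
    probability for sample i, from a model trained on every fold except
    sample i's own.

    ``hard_labels=True`` emits 0/1 votes instead of probabilities.

    Returns ``(n x len(configs) matrix, column names)``.

    Raises
    ------
    ValueError
        If some fold's training complement contains a single class
        (advice: undersample and/or use stratified folds).
    """
    if table.labels is None:
        raise ValueError("OOF generation needs labels")
    fold_of = np.array([folds[i] for i in table.ids])
    y = table.labels
    X = table.values
    k = int(fold_of.max()) + 1
    oof = np.empty((table.n, len(configs)))
    for fold in range(k):
        val = fold_of == fold
        if not val.any():
            continue
        train = ~val
        if len(np.unique(y[train])) < 2:
            raise ValueError(
                f"training complement of fold {fold} has a single class; "
                "undersample the data and/or use stratified folds"
            )
        for m, config in enumerate(configs):
            est = build_estimator(config, seed=seed)
            est.fit(X[train], y[train])
            proba = _positive_proba(est, X[val])
            oof[val, m] = (proba >= 0.5).astype(float) if hard_labels else proba
    names = [c.family for c in configs]
    return oof, names


def _positive_proba(estimator, X: np.ndarray) -> np.ndarray:
    import warnings

    with warnings.catch_warnings():
        # LightGBM's sklearn wrapper warns about feature names even when
        # both fit and predict receive plain arrays; harmless here
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names", category=UserWarning
        )
        proba = estimator.predict_proba(X)
    pos_col = list(estimator.classes_).index(1)
    return proba[:, pos_col]


@dataclass
class TrainedStack:
    """A fitted two-layer stack, persistable to a single archive file."""

    base_configs: tuple[BaseConfig, ...]
    base_models: dict
    meta_model: LogisticRegression
    fold_assignment: dict[str, int]
    oof_matrix: np.ndarray
    oof_columns: list[str]
    feature_names: list[str]
    seed: int
    threshold: float = 0.5
    version: int = _ARCHIVE_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedStack":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not contain a TrainedStack")
        if obj.version != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported archive version {obj.version}")
        return obj


def fit_stack(
    table: FeatureTable,
    configs: Sequence[BaseConfig] | None = None,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
    threshold: float = 0.5,
) -> TrainedStack:
    """Train the full stack on a labeled table.

    Folds are built (stratified by default), the OOF matrix is generated,
    a logistic-regression meta-model (lbfgs, at most 100 iterations) is fit
    on OOF probabilities vs labels, and each base learner is refit on the
    full table for inference.
    """
    if table.labels is None:
        raise ValueError("fit_stack needs labels")
    configs = tuple(configs) if configs is not None else default_base_configs()
    folds = make_folds(
        table.ids, k=k, seed=seed, labels=table.labels if stratified else None
    )
    oof, oof_columns = generate_oof(table, configs, folds, seed=seed)
    meta = LogisticRegression(solver="lbfgs", max_iter=100, random_state=seed)
    meta.fit(oof, table.labels)
    base_models = {}
    for config in configs:
        est = build_estimator(config, seed=seed)
        est.fit(table.values, table.labels)
        base_models[config.family] = est
    return TrainedStack(
        base_configs=configs,
        base_models=base_models,
        meta_model=meta,
        fold_assignment=dict(folds),
        oof_matrix=oof,
        oof_columns=oof_columns,
        feature_names=list(table.names),
        seed=seed,
        threshold=threshold,
    )


def _align_features(table: FeatureTable, feature_names: Sequence[str]) -> np.ndarray:
    have, want = set(table.names), set(feature_names)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        raise ValueError(
            f"feature mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    pos = {n: j for j, n in enumerate(table.names)}
    return table.values[:, [pos[n] for n in feature_names]]


def stack_base_probabilities(stack: TrainedStack, table: FeatureTable) -> np.ndarray:
    """Positive-class probabilities from the full-data base models (n x 3)."""
    X = _align_features(table, stack.feature_names)
    cols = [_positive_proba(stack.base_models[c.family], X) for c in stack.base_configs]
    return np.column_stack(cols)


def predict(stack: TrainedStack, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and meta probabilities for a feature table.

    Columns are matched to the stack's feature names by name; any
    missing or extra feature raises with the full mismatch list.

    Returns ``(labels, probabilities)``, labels at the stack's threshold.
    """
    base = stack_base_probabilities(stack, table)
    proba = _positive_proba(stack.meta_model, base)
    return (proba >= stack.threshold).astype(int), proba


def voting_predict(
    table: FeatureTable,
    configs: Sequence[BaseConfig] | None = None,
    mode: str = "hard",
    k: int = 10,
    seed: int = 0,
    test_table: FeatureTable | None = None,
) -> np.ndarray:
    """Majority-vote baseline over the same three base learners.

    ``hard``: each base votes its thresholded label, majority wins.
    ``soft``: base probabilities are averaged and thresholded at 0.5.

    Without ``test_table``, votes are out-of-fold over ``table`` (no
    sample is predicted by a model that saw it).  With ``test_table``,
    bases are fit on the full ``table`` and vote on the test rows.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    configs = tuple(configs) if configs is not None else default_base_configs()
    if test_table is None:
        folds = make_folds(table.ids, k=k, seed=seed, labels=table.labels)
        proba, _ = generate_oof(table, configs, folds, seed=seed)
    else:
        if table.labels is None:
            raise ValueError("voting needs labels on the training table")
        proba_cols = []
        for config in configs:
            est = build_estimator(config, seed=seed)
            est.fit(table.values, table.labels)
            proba_cols.append(
                _positive_proba(est, _align_features(test_table, table.names))
            )
        proba = np.column_stack(proba_cols)
    return combine_votes(proba, mode)


def combine_votes(proba: np.ndarray, mode: str) -> np.ndarray:
    """Combine an n x m base-probability matrix into labels.

    ``soft``: mean probability thresholded at 0.5.  ``hard``: each base's
    thresholded label votes; strict majority wins (ties go negative).
    """
    if mode == "soft":
        return (proba.mean(axis=1) >= 0.5).astype(int)
    if mode == "hard":
        votes = (proba >= 0.5).astype(int)
        return (votes.sum(axis=1) * 2 > votes.shape[1]).astype(int)
    raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")


def grid_search(
    config_space: Sequence[BaseConfig],
    table: FeatureTable,
    cv: int = 5,
    seed: int = 0,
) -> BaseConfig:
    """Exhaustive CV-accuracy search over a declared finite grid.

    Ties are broken by declaration order (first wins).
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    if len(config_space) == 0:
        raise ValueError("config_space must be non-empty")
    if table.labels is None:
        raise ValueError("grid_search needs labels")
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    best_config, best_score = None, -np.inf
    for config in config_space:
        est = build_estimator(config, seed=seed)
        score = cross_val_score(
            est, table.values, table.labels, cv=splitter, scoring="accuracy"
        ).mean()
        if score > best_score:
            best_config, best_score = config, score
    return best_config
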