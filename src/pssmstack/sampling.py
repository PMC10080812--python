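"""Class balancing and train/test splitting.

The benchmark task is heavily imbalanced (roughly 1 vesicle-transport
protein for every 3.6 others), so the training portion is balanced by
random undersampling of the majority class before cross-validation; the
held-out test set keeps its natural imbalance.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureTable


def _class_indices(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    if table.labels is None:
        raise ValueError("feature table has no labels")
    y = table.labels
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def random_undersample(table: FeatureTable, ratio: float = 1.0, seed: int = 0) -> FeatureTable:
    """Downsample the majority class without replacement.

    The minority class is kept in full; ``round(ratio * n_minority)``
    majority samples are drawn.  Row order of the result is shuffled
    deterministically by ``seed``.

    Parameters
    ----------
    ratio
        Majority-to-minority ratio after sampling (1.0 = balanced).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos, neg = _class_indices(table)
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    n_keep = int(round(ratio * len(minority)))
    if n_keep > len(majority):
        raise ValueError(
            f"ratio {ratio} needs {n_keep} majority samples but only {len(majority)} exist"
        )
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=n_keep, replace=False)
    idx = np.concatenate([minority, kept_majority])
    rng.shuffle(idx)
    return table.subset_rows(idx.tolist())


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Split into train/test preserving class proportions (±1 per class).

    ID sets of the two parts are disjoint; shuffling is deterministic
    under ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    pos, neg = _class_indices(table)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in (pos, neg):
        perm = rng.permutation(cls)
        n_test = int(round(test_fraction * len(cls)))
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    rng.shuffle(train_idx)
    rng.shuffle(test_idx)
    return table.subset_rows(train_idx), table.subset_rows(test_idx)
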