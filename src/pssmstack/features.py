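"""Evolutionary-information feature vectors from scaled PSSMs.

Two feature families are extracted from the sigmoid-scaled L x 20 matrix:

* **Reduced-alphabet PSSM (RPSSM, 110-d)** — the 20 columns are merged into
  10 amino-acid similarity groups, then a per-group variance term

  .. math:: D_s = \\frac{1}{L}\\sum_{i=1}^{L}(p_{i,s} - \\bar p_s)^2

  (with :math:`\\bar p_s` the column mean) captures pseudo-composition, and
  an adjacent-row squared-difference term

  .. math:: D_{s,t} = \\frac{1}{L-1}\\sum_{i=1}^{L-1}\\frac{(p_{i,s} - p_{i+1,t})^2}{2}

  captures dipeptide pseudo-composition, giving 10 + 100 = 110 features.

* **AADP-PSSM (420-d)** — amino-acid composition (AAC-PSSM): the 20 column
  means :math:`x_j = \\frac{1}{L}\\sum_i p_{i,j}`; plus dipeptide
  composition (DPC-PSSM): the 400 adjacent-row cross products
  :math:`y_{i,j} = \\frac{1}{L-1}\\sum_k p_{k,i}\\,p_{k+1,j}`.

Their concatenation (RPSSM first) is the 530-d combined representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pssm_io import AA_ORDER, ScaledPssm

#: The 10-group reduced amino-acid alphabet of the RPSSM literature.
DEFAULT_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("FYW", "ML", "IV", "ATS", "NH", "QED", "RK", "C", "G", "P")
)

# CSV float precision: enough for exact float64 round-trip.
_CSV_FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class ReductionScheme:
    """Partition of the 20-letter alphabet into 10 ordered groups.

    ``merge_rule`` decides how member columns combine into the group column:
    ``"mean"`` (default) or ``"sum"``.
    """

    groups: tuple[frozenset[str], ...] = DEFAULT_GROUPS
    merge_rule: str = "mean"

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) != 10:
            raise ValueError(f"expected exactly 10 groups, got {len(groups)}")
        union: set[str] = set()
        for g in groups:
            if union & g:
                raise ValueError("groups must be pairwise disjoint")
            union |= g
        if union != set(AA_ORDER):
            missing = set(AA_ORDER) - union
            extra = union - set(AA_ORDER)
            raise ValueError(
                f"groups must cover the 20-letter alphabet exactly "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if self.merge_rule not in ("mean", "sum"):
            raise ValueError(f"unknown merge_rule {self.merge_rule!r}")

    def column_indices(self) -> list[list[int]]:
        """Member column indices (into :data:`AA_ORDER`) per group."""
        return [sorted(AA_ORDER.index(a) for a in g) for g in self.groups]


@dataclass
class ReducedPssm:
    """L x 10 matrix obtained by merging PSSM columns under a scheme."""

    id: str
    values: np.ndarray
    scheme: ReductionScheme

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 10:
            raise ValueError(f"expected L x 10 matrix, got shape {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Named feature vector for one protein; order is deterministic."""

    id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values must have the same length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


@dataclass
class FeatureTable:
    """n samples x d named features, with optional binary labels.

    Labels are +1 for the positive class (vesicle-transport protein) and
    0 for the negative class.
    """

    ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(len(self.ids), len(self.names))
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int)
            if labels.shape[0] != len(self.ids):
                raise ValueError("label count must equal row count")
            # normalize -1/0 negative encodings to 0
            self.labels = (labels > 0).astype(int)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def d(self) -> int:
        return len(self.names)

    def subset_rows(self, index: Sequence[int]) -> "FeatureTable":
        idx = list(index)
        return FeatureTable(
            ids=[self.ids[i] for i in idx],
            names=list(self.names),
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        pos = {n: j for j, n in enumerate(self.names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        cols = [pos[n] for n in names]
        return FeatureTable(
            ids=list(self.ids), names=list(names), values=self.values[:, cols], labels=self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "id", self.ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write as headered CSV: ``id[,label],feature...`` columns.

        Floats use repr-exact formatting so a rerun is byte-identical.
        """
        self.to_frame().to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        if "id" not in df.columns:
            raise ValueError("feature table CSV must have an 'id' column")
        labels = None
        feature_cols = [c for c in df.columns if c != "id"]
        if "label" in df.columns:
            labels = df["label"].to_numpy(dtype=int)
            feature_cols.remove("label")
        return cls(
            ids=df["id"].astype(str).tolist(),
            names=feature_cols,
            values=df[feature_cols].to_numpy(dtype=float),
            labels=labels,
        )


# ---------------------------------------------------------------------------
# RPSSM
# ---------------------------------------------------------------------------

def reduce_pssm(scaled: ScaledPssm, scheme: ReductionScheme | None = None) -> ReducedPssm:
    """Merge the 20 scaled columns into the scheme's 10 group columns."""
    scheme = scheme or ReductionScheme()
    V = scaled.values
    cols = []
    for idx in scheme.column_indices():
        block = V[:, idx]
        cols.append(block.mean(axis=1) if scheme.merge_rule == "mean" else block.sum(axis=1))
    return ReducedPssm(id=scaled.id, values=np.column_stack(cols), scheme=scheme)


def rpssm_ds(reduced: ReducedPssm) -> np.ndarray:
    """Per-group pseudo-composition: column variance around the column mean.

    Returns 10 non-negative reals.
    """
    R = reduced.values
    return np.mean((R - R.mean(axis=0)) ** 2, axis=0)


def rpssm_dst(reduced: ReducedPssm) -> np.ndarray:
    """Dipeptide pseudo-composition over adjacent rows.

    ``D[s, t] = mean over i of (R[i, s] - R[i+1, t])^2 / 2``, flattened
    row-major (s outer, t inner).  Returns 100 non-negative reals.
    """
    R = reduced.values
    L = R.shape[0]
    if L < 2:
        raise ValueError("dipeptide terms need at least 2 rows")
    # direct (L-1) x 10 x 10 broadcast; avoids the cancellation-prone
    # expanded form a^2 + b^2 - 2ab
    diff = R[:-1, :, None] - R[1:, None, :]
    return ((diff**2).sum(axis=0) / (2.0 * (L - 1))).ravel()


def extract_rpssm(scaled: ScaledPssm, scheme: ReductionScheme | None = None) -> FeatureVector:
    """110-d reduced-alphabet feature vector: [D_1..D_10, D_{1,1}..D_{10,10}]."""
    reduced = reduce_pssm(scaled, scheme)
    ds = rpssm_ds(reduced)
    dst = rpssm_dst(reduced)
    names = [f"rpssm_D_{s}" for s in range(1, 11)]
    names += [f"rpssm_Dst_{s}_{t}" for s in range(1, 11) for t in range(1, 11)]
    return FeatureVector(id=scaled.id, names=names, values=np.concatenate([ds, dst]))


# ---------------------------------------------------------------------------
# AADP-PSSM
# ---------------------------------------------------------------------------

def aac_pssm(scaled: ScaledPssm) -> np.ndarray:
    """Amino-acid composition: the 20 full-column means of the scaled PSSM."""
    return scaled.values.mean(axis=0)


def dpc_pssm(scaled: ScaledPssm) -> np.ndarray:
    """Dipeptide composition: adjacent-row cross products.

    ``y[i, j] = mean over k of P[k, i] * P[k+1, j]``, flattened row-major.
    Returns 400 reals, each in (0, 1) when the input is in (0, 1).
    """
    P = scaled.values
    L = P.shape[0]
    if L < 2:
        raise ValueError("dipeptide terms need at least 2 rows")
    return ((P[:-1].T @ P[1:]) / (L - 1)).ravel()


def extract_aadp(scaled: ScaledPssm) -> FeatureVector:
    """420-d AADP-PSSM vector: (x_1..x_20, y_{1,1}..y_{20,20})."""
    names = [f"aac_{a}" for a in AA_ORDER]
    names += [f"dpc_{a}_{b}" for a in AA_ORDER for b in AA_ORDER]
    return FeatureVector(
        id=scaled.id, names=names, values=np.concatenate([aac_pssm(scaled), dpc_pssm(scaled)])
    )


def extract_all(scaled: ScaledPssm, scheme: ReductionScheme | None = None) -> FeatureVector:
    """Combined 530-d vector: RPSSM (110) followed by AADP-PSSM (420)."""
    r = extract_rpssm(scaled, scheme)
    a = extract_aadp(scaled)
    return FeatureVector(
        id=scaled.id, names=r.names + a.names, values=np.concatenate([r.values, a.values])
    )


def featurize_batch(
    scaled_profiles: Iterable[ScaledPssm],
    labels: Mapping[str, int] | None = None,
    scheme: ReductionScheme | None = None,
) -> FeatureTable:
    """Extract the combined 530-d vector for every profile.

    Rows follow the input profile order.  When ``labels`` is given, every
    profile ID must appear in it.

    Raises
    ------
    KeyError
        Listing the profile IDs missing from ``labels``.
    """
    scheme = scheme or ReductionScheme()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    for scaled in scaled_profiles:
        fv = extract_all(scaled, scheme)
        if names is None:
            names = fv.names
        ids.append(fv.id)
        rows.append(fv.values)
    if names is None:  # empty input
        dummy_names = extract_all(
            ScaledPssm(id="_", values=np.full((2, 20), 0.5)), scheme
        ).names
        return FeatureTable(ids=[], names=dummy_names, values=np.empty((0, 530)), labels=None)
    y = None
    if labels is not None:
        missing = [i for i in ids if i not in labels]
        if missing:
            raise KeyError(f"labels missing for profile IDs: {missing}")
        y = np.array([labels[i] for i in ids], dtype=int)
    return FeatureTable(ids=ids, names=names, values=np.vstack(rows), labels=y)
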