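"""Independent naive-loop oracles used to cross-check the vectorized code.

Everything here is written straight from the defining formulas with plain
Python loops (or an established library's independent routine), on purpose:
these implementations share no code path with the package.
"""

import math

import numpy as np
from scipy import stats


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def reduce_matrix(V, groups, aa_order):
    """Group-mean merge of the 20 columns, by explicit loops."""
    L = len(V)
    R = [[0.0] * len(groups) for _ in range(L)]
    for i in range(L):
        for s, group in enumerate(groups):
            members = [V[i][aa_order.index(a)] for a in sorted(group)]
            R[i][s] = sum(members) / len(members)
    return R


def rpssm_ds(R):
    L = len(R)
    out = []
    for s in range(10):
        mean = sum(R[i][s] for i in range(L)) / L
        out.append(sum((R[i][s] - mean) ** 2 for i in range(L)) / L)
    return out


def rpssm_dst(R):
    L = len(R)
    out = []
    for s in range(10):
        for t in range(10):
            total = sum((R[i][s] - R[i + 1][t]) ** 2 / 2.0 for i in range(L - 1))
            out.append(total / (L - 1))
    return out


def aac(V):
    L = len(V)
    return [sum(V[i][j] for i in range(L)) / L for j in range(20)]


def dpc(V):
    L = len(V)
    out = []
    for i in range(20):
        for j in range(20):
            total = sum(V[k][i] * V[k + 1][j] for k in range(L - 1))
            out.append(total / (L - 1))
    return out


def rpssm_vector(V, groups, aa_order):
    R = reduce_matrix(V, groups, aa_order)
    return rpssm_ds(R) + rpssm_dst(R)


def aadp_vector(V):
    return aac(V) + dpc(V)


def relevance(X, y):
    """Per-column |Pearson r| via scipy, 0 for constant columns."""
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0 or np.std(y) == 0:
            out.append(0.0)
        else:
            out.append(abs(stats.pearsonr(col, y)[0]))
    return np.array(out)


def mean_pairwise_distance(X, metric="euclidean"):
    """Brute-force all-pairs mean distance between z-scored columns."""
    n, d = X.shape
    Z = np.empty_like(X, dtype=float)
    constant = []
    for j in range(d):
        sd = X[:, j].std()
        if sd == 0:
            Z[:, j] = 0.0
            constant.append(j)
        else:
            Z[:, j] = (X[:, j] - X[:, j].mean()) / sd
    out = np.zeros(d)
    valid = [j for j in range(d) if j not in constant]
    for a in range(d):
        if a in constant:
            continue
        dists = []
        for b in valid:
            if b == a:
                continue
            u, v = Z[:, a], Z[:, b]
            if metric == "euclidean":
                dists.append(math.sqrt(float(np.sum((u - v) ** 2)) / n))
            elif metric == "cosine":
                dists.append(1.0 - float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            else:  # tanimoto
                dists.append(1.0 - float(u @ v) / (u @ u + v @ v - u @ v))
        out[a] = sum(dists) / len(dists) if dists else 0.0
    return out


def confusion_metrics(tp, tn, fp, fn):
    """SN/SP/ACC%/MCC straight from the definitions."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return sn, sp, acc, mcc


def rank_auc(y, scores):
    """ROC area via the Mann-Whitney midrank formulation."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    r_pos = ranks[y == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
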