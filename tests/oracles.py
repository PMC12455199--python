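"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (explicit loops over
voxels, pairs and matrix entries) so that it shares no code path with the
package implementation it is checking.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


def pair_count_matrix(levels_3d: np.ndarray, ng: int, slice_idx: int, direction, d=1) -> np.ndarray:
    """Symmetric pair counts by scanning every voxel of one slice."""
    plane = levels_3d[slice_idx]
    counts = np.zeros((ng, ng))
    nr, nc = plane.shape
    dr, dc = direction
    for r in range(nr):
        for c in range(nc):
            if plane[r, c] <= 0:
                continue
            for sign in (+1, -1):
                r2, c2 = r + sign * dr * d, c + sign * dc * d
                if 0 <= r2 < nr and 0 <= c2 < nc and plane[r2, c2] > 0:
                    counts[plane[r, c] - 1, plane[r2, c2] - 1] += 1
    return counts


def glcm_features_naive(P: np.ndarray) -> dict:
    """Co-occurrence features by explicit double loops over (i, j)."""
    ng = P.shape[0]
    mu = 0.0
    for i in range(ng):
        for j in range(ng):
            mu += (i + 1) * P[i, j]
    var = 0.0
    for i in range(ng):
        for j in range(ng):
            var += (i + 1 - mu) ** 2 * P[i, j]
    cov = 0.0
    for i in range(ng):
        for j in range(ng):
            cov += (i + 1 - mu) * (j + 1 - mu) * P[i, j]
    corr = 1.0 if var <= 0 else max(-1.0, min(1.0, cov / var))
    out = {
        "joint.max": P.max(),
        "joint.avg": mu,
        "joint.var": var,
        "joint.entr": -sum(
            P[i, j] * math.log2(P[i, j]) for i in range(ng) for j in range(ng) if P[i, j] > 0
        ),
        "asm": sum(P[i, j] ** 2 for i in range(ng) for j in range(ng)),
        "contrast": sum((i - j) ** 2 * P[i, j] for i in range(ng) for j in range(ng)),
        "dissimilarity": sum(abs(i - j) * P[i, j] for i in range(ng) for j in range(ng)),
        "inv.diff": sum(P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng)),
        "corr": corr,
        "clust.tend": sum(
            (i + j + 2 - 2 * mu) ** 2 * P[i, j] for i in range(ng) for j in range(ng)
        ),
    }
    return out


def aggregate_naive(levels_3d: np.ndarray, ng: int, mode: str, d=1) -> dict:
    """Aggregation by explicitly collecting/merging per-slice-direction counts."""
    per = {}
    for s in range(levels_3d.shape[0]):
        for k, direction in enumerate(DIRECTIONS):
            c = pair_count_matrix(levels_3d, ng, s, direction, d)
            if c.sum() > 0:
                per[(s, k)] = c
    if not per:
        return {}
    groups: list[np.ndarray] = []
    if mode == "2d_avg":
        groups = list(per.values())
    elif mode == "2d_merged":
        for s in sorted({s for s, _ in per}):
            groups.append(sum(m for (si, _), m in per.items() if si == s))
    elif mode == "25d_avg":
        for k in sorted({k for _, k in per}):
            groups.append(sum(m for (_, ki), m in per.items() if ki == k))
    elif mode == "25d_merged":
        groups = [sum(per.values())]
    feats = [glcm_features_naive(g / g.sum()) for g in groups]
    return {name: float(np.mean([f[name] for f in feats])) for name in feats[0]}


def mann_whitney_exact(group0, group1) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    pooled = list(group0) + list(group1)
    n0 = len(group0)

    def u_of(sel):
        g0 = [pooled[i] for i in sel]
        g1 = [pooled[i] for i in range(len(pooled)) if i not in sel]
        return sum(1 for a in g0 for b in g1 if a > b) + 0.5 * sum(
            1 for a in g0 for b in g1 if a == b
        )

    u_obs = u_of(set(range(n0)))
    mean_u = n0 * (len(group1)) / 2.0
    count = 0
    total = 0
    for sel in itertools.combinations(range(len(pooled)), n0):
        u = u_of(set(sel))
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return u_obs, count / total


def bh_stepup_naive(p: np.ndarray) -> np.ndarray:
    """Adjusted p-values by the literal step-up definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_pos in range(m):
        i = rank_pos + 1
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        adj[order[rank_pos]] = min(1.0, min(candidates))
    return adj


def ols_slope_normal_equations(t, y) -> float:
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(t), t])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return float(beta[1])


def trapezoid_roc_auc(scores, labels) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        pred = scores >= t
        tpr = np.mean(pred[labels == 1])
        fpr = np.mean(pred[labels == 0])
        pts.append((float(fpr), float(tpr)))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def delong_variance_naive(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance via explicit placement values."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    auc = sum(psi(a, b) for a in pos for b in neg) / (m * n)
    v10 = [sum(psi(a, b) for b in neg) / n for a in pos]
    v01 = [sum(psi(a, b) for a in pos) / m for b in neg]
    s10 = sum((v - auc) ** 2 for v in v10) / (m - 1)
    s01 = sum((v - auc) ** 2 for v in v01) / (n - 1)
    return auc, s10 / m + s01 / n
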