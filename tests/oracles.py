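"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested loops straight from the
definitions, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBORS_26 = [
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) != (0, 0, 0)
]
DIRECTIONS_13 = [d for d in NEIGHBORS_26 if d > (0, 0, 0)]


def brute_signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel distance to the nearest voxel center of the opposite
    class; negative inside the mask."""
    sp = np.asarray(spacing, float)
    inside = np.argwhere(mask) * sp
    outside = np.argwhere(~mask) * sp
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * sp
        if mask[idx]:
            d = np.sqrt(((outside - p) ** 2).sum(axis=1)).min()
            out[idx] = -d
        else:
            d = np.sqrt(((inside - p) ** 2).sum(axis=1)).min()
            out[idx] = d
    return out


def _in(shape, i, j, k):
    return 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]


def brute_glcm(levels, mask):
    ng = int(levels[mask].max())
    P = np.zeros((ng, ng))
    for (i, j, k) in np.argwhere(mask):
        for (a, b, c) in DIRECTIONS_13:
            for sgn in (1, -1):
                ii, jj, kk = i + sgn * a, j + sgn * b, k + sgn * c
                if _in(mask.shape, ii, jj, kk) and mask[ii, jj, kk]:
                    P[levels[i, j, k] - 1, levels[ii, jj, kk] - 1] += 1
    return P


def brute_glrlm(levels, mask):
    """Runs of equal level along each of the 13 directions."""
    shape = mask.shape
    runs = []
    for d in DIRECTIONS_13:
        counted = set()
        for start in np.ndindex(shape):
            if not mask[start]:
                continue
            prev = (start[0] - d[0], start[1] - d[1], start[2] - d[2])
            # run start: predecessor out of grid, out of mask, or other level
            if (
                _in(shape, *prev)
                and mask[prev]
                and levels[prev] == levels[start]
            ):
                continue
            length = 0
            cur = start
            while _in(shape, *cur) and mask[cur] and levels[cur] == levels[start]:
                length += 1
                cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
            key = (d, start)
            assert key not in counted
            counted.add(key)
            runs.append((int(levels[start]), length))
    ng = int(levels[mask].max())
    max_l = max(l for _, l in runs)
    R = np.zeros((ng, max_l))
    for gl, l in runs:
        R[gl - 1, l - 1] += 1
    return R


def brute_glszm(levels, mask):
    """Zones by 26-connected flood fill per gray level."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.ndindex(shape):
        if not mask[start] or seen[start]:
            continue
        gl = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if _in(shape, *w) and mask[w] and not seen[w] and levels[w] == gl:
                    seen[w] = True
                    stack.append(w)
        zones.append((int(gl), size))
    ng = int(levels[mask].max())
    max_s = max(s for _, s in zones)
    S = np.zeros((ng, max_s))
    for gl, s in zones:
        S[gl - 1, s - 1] += 1
    return S


def brute_gldm(levels, mask, alpha=0):
    deps = []
    for (i, j, k) in np.argwhere(mask):
        d = 1  # the center voxel
        for (a, b, c) in NEIGHBORS_26:
            w = (i + a, j + b, k + c)
            if _in(mask.shape, *w) and mask[w] and abs(int(levels[w]) - int(levels[i, j, k])) <= alpha:
                d += 1
        deps.append((int(levels[i, j, k]), d))
    ng = int(levels[mask].max())
    max_d = max(d for _, d in deps)
    P = np.zeros((ng, max_d))
    for gl, d in deps:
        P[gl - 1, d - 1] += 1
    return P


def brute_ngtdm(levels, mask):
    ng = int(levels[mask].max())
    n = np.zeros(ng)
    s = np.zeros(ng)
    for (i, j, k) in np.argwhere(mask):
        nb = []
        for (a, b, c) in NEIGHBORS_26:
            w = (i + a, j + b, k + c)
            if _in(mask.shape, *w) and mask[w]:
                nb.append(levels[w])
        gl = int(levels[i, j, k])
        if nb:
            n[gl - 1] += 1
            s[gl - 1] += abs(gl - sum(nb) / len(nb))
    return n, s


def brute_auc(scores, labels) -> float:
    """Exhaustive concordant-pair enumeration with tie correction."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_pr_auc(scores, labels) -> float:
    """Step integration over recall with one step per distinct threshold."""
    thresholds = sorted(set(scores), reverse=True)
    npos = sum(labels)
    area = 0.0
    prev_recall = 0.0
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        recall = tp / npos
        precision = tp / (tp + fp)
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


def brute_net_benefit(probs, labels, pt) -> float:
    n = len(labels)
    tp = sum(1 for p, y in zip(probs, labels) if p >= pt and y == 1)
    fp = sum(1 for p, y in zip(probs, labels) if p >= pt and y == 0)
    return tp / n - fp / n * pt / (1 - pt)


def brute_nri_categorical(p_ref, p_new, labels, cut) -> float:
    def cat(p):
        return 1 if p >= cut else 0

    ev_up = ev_dn = ne_up = ne_dn = 0
    n_ev = sum(labels)
    n_ne = len(labels) - n_ev
    for pr, pn, y in zip(p_ref, p_new, labels):
        up = cat(pn) > cat(pr)
        dn = cat(pn) < cat(pr)
        if y == 1:
            ev_up += up
            ev_dn += dn
        else:
            ne_up += up
            ne_dn += dn
    return (ev_up - ev_dn) / n_ev - (ne_up - ne_dn) / n_ne


def brute_idi(p_ref, p_new, labels) -> float:
    ev = [i for i, y in enumerate(labels) if y == 1]
    ne = [i for i, y in enumerate(labels) if y == 0]
    slope_new = np.mean([p_new[i] for i in ev]) - np.mean([p_new[i] for i in ne])
    slope_ref = np.mean([p_ref[i] for i in ev]) - np.mean([p_ref[i] for i in ne])
    return slope_new - slope_ref


def anova_icc21(y: np.ndarray) -> float:
    """ICC(2,1) from explicitly accumulated ANOVA sums."""
    n, k = y.shape
    grand = sum(y[i][j] for i in range(n) for j in range(k)) / (n * k)
    ssr = sum(k * (sum(y[i]) / k - grand) ** 2 for i in range(n))
    ssc = sum(n * (sum(y[i][j] for i in range(n)) / n - grand) ** 2 for j in range(k))
    sse = (
        sum((y[i][j] - grand) ** 2 for i in range(n) for j in range(k)) - ssr - ssc
    )
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def bh_stepup(p):
    """Hand application of the Benjamini-Hochberg step-up rule."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
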