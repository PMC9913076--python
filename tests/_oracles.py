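"""Independent brute-force oracles: naive pair/run/zone/neighbour enumeration
and direct-sum feature formulas, written as explicit Python loops so they
share no code path with the vectorized implementations they check."""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def _inb(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def bf_glcm(grey, mask, offset, n_bins):
    """Symmetric co-occurrence counts by scanning every voxel pair."""
    M = np.zeros((n_bins, n_bins))
    shape = grey.shape
    for p in product(*[range(n) for n in shape]):
        if not mask[p]:
            continue
        q = tuple(c + d for c, d in zip(p, offset))
        if _inb(shape, q) and mask[q]:
            M[grey[p] - 1, grey[q] - 1] += 1
            M[grey[q] - 1, grey[p] - 1] += 1
    return M


def bf_glrlm(grey, mask, offset, n_bins):
    """Run counts: start at voxels with no same-grey predecessor, walk forward."""
    runs = {}
    shape = grey.shape
    for p in product(*[range(n) for n in shape]):
        if not mask[p]:
            continue
        prev = tuple(c - d for c, d in zip(p, offset))
        if _inb(shape, prev) and mask[prev] and grey[prev] == grey[p]:
            continue  # not a run start
        length = 1
        q = tuple(c + d for c, d in zip(p, offset))
        while _inb(shape, q) and mask[q] and grey[q] == grey[p]:
            length += 1
            q = tuple(c + d for c, d in zip(q, offset))
        runs[(grey[p], length)] = runs.get((grey[p], length), 0) + 1
    if not runs:
        return np.zeros((n_bins, 1))
    max_len = max(l for _, l in runs)
    R = np.zeros((n_bins, max_len))
    for (g, l), c in runs.items():
        R[g - 1, l - 1] = c
    return R


def _neighbours(p, shape, offsets):
    for off in offsets:
        q = tuple(c + d for c, d in zip(p, off))
        if _inb(shape, q):
            yield q


def _full_offsets(two_d):
    out = []
    for dz in ((0,) if two_d else (-1, 0, 1)):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) != (0, 0, 0):
                    out.append((dz, dy, dx))
    return out


def bf_zones(grey, mask, two_d):
    """Constant-grey connected zones by BFS (full Chebyshev connectivity).

    Returns a list of (grey, size, min city-block distance to outside-ROI,
    border = 1) tuples.
    """
    shape = grey.shape
    offsets = _full_offsets(two_d)
    seen = np.zeros(shape, bool)
    zones = []
    roi = [p for p in product(*[range(n) for n in shape]) if mask[p]]
    # brute-force distance: min over outside voxels and virtual outside-grid
    dist = {}
    for p in roi:
        axes = range(1 if two_d else 0, 3)
        d = min(min(p[a] + 1, shape[a] - p[a]) for a in axes)
        for q in product(*[range(n) for n in shape]):
            if two_d and q[0] != p[0]:
                continue
            if not mask[q]:
                d = min(d, sum(abs(a - b) for a, b in zip(p, q)))
        dist[p] = d
    for p in roi:
        if seen[p]:
            continue
        g = grey[p]
        stack = [p]
        seen[p] = True
        members = []
        while stack:
            u = stack.pop()
            members.append(u)
            for v in _neighbours(u, shape, offsets):
                if mask[v] and not seen[v] and grey[v] == g:
                    seen[v] = True
                    stack.append(v)
        zones.append((int(g), len(members), min(dist[m] for m in members)))
    return zones


def bf_ngtdm(grey, mask, two_d, n_bins):
    """(n_i, s_i) per grey by explicit neighbourhood means."""
    shape = grey.shape
    offsets = _full_offsets(two_d)
    n = np.zeros(n_bins)
    s = np.zeros(n_bins)
    for p in product(*[range(nn) for nn in shape]):
        if not mask[p]:
            continue
        vals = [grey[q] for q in _neighbours(p, shape, offsets) if mask[q]]
        if not vals:
            continue
        n[grey[p] - 1] += 1
        s[grey[p] - 1] += abs(grey[p] - sum(vals) / len(vals))
    return np.stack([n, s], axis=1)


def bf_ngldm(grey, mask, two_d, n_bins, alpha=0):
    """Dependence counts by explicit neighbour comparison."""
    shape = grey.shape
    offsets = _full_offsets(two_d)
    entries = {}
    for p in product(*[range(nn) for nn in shape]):
        if not mask[p]:
            continue
        k = sum(
            1
            for q in _neighbours(p, shape, offsets)
            if mask[q] and abs(int(grey[q]) - int(grey[p])) <= alpha
        )
        entries[(grey[p], k)] = entries.get((grey[p], k), 0) + 1
    max_k = max(k for _, k in entries)
    M = np.zeros((n_bins, max_k + 1))
    for (g, k), c in entries.items():
        M[g - 1, k] = c
    return M


# ---- direct-sum feature formulas ---------------------------------------------


def _log2(x):
    return math.log(x, 2.0)


def bf_glcm_features(counts):
    """All 25 co-occurrence features from explicit double sums."""
    total = counts.sum()
    D = counts.shape[0]
    P = {(i, j): counts[i - 1, j - 1] / total for i in range(1, D + 1) for j in range(1, D + 1)}
    p_i = {i: sum(P[i, j] for j in range(1, D + 1)) for i in range(1, D + 1)}
    present = [i for i in range(1, D + 1) if p_i[i] > 0]
    ng = len(present)
    mu = sum(i * p_i[i] for i in present)
    var = sum((i - mu) ** 2 * p_i[i] for i in present)
    pd_ = {}
    ps = {}
    for i in range(1, D + 1):
        for j in range(1, D + 1):
            if P[i, j] > 0:
                pd_[abs(i - j)] = pd_.get(abs(i - j), 0.0) + P[i, j]
                ps[i + j] = ps.get(i + j, 0.0) + P[i, j]
    mu_d = sum(k * v for k, v in pd_.items())
    mu_s = sum(k * v for k, v in ps.items())
    nz = [(i, j) for i in present for j in present if P[i, j] > 0]
    h_xy = -sum(P[i, j] * _log2(P[i, j]) for i, j in nz)
    h_x = -sum(p_i[i] * _log2(p_i[i]) for i in present)
    h_xy1 = -sum(P[i, j] * _log2(p_i[i] * p_i[j]) for i, j in nz)
    h_xy2 = -sum(
        p_i[i] * p_i[j] * _log2(p_i[i] * p_i[j]) for i in present for j in present
    )
    corr = ((sum(i * j * P[i, j] for i, j in nz) - mu * mu) / var) if var > 0 else 1.0
    return {
        "joint_maximum": max(P.values()),
        "joint_average": mu,
        "joint_variance": var,
        "joint_entropy": h_xy,
        "difference_average": mu_d,
        "difference_variance": sum((k - mu_d) ** 2 * v for k, v in pd_.items()),
        "difference_entropy": -sum(v * _log2(v) for v in pd_.values() if v > 0),
        "sum_average": mu_s,
        "sum_variance": sum((k - mu_s) ** 2 * v for k, v in ps.items()),
        "sum_entropy": -sum(v * _log2(v) for v in ps.values() if v > 0),
        "angular_second_moment": sum(P[i, j] ** 2 for i, j in nz),
        "contrast": sum((i - j) ** 2 * P[i, j] for i, j in nz),
        "dissimilarity": sum(abs(i - j) * P[i, j] for i, j in nz),
        "inverse_difference": sum(P[i, j] / (1 + abs(i - j)) for i, j in nz),
        "inverse_difference_normalized": sum(P[i, j] / (1 + abs(i - j) / ng) for i, j in nz),
        "inverse_difference_moment": sum(P[i, j] / (1 + (i - j) ** 2) for i, j in nz),
        "inverse_difference_moment_normalized": sum(
            P[i, j] / (1 + (i - j) ** 2 / ng**2) for i, j in nz
        ),
        "inverse_variance": sum(P[i, j] / (i - j) ** 2 for i, j in nz if i != j),
        "correlation": corr,
        "autocorrelation": sum(i * j * P[i, j] for i, j in nz),
        "cluster_tendency": sum((i + j - 2 * mu) ** 2 * P[i, j] for i, j in nz),
        "cluster_shade": sum((i + j - 2 * mu) ** 3 * P[i, j] for i, j in nz),
        "cluster_prominence": sum((i + j - 2 * mu) ** 4 * P[i, j] for i, j in nz),
        "information_correlation_1": (h_xy - h_xy1) / h_x if h_x > 0 else 0.0,
        "information_correlation_2": math.sqrt(
            max(0.0, 1.0 - 2.0 ** (-2.0 * (h_xy2 - h_xy)))
        ),
    }


def bf_rlm_features(counts, n_vox, with_energy=False):
    """Generic run/zone/dependence family by explicit sums; keys are the
    generic slots (se, le, ...) to be renamed by the caller."""
    D, nc = counts.shape
    ns = counts.sum()
    cells = [
        (i, j, counts[i - 1, j - 1])
        for i in range(1, D + 1)
        for j in range(1, nc + 1)
        if counts[i - 1, j - 1] > 0
    ]
    r = {i: sum(c for ii, j, c in cells if ii == i) for i in range(1, D + 1)}
    cj = {j: sum(c for i, jj, c in cells if jj == j) for j in range(1, nc + 1)}
    mu_i = sum(i * c for i, j, c in cells) / ns
    mu_j = sum(j * c for i, j, c in cells) / ns
    out = {
        "se": sum(c / j**2 for i, j, c in cells) / ns,
        "le": sum(c * j**2 for i, j, c in cells) / ns,
        "lgle": sum(c / i**2 for i, j, c in cells) / ns,
        "hgle": sum(c * i**2 for i, j, c in cells) / ns,
        "slgle": sum(c / (i**2 * j**2) for i, j, c in cells) / ns,
        "shgle": sum(c * i**2 / j**2 for i, j, c in cells) / ns,
        "llgle": sum(c * j**2 / i**2 for i, j, c in cells) / ns,
        "lhgle": sum(c * i**2 * j**2 for i, j, c in cells) / ns,
        "gln": sum(v**2 for v in r.values()) / ns,
        "glnn": sum(v**2 for v in r.values()) / ns**2,
        "nun": sum(v**2 for v in cj.values()) / ns,
        "nunn": sum(v**2 for v in cj.values()) / ns**2,
        "pct": ns / n_vox,
        "glv": sum((i - mu_i) ** 2 * c for i, j, c in cells) / ns,
        "nv": sum((j - mu_j) ** 2 * c for i, j, c in cells) / ns,
        "ent": -sum((c / ns) * _log2(c / ns) for _, _, c in cells),
    }
    if with_energy:
        out["energy"] = sum((c / ns) ** 2 for _, _, c in cells)
    return out


def bf_ngtdm_features(counts, cap=1.0e6):
    n = counts[:, 0]
    s = counts[:, 1]
    N = n.sum()
    D = len(n)
    p = {i: n[i - 1] / N for i in range(1, D + 1)}
    sv = {i: s[i - 1] for i in range(1, D + 1)}
    pres = [i for i in range(1, D + 1) if p[i] > 0]
    ngp = len(pres)
    ps = sum(p[i] * sv[i] for i in pres)
    coarseness = min(1.0 / ps, cap) if ps > 0 else cap
    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in pres for j in pres)
            / (ngp * (ngp - 1))
            * (sum(sv[i] for i in pres) / N)
        )
        denom = sum(abs(i * p[i] - j * p[j]) for i in pres for j in pres)
        busyness = ps / denom if denom > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
    complexity = (
        sum(
            abs(i - j) * (p[i] * sv[i] + p[j] * sv[j]) / (p[i] + p[j])
            for i in pres
            for j in pres
        )
        / N
    )
    s_tot = sum(sv[i] for i in pres)
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in pres for j in pres) / s_tot
        if s_tot > 0
        else 0.0
    )
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


def bf_icc(table):
    """One-way ANOVA ICC by explicit sums of squares."""
    x = np.asarray(table, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssb = k * sum((row.mean() - grand) ** 2 for row in x)
    ssw = sum((v - row.mean()) ** 2 for row in x for v in row)
    bms = ssb / (n - 1)
    wms = ssw / (n * (k - 1))
    if bms + wms == 0:
        return 1.0
    return (bms - wms) / (bms + wms)


def bf_spearman(x, y):
    """Rank correlation with average ranks, from the Pearson formula on ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        rk = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                rk[order[t]] = avg
            i = j + 1
        return rk

    rx, ry = ranks(list(x)), ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den
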