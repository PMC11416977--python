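"""Independent brute-force oracles for the texture and statistics code.

Everything here is written in plain enumeration style (dicts, explicit
loops, no vectorization) and deliberately shares no code with the package
implementation: pair counting for co-occurrence, line walking for runs,
breadth-first search for zones, neighbor loops for gray-tone and
dependence statistics, and direct pair counting / grid search for AUC and
the Cox partial likelihood.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np


def _in_roi(levels, mask, z, y, x):
    nz, ny, nx = mask.shape
    return 0 <= z < nz and 0 <= y < ny and 0 <= x < nx and mask[z, y, x]


def brute_glcm(levels, mask, d, symmetric=True):
    """Co-occurrence counts {(i, j): count} for one direction offset."""
    counts: dict = defaultdict(float)
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + d[0], y + d[1], x + d[2]
                if _in_roi(levels, mask, z2, y2, x2):
                    a, b = int(levels[z, y, x]), int(levels[z2, y2, x2])
                    counts[(a, b)] += 1
                    if symmetric:
                        counts[(b, a)] += 1
    return dict(counts)


def brute_runs(levels, mask, d):
    """All maximal runs [(gray level, length), ...] along direction d."""
    runs = []
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                pz, py, px = z - d[0], y - d[1], x - d[2]
                g = int(levels[z, y, x])
                # only start a run if the predecessor does not continue it
                if _in_roi(levels, mask, pz, py, px) and int(levels[pz, py, px]) == g:
                    continue
                length = 1
                cz, cy, cx = z + d[0], y + d[1], x + d[2]
                while _in_roi(levels, mask, cz, cy, cx) and int(levels[cz, cy, cx]) == g:
                    length += 1
                    cz, cy, cx = cz + d[0], cy + d[1], cx + d[2]
                runs.append((g, length))
    return runs


def brute_zones(levels, mask):
    """All 26-connected constant-level zones [(gray level, size), ...]."""
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    nz, ny, nx = mask.shape
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or seen[z, y, x]:
                    continue
                g = int(levels[z, y, x])
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for a, b, c in offs:
                        vz, vy, vx = cz + a, cy + b, cx + c
                        if (_in_roi(levels, mask, vz, vy, vx)
                                and not seen[vz, vy, vx]
                                and int(levels[vz, vy, vx]) == g):
                            seen[vz, vy, vx] = True
                            stack.append((vz, vy, vx))
                zones.append((g, size))
    return zones


def brute_ngtdm(levels, mask):
    """Per-level (n_i, s_i) dicts from explicit neighbor averaging."""
    n_i: dict = defaultdict(int)
    s_i: dict = defaultdict(float)
    nz, ny, nx = mask.shape
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                nbrs = [int(levels[z + a, y + b, x + c]) for a, b, c in offs
                        if _in_roi(levels, mask, z + a, y + b, x + c)]
                if not nbrs:
                    continue
                g = int(levels[z, y, x])
                n_i[g] += 1
                s_i[g] += abs(g - sum(nbrs) / len(nbrs))
    return dict(n_i), dict(s_i)


def brute_gldm(levels, mask, alpha=0):
    """Dependence counts {(gray level, n dependent neighbors): count}."""
    counts: dict = defaultdict(int)
    nz, ny, nx = mask.shape
    offs = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)]
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                g = int(levels[z, y, x])
                dep = sum(
                    1 for a, b, c in offs
                    if _in_roi(levels, mask, z + a, y + b, x + c)
                    and abs(int(levels[z + a, y + b, x + c]) - g) <= alpha
                )
                counts[(g, dep)] += 1
    return dict(counts)


# --------------------------------------------------------------------------
# independent feature formulas, straight from the enumerations


def glcm_features_from_pairs(counts):
    """A subset of GLCM features computed directly from pair counts."""
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    energy = sum(v * v for v in p.values())
    entropy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    contrast = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    maxp = max(p.values())
    mu_x = sum(i * v for (i, _j), v in p.items())
    ssq = sum(v * (i - mu_x) ** 2 for (i, _j), v in p.items())
    return {
        "JointEnergy": energy,
        "JointEntropy": entropy,
        "Contrast": contrast,
        "MaximumProbability": maxp,
        "SumSquares": ssq,
    }


def rlm_features_from_sizes(items, n_voxels, short_key, size_key):
    """Shared run-length / size-zone formulas from (level, size) lists."""
    nr = len(items)
    sre = sum(1.0 / (ln * ln) for _g, ln in items) / nr
    lre = sum(float(ln * ln) for _g, ln in items) / nr
    by_level: dict = defaultdict(int)
    by_size: dict = defaultdict(int)
    for g, ln in items:
        by_level[g] += 1
        by_size[ln] += 1
    gln = sum(c * c for c in by_level.values()) / nr
    szn = sum(c * c for c in by_size.values()) / nr
    pct = nr / n_voxels
    hgl = sum(g * g for g, _ln in items) / nr
    return {
        short_key: sre,
        "Long" + size_key: lre,
        "GrayLevelNonUniformity": gln,
        "SizeNonUniformity": szn,
        "Percentage": pct,
        "HighGrayLevel": hgl,
    }


def ngtdm_features_from_table(n_i, s_i):
    """NGTDM Coarseness/Contrast from explicit (n_i, s_i) dictionaries."""
    n = sum(n_i.values())
    p = {g: c / n for g, c in n_i.items()}
    ps = sum(p[g] * s_i.get(g, 0.0) for g in p)
    coarseness = min(1.0 / ps, 1e6) if ps > 0 else 1e6
    levels = sorted(p)
    ngp = len(levels)
    if ngp <= 1:
        contrast = 0.0
    else:
        acc = sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
        contrast = acc / (ngp * (ngp - 1)) * (sum(s_i.values()) / n)
    return {"Coarseness": coarseness, "Contrast": contrast}


def gldm_features_from_counts(counts):
    """GLDM dependence-non-uniformity (plain + normalized) from counts."""
    n = sum(counts.values())
    by_dep: dict = defaultdict(int)
    for (_g, d), c in counts.items():
        by_dep[d] += c
    dn = sum(c * c for c in by_dep.values()) / n
    return {"DependenceNonUniformity": dn,
            "DependenceNonUniformityNormalized": dn / n}


# --------------------------------------------------------------------------
# statistics oracles


def auc_pair_counting(scores, labels):
    """AUC by enumerating all positive-negative pairs, ties half credit."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def cox_loglik_1d(beta, x, times, events):
    """Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for i in range(len(times)):
        if not events[i]:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def cox_grid_mle_1d(x, times, events, lo=-5.0, hi=5.0, steps=20001):
    """Maximize the 1-D partial likelihood by brute-force grid search."""
    grid = np.linspace(lo, hi, steps)
    lls = [cox_loglik_1d(b, x, times, events) for b in grid]
    return float(grid[int(np.argmax(lls))])


def icc_two_way(table):
    """ICC(2,1) via explicitly accumulated ANOVA sums of squares."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ms_r = sum((row.mean() - grand) ** 2 for row in x) * k / (n - 1)
    ms_c = sum((x[:, j].mean() - grand) ** 2 for j in range(k)) * n / (k - 1)
    ss_e = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n) for j in range(k)
    )
    ms_e = ss_e / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))
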