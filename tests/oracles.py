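"""Independent brute-force oracles for the texture matrices and AUC.

Everything here is written as plain nested loops over voxels/pairs/zones,
deliberately sharing no code with the package implementation, so the fuzz
tests compare two independent routes to the same quantity.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Dict, List, Tuple

import numpy as np

OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx, dy, dz in product((-1, 0, 1), repeat=3)
    if (dx, dy, dz) != (0, 0, 0)
]


def naive_glcm(levels: np.ndarray, G: int) -> np.ndarray:
    """Symmetric direction-pooled co-occurrence probabilities by voxel loop."""
    counts = np.zeros((G, G))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                for dx, dy, dz in OFFSETS_13:
                    for sgn in (1, -1):
                        xx, yy, zz = x + sgn * dx, y + sgn * dy, z + sgn * dz
                        if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                            b = levels[xx, yy, zz]
                            if b:
                                counts[a - 1, b - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def naive_glcm_features(P: np.ndarray) -> Dict[str, float]:
    G = P.shape[0]
    idx = range(1, G + 1)
    px = [sum(P[i - 1, j - 1] for j in idx) for i in idx]
    mu = sum(i * px[i - 1] for i in idx)
    var = sum((i - mu) ** 2 * px[i - 1] for i in idx)
    sigma = math.sqrt(var)

    def lg(v):
        return math.log2(v) if v > 0 else 0.0

    f: Dict[str, float] = {}
    f["energy"] = sum(P[i - 1, j - 1] ** 2 for i in idx for j in idx)
    f["contrast"] = sum((i - j) ** 2 * P[i - 1, j - 1] for i in idx for j in idx)
    f["correlation"] = (
        sum((i - mu) * (j - mu) * P[i - 1, j - 1] for i in idx for j in idx) / var
        if var > 0 else 0.0
    )
    f["sum_of_squares_variance"] = sum(
        (i - mu) ** 2 * P[i - 1, j - 1] for i in idx for j in idx
    )
    f["homogeneity"] = sum(
        P[i - 1, j - 1] / (1 + (i - j) ** 2) for i in idx for j in idx
    )
    psum = {k: 0.0 for k in range(2, 2 * G + 1)}
    pdiff = {k: 0.0 for k in range(0, G)}
    for i in idx:
        for j in idx:
            psum[i + j] += P[i - 1, j - 1]
            pdiff[abs(i - j)] += P[i - 1, j - 1]
    sa = sum(k * v for k, v in psum.items())
    f["sum_average"] = sa
    f["sum_variance"] = sum((k - sa) ** 2 * v for k, v in psum.items())
    f["sum_entropy"] = -sum(v * lg(v) for v in psum.values())
    ent = -sum(
        P[i - 1, j - 1] * lg(P[i - 1, j - 1]) for i in idx for j in idx
    )
    f["entropy"] = ent
    da = sum(k * v for k, v in pdiff.items())
    f["difference_variance"] = sum((k - da) ** 2 * v for k, v in pdiff.items())
    f["difference_entropy"] = -sum(v * lg(v) for v in pdiff.values())
    hxy1 = -sum(
        P[i - 1, j - 1] * lg(px[i - 1] * px[j - 1]) for i in idx for j in idx
    )
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * lg(px[i - 1] * px[j - 1]) for i in idx for j in idx
    )
    hx = -sum(p * lg(p) for p in px)
    f["imc1"] = (ent - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - ent) * math.log(2.0))
    f["imc2"] = math.sqrt(max(arg, 0.0))
    f["autocorrelation"] = sum(i * j * P[i - 1, j - 1] for i in idx for j in idx)
    for power, name in ((3, "cluster_shade"), (4, "cluster_prominence"), (2, "cluster_tendency")):
        f[name] = sum(
            (i + j - 2 * mu) ** power * P[i - 1, j - 1] for i in idx for j in idx
        )
    f["dissimilarity"] = sum(abs(i - j) * P[i - 1, j - 1] for i in idx for j in idx)
    f["maximum_probability"] = float(P.max())
    return f


def naive_ngtdm(levels: np.ndarray, G: int) -> Tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) arrays (index 1..G) by explicit neighborhood loops."""
    nx, ny, nz = levels.shape
    n = np.zeros(G + 1)
    s = np.zeros(G + 1)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                vals = []
                for dx, dy, dz in NEIGHBORS_26:
                    xx, yy, zz = x + dx, y + dy, z + dz
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        b = levels[xx, yy, zz]
                        if b:
                            vals.append(b)
                if not vals:
                    continue
                n[a] += 1
                s[a] += abs(a - sum(vals) / len(vals))
    return n, s


def naive_ngtdm_features(n: np.ndarray, s: np.ndarray, cap: float) -> Dict[str, float]:
    N = n.sum()
    G = len(n) - 1
    p = n / N
    present = [i for i in range(1, G + 1) if n[i] > 0]
    f: Dict[str, float] = {}
    ps = sum(p[i] * s[i] for i in present)
    f["coarseness"] = min(1.0 / ps, cap) if ps > 0 else cap
    ngp = len(present)
    if ngp > 1:
        f["contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1))
        ) * (s.sum() / N)
    else:
        f["contrast"] = 0.0
    denom = sum(abs(i * p[i] - j * p[j]) for i in present for j in present)
    f["busyness"] = ps / denom if denom > 0 else 0.0
    f["complexity"] = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (N * (p[i] + p[j]))
        for i in present for j in present
    )
    ssum = s.sum()
    f["strength"] = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / ssum
        if ssum > 0 else 0.0
    )
    return f


def naive_glszm(levels: np.ndarray, G: int) -> Dict[Tuple[int, int], int]:
    """Zone counts {(gray level, size): count} by BFS flood fill."""
    nx, ny, nz = levels.shape
    seen = np.zeros(levels.shape, dtype=bool)
    zones: Dict[Tuple[int, int], int] = {}
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = levels[x, y, z]
                if g == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in NEIGHBORS_26:
                        xx, yy, zz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz
                            and not seen[xx, yy, zz] and levels[xx, yy, zz] == g
                        ):
                            seen[xx, yy, zz] = True
                            stack.append((xx, yy, zz))
                zones[(int(g), size)] = zones.get((int(g), size), 0) + 1
    return zones


def naive_glszm_features(zones: Dict[Tuple[int, int], int], n_voxels: int) -> Dict[str, float]:
    nz = sum(zones.values())
    f: Dict[str, float] = {}
    f["small_zone_emphasis"] = sum(c / j ** 2 for (i, j), c in zones.items()) / nz
    f["large_zone_emphasis"] = sum(c * j ** 2 for (i, j), c in zones.items()) / nz
    by_g: Dict[int, int] = {}
    by_s: Dict[int, int] = {}
    for (i, j), c in zones.items():
        by_g[i] = by_g.get(i, 0) + c
        by_s[j] = by_s.get(j, 0) + c
    f["gray_level_nonuniformity"] = sum(v ** 2 for v in by_g.values()) / nz
    f["zone_size_nonuniformity"] = sum(v ** 2 for v in by_s.values()) / nz
    f["zone_percentage"] = nz / n_voxels
    f["low_gray_level_zone_emphasis"] = sum(c / i ** 2 for (i, j), c in zones.items()) / nz
    f["high_gray_level_zone_emphasis"] = sum(c * i ** 2 for (i, j), c in zones.items()) / nz
    f["small_zone_low_gray_level_emphasis"] = sum(
        c / (i ** 2 * j ** 2) for (i, j), c in zones.items()
    ) / nz
    f["small_zone_high_gray_level_emphasis"] = sum(
        c * i ** 2 / j ** 2 for (i, j), c in zones.items()
    ) / nz
    f["large_zone_low_gray_level_emphasis"] = sum(
        c * j ** 2 / i ** 2 for (i, j), c in zones.items()
    ) / nz
    f["large_zone_high_gray_level_emphasis"] = sum(
        c * i ** 2 * j ** 2 for (i, j), c in zones.items()
    ) / nz
    return f


def naive_auc(scores, labels) -> float:
    """Pairwise-count AUC: wins + half-ties over positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
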