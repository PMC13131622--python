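"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written as plain Python loops over explicit
definitions (exhaustive neighborhood scans, BFS flood fill, pair-counting
co-occurrence statistics) and shares no code with the package.
"""

import math
from collections import deque

import numpy as np


def brute_force_extrema(dog):
    """Exhaustive 3x3x3 strict-extremum scan over one DoG volume.

    Returns {(z, y, x): polarity} for interior voxels that are strictly
    greater ("dark", maxima) or strictly less ("bright", minima) than all 26
    neighbors.
    """
    nz, ny, nx = dog.shape
    out = {}
    for z in range(1, nz - 1):
        for y in range(1, ny - 1):
            for x in range(1, nx - 1):
                v = dog[z, y, x]
                is_max = True
                is_min = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            w = dog[z + dz, y + dy, x + dx]
                            if v <= w:
                                is_max = False
                            if v >= w:
                                is_min = False
                    if not (is_max or is_min):
                        break
                if is_max:
                    out[(z, y, x)] = "dark"
                elif is_min:
                    out[(z, y, x)] = "bright"
    return out


def flood_fill_components(mask, connectivity=26):
    """BFS connected components of a boolean 3D mask; returns sorted volumes."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    elif connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        raise ValueError(connectivity)
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros(mask.shape, dtype=bool)
    sizes = []
    nz, ny, nx = mask.shape
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[z0, y0, x0] or seen[z0, y0, x0]:
                    continue
                q = deque([(z0, y0, x0)])
                seen[z0, y0, x0] = True
                size = 0
                while q:
                    z, y, x = q.popleft()
                    size += 1
                    for dz, dy, dx in offsets:
                        a, b, c = z + dz, y + dy, x + dx
                        if 0 <= a < nz and 0 <= b < ny and 0 <= c < nx:
                            if mask[a, b, c] and not seen[a, b, c]:
                                seen[a, b, c] = True
                                q.append((a, b, c))
                sizes.append(size)
    return sorted(sizes)


# 13 unique distance-1 offsets in 3D (same canonical half-set convention)
OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, -1), (0, 1, 0), (0, 1, 1),
    (1, -1, -1), (1, -1, 0), (1, -1, 1),
    (1, 0, -1), (1, 0, 0), (1, 0, 1),
    (1, 1, -1), (1, 1, 0), (1, 1, 1),
]


def _log2(x):
    return math.log(x, 2.0)


def haralick_bruteforce(qpatch, n_levels=32):
    """Pair-counting Haralick oracle: 13 features averaged over directions.

    For each of the 13 unique distance-1 offsets, counts co-occurring level
    pairs where both voxels are nonzero, symmetrizes, normalizes, computes the
    13 statistics with explicit loops, then averages over directions that had
    at least one valid pair. Returns None when no direction has a valid pair.
    """
    q = np.asarray(qpatch)
    nz, ny, nx = q.shape
    per_dir = []
    for dz, dy, dx in OFFSETS_13:
        counts = [[0.0] * n_levels for _ in range(n_levels)]
        total = 0.0
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    a, b, c = z + dz, y + dy, x + dx
                    if not (0 <= a < nz and 0 <= b < ny and 0 <= c < nx):
                        continue
                    la, lb = int(q[z, y, x]), int(q[a, b, c])
                    if la == 0 or lb == 0:
                        continue
                    counts[la - 1][lb - 1] += 1.0
                    counts[lb - 1][la - 1] += 1.0  # symmetric
                    total += 2.0
        if total == 0:
            continue
        P = [[counts[i][j] / total for j in range(n_levels)] for i in range(n_levels)]
        per_dir.append(_haralick_13(P, n_levels))
    if not per_dir:
        return None
    return [sum(col) / len(per_dir) for col in zip(*per_dir)]


def _haralick_13(P, n):
    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    ux = sum(i * px[i] for i in range(n))
    uy = sum(j * py[j] for j in range(n))
    vx = sum(i * i * px[i] for i in range(n)) - ux * ux
    vy = sum(j * j * py[j] for j in range(n)) - uy * uy

    p_sum = [0.0] * (2 * n - 1)
    p_diff = [0.0] * n
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    asm = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    contrast = sum(k * k * p_diff[k] for k in range(n))
    if vx <= 0 or vy <= 0:
        correlation = 0.0
    else:
        correlation = (
            sum(i * j * P[i][j] for i in range(n) for j in range(n)) - ux * uy
        ) / math.sqrt(vx * vy)
    variance = vx
    idm = sum(P[i][j] / (1.0 + (i - j) ** 2) for i in range(n) for j in range(n))
    sum_avg = sum(k * p_sum[k] for k in range(2 * n - 1))
    sum_var = sum(k * k * p_sum[k] for k in range(2 * n - 1)) - sum_avg ** 2
    sum_ent = -sum(p * _log2(p) for p in p_sum if p > 0)
    entropy = -sum(P[i][j] * _log2(P[i][j]) for i in range(n) for j in range(n) if P[i][j] > 0)
    mu_d = sum(k * p_diff[k] for k in range(n))
    diff_var = sum(k * k * p_diff[k] for k in range(n)) - mu_d ** 2
    diff_ent = -sum(p * _log2(p) for p in p_diff if p > 0)

    hx = -sum(p * _log2(p) for p in px if p > 0)
    hy = -sum(p * _log2(p) for p in py if p > 0)
    hxy1 = -sum(
        P[i][j] * _log2(px[i] * py[j])
        for i in range(n) for j in range(n)
        if P[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * _log2(px[i] * py[j])
        for i in range(n) for j in range(n)
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))
    return [asm, contrast, correlation, variance, idm, sum_avg, sum_var,
            sum_ent, entropy, diff_var, diff_ent, imc1, imc2]


def attention_bruteforce(weights, x_norm, abs_coeffs):
    """O(K * P) double loop over (word, patch) for the attention redistribution."""
    n_patches, K = abs_coeffs.shape
    scores = [0.0] * n_patches
    for k in range(K):
        usage = sum(abs_coeffs[p][k] for p in range(n_patches))
        if usage <= 0:
            continue
        c_k = weights[k] * x_norm[k]
        for p in range(n_patches):
            scores[p] += c_k * abs_coeffs[p][k] / usage
    return np.array(scores)


def auc_pair_counting(scores, labels):
    """AUC by exhaustive positive/negative pair comparison with midrank ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
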