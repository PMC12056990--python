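"""Independent brute-force oracles used only by the tests.

Each function here is written directly from the defining formulas with
plain Python loops, deliberately avoiding the vectorized code paths of
the package, so agreement between the two is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def haralick13_brute(P: np.ndarray) -> np.ndarray:
    """The 13 co-occurrence statistics, coded with explicit loops.

    Entropies in bits (0·log0 := 0); sum variance about the sum average;
    difference variance as the variance of the |i−j| marginal;
    degenerate denominators yield 0.
    """
    L = P.shape[0]

    def log2(x):
        return math.log2(x) if x > 0 else 0.0

    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum(i * px[i] for i in range(L))
    mu_y = sum(j * py[j] for j in range(L))
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(L)))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(L)))

    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    asm = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    contrast = sum(k * k * p_diff[k] for k in range(L))
    if sd_x > 0 and sd_y > 0:
        corr = (sum(i * j * P[i][j] for i in range(L) for j in range(L))
                - mu_x * mu_y) / (sd_x * sd_y)
    else:
        corr = 0.0
    sos = sum((i - mu_x) ** 2 * P[i][j] for i in range(L) for j in range(L))
    idm = sum(P[i][j] / (1.0 + (i - j) ** 2) for i in range(L) for j in range(L))
    sum_avg = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_ent = -sum(p_sum[k] * log2(p_sum[k]) for k in range(2 * L - 1))
    ent = -sum(P[i][j] * log2(P[i][j]) for i in range(L) for j in range(L))
    mu_d = sum(k * p_diff[k] for k in range(L))
    diff_var = sum((k - mu_d) ** 2 * p_diff[k] for k in range(L))
    diff_ent = -sum(p_diff[k] * log2(p_diff[k]) for k in range(L))

    hx = -sum(px[i] * log2(px[i]) for i in range(L))
    hy = -sum(py[j] * log2(py[j]) for j in range(L))
    hxy1 = -sum(P[i][j] * log2(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j])
                for i in range(L) for j in range(L))
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - ent))))

    return np.array([asm, contrast, corr, sos, idm, sum_avg, sum_var,
                     sum_ent, ent, diff_var, diff_ent, imc1, imc2])


def random_glcm(rng: np.random.Generator, levels: int = 8) -> np.ndarray:
    """A random symmetric normalized co-occurrence matrix."""
    M = rng.uniform(0, 1, (levels, levels))
    M = M + M.T
    return M / M.sum()


def es_brute(stats: dict[str, float], gene_set, weight: float = 1.0) -> float:
    """Enrichment score by explicit enumeration of the running sum."""
    ordered = sorted(stats, key=lambda g: (-stats[g], list(stats).index(g)))
    members = set(gene_set)
    n = len(ordered)
    n_hit = sum(1 for g in ordered if g in members)
    denom = sum(abs(stats[g]) ** weight for g in ordered if g in members)
    running, best = 0.0, 0.0
    for g in ordered:
        if g in members:
            if denom > 0:
                running += abs(stats[g]) ** weight / denom
            else:
                running += 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


# ---------------------------------------------------------------------------
# naive Relief-family implementations (plain loops)
# ---------------------------------------------------------------------------


def _prep(X: np.ndarray):
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng_f = [max(X[:, f].max() - X[:, f].min(), 0.0) or 1.0 for f in range(p)]
    sd = X.std(axis=0, ddof=1)
    sd = [s or 1.0 for s in sd]
    mean = X.mean(axis=0)
    Xz = (X - mean) / sd
    D = [[sum(abs(Xz[i, f] - Xz[j, f]) for f in range(p)) for j in range(n)]
         for i in range(n)]
    return X, D, rng_f, n, p


def _diff(X, rng_f, f, a, b):
    return abs(X[a, f] - X[b, f]) / rng_f[f]


def relieff_naive(X, y, k):
    X, D, rng_f, n, p = _prep(X)
    W = [0.0] * p
    for i in range(n):
        hits = sorted((j for j in range(n) if j != i and y[j] == y[i]),
                      key=lambda j: (D[i][j], j))[:k]
        misses = sorted((j for j in range(n) if y[j] != y[i]),
                        key=lambda j: (D[i][j], j))[:k]
        if not hits or not misses:
            continue
        for f in range(p):
            W[f] += (sum(_diff(X, rng_f, f, i, j) for j in misses) / len(misses)
                     - sum(_diff(X, rng_f, f, i, j) for j in hits) / len(hits))
    return np.array(W) / n


def surf_family_naive(X, y, variant):
    X, D, rng_f, n, p = _prep(X)
    T_global = sum(D[i][j] for i in range(n) for j in range(n) if i != j) / (n * (n - 1))
    W = [0.0] * p
    for i in range(n):
        if variant == "multisurf":
            d = [D[i][j] for j in range(n) if j != i]
            mu = sum(d) / len(d)
            sdv = math.sqrt(sum((x - mu) ** 2 for x in d) / len(d))
            T = mu - sdv / 2.0
        else:
            T = T_global
        near_h = [j for j in range(n) if j != i and D[i][j] < T and y[j] == y[i]]
        near_m = [j for j in range(n) if j != i and D[i][j] < T and y[j] != y[i]]
        for f in range(p):
            if near_m:
                W[f] += sum(_diff(X, rng_f, f, i, j) for j in near_m) / len(near_m)
            if near_h:
                W[f] -= sum(_diff(X, rng_f, f, i, j) for j in near_h) / len(near_h)
        if variant == "surfstar":
            far_h = [j for j in range(n) if j != i and D[i][j] >= T and y[j] == y[i]]
            far_m = [j for j in range(n) if j != i and D[i][j] >= T and y[j] != y[i]]
            for f in range(p):
                if far_h:
                    W[f] += sum(_diff(X, rng_f, f, i, j) for j in far_h) / len(far_h)
                if far_m:
                    W[f] -= sum(_diff(X, rng_f, f, i, j) for j in far_m) / len(far_m)
    return np.array(W) / n
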