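"""Independent brute-force oracles for the statistical primitives.

Each oracle is written from the defining formula with explicit loops and no
shared code with the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import t as t_dist


def average_ranks(v):
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = average_ranks(x), average_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    rho = num / den
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho ** 2))
    return rho, 2.0 * t_dist.sf(abs(t), n - 2)


def ks_oracle(a, b):
    a, b = sorted(a), sorted(b)
    gaps = []
    for v in a + b:
        fa = sum(1 for x in a if x <= v) / len(a)
        fb = sum(1 for x in b if x <= v) / len(b)
        gaps.append(abs(fa - fb))
    d = max(gaps)
    x = math.sqrt(len(a) * len(b) / (len(a) + len(b))) * d
    # classic Kolmogorov survival function by direct series summation
    p = 2.0 * sum((-1) ** (k - 1) * math.exp(-2.0 * k * k * x * x)
                  for k in range(1, 101))
    return d, min(max(p, 0.0), 1.0)


def cronbach_oracle(X):
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    item_vars = []
    for j in range(k):
        m = X[:, j].mean()
        item_vars.append(sum((v - m) ** 2 for v in X[:, j]) / (n - 1))
    total = X.sum(axis=1)
    mt = total.mean()
    var_total = sum((v - mt) ** 2 for v in total) / (n - 1)
    return k / (k - 1) * (1.0 - sum(item_vars) / var_total)


def cohen_d_oracle(values, group):
    x0 = [v for v, g in zip(values, group) if g == 0]
    x1 = [v for v, g in zip(values, group) if g == 1]
    m0, m1 = sum(x0) / len(x0), sum(x1) / len(x1)
    ss0 = sum((v - m0) ** 2 for v in x0)
    ss1 = sum((v - m1) ** 2 for v in x1)
    pooled = math.sqrt((ss0 + ss1) / (len(x0) + len(x1) - 2))
    return (m1 - m0) / pooled


def icc_a1_oracle(x, y):
    """ICC(A,1) from the explicit two-way ANOVA decomposition."""
    n = len(x)
    k = 2
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    grand = sum(sum(row) for row in data) / (n * k)
    row_means = [sum(row) / k for row in data]
    col_means = [sum(data[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def knn_impute_oracle(X, k=1, groups=None):
    """Exhaustive-distance nearest-neighbour imputation."""
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n, p = X.shape
    if groups is None:
        groups = [0] * p
    for i in range(n):
        for j in range(p):
            if np.isfinite(X[i, j]):
                continue
            cols = [c for c in range(p) if groups[c] == groups[j]]
            dist = []
            for i2 in range(n):
                if i2 == i or not np.isfinite(X[i2, j]):
                    continue
                shared = [c for c in cols
                          if np.isfinite(X[i, c]) and np.isfinite(X[i2, c])]
                if not shared:
                    continue
                d2 = sum((X[i, c] - X[i2, c]) ** 2 for c in shared)
                dist.append((d2, i2))
            dist.sort(key=lambda t: t[0])
            donors = [X[i2, j] for _, i2 in dist[:k]]
            out[i, j] = sum(donors) / len(donors)
    return out


def percentile_rank_oracle(sample, s):
    below = sum(1 for v in sample if v < s)
    equal = sum(1 for v in sample if v == s)
    return 100.0 * (below + 0.5 * equal) / len(sample)


def depression_status_oracle(ed, ei, dd, di, gp, ps):
    """Truth-table evaluation of the probable-depression rule."""
    occurrence = (ed == 1) or (ei == 1)
    duration = (dd >= 1) or (di >= 1)
    help_seeking = (gp == 1) or (ps == 1)
    return 1 if (occurrence and duration and help_seeking) else 0
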