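"""Independent brute-force oracles used to cross-check the statistics
implementations.  Deliberately naive: plain-Python sums, full enumeration,
direct textbook formulas — no shared code with the package."""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def pearson_bruteforce(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den


def friedman_bruteforce(table) -> float:
    """Rank formula 12/(n k (k+1)) * sum_j (R_j - n(k+1)/2)^2 with
    mid-ranks (valid for tables without within-row ties)."""
    table = np.asarray(table, dtype=float)
    n, k = table.shape
    ranks = np.array([rankdata(row) for row in table])
    col = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * np.sum((col - n * (k + 1) / 2.0) ** 2))


def mannwhitney_exact_p(x, y) -> float:
    """Two-sided exact p by enumerating every assignment of the pooled
    ranks (untied samples only)."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = rankdata(pooled)
    mu = len(x) * len(y) / 2.0

    def u_of(idx):
        return float(ranks[list(idx)].sum() - n * (n + 1) / 2.0)

    obs = abs(u_of(range(n)) - mu)
    us = [abs(u_of(c) - mu) for c in combinations(range(len(pooled)), n)]
    return float(np.mean([u >= obs - 1e-12 for u in us]))


def holm_sidak_bruteforce(pvals) -> np.ndarray:
    """Step-down Sidak: sort ascending, adj_(i) = max_{j<=i}
    1-(1-p_(j))^(m-j+1), clip to 1, unsort."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = 1.0 - (1.0 - p[idx]) ** (m - i)
        running = max(running, val)
        adj_sorted[i] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out
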