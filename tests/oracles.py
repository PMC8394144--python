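"""Independent brute-force oracles shared by the test modules.

These deliberately re-derive expected values from first principles
(enumeration, closed forms) and never call the implementation under test.
"""

import itertools

from scipy.stats import hypergeom


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p: sum hypergeometric probabilities <= observed's."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def mwu_p_enumeration(x, y):
    """Exact two-sided Mann-Whitney p over all rank assignments (no ties)."""
    nx, ny = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rx = sum(ranks[v] for v in x)
    u_obs = rx - nx * (nx + 1) / 2
    mean_u = nx * ny / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, nx + ny + 1), nx):
        total += 1
        u = sum(combo) - nx * (nx + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


def affine_sw_score(a, b, matrix, gap_open=11, gap_extend=1):
    """Optimal local-alignment score with affine gaps (independent DP)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]))
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def brute_force_partitions(n):
    """All set partitions of range(n) (for tiny clustering oracles)."""
    if n == 0:
        yield []
        return
    for part in brute_force_partitions(n - 1):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {n - 1}] + part[i + 1 :]
        yield part + [{n - 1}]
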