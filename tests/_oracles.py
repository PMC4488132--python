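"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths (and the library
routines they delegate to): the FDR references apply the step-up definition
literally, the hypergeometric tail is summed from a Pascal-triangle
binomial table, and the local aligner is a direct Gotoh dynamic program.
"""

import numpy as np


def stepup_reference(pvalues, method="bh"):
    """Literal step-up FDR: adj_(k) = min_{l >= k} p_(l) * n * c / l, clipped."""
    p = list(pvalues)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    c = sum(1.0 / i for i in range(1, n + 1)) if method == "by" else 1.0
    adj_sorted = []
    for k in range(n):
        candidates = [p[order[l]] * n * c / (l + 1) for l in range(k, n)]
        adj_sorted.append(min(1.0, min(candidates)))
    out = [0.0] * n
    for k, i in enumerate(order):
        out[i] = adj_sorted[k]
    return out


def comb_table(n_max):
    """Pascal-triangle binomial coefficients as floats."""
    C = np.zeros((n_max + 1, n_max + 1))
    C[:, 0] = 1.0
    for i in range(1, n_max + 1):
        for j in range(1, i + 1):
            C[i, j] = C[i - 1, j - 1] + C[i - 1, j]
    return C


def hypergeom_tail(a, N, K, n, C=None):
    """P(X >= a) for X ~ Hypergeom(N, K, n) by direct summation."""
    C = comb_table(N) if C is None else C
    lo = max(0, n + K - N)
    hi = min(n, K)
    total = C[N, n]
    return sum(C[K, k] * C[N - K, n - k] for k in range(max(a, lo), hi + 1)) / total


def hypergeom_mean_sd(N, K, n):
    """Mean and SD of the annotated *fraction* in a draw of n from N (K annotated)."""
    p = K / N
    mean = p
    var = n * p * (1 - p) * (N - n) / (N - 1)
    return mean, np.sqrt(var) / n


def gotoh_local(a, b, sub, gap_open=11.0, gap_extend=1.0):
    """Brute-force affine-gap local alignment score.

    A gap of length L costs ``gap_open + L * gap_extend``; ``sub`` is a
    callable (char, char) -> score.
    """
    n, m = len(a), len(b)
    NEG = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub(a[i - 1], b[j - 1]), E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def groupwise_mean_var(values, groups):
    """Per-group means plus pooled residual variance, computed the long way."""
    means = {}
    rss = 0.0
    n_obs = 0
    for g in sorted(set(groups)):
        xs = [v for v, gg in zip(values, groups) if gg == g and np.isfinite(v)]
        means[g] = sum(xs) / len(xs)
        rss += sum((x - means[g]) ** 2 for x in xs)
        n_obs += len(xs)
    df = n_obs - len(means)
    return means, (rss / df if df > 0 else float("nan")), df
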