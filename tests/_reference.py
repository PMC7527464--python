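"""Independent reference implementations used only by the tests.

These are literal, slow translations of the defining formulas (plain
Python loops, 1-based indices), kept deliberately separate from the
package's optimized code paths so they can serve as oracles.
"""

from __future__ import annotations

import numpy as np


def brute_force_score(x, m: int, tau: int, k: int, h: int, W: int) -> float:
    """Rank-based predictability score by exhaustive loops.

    1-based translation: embedded indices i = eta+1..N, reference states
    i0 = eta+1..N-h, neighbor candidates j = eta+1..N-h with |i0-j| > W,
    rank lists at i0+h over j = eta+1..N with |i0+h-j| > W, mid-ranks for
    ties, neighbor ties broken toward smaller j.
    """
    x = [float(v) for v in x]
    N = len(x)
    eta = (m - 1) * tau
    if N - eta - h < 1:
        raise ValueError("too short")

    def vec(i):  # 1-based embedded vector
        return [x[i - 1 - d * tau] for d in range(m)]

    def d2(i, j):
        vi, vj = vec(i), vec(j)
        s = 0.0
        for a, b in zip(vi, vj):
            t = a - b
            s += t * t
        return s

    terms = []
    for i0 in range(eta + 1, N - h + 1):
        cands = [j for j in range(eta + 1, N - h + 1) if abs(i0 - j) > W]
        if len(cands) < k:
            raise ValueError("fewer than k candidates")
        neighbors = sorted(cands, key=lambda j: (d2(i0, j), j))[:k]

        b = i0 + h
        rank_js = [j for j in range(eta + 1, N + 1) if abs(b - j) > W]
        M = len(rank_js)
        u = {j: abs(x[b - 1] - x[j - 1]) for j in rank_js}

        g_sum = 0.0
        for jr in neighbors:
            t = abs(x[b - 1] - x[jr + h - 1])
            c_less = sum(1 for j in rank_js if u[j] < t)
            c_eq = sum(1 for j in rank_js if u[j] == t)
            g_sum += c_less + (c_eq + 1) / 2.0
        R = g_sum / k
        RU = (M + 1) / 2.0
        RL = (k + 1) / 2.0
        terms.append((RU - R) / (RU - RL))
    return sum(terms) / len(terms)


def balanced_anova_2way(y: np.ndarray) -> dict:
    """Closed-form two-way ANOVA with interaction for a balanced design.

    ``y`` has shape (levels_a, levels_b, n_per_cell).  Returns F
    statistics and p-values for factor A, factor B and the interaction.
    """
    from scipy.stats import f as fdist

    a, b, n = y.shape
    grand = y.mean()
    mean_a = y.mean(axis=(1, 2))
    mean_b = y.mean(axis=(0, 2))
    mean_ab = y.mean(axis=2)

    ss_a = b * n * ((mean_a - grand) ** 2).sum()
    ss_b = a * n * ((mean_b - grand) ** 2).sum()
    ss_ab = n * ((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2).sum()
    ss_err = ((y - mean_ab[:, :, None]) ** 2).sum()

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_err = a * b * (n - 1)
    ms_err = ss_err / df_err

    out = {}
    for name, ss, df in (("a", ss_a, df_a), ("b", ss_b, df_b), ("ab", ss_ab, df_ab)):
        F = (ss / df) / ms_err
        out[f"F_{name}"] = F
        out[f"p_{name}"] = float(fdist.sf(F, df, df_err))
    return out


def mannwhitney_exact_enumeration(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all assignments of
    the pooled values to the two groups (tie-free data only)."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group1, rest):
        u = 0
        for x in group1:
            for y in rest:
                u += 1 if x > y else 0
        return u

    u_obs = u_stat(a, b)
    mu = n1 * len(b) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(g1, g2)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return float(u_obs), count / total
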