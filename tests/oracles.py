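"""Independent brute-force oracles used only by the tests.

Each function re-derives a statistic from its definition by the most direct
(usually O(n^2)) route, sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def agb_direct(d_cm: float, rho: float, e: float) -> float:
    """Direct scalar evaluation of the height-free allometry, written out
    term by term with math (not numpy) primitives."""
    ln_d = math.log(d_cm)
    exponent = (
        -1.803
        - 0.976 * e
        + 0.976 * math.log(rho)
        + 2.673 * ln_d
        - 0.0339 * ln_d * ln_d
    )
    return math.exp(exponent)


def pettitt_brute(x) -> tuple[int, int]:
    """K and tau from the literal double sum over all split points."""
    x = list(map(float, x))
    t_len = len(x)
    best_k, best_tau = -1, -1
    for t in range(1, t_len):
        u = 0
        for i in range(t):
            for j in range(t, t_len):
                if x[i] > x[j]:
                    u += 1
                elif x[i] < x[j]:
                    u -= 1
        if abs(u) > best_k:
            best_k, best_tau = abs(u), t
    return best_k, best_tau


def midranks_brute(values) -> list[float]:
    """Midranks computed by explicit counting, no sorting library calls."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def dunn_z_brute(group_a, group_b, all_groups) -> float:
    """Dunn z-statistic for one pair from the rank formula, brute force."""
    pooled = [v for g in all_groups for v in g]
    ranks = midranks_brute(pooled)
    n_total = len(pooled)
    pos = 0
    mean_rank = []
    sizes = []
    for g in all_groups:
        k = len(g)
        mean_rank.append(sum(ranks[pos : pos + k]) / k)
        sizes.append(k)
        pos += k
    # tie term from explicit value counts
    tie = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie += t**3 - t
    var = n_total * (n_total + 1) / 12.0 - tie / (12.0 * (n_total - 1))
    ia = all_groups.index(group_a)
    ib = all_groups.index(group_b)
    se = math.sqrt(var * (1.0 / sizes[ia] + 1.0 / sizes[ib]))
    return (mean_rank[ia] - mean_rank[ib]) / se


def quartile_shares_brute(annual) -> list[float]:
    """Quartile shares from explicit per-year quarter assignment."""
    annual = list(map(float, annual))
    t_len = len(annual)
    sums = [0.0, 0.0, 0.0, 0.0]
    for idx, value in enumerate(annual):
        year = idx + 1
        if year <= math.ceil(t_len / 4):
            q = 0
        elif year <= math.ceil(t_len / 2):
            q = 1
        elif year <= math.ceil(3 * t_len / 4):
            q = 2
        else:
            q = 3
        sums[q] += value
    total = sum(annual)
    return [100.0 * s / total for s in sums]
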