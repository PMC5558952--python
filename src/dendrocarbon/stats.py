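"""Nonparametric trend and change-point inference, and the growth-pattern
classifier built on it.

Implemented from first principles (scipy contributes only distribution
functions and midranks):

- Cox–Stuart sign test for monotone trend, with the exact binomial p-value;
- Pettitt change-point test with the standard closed-form significance
  approximation ``p = 2 exp(-6 K^2 / (T^3 + T^2))``;
- Dunn's rank-sum test for multiple pairwise comparisons with midrank tie
  correction, optional Holm adjustment;
- Pearson product-moment correlation with the t-approximation p-value;
- one-way ANOVA plus pairwise t-tests using the pooled within-group SD and
  Holm step-down adjustment;
- a deterministic four-way classifier of lifetime growth patterns
  (sustained increase / increase with depression / plateau / rise then
  decline) driven by the trend test on the smoothed annual-carbon series.

Cox–Stuart and Pettitt are rank/sign based and therefore invariant under
strictly monotone transformations of the data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TrendResult",
    "ChangePointResult",
    "PairwiseComparison",
    "PatternLabel",
    "ClassifierConfig",
    "ARCHETYPES",
    "cox_stuart",
    "pettitt",
    "dunn_test",
    "holm_adjust",
    "pearson_correlation",
    "compare_species",
    "classify_pattern",
]

ARCHETYPES = (
    "sustained_increase",
    "increase_with_depression",
    "plateau",
    "rise_then_decline",
)

Alternative = Literal["two_sided", "increasing", "decreasing"]


@dataclass(frozen=True)
class TrendResult:
    n_pairs_used: int
    s_plus: int
    p_value: float
    direction: str  # increasing / decreasing / none
    alternative: str = "two_sided"
    degenerate: bool = False


@dataclass(frozen=True)
class ChangePointResult:
    u: np.ndarray      # signed statistic per split point t = 1..T-1
    k: int             # max |U_t|
    tau: int           # 1-based argmax split index
    p_approx: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    method: str


@dataclass(frozen=True)
class PatternLabel:
    tree_id: str
    label: str
    trend_p: float
    second_half_decline_p: float
    depression: tuple | None  # (start_idx, length, min_rel_level) or None


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the pattern classifier.

    alpha: significance level of the trend tests; window: odd moving-average
    window (years) applied before testing; depression_factor: a smoothed
    value below ``factor x running maximum`` counts as depressed;
    depression_min_years: minimal depressed run length to call a depression.
    """

    alpha: float = 0.05
    window: int = 11
    depression_factor: float = 0.8
    depression_min_years: int = 15


def cox_stuart(series, alternative: Alternative = "two_sided") -> TrendResult:
    """Cox–Stuart sign test for monotone trend, exact binomial p-value.

    The series is split in half (odd length: the middle element is dropped)
    and each x_i is paired with x_{i+c}, c = floor(n/2). Tied pairs are
    discarded; under H0 the number of positive differences is
    Binomial(m, 1/2).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("cox_stuart needs at least 4 observations")
    c = n // 2
    first = x[:c]
    second = x[n - c :]
    diff = second - first
    # pair differences at floating-point noise level are ties, not signal
    tol = 1e-9 * float(np.max(np.abs(x))) if x.size else 0.0
    signs = diff[np.abs(diff) > tol]
    m = signs.size
    s_plus = int((signs > 0).sum())
    if m == 0:
        return TrendResult(0, 0, 1.0, "none", alternative, degenerate=True)
    if alternative == "increasing":
        p = float(sps.binom.sf(s_plus - 1, m, 0.5))
    elif alternative == "decreasing":
        p = float(sps.binom.cdf(s_plus, m, 0.5))
    elif alternative == "two_sided":
        tail = max(s_plus, m - s_plus)
        p = min(1.0, 2.0 * float(sps.binom.sf(tail - 1, m, 0.5)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    if s_plus * 2 > m:
        direction = "increasing"
    elif s_plus * 2 < m:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendResult(m, s_plus, p, direction, alternative)


def pettitt(series) -> ChangePointResult:
    """Pettitt's change-point test for a shift in central tendency.

    U_t = sum_{i<=t} sum_{j>t} sgn(x_i - x_j) for t = 1..T-1;
    K = max |U_t|, tau = argmax, with the closed-form approximation
    p = 2 exp(-6 K^2 / (T^3 + T^2)) capped at 1. Ties contribute 0 via sgn.
    """
    x = np.asarray(series, dtype=float)
    t_len = x.size
    if t_len < 8:
        raise ValueError("pettitt needs at least 8 observations")
    # recursion: U_t = U_{t-1} + sum_j sgn(x_t - x_j)
    v = np.sign(x[:, None] - x[None, :]).sum(axis=1)
    u = np.cumsum(v)[:-1]
    k = int(np.max(np.abs(u)))
    tau = int(np.argmax(np.abs(u))) + 1
    p = min(1.0, 2.0 * math.exp(-6.0 * k * k / (t_len**3 + t_len**2)))
    return ChangePointResult(u=u, k=k, tau=tau, p_approx=p)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment; monotone, never below the raw p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def dunn_test(
    groups: dict[str, Sequence[float]],
    adjustment: Literal["none", "holm"] = "none",
) -> list[PairwiseComparison]:
    """Dunn's test: pairwise z-statistics on joint midranks with tie
    correction.

    z_ab = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - sum(t^3 - t)/(12(N-1)))
                                    (1/n_a + 1/n_b)]
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("dunn_test needs at least 2 groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, a in arrays.items():
        if a.size == 0:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate([arrays[g] for g in names])
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        raise ValueError("degenerate ranking: all values identical")
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    pos = 0
    for g in names:
        size = arrays[g].size
        mean_rank[g] = float(ranks[pos : pos + size].mean())
        pos += size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    comparisons = []
    raw = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(base_var * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se
        raw.append(2.0 * float(sps.norm.sf(abs(z))))
        comparisons.append((a, b, z))
    if adjustment == "holm":
        adjusted = holm_adjust(raw)
    elif adjustment == "none":
        adjusted = np.asarray(raw)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return [
        PairwiseComparison(a, b, z, p, float(pa), adjustment)
        for (a, b, z), p, pa in zip(comparisons, raw, adjusted)
    ]


def pearson_correlation(x, y) -> tuple[float, float, float]:
    """Pearson r, r^2 and the two-sided p-value from the t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("pearson_correlation needs aligned samples of n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc**2)))
    sy = float(np.sqrt(np.sum(yc**2)))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the samples")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return r, r * r, p


@dataclass(frozen=True)
class SpeciesComparison:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def compare_species(groups: dict[str, Sequence[float]]) -> SpeciesComparison:
    """One-way ANOVA plus Holm-adjusted pairwise t-tests with pooled SD.

    The pairwise t statistics use the pooled within-group standard deviation
    from all groups (df = N - k), as in classical post-hoc pairwise t-tests.
    Groups with fewer than 2 values are excluded with a note.
    """
    usable = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    excluded = [g for g, v in usable.items() if v.size < 2]
    usable = {g: v for g, v in usable.items() if v.size >= 2}
    k = len(usable)
    if k < 2:
        raise ValueError("compare_species needs >= 2 groups with >= 2 values")
    names = list(usable)
    n_total = sum(v.size for v in usable.values())
    grand = np.concatenate(list(usable.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in usable.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in usable.values())
    df_b, df_w = k - 1, n_total - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        f_stat, p_f = 0.0, 1.0
    else:
        f_stat = (ss_between / df_b) / ms_within
        p_f = float(sps.f.sf(f_stat, df_b, df_w))
    pooled_sd = math.sqrt(ms_within) if ms_within > 0 else 0.0
    raw, pairs = [], []
    for a, b in itertools.combinations(names, 2):
        va, vb = usable[a], usable[b]
        if pooled_sd == 0:
            t_stat, p = 0.0, 1.0
        else:
            se = pooled_sd * math.sqrt(1.0 / va.size + 1.0 / vb.size)
            t_stat = (va.mean() - vb.mean()) / se
            p = 2.0 * float(sps.t.sf(abs(t_stat), df_w))
        raw.append(p)
        pairs.append((a, b, t_stat))
    adjusted = holm_adjust(raw)
    pairwise = [
        PairwiseComparison(a, b, t, p, float(pa), "holm")
        for (a, b, t), p, pa in zip(pairs, raw, adjusted)
    ]
    return SpeciesComparison(f_stat, p_f, df_b, df_w, pairwise, excluded)


# ---------------------------------------------------------------------------
# Growth-pattern classification
# ---------------------------------------------------------------------------

def _find_depression(
    m: np.ndarray, factor: float, min_years: int
) -> tuple | None:
    """First qualifying depression in a smoothed series.

    A depression is a run of at least ``min_years`` consecutive years where
    m(t) < factor * running max of m, followed by a later recovery above the
    running max held at the start of the run.
    """
    runmax = np.maximum.accumulate(m)
    depressed = m < factor * runmax
    t = m.size
    i = 0
    while i < t:
        if not depressed[i]:
            i += 1
            continue
        j = i
        while j < t and depressed[j]:
            j += 1
        if j - i >= min_years:
            ceiling = runmax[i]
            if np.any(m[j:] > ceiling):
                rel = float(np.min(m[i:j]) / ceiling) if ceiling > 0 else 0.0
                return (i, j - i, rel)
        i = j
    return None


def classify_pattern(
    annual_c,
    config: ClassifierConfig = ClassifierConfig(),
    tree_id: str = "",
) -> PatternLabel:
    """Assign one of the four lifetime growth archetypes.

    Deterministic rule on the moving-average-smoothed annual-carbon series
    m(t), checked in order:

    1. rise_then_decline — Cox–Stuart on the second half of m is
       significantly decreasing;
    2. increase_with_depression — Cox–Stuart on all of m is significantly
       increasing and m shows a qualifying depression (see
       :func:`_find_depression`);
    3. sustained_increase — the full-series trend is significantly
       increasing with no qualifying depression;
    4. plateau — otherwise.

    Because the trend tests are sign-based and the depression rule is
    relative to the running maximum, the label is invariant to positive
    rescaling of the series.
    """
    x = np.asarray(annual_c, dtype=float)
    if x.size < 40:
        raise ValueError("classification needs a series of at least 40 years")
    from .series import moving_average  # local import to avoid cycle at init

    m = moving_average(x, config.window)
    second_half = m[m.size // 2 :]
    decline = cox_stuart(second_half, alternative="decreasing")
    rising = cox_stuart(m, alternative="increasing")
    depression = _find_depression(
        m, config.depression_factor, config.depression_min_years
    )
    if decline.p_value <= config.alpha:
        label = "rise_then_decline"
    elif rising.p_value <= config.alpha and depression is not None:
        label = "increase_with_depression"
    elif rising.p_value <= config.alpha:
        label = "sustained_increase"
    else:
        label = "plateau"
    return PatternLabel(
        tree_id=tree_id,
        label=label,
        trend_p=rising.p_value,
        second_half_decline_p=decline.p_value,
        depression=depression,
    )
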