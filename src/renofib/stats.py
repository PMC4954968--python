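"""Descriptive and inferential statistics used by the cohort analysis.

Everything here is computed from the defining formulas; scipy supplies only
the reference distributions (t, F, normal) and rank assignment. All p-values
are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    n: int
    p_two_sided: float


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    n_subjects: int


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"zero variance in {name}")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, r_squared=r * r, n=n, p_two_sided=p)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Compare two correlation coefficients from independent samples.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 (atanh diverges)")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * sps.norm.sf(abs(z))
    return z, p


class DegenerateSplitError(ValueError):
    """A two-group comparison where one group is empty."""


def _ranksum_exact(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Exact permutation two-sided p for the rank-sum of group a.

    Enumerates every assignment of the observed (possibly tied, midrank)
    ranks to group a; p is the fraction of assignments whose rank-sum
    deviates from its permutation mean by at least the observed deviation.
    """
    n = len(ranks)
    w_obs = float(ranks[:n_a].sum())
    mu = n_a * (ranks.sum() / n)
    d_obs = abs(w_obs - mu)
    total = math.comb(n, n_a)
    count = 0
    for idx in combinations(range(n), n_a):
        w = float(ranks[list(idx)].sum())
        if abs(w - mu) >= d_obs - 1e-9:
            count += 1
    return w_obs, count / total


def _ranksum_normal(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Tie-corrected normal approximation with continuity correction."""
    n = len(ranks)
    n_b = n - n_a
    w = float(ranks[:n_a].sum())
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    d = abs(w - mu)
    z = max(0.0, d - 0.5) / math.sqrt(var)
    return w, 2.0 * sps.norm.sf(z)


def rank_sum_test(a, b, mode: str = "auto") -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney rank-sum test.

    Returns (rank-sum of ``a``, two-sided p). ``mode="exact"`` enumerates the
    full permutation distribution of the observed midranks (ties handled by
    enumeration); ``"normal_approx"`` uses the tie-corrected normal
    approximation with continuity correction; ``"auto"`` picks exact when
    n_a + n_b <= 12.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateSplitError("degenerate split: one group is empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    if mode == "auto":
        mode = "exact" if n <= 12 else "normal_approx"
    if mode == "exact":
        return _ranksum_exact(ranks, len(a))
    return _ranksum_normal(ranks, len(a))


def icc_oneway_single(readings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(1,1): one-way random-effects, single-measure agreement.

    ``readings`` is (n_subjects, k) with k >= 2 readings per subject.
    ICC = (MSB - MSW) / (MSB + (k-1) MSW) from the one-way ANOVA
    decomposition, with the F-based confidence interval.
    """
    x = np.asarray(readings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("readings must be (n_subjects, k>=2)")
    n, k = x.shape
    if n < 5:
        raise ValueError("need >= 5 subjects")
    grand = x.mean()
    subject_means = x.mean(axis=1)
    ssb = k * float(np.sum((subject_means - grand) ** 2))
    ssw = float(np.sum((x - subject_means[:, None]) ** 2))
    if ssb == 0 and ssw == 0:
        raise ValueError("zero between- and within-subject variance")
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0:
        return ICCResult(icc=1.0, ci95=(1.0, 1.0), n_subjects=n)
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_low = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_up = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci = (
        (f_low - 1) / (f_low + k - 1),
        (f_up - 1) / (f_up + k - 1),
    )
    return ICCResult(icc=float(icc), ci95=(float(ci[0]), float(ci[1])), n_subjects=n)


def anova_bonferroni(groups) -> tuple[float, float, list[dict]]:
    """One-way ANOVA with Bonferroni-adjusted pairwise comparisons.

    Pairwise tests use the pooled within-group mean square as the error term
    (the convention of standard post-hoc Bonferroni output); each pairwise p
    is multiplied by the number of comparisons and capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    if ssw == 0:
        if ssb == 0:
            raise ValueError("all observations identical: zero pooled variance")
        return math.inf, 0.0, _bonferroni_pairs(groups, ssw, df_w)
    msb = ssb / df_b
    msw = ssw / df_w
    f = msb / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p, _bonferroni_pairs(groups, ssw, df_w)


def _bonferroni_pairs(groups, ssw, df_w) -> list[dict]:
    m = math.comb(len(groups), 2)
    msw = ssw / df_w if df_w > 0 else 0.0
    out = []
    for i, j in combinations(range(len(groups)), 2):
        gi, gj = groups[i], groups[j]
        se = math.sqrt(msw * (1 / len(gi) + 1 / len(gj))) if msw > 0 else 0.0
        diff = gi.mean() - gj.mean()
        if se == 0:
            p_raw = 0.0 if diff != 0 else 1.0
            t = math.inf if diff != 0 else 0.0
        else:
            t = diff / se
            p_raw = 2.0 * sps.t.sf(abs(t), df=df_w)
        out.append(
            {
                "pair": (i, j),
                "mean_diff": float(diff),
                "t": float(t) if np.isfinite(t) else math.inf,
                "p_adjusted": min(1.0, p_raw * m),
            }
        )
    return out
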