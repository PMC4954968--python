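"""Fibrosis-threshold discovery and ΔADC discriminant classification.

The cohort analysis proceeds in three steps:

1. **Threshold sweep** — interstitial-fibrosis percentages are binarised at
   each candidate cut-off (default 10%..70% step 10); the cut-off whose
   High-IF vs Low-IF split gives the most significant rank-sum difference in
   ΔADC is selected.
2. **1-D linear discriminant analysis** — a Gaussian LDA with pooled
   within-class variance classifies each ΔADC as High-IF (pathologic) or
   Low-IF (normal); sensitivity/specificity are resubstitution estimates.
3. **Bootstrap** — the resubstitution accuracy is bootstrapped (default 1000
   replicates, subjects resampled with replacement) to a mean and percentile
   95% CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .stats import DegenerateSplitError, rank_sum_test

logger = logging.getLogger("renofib")

DEFAULT_GRID = tuple(range(10, 71, 10))


@dataclass
class ThresholdSweepResult:
    grid: np.ndarray
    p_values: np.ndarray  # NaN where the split was degenerate
    degenerate: np.ndarray  # bool per threshold
    group_sizes: list[tuple[int, int]]  # (n_high, n_low) per threshold
    selected_threshold: float
    uninformative: bool  # all admissible p-values == 1


@dataclass
class DiscriminantResult:
    boundary: float  # ΔADC decision value; High-IF predicted below it
    class_means: dict
    pooled_variance: float
    priors: dict
    sensitivity: float  # % recall on the High-IF class
    specificity: float  # % recall on the Low-IF class
    confusion: dict  # tp/fn/tn/fp with High-IF as positive
    accuracy: float  # fraction correct, resubstitution

    def predict(self, x) -> np.ndarray:
        """True where a ΔADC value is classified High-IF."""
        x = np.asarray(x, dtype=float)
        if self._high_is_low_side:
            return x < self.boundary
        return x > self.boundary

    _high_is_low_side: bool = field(default=True, repr=False)


@dataclass
class AccuracyEstimate:
    accuracy_mean: float
    ci95: tuple[float, float]
    n_bootstrap: int
    seed: int
    n_redrawn: int = 0


def threshold_sweep(if_percent, delta_adc, grid=DEFAULT_GRID) -> ThresholdSweepResult:
    """Select the IF cut-off with the most significant ΔADC rank-sum split.

    Subjects with IF strictly above a threshold form the High-IF group.
    Thresholds producing an empty group are flagged degenerate and excluded
    from the argmin; if every admissible p equals 1 the result carries an
    ``uninformative`` flag.
    """
    if_percent = np.asarray(if_percent, dtype=float)
    delta_adc = np.asarray(delta_adc, dtype=float)
    if if_percent.shape != delta_adc.shape:
        raise ValueError("if_percent and delta_adc must be aligned")
    if len(if_percent) < 6:
        raise ValueError("need at least 6 subjects")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")

    p_values = np.full(grid.shape, np.nan)
    degenerate = np.zeros(grid.shape, dtype=bool)
    sizes: list[tuple[int, int]] = []
    for i, t in enumerate(grid):
        high = if_percent > t
        sizes.append((int(high.sum()), int((~high).sum())))
        try:
            _, p = rank_sum_test(delta_adc[high], delta_adc[~high], mode="auto")
        except DegenerateSplitError:
            degenerate[i] = True
            continue
        p_values[i] = p

    admissible = ~degenerate
    if not admissible.any():
        raise ValueError("no admissible threshold: all splits degenerate")
    masked_p = np.where(admissible, p_values, np.inf)
    p_min = np.min(masked_p)
    tied = np.flatnonzero(masked_p <= p_min * (1 + 1e-12))
    if len(tied) == 1:
        idx = int(tied[0])
    else:
        # several grid thresholds fall inside the same gap of the IF
        # distribution and induce the identical split; pick the tied
        # threshold closest to the centre of its own gap
        def gap_distance(i):
            t = grid[i]
            high = if_percent > t
            gap_mid = (if_percent[~high].max() + if_percent[high].min()) / 2.0
            return abs(t - gap_mid)

        idx = int(min(tied, key=gap_distance))
    uninformative = bool(np.all(p_values[admissible] >= 1.0 - 1e-12))
    return ThresholdSweepResult(
        grid=grid,
        p_values=p_values,
        degenerate=degenerate,
        group_sizes=sizes,
        selected_threshold=float(grid[idx]),
        uninformative=uninformative,
    )


def lda_fit_evaluate(delta_adc, high_if, priors: str = "frequency") -> DiscriminantResult:
    """1-D Gaussian LDA of ΔADC against a binary High-IF label.

    Pooled within-class variance, class priors from frequencies (or equal
    with ``priors="equal"``); the decision boundary solves the equality of
    the two linear discriminant scores in closed form:

        x* = (µ_H + µ_L)/2 + σ² ln(π_L/π_H) / (µ_H − µ_L)

    Sensitivity is the recall on the High-IF class, specificity the recall
    on the Low-IF class, both evaluated on the fitting sample
    (resubstitution).
    """
    x = np.asarray(delta_adc, dtype=float)
    y = np.asarray(high_if, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("delta_adc and labels must be aligned")
    n_h, n_l = int(y.sum()), int((~y).sum())
    if n_h < 2 or n_l < 2:
        raise ValueError("each class needs n >= 2")
    if priors not in ("frequency", "equal"):
        raise ValueError(f"unknown priors {priors!r}")

    mu_h = float(x[y].mean())
    mu_l = float(x[~y].mean())
    ss = float(np.sum((x[y] - mu_h) ** 2) + np.sum((x[~y] - mu_l) ** 2))
    var = ss / (n_h + n_l - 2)
    if var == 0:
        raise ValueError("zero pooled within-class variance")
    if priors == "frequency":
        pi_h, pi_l = n_h / len(x), n_l / len(x)
    else:
        pi_h = pi_l = 0.5

    if mu_h == mu_l:
        # no-information case: every point gets the larger prior's class
        majority_high = pi_h >= pi_l
        high_side_low = True
        boundary = math.inf if majority_high else -math.inf
        pred = np.full(len(x), majority_high)
    else:
        boundary = (mu_h + mu_l) / 2.0 + var * math.log(pi_l / pi_h) / (mu_h - mu_l)
        high_side_low = mu_h < mu_l  # fibrotic kidneys sit at lower ΔADC
        pred = x < boundary if high_side_low else x > boundary

    tp = int(np.sum(pred & y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    return DiscriminantResult(
        boundary=float(boundary),
        class_means={"high_if": mu_h, "low_if": mu_l},
        pooled_variance=float(var),
        priors={"high_if": pi_h, "low_if": pi_l},
        sensitivity=100.0 * tp / n_h,
        specificity=100.0 * tn / n_l,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        accuracy=(tp + tn) / len(x),
        _high_is_low_side=bool(high_side_low),
    )


def bootstrap_accuracy(
    delta_adc,
    high_if,
    n_boot: int = 1000,
    seed: int = 0,
    priors: str = "frequency",
) -> AccuracyEstimate:
    """Bootstrap the LDA resubstitution accuracy.

    Subjects are resampled with replacement; each replicate refits the LDA
    and records its resubstitution accuracy. Replicates missing a class (or
    with zero pooled variance) are redrawn, keeping the number of replicates
    fixed; more than 50% redraws aborts with an error. The 95% CI is the
    2.5/97.5 percentile interval.
    """
    x = np.asarray(delta_adc, dtype=float)
    y = np.asarray(high_if, dtype=bool)
    lda_fit_evaluate(x, y, priors=priors)  # validate the full-sample fit
    rng = np.random.default_rng(seed)
    n = len(x)
    acc = np.empty(n_boot)
    redrawn = 0
    max_redraws = math.ceil(n_boot / 2)
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.sum() < 2 or (~yb).sum() < 2:
            redrawn += 1
            if redrawn > max_redraws:
                raise ValueError(
                    "class imbalance too severe: >50% of bootstrap replicates redrawn"
                )
            continue
        try:
            res = lda_fit_evaluate(x[idx], yb, priors=priors)
        except ValueError:
            redrawn += 1
            if redrawn > max_redraws:
                raise ValueError(
                    "class imbalance too severe: >50% of bootstrap replicates redrawn"
                ) from None
            continue
        acc[i] = res.accuracy
        i += 1
    if redrawn:
        logger.info("bootstrap: %d degenerate replicates redrawn", redrawn)
    lo, hi = np.percentile(acc, [2.5, 97.5])
    return AccuracyEstimate(
        accuracy_mean=float(acc.mean()),
        ci95=(float(lo), float(hi)),
        n_bootstrap=n_boot,
        seed=seed,
        n_redrawn=redrawn,
    )


def bootstrap_accuracy_vector(delta_adc, high_if, n_boot, seed, priors="frequency"):
    """The raw bootstrap accuracy vector (same seed stream as
    :func:`bootstrap_accuracy`); exposed for reproducibility checks."""
    x = np.asarray(delta_adc, dtype=float)
    y = np.asarray(high_if, dtype=bool)
    rng = np.random.default_rng(seed)
    n = len(x)
    out = []
    while len(out) < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.sum() < 2 or (~yb).sum() < 2:
            continue
        try:
            out.append(lda_fit_evaluate(x[idx], yb, priors=priors).accuracy)
        except ValueError:
            continue
    return np.asarray(out)
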