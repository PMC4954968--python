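"""Pixel-wise ADC and T1 parametric-map fitting.

Diffusion-weighted series are fitted with the mono-exponential decay model

    S(b) = S0 * exp(-b * ADC)

with b in s/mm^2 and ADC stored in units of 1e-6 mm^2/s (so the exponent uses
``ADC * 1e-6``), matching the convention used throughout renal DWI literature.

Inversion-recovery (MOLLI-style) series are fitted with the 3-parameter
magnitude model

    |S(TI)| = |A - B * exp(-TI / T1*)|

with magnitude-polarity restoration (exhaustive search over the sign-flip
point of the TI-sorted samples) followed by the Look-Locker correction
``T1 = T1* * (B/A - 1)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("renofib")

ADC_UNITS = "1e-6 mm^2/s"
T1_UNITS = "ms"

#: per-pixel quality flags on ParametricMap.flags
FLAG_OK = 0
FLAG_LL_CORRECTION_INVALID = 1  # B/A <= 1: Look-Locker correction non-physical,
#                                 T1* reported instead of corrected T1


class EmptyCompartmentError(ValueError):
    """Raised when an ROI aggregation finds no valid pixels."""


@dataclass
class DiffusionSeries:
    """A stack of diffusion-weighted volumes with their b-values.

    ``volumes`` has shape ``(n_b, *grid)``; grid axes are ordered
    (slice, row, col) for 3-D data or (row, col) for single slices.
    """

    volumes: np.ndarray
    b_values: np.ndarray
    pixel_spacing: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.volumes.ndim < 3:
            self.volumes = self.volumes[:, None, :] if self.volumes.ndim == 2 else self.volumes
        if self.b_values.ndim != 1 or len(self.b_values) != self.volumes.shape[0]:
            raise ValueError("b_values must be 1-D and match the number of volumes")
        if len(self.b_values) < 2:
            raise ValueError("need at least 2 b-values")
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        order = np.argsort(self.b_values, kind="stable")
        self.b_values = self.b_values[order]
        self.volumes = self.volumes[order]
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b-values must be distinct")

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]


@dataclass
class InversionSeries:
    """A stack of inversion-recovery volumes with their inversion times [ms]."""

    volumes: np.ndarray
    inversion_times: np.ndarray

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.inversion_times = np.asarray(self.inversion_times, dtype=float)
        if self.inversion_times.ndim != 1 or len(self.inversion_times) != self.volumes.shape[0]:
            raise ValueError("inversion_times must be 1-D and match the number of volumes")
        if len(np.unique(self.inversion_times)) < 3:
            raise ValueError("need at least 3 distinct inversion times")
        if np.any(self.inversion_times <= 0):
            raise ValueError("inversion times must be positive")
        order = np.argsort(self.inversion_times, kind="stable")
        self.inversion_times = self.inversion_times[order]
        self.volumes = self.volumes[order]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.volumes.shape[1:]


@dataclass
class ParametricMap:
    """A fitted per-pixel parameter grid with validity mask and fit quality.

    ``values`` are finite wherever ``mask`` is True; ``fit_quality`` holds the
    per-pixel residual sum of squares of the fit. ``flags`` carries per-pixel
    quality codes (see FLAG_* constants).
    """

    values: np.ndarray
    mask: np.ndarray
    units: str
    fit_quality: np.ndarray | None = None
    flags: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.units not in (ADC_UNITS, T1_UNITS):
            raise ValueError(f"unknown units label {self.units!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("masked-valid values must be finite")


# ---------------------------------------------------------------------------
# ADC fitting
# ---------------------------------------------------------------------------


def _loglinear_adc(signals: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least squares of ln S on b for pixels with all-positive signals.

    signals: (n_b, n_pix). Returns (s0, adc_1e6, valid).
    """
    valid = np.all(signals > 0, axis=0)
    s0 = np.full(signals.shape[1], np.nan)
    adc = np.full(signals.shape[1], np.nan)
    if valid.any():
        y = np.log(signals[:, valid])  # (n_b, m)
        design = np.stack([np.ones_like(b), -b], axis=1)  # (n_b, 2)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)  # (2, m)
        s0[valid] = np.exp(coef[0])
        adc[valid] = coef[1] * 1e6  # slope is ADC in mm^2/s
    return s0, adc, valid


def _gauss_newton_adc(
    signals: np.ndarray,
    b: np.ndarray,
    s0_init: np.ndarray,
    adc_init: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-14,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised damped Gauss-Newton for S(b) = S0 exp(-b * ADC*1e-6).

    Operates on all pixels simultaneously; Levenberg-style damping is adapted
    per pixel so benign pixels converge quadratically while ill-conditioned
    ones stay stable.
    """
    s0 = s0_init.copy()
    adc = adc_init.copy()
    lam = np.full(s0.shape, 1e-8)
    bcol = b[:, None]

    def sse(s0v, adcv):
        model = s0v[None, :] * np.exp(-bcol * adcv[None, :] * 1e-6)
        return np.sum((signals - model) ** 2, axis=0)

    cur = sse(s0, adc)
    for _ in range(max_iter):
        e = np.exp(-bcol * adc[None, :] * 1e-6)  # (n_b, n_pix)
        model = s0[None, :] * e
        r = signals - model
        j0 = e  # d model / d s0
        j1 = -model * bcol * 1e-6  # d model / d adc (adc in 1e-6 units)
        g0 = np.sum(j0 * r, axis=0)
        g1 = np.sum(j1 * r, axis=0)
        h00 = np.sum(j0 * j0, axis=0) + lam
        h11 = np.sum(j1 * j1, axis=0) + lam
        h01 = np.sum(j0 * j1, axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d_s0 = (h11 * g0 - h01 * g1) / det
        d_adc = (h00 * g1 - h01 * g0) / det
        new_s0 = s0 + d_s0
        new_adc = adc + d_adc
        new = sse(new_s0, new_adc)
        better = new <= cur
        s0 = np.where(better, new_s0, s0)
        adc = np.where(better, new_adc, adc)
        lam = np.where(better, lam * 0.3, lam * 10.0)
        np.clip(lam, 1e-12, 1e12, out=lam)
        improved = cur - new
        cur = np.where(better, new, cur)
        if np.all(improved[better] <= tol * (cur[better] + 1e-300)) and better.all():
            break
    return s0, adc


def fit_adc_map(
    series: DiffusionSeries,
    mask: np.ndarray | None = None,
    method: str = "loglinear",
) -> tuple[ParametricMap, ParametricMap]:
    """Fit a mono-exponential ADC map pixel-by-pixel.

    Parameters
    ----------
    series
        Diffusion series with >= 2 distinct b-values.
    mask
        Boolean grid of pixels to fit; ``None`` fits every pixel.
    method
        ``"loglinear"`` — least squares on ln S vs b (pixels with any
        non-positive signal are flagged invalid); ``"nonlinear"`` — least
        squares on S vs b, initialised from the log-linear solution.

    Returns
    -------
    (adc_map, s0_map)
        ADC in 1e-6 mm^2/s and the fitted b=0 signal, each a ParametricMap.
    """
    if method not in ("loglinear", "nonlinear"):
        raise ValueError(f"unknown method {method!r}")
    grid = series.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match series grid")

    b = series.b_values
    flat = series.volumes.reshape(len(b), -1)
    midx = np.flatnonzero(mask.ravel())
    signals = flat[:, midx]  # (n_b, n_pix)

    if signals.size and np.all(signals == 0):
        logger.warning("all-zero diffusion series: returning empty-mask map")

    s0_ll, adc_ll, valid_ll = _loglinear_adc(signals, b)

    if method == "loglinear":
        s0_fit, adc_fit, valid = s0_ll, adc_ll, valid_ll
    else:
        # need >= 2 positive samples for any fit at all
        n_pos = np.sum(signals > 0, axis=0)
        valid = n_pos >= 2
        s0_init = np.where(valid_ll, s0_ll, np.max(signals, axis=0, initial=0.0))
        s0_init = np.maximum(s0_init, 1e-6)
        adc_init = np.where(valid_ll, adc_ll, 1000.0)
        s0_fit, adc_fit = _gauss_newton_adc(signals, b, s0_init, adc_init)
        s0_fit = np.where(valid, s0_fit, np.nan)
        adc_fit = np.where(valid, adc_fit, np.nan)

    # negative decay rates are non-physical for pure diffusion but arise from
    # noise; keep the least-squares value, mask only non-finite fits
    valid = valid & np.isfinite(adc_fit) & np.isfinite(s0_fit)

    model = np.where(
        valid[None, :],
        np.nan_to_num(s0_fit)[None, :] * np.exp(-b[:, None] * np.nan_to_num(adc_fit)[None, :] * 1e-6),
        0.0,
    )
    rss = np.where(valid, np.sum((signals - model) ** 2, axis=0), np.nan)

    def to_grid(vec, fill=np.nan):
        out = np.full(mask.size, fill)
        out[midx] = vec
        return out.reshape(grid)

    full_valid = np.zeros(mask.size, dtype=bool)
    full_valid[midx] = valid
    full_valid = full_valid.reshape(grid)

    adc_map = ParametricMap(to_grid(adc_fit), full_valid, ADC_UNITS, to_grid(rss))
    s0_map = ParametricMap(to_grid(s0_fit), full_valid, ADC_UNITS, to_grid(rss))
    return adc_map, s0_map


# ---------------------------------------------------------------------------
# T1 fitting
# ---------------------------------------------------------------------------


def _linear_ab(e: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form least squares of y = A - B*e over (A, B), vectorised.

    e: (n_ti,) regressor exp(-TI/T1*); y: (n_ti, n_pix). Returns (A, B, sse).
    """
    n = len(e)
    se = e.sum()
    see = (e * e).sum()
    sy = y.sum(axis=0)
    sey = (e[:, None] * y).sum(axis=0)
    det = n * see - se * se
    if abs(det) < 1e-300:
        a = np.full(y.shape[1], np.nan)
        return a, a.copy(), np.full(y.shape[1], np.inf)
    # solve [n -se; se -see] [A; B] = [sy; sey]  (model y = A - B e)
    a = (-see * sy + se * sey) / -det
    bb = (-se * sy + n * sey) / -det
    model = a[None, :] - bb[None, :] * e[:, None]
    sse = np.sum((y - model) ** 2, axis=0)
    return a, bb, sse


def _t1star_objective(t1s: float, ti: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e = np.exp(-ti / t1s)
    return _linear_ab(e, y)


def _golden_refine(
    ti: np.ndarray, y: np.ndarray, lo: np.ndarray, hi: np.ndarray, iters: int = 90
) -> np.ndarray:
    """Vectorised golden-section minimisation of the projected SSE over T1*.

    Each pixel carries its own bracket [lo, hi]. The objective (SSE after the
    exact linear solve for A, B) is smooth and, near the optimum, unimodal.
    """
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)

    def f(t):
        # t: (n_pix,) candidate T1* per pixel
        e = np.exp(-ti[:, None] / t[None, :])
        n = len(ti)
        se = e.sum(axis=0)
        see = (e * e).sum(axis=0)
        sy = y.sum(axis=0)
        sey = (e * y).sum(axis=0)
        det = n * see - se * se
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        av = (see * sy - se * sey) / det
        bv = (se * sy - n * sey) / det
        model = av[None, :] - bv[None, :] * e
        return np.sum((y - model) ** 2, axis=0)

    fc, fd = f(c), f(d)
    for _ in range(iters):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
    return (a + b) / 2.0


def fit_t1_map(series: InversionSeries, mask: np.ndarray | None = None) -> ParametricMap:
    """Fit a Look-Locker-corrected T1 map from magnitude inversion-recovery data.

    Per masked pixel the 3-parameter model |A - B exp(-TI/T1*)| is fitted by
    trying every sign-flip point of the TI-sorted magnitude samples (first k
    samples negated, k = 0..n) and keeping the signed fit of lowest SSE; the
    apparent T1* is then corrected to T1 = T1* (B/A - 1). Pixels with A <= 0
    or a degenerate fit are marked invalid; pixels where B/A <= 1 (correction
    non-physical) report T1* and carry FLAG_LL_CORRECTION_INVALID.
    """
    grid = series.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match series grid")

    ti = series.inversion_times
    n_ti = len(ti)
    flat = series.volumes.reshape(n_ti, -1)
    midx = np.flatnonzero(mask.ravel())
    mags = np.abs(flat[:, midx])  # magnitude data, TI-sorted
    n_pix = mags.shape[1]

    # T1* search grid: log-spaced, wide enough for renal tissue at 3T and the
    # synthetic phantoms (apparent T1* of hundreds of ms up to several s)
    t1s_grid = np.geomspace(20.0, 8000.0, 160)

    best_sse = np.full(n_pix, np.inf)
    best_k = np.zeros(n_pix, dtype=int)
    best_gi = np.zeros(n_pix, dtype=int)

    sign_patterns = []
    for k in range(n_ti + 1):
        s = np.ones(n_ti)
        s[:k] = -1.0
        sign_patterns.append(s)

    # stage 1: coarse grid over (sign pattern, T1*)
    for k, s in enumerate(sign_patterns):
        y = s[:, None] * mags
        for gi, t1s in enumerate(t1s_grid):
            _, _, sse = _t1star_objective(t1s, ti, y)
            upd = sse < best_sse
            best_sse = np.where(upd, sse, best_sse)
            best_k = np.where(upd, k, best_k)
            best_gi = np.where(upd, gi, best_gi)

    # stage 2: golden-section refinement of T1* per pixel for its best pattern
    lo = t1s_grid[np.maximum(best_gi - 1, 0)]
    hi = t1s_grid[np.minimum(best_gi + 1, len(t1s_grid) - 1)]
    y_best = np.empty_like(mags)
    for k, s in enumerate(sign_patterns):
        sel = best_k == k
        if sel.any():
            y_best[:, sel] = s[:, None] * mags[:, sel]

    t1s_fit = _golden_refine(ti, y_best, lo, hi)
    a_fit, b_fit, sse_fit = np.empty(n_pix), np.empty(n_pix), np.empty(n_pix)
    e = np.exp(-ti[:, None] / t1s_fit[None, :])
    n = n_ti
    se = e.sum(axis=0)
    see = (e * e).sum(axis=0)
    sy = y_best.sum(axis=0)
    sey = (e * y_best).sum(axis=0)
    det = n * see - se * se
    degen = np.abs(det) < 1e-12 * np.maximum(1.0, see * n)
    det = np.where(degen, 1.0, det)
    a_fit = (see * sy - se * sey) / det
    b_fit = (se * sy - n * sey) / det
    model = a_fit[None, :] - b_fit[None, :] * e
    sse_fit = np.sum((y_best - model) ** 2, axis=0)

    valid = (~degen) & np.isfinite(t1s_fit) & np.isfinite(a_fit) & (a_fit > 0)
    ratio = np.where(a_fit > 0, b_fit / np.where(a_fit == 0, 1.0, a_fit), np.nan)
    correctable = valid & (ratio > 1.0)
    flagged = valid & ~correctable

    t1 = np.full(n_pix, np.nan)
    t1[correctable] = t1s_fit[correctable] * (ratio[correctable] - 1.0)
    t1[flagged] = t1s_fit[flagged]  # report apparent T1*, flag the pixel
    flags = np.where(flagged, FLAG_LL_CORRECTION_INVALID, FLAG_OK)

    def to_grid(vec, fill=np.nan, dtype=float):
        out = np.full(mask.size, fill, dtype=dtype)
        out[midx] = vec
        return out.reshape(grid)

    full_valid = np.zeros(mask.size, dtype=bool)
    full_valid[midx] = valid
    return ParametricMap(
        to_grid(np.where(valid, t1, np.nan)),
        full_valid.reshape(grid),
        T1_UNITS,
        to_grid(np.where(valid, sse_fit, np.nan)),
        flags=to_grid(flags, fill=FLAG_OK, dtype=int),
    )
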