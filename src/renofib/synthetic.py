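"""Seeded generators for every input the pipeline consumes.

Phantoms are two-compartment kidneys — a medullary ellipse inside a cortical
ring — with per-compartment ADC, T1 and proton-density values drawn from the
ranges observed in renal allografts at 3T; magnitude images carry Rician
noise (the magnitude of a complex signal with Gaussian noise on both
channels). Histology sections are stain-composed RGB images with a painted
collagen fraction known to 0.1%. Cohorts follow a linear ΔADC–fibrosis link
whose noiseless zero-crossing sits at 40% interstitial fibrosis, matching
the clinical observation that ΔADC turns negative above that level.

Every generator is a deterministic function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histology import OD_MAX, HistologyImage, default_stain_matrix
from .mapping import DiffusionSeries, InversionSeries

#: the ten diffusion weightings [s/mm^2] of the segmented-readout protocol
DEFAULT_B_VALUES = (0.0, 10.0, 20.0, 40.0, 60.0, 150.0, 300.0, 500.0, 700.0, 900.0)
#: inversion times [ms]; the first three are the protocol's printed TIs, the
#: rest extend the sampling so the 3-parameter fit is over-determined
DEFAULT_TIS = (161.0, 241.0, 321.0, 800.0, 1600.0, 3200.0)


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + g1) + i*g2 with g ~ Normal(0, sigma)."""
    if sigma < 0:
        raise ValueError("rician_sigma must be >= 0")
    if sigma == 0:
        return np.abs(signal)
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + g1, g2)


# ---------------------------------------------------------------------------
# Imaging phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """A two-compartment kidney phantom: medulla ellipse inside cortex ring.

    True per-compartment parameters default to mid-range renal values:
    ADC in 1e-6 mm^2/s (cortex 1634-2816, medulla 1735-2620 observed),
    T1 in ms (cortex 1175-1527, medulla 1327-1576 observed).
    """

    shape: tuple[int, int] = (64, 64)
    adc: dict = field(default_factory=lambda: {"cortex": 1800.0, "medulla": 2000.0})
    t1: dict = field(default_factory=lambda: {"cortex": 1350.0, "medulla": 1450.0})
    s0: dict = field(default_factory=lambda: {"cortex": 100.0, "medulla": 95.0})
    rician_sigma: float = 2.0
    b_values: tuple = DEFAULT_B_VALUES
    inversion_times: tuple = DEFAULT_TIS
    seed: int = 0

    def label_map(self) -> np.ndarray:
        """0 background, 1 cortex, 2 medulla; compartments disjoint."""
        h, w = self.shape
        r, c = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        outer = ((r - cy) / (0.44 * h)) ** 2 + ((c - cx) / (0.31 * w)) ** 2 <= 1.0
        inner = ((r - cy) / (0.22 * h)) ** 2 + ((c - cx) / (0.14 * w)) ** 2 <= 1.0
        labels = np.zeros(self.shape, dtype=int)
        labels[outer] = 1
        labels[inner] = 2
        return labels


def _truth_table(spec: PhantomSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compartment": ["cortex", "medulla"],
            "label": [1, 2],
            "adc_true": [spec.adc["cortex"], spec.adc["medulla"]],
            "t1_true": [spec.t1["cortex"], spec.t1["medulla"]],
            "s0_true": [spec.s0["cortex"], spec.s0["medulla"]],
        }
    )


def gen_dwi_phantom(spec: PhantomSpec) -> tuple[DiffusionSeries, np.ndarray, pd.DataFrame]:
    """Diffusion series of the phantom plus truth label map and table."""
    labels = spec.label_map()
    b = np.asarray(spec.b_values, dtype=float)
    clean = np.zeros((len(b),) + spec.shape)
    for name, lb in (("cortex", 1), ("medulla", 2)):
        sel = labels == lb
        clean[:, sel] = (
            spec.s0[name] * np.exp(-b * spec.adc[name] * 1e-6)
        )[:, None]
    rng = np.random.default_rng(spec.seed)
    noisy = rician(clean, spec.rician_sigma, rng)
    return DiffusionSeries(noisy, b), labels, _truth_table(spec)


def gen_ir_phantom(spec: PhantomSpec) -> tuple[InversionSeries, np.ndarray, pd.DataFrame]:
    """Inversion-recovery series (magnitude) of the phantom plus truth.

    The signed signal is A - B exp(-TI/T1*) with B = 2A, which makes the
    Look-Locker-corrected T1 equal the apparent T1*; noise is applied before
    taking the magnitude.
    """
    labels = spec.label_map()
    ti = np.asarray(spec.inversion_times, dtype=float)
    clean = np.zeros((len(ti),) + spec.shape)
    for name, lb in (("cortex", 1), ("medulla", 2)):
        sel = labels == lb
        a = spec.s0[name]
        b_amp = 2.0 * a
        t1_star = spec.t1[name] / (b_amp / a - 1.0)
        clean[:, sel] = (a - b_amp * np.exp(-ti / t1_star))[:, None]
    rng = np.random.default_rng(spec.seed + 1)
    noisy = rician(clean, spec.rician_sigma, rng)
    return InversionSeries(noisy, ti), labels, _truth_table(spec)


def gen_roi_set(labels: np.ndarray, rng: np.random.Generator | int = 0, n_cortex: int = 11, n_medulla: int = 19):
    """Split the phantom compartments into multiple ROIs, mimicking manual
    placement (about 11 cortical and 19 medullary ROIs per subject)."""
    from .roi import ROISet

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    label_map = np.zeros_like(labels)
    rows = []
    next_label = 1
    for comp, lb, n_rois in (("cortex", 1, n_cortex), ("medulla", 2, n_medulla)):
        idx = np.flatnonzero(labels.ravel() == lb)
        if len(idx) == 0:
            continue
        n_rois = min(n_rois, len(idx))
        assignment = rng.integers(0, n_rois, size=len(idx))
        for k in range(n_rois):
            px = idx[assignment == k]
            if len(px) == 0:
                continue
            label_map.ravel()[px] = next_label
            rows.append({"label": next_label, "compartment": comp, "slice": 0, "area_cm2": len(px) * 1e-2})
            next_label += 1
    return ROISet(label_map, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Histology sections
# ---------------------------------------------------------------------------


def _compose_rgb(concentrations: np.ndarray, stain_matrix: np.ndarray) -> np.ndarray:
    """Beer-Lambert composition: RGB = 255 * 10^-(C @ M)."""
    od = concentrations @ stain_matrix
    rgb = 255.0 * np.power(10.0, -od)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def gen_histology(
    fraction_percent: float,
    calibration_um_per_px: float = 0.232,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    blob_radius_range: tuple[int, int] = (8, 18),
    marker_concentration: float = 1.0,
) -> tuple[HistologyImage, dict]:
    """A synthetic stained section with a known collagen fraction.

    Red-marker blobs are painted onto a faint tissue background until the
    painted fraction of the (full-image) ROI matches the target; the final
    pixel count is trimmed/grown at blob boundaries so the painted truth is
    within 0.1% of the request. ``blob_radius_range`` controls component
    sizes (shrink it below ~8 px to exercise the minimum-area filter).
    """
    if not 0.0 <= fraction_percent <= 90.0:
        raise ValueError("fraction_percent must lie in [0, 90]")
    rng = np.random.default_rng(seed)
    h, w = shape
    n_px = h * w
    target_px = int(round(fraction_percent / 100.0 * n_px))

    # paint random disks, stopping just *below* the target, then grow the
    # painted region outwards pixel-by-pixel to the exact count; growing
    # (rather than trimming the overshoot) never fragments a component, so
    # the minimum-area filter sees only full-sized blobs
    painted = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    r_lo, r_hi = blob_radius_range
    guard = 0
    while guard < 100_000:
        guard += 1
        radius = int(rng.integers(r_lo, r_hi + 1))
        # keep each disk wholly inside the frame so no blob is clipped into
        # a fragment smaller than the physical minimum area
        cy = int(rng.integers(radius, h - radius))
        cx = int(rng.integers(radius, w - radius))
        blob = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        if int((painted | blob).sum()) > target_px:
            break
        painted |= blob

    deficit = target_px - int(painted.sum())
    if deficit > 0:
        from scipy.ndimage import distance_transform_edt

        if not painted.any():
            painted[h // 2, w // 2] = True
            deficit -= 1
        if deficit > 0:
            dist = distance_transform_edt(~painted)
            outside = np.flatnonzero(~painted.ravel())
            order = np.argsort(dist.ravel()[outside], kind="stable")
            painted.ravel()[outside[order[:deficit]]] = True

    true_fraction = 100.0 * painted.sum() / n_px

    # stain concentrations: faint hematoxylin-ish background, strong marker
    # in painted collagen, mild texture everywhere
    conc = np.zeros(shape + (3,))
    conc[..., 0] = 0.05 + 0.02 * rng.random(shape)  # hematoxylin
    conc[..., 1] = 0.01 * rng.random(shape)  # marker background
    conc[..., 1][painted] = marker_concentration * OD_MAX * (0.52 + 0.1 * rng.random(shape)[painted])
    rgb = _compose_rgb(conc, default_stain_matrix())

    roi_polygon = np.array([[0.0, 0.0], [0.0, w - 1.0], [h - 1.0, w - 1.0], [h - 1.0, 0.0]])
    truth = {
        "true_fraction_percent": float(true_fraction),
        "painted_mask": painted,
        "roi_polygon": roi_polygon,
        "seed": seed,
    }
    return HistologyImage(rgb, calibration_um_per_px), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """A synthetic allograft cohort with a linear ΔADC-fibrosis link.

    ΔADC = alpha_adc + beta_adc * IF + Normal(0, sigma_adc); the defaults
    put the noiseless zero-crossing at IF = 40% (alpha = -40 * beta) and the
    noise level where the squared ΔADC-IF correlation is ~0.64. The ΔT1 link
    is weaker (R^2 ~ 0.29). A noisier Sirius-red fibrosis column correlates
    with the primary (Masson-like) column at R^2 ~ 0.56.
    """

    n_subjects: int = 29
    # interstitial fibrosis [%]: mixture of a low-IF majority and a high tail
    if_low_range: tuple[float, float] = (2.0, 35.0)
    if_high_range: tuple[float, float] = (35.0, 80.0)
    p_low: float = 0.55
    beta_adc: float = -5.5
    alpha_adc: float = 220.0  # = -40 * beta_adc: zero-crossing at 40% IF
    sigma_adc: float = 92.0
    beta_t1: float = -2.0
    alpha_t1: float = 10.0
    sigma_t1: float = 70.0
    sigma_sirius: float = 20.0
    seed: int = 0


def _banff_ci(if_percent: np.ndarray) -> np.ndarray:
    """Standard Banff ci bands: 0 for IF<=5%, 1 for 6-25%, 2 for 26-50%, 3 above."""
    return np.digitize(if_percent, [5.0, 25.0, 50.0], right=True)


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-subject table of Δ indices, compartment means, fibrosis and covariates."""
    if spec.n_subjects < 6:
        raise ValueError("need n >= 6 subjects (threshold sweep needs admissible splits)")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    low = rng.random(n) < spec.p_low
    if_pct = np.where(
        low,
        rng.uniform(*spec.if_low_range, n),
        rng.uniform(*spec.if_high_range, n),
    )
    delta_adc = spec.alpha_adc + spec.beta_adc * if_pct + rng.normal(0, spec.sigma_adc, n)
    delta_t1 = spec.alpha_t1 + spec.beta_t1 * if_pct + rng.normal(0, spec.sigma_t1, n)
    if_sirius = np.clip(if_pct + rng.normal(0, spec.sigma_sirius, n), 0.0, 95.0)

    adc_medulla = np.clip(rng.normal(2150.0, 150.0, n), 1735.0, 2620.0)
    t1_medulla = np.clip(rng.normal(1450.0, 50.0, n), 1327.0, 1576.0)
    ci = _banff_ci(if_pct)
    ct = np.clip(ci + rng.integers(-1, 2, n), 0, 3)
    inflammation = rng.choice(4, size=(n, 3), p=[0.5, 0.3, 0.15, 0.05])
    egfr = np.clip(90.0 - 0.7 * if_pct + rng.normal(0, 15.0, n), 5.0, 120.0)

    return pd.DataFrame(
        {
            "subject": np.arange(1, n + 1),
            "if_masson_pct": if_pct,
            "if_sirius_pct": if_sirius,
            "delta_adc": delta_adc,
            "delta_t1": delta_t1,
            "adc_cortex": adc_medulla + delta_adc,
            "adc_medulla": adc_medulla,
            "t1_cortex": t1_medulla + delta_t1,
            "t1_medulla": t1_medulla,
            "banff_ci": ci,
            "banff_ct": ct,
            "banff_i": inflammation[:, 0],
            "banff_t": inflammation[:, 1],
            "banff_ti": inflammation[:, 2],
            "egfr": egfr,
        }
    )


def gen_planted_cohort(
    n: int = 29,
    seed: int = 0,
    low_if_range: tuple[float, float] = (5.0, 35.0),
    high_if_range: tuple[float, float] = (45.0, 80.0),
    delta_low: tuple[float, float] = (150.0, 40.0),
    delta_high: tuple[float, float] = (-100.0, 40.0),
) -> pd.DataFrame:
    """A cohort with the High/Low-IF separation planted exactly at 40% IF.

    Low-IF subjects (IF in 5-35%) have ΔADC ~ Normal(150, 40²); high-IF
    subjects (IF in 45-80%) have ΔADC ~ Normal(-100, 40²). Used to verify
    that the threshold sweep recovers the planted cut-off.
    """
    rng = np.random.default_rng(seed)
    n_high = n // 2
    n_low = n - n_high
    if_pct = np.concatenate(
        [rng.uniform(*low_if_range, n_low), rng.uniform(*high_if_range, n_high)]
    )
    delta = np.concatenate(
        [
            rng.normal(delta_low[0], delta_low[1], n_low),
            rng.normal(delta_high[0], delta_high[1], n_high),
        ]
    )
    return pd.DataFrame({"if_masson_pct": if_pct, "delta_adc": delta})
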