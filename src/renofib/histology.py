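"""Automated Sirius-red fibrosis percent-area quantification.

A stained section is unmixed into stain channels by optical-density colour
deconvolution (Beer-Lambert: OD = -log10(I / I0), concentrations recovered
with the inverse stain matrix). Collagen (Sirius-red marker) pixels inside a
polygonal cortical ROI are those whose marker channel exceeds its threshold
while the hematoxylin channel stays below its threshold; connected marker
components smaller than a physical minimum area are discarded, and the
fibrosis fraction is the kept marker area divided by the ROI area, as a
percentage.

The commercial analysis software's channel definitions are proprietary, so
the stain matrix here is the standard published hematoxylin vector plus a
fast-red-like vector for the Sirius-red marker; it is configurable for users
who recalibrate against their own scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import separate_stains
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label

# Ruifrok-Johnston hematoxylin and a fast-red-like vector for the Sirius-red
# marker; third row completes an orthogonal basis (residual channel).
_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_SIRIUS_RED = np.array([0.214, 0.851, 0.478])


def default_stain_matrix() -> np.ndarray:
    h = _HEMATOXYLIN / np.linalg.norm(_HEMATOXYLIN)
    r = _SIRIUS_RED / np.linalg.norm(_SIRIUS_RED)
    res = np.cross(h, r)
    res /= np.linalg.norm(res)
    return np.stack([h, r, res])


#: maximum optical density of an 8-bit channel; used to rescale stain
#: concentrations to [0, 1]
OD_MAX = -np.log10(1.0 / 255.0)


@dataclass
class HistologyImage:
    """An RGB section image with its physical calibration [µm / pixel]."""

    rgb: np.ndarray
    calibration_um_per_px: float

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an (H, W, 3) image")
        if not (self.calibration_um_per_px and self.calibration_um_per_px > 0):
            raise ValueError("calibration must be a positive µm/pixel scalar")


@dataclass
class StainThresholds:
    """Marker-area detection parameters (all channel thresholds in [0, 1])."""

    threshold_hematoxylin: float
    threshold_marker: float
    min_area_um2: float = 10.0
    threshold_brown: float | None = None
    use_brown_exclusion: bool = False

    def __post_init__(self) -> None:
        for t in (self.threshold_hematoxylin, self.threshold_marker):
            if not 0.0 <= t <= 1.0:
                raise ValueError("channel thresholds must lie in [0, 1]")
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")


#: presets shipped verbatim for human and rat Sirius-red sections
HUMAN_SIRIUS_RED = StainThresholds(
    threshold_hematoxylin=0.15,
    threshold_marker=0.11,
    threshold_brown=0.59,
    min_area_um2=10.0,
)
RAT_SIRIUS_RED = StainThresholds(
    threshold_hematoxylin=0.07,
    threshold_marker=0.45,
    min_area_um2=10.0,
)
PRESETS = {"human": HUMAN_SIRIUS_RED, "rat": RAT_SIRIUS_RED}


@dataclass
class FibrosisFraction:
    percent_area: float
    marker_area_um2: float
    roi_area_um2: float
    n_components_kept: int
    n_components_removed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_area <= 100.0:
            raise ValueError("percent_area must lie in [0, 100]")


def stain_channels(img: HistologyImage, stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Unmix RGB into (hematoxylin, marker, residual) channels scaled to [0, 1].

    Concentrations from the optical-density deconvolution are divided by the
    8-bit maximum OD and clipped, so thresholds are comparable across images.
    """
    if stain_matrix is None:
        stain_matrix = default_stain_matrix()
    rgb = img.rgb.astype(float)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    # separate_stains normalises OD by log(1e-6); undo that to recover
    # concentrations on the log10 optical-density scale
    conc = separate_stains(rgb, np.linalg.inv(stain_matrix)) * 6.0
    return np.clip(conc / OD_MAX, 0.0, 1.0)


def quantify_sirius_red(
    img: HistologyImage,
    roi_polygon: np.ndarray,
    params: StainThresholds = HUMAN_SIRIUS_RED,
    stain_matrix: np.ndarray | None = None,
) -> FibrosisFraction:
    """Percent of a polygonal ROI covered by Sirius-red marker.

    Parameters
    ----------
    img
        Calibrated RGB section.
    roi_polygon
        (n, 2) array of (row, col) vertices, n >= 3; pixels whose centre lies
        inside (even-odd rule) belong to the ROI.
    params
        Channel thresholds and the physical minimum component area;
        connectivity is 8-connected.
    """
    roi_polygon = np.asarray(roi_polygon, dtype=float)
    if roi_polygon.ndim != 2 or roi_polygon.shape[0] < 3 or roi_polygon.shape[1] != 2:
        raise ValueError("roi_polygon must be (n>=3, 2) vertices")
    r, c = roi_polygon[:, 0], roi_polygon[:, 1]
    shoelace = 0.5 * abs(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))
    if shoelace <= 0:
        raise ValueError("degenerate ROI polygon: zero area")
    shape = img.rgb.shape[:2]
    roi_mask = polygon2mask(shape, roi_polygon)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("degenerate ROI polygon: zero area inside the image")

    channels = stain_channels(img, stain_matrix)
    hema, marker = channels[..., 0], channels[..., 1]
    marker_mask = roi_mask & (marker >= params.threshold_marker) & (hema < params.threshold_hematoxylin)
    if params.use_brown_exclusion and params.threshold_brown is not None:
        brown = channels[..., 2]
        marker_mask &= brown < params.threshold_brown

    px_area_um2 = img.calibration_um_per_px ** 2
    labelled = cc_label(marker_mask, connectivity=2)
    counts = np.bincount(labelled.ravel())[1:]  # pixels per component
    keep = counts * px_area_um2 >= params.min_area_um2
    kept = int(keep.sum())
    removed = int((~keep).sum())
    kept_px = int(counts[keep].sum())

    marker_area = kept_px * px_area_um2
    roi_area = n_roi * px_area_um2
    return FibrosisFraction(
        percent_area=100.0 * marker_area / roi_area,
        marker_area_um2=marker_area,
        roi_area_um2=roi_area,
        n_components_kept=kept,
        n_components_removed=removed,
    )
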