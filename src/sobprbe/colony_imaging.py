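"""Automated colony counting for stained 96-well plate images.

The counting procedure mirrors a particle-analyzer workflow: binarize by Yen's
entropic-correlation threshold, label connected components, discard particles
of four pixels or fewer (a colony must cover at least five pixels, the proxy
for the conventional >= 50-cell criterion), and report one colony per
surviving component.  Lightly stained debris is removed by the threshold
itself; no second intensity cutoff is applied.

Thresholding is per-well by default — each well ROI is binarized from its own
histogram, which is robust to plate-edge illumination gradients — with a
whole-plate mode available through :class:`ImagingConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .errors import ROIError, UniformImageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImagingConfig:
    """Counting parameters.

    ``min_colony_area_px`` is the smallest component area counted as a colony
    (default 5: strictly bigger than four pixels).  ``polarity`` states whether
    colonies are darker or brighter than background; foreground is the pixel
    set on that side of the threshold.  ``per_well_threshold`` selects per-ROI
    versus whole-image binarization.

    ``min_foreground_contrast`` guards against unimodal wells: Yen's criterion
    assumes a two-class histogram and will happily split pure background
    noise, so a well whose foreground and background class means differ by
    fewer gray levels than this is treated as colony-free.  Stained colonies
    sit >= 100 gray levels from background in practice; set 0 to disable.
    """

    min_colony_area_px: int = 5
    connectivity: int = 8
    polarity: str = "dark"
    bit_depth: int = 8
    per_well_threshold: bool = True
    min_foreground_contrast: float = 20.0

    def __post_init__(self):
        if self.min_colony_area_px < 1:
            raise ValueError("min_colony_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit grayscale images are supported")


@dataclass(frozen=True)
class WellROI:
    """A circular well region of interest in image coordinates."""

    row: int
    col: int
    center_y: float
    center_x: float
    radius: float

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
        return (yy - self.center_y) ** 2 + (xx - self.center_x) ** 2 <= self.radius**2


def grid_rois(
    n_rows: int = 8,
    n_cols: int = 12,
    well_pitch_px: float = 40.0,
    roi_radius_px: float = 16.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> list[WellROI]:
    """Build the regular ROI grid of a plate image (row-major, zero-based)."""
    oy, ox = origin
    return [
        WellROI(r, c, oy + (r + 0.5) * well_pitch_px, ox + (c + 0.5) * well_pitch_px, roi_radius_px)
        for r in range(n_rows)
        for c in range(n_cols)
    ]


def yen_threshold(histogram: np.ndarray) -> int:
    """Yen's entropic-correlation threshold of a 256-bin intensity histogram.

    Maximizes ``TC(t) = -ln[(sum_{i<=t} p_i^2)(sum_{i>t} p_i^2)]
    + 2 ln[P(t)(1 - P(t))]`` over t in [0, 254], where ``p_i`` are normalized
    frequencies and ``P(t)`` the cumulative mass up to t.  Ties are broken by
    the smallest t.

    Raises :class:`UniformImageError` when fewer than two bins are occupied.
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    total = h.sum()
    if np.count_nonzero(h) < 2:
        raise UniformImageError("histogram has fewer than two occupied bins")
    p = h / total
    P = np.cumsum(p)
    S = np.cumsum(p * p)  # sum of squared frequencies up to t
    t = np.arange(255)
    lo_sq, hi_sq = S[:-1], S[-1] - S[:-1]
    Pt = P[:-1]
    valid = (Pt > 0) & (Pt < 1) & (lo_sq > 0) & (hi_sq > 0)
    tc = np.full(255, -np.inf)
    tc[valid] = -np.log(lo_sq[valid] * hi_sq[valid]) + 2.0 * np.log(Pt[valid] * (1.0 - Pt[valid]))
    # argmax takes the first (= smallest t) maximum; guard against float ties
    best = np.flatnonzero(np.isclose(tc, tc.max(), rtol=0, atol=1e-12))[0]
    return int(t[best])


def binarize(pixels: np.ndarray, threshold: int, polarity: str = "dark") -> np.ndarray:
    """Foreground mask on the configured polarity side of the threshold."""
    if polarity == "dark":
        return pixels <= threshold
    return pixels > threshold


def count_colonies_in_mask(
    mask: np.ndarray, config: ImagingConfig = ImagingConfig()
) -> tuple[int, np.ndarray]:
    """Count connected foreground components of area >= ``min_colony_area_px``.

    Returns the colony count and the label image restricted to kept
    components (small particles are zeroed out).  An empty mask is valid and
    yields zero.
    """
    mask = np.asarray(mask).astype(bool)
    skim_conn = 2 if config.connectivity == 8 else 1
    labels = cc_label(mask, connectivity=skim_conn)
    if labels.max() == 0:
        return 0, labels
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= config.min_colony_area_px) + 1
    kept_labels = np.where(np.isin(labels, keep), labels, 0)
    return int(keep.size), kept_labels


def _validate_rois(rois: Sequence[WellROI], shape: tuple[int, int]) -> None:
    for roi in rois:
        if (
            roi.center_y - roi.radius < 0
            or roi.center_x - roi.radius < 0
            or roi.center_y + roi.radius > shape[0]
            or roi.center_x + roi.radius > shape[1]
        ):
            raise ROIError(f"ROI ({roi.row}, {roi.col}) extends outside the image")
    for i, a in enumerate(rois):
        for b in rois[i + 1 :]:
            if np.hypot(a.center_y - b.center_y, a.center_x - b.center_x) < a.radius + b.radius:
                raise ROIError(
                    f"ROIs ({a.row}, {a.col}) and ({b.row}, {b.col}) overlap"
                )


def count_plate(
    image: np.ndarray,
    rois: Sequence[WellROI],
    config: ImagingConfig = ImagingConfig(),
    plate_id: int = 0,
) -> pd.DataFrame:
    """Count colonies in every well ROI of an 8-bit grayscale plate image.

    Per-well mode thresholds each ROI from its own histogram; whole-plate mode
    computes one threshold from the full image.  A uniform (single-intensity)
    well cannot be thresholded and degrades to a count of 0 with a warning.

    Returns a table ``plate_id, row, col, colony_count, threshold_used``
    (threshold NaN for degraded wells).
    """
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise ValueError("image must be 8-bit grayscale (uint8)")
    _validate_rois(rois, image.shape)

    global_t: int | None = None
    if not config.per_well_threshold:
        global_t = yen_threshold(np.bincount(image.ravel(), minlength=256))

    records = []
    for roi in rois:
        pix = image[roi.pixel_mask(image.shape)]
        if global_t is None:
            try:
                t = yen_threshold(np.bincount(pix, minlength=256))
            except UniformImageError:
                logger.warning(
                    "well (%s, %s): uniform intensity, counting 0 colonies", roi.row, roi.col
                )
                records.append((plate_id, roi.row, roi.col, 0, np.nan))
                continue
        else:
            t = global_t
        # count inside the ROI bounding box so component geometry is preserved
        y0 = int(np.floor(roi.center_y - roi.radius))
        y1 = int(np.ceil(roi.center_y + roi.radius))
        x0 = int(np.floor(roi.center_x - roi.radius))
        x1 = int(np.ceil(roi.center_x + roi.radius))
        sub = image[y0:y1, x0:x1]
        yy, xx = np.ogrid[y0:y1, x0:x1]
        inside = (yy - roi.center_y) ** 2 + (xx - roi.center_x) ** 2 <= roi.radius**2
        fg = binarize(sub, t, config.polarity) & inside
        if config.min_foreground_contrast > 0 and fg.any():
            bg = inside & ~fg
            contrast = abs(float(sub[bg].mean()) - float(sub[fg].mean())) if bg.any() else 0.0
            if contrast < config.min_foreground_contrast:
                logger.warning(
                    "well (%s, %s): foreground/background contrast %.1f below %.1f, "
                    "treating as colony-free", roi.row, roi.col, contrast,
                    config.min_foreground_contrast,
                )
                records.append((plate_id, roi.row, roi.col, 0, float(t)))
                continue
        n, _ = count_colonies_in_mask(fg, config)
        records.append((plate_id, roi.row, roi.col, n, float(t)))
    return pd.DataFrame(
        records, columns=["plate_id", "row", "col", "colony_count", "threshold_used"]
    )
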