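"""Standardized-ROI construction and automatic spot counting.

The measurement protocol re-implemented here quantifies flank spots inside a
standardized rectangle anchored to four anatomical landmarks: the rectangle
initially spans from the gill crease to the front of the dorsal fin
horizontally, and from the lateral line down to the top of the pectoral fin
vertically; it is then translated upwards so that it is centred on the
lateral line.  Spots are dark melanised marks, detected by thresholding the
ROI and labelling 8-connected components; counts are normalised by ROI area
into spot densities (spots/cm^2).

Conventions: pixel indices are 0-based and row-major; rectangles are
half-open ``[x0, x1) x [y0, y1)``; physical units come from a single
isotropic scale (cm per pixel) supplied with each image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "Landmarks",
    "ROI",
    "DetectedSpots",
    "construct_roi",
    "detect_spots",
    "spot_density",
    "head_density",
    "apply_exclusions",
]


@dataclass(frozen=True)
class Landmarks:
    """Anatomical landmarks in image pixel coordinates (x = column, y = row).

    The lateral line is treated as horizontal within the ROI span, so only
    its row index is needed.  Image rows increase downwards, hence the
    lateral line has a *smaller* row index than the pectoral fin top.
    """

    pectoral_fin_top: tuple[int, int]
    gill_crease_x: int
    lateral_line_y: int
    dorsal_fin_front_x: int
    eye: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.gill_crease_x >= self.dorsal_fin_front_x:
            raise ValueError("gill crease must be left of the dorsal fin front")
        if self.lateral_line_y >= self.pectoral_fin_top[1]:
            raise ValueError("lateral line must be above the pectoral fin top")


@dataclass(frozen=True)
class ROI:
    """Half-open rectangle [x0, x0+width) x [y0, y0+height) with physical area."""

    x0: int
    y0: int
    width: int
    height: int
    area_cm2: float

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the ROI from an image array."""
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))


@dataclass(frozen=True)
class DetectedSpots:
    """Spots found in one ROI: count, per-spot areas and ROI-local centroids."""

    count: int
    areas_cm2: np.ndarray
    centroids_cm: np.ndarray  # shape (count, 2): (x, y) from the ROI origin
    threshold: float

    def to_frame(self, image_id: str = "") -> pd.DataFrame:
        """Per-spot table (image_id, spot_index, x_cm, y_cm, area_cm2)."""
        return pd.DataFrame(
            {
                "image_id": image_id,
                "spot_index": np.arange(self.count),
                "x_cm": self.centroids_cm[:, 0] if self.count else np.array([]),
                "y_cm": self.centroids_cm[:, 1] if self.count else np.array([]),
                "area_cm2": self.areas_cm2,
            }
        )


def construct_roi(
    landmarks: Landmarks, image_dims: tuple[int, int], scale: float
) -> ROI:
    """Build the standardized ROI from landmarks.

    The initial rectangle spans x in [gill_crease_x, dorsal_fin_front_x) and
    y in [lateral_line_y, pectoral_fin_top.y); the final ROI has the same
    width and height but is translated vertically so its vertical midline is
    the lateral line.

    Parameters
    ----------
    landmarks
        Validated landmark set.
    image_dims
        (height, width) of the image in pixels.
    scale
        cm per pixel (isotropic).

    Raises
    ------
    ValueError
        If the rectangle is degenerate, the scale non-positive, or the final
        ROI exceeds the image bounds (no clipping is ever performed).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    h_img, w_img = image_dims
    width = landmarks.dorsal_fin_front_x - landmarks.gill_crease_x
    height = landmarks.pectoral_fin_top[1] - landmarks.lateral_line_y
    if width <= 0 or height <= 0:
        raise ValueError("degenerate ROI: landmarks give zero width or height")
    x0 = landmarks.gill_crease_x
    y0 = landmarks.lateral_line_y - height // 2
    if x0 < 0 or y0 < 0 or x0 + width > w_img or y0 + height > h_img:
        raise ValueError(
            f"ROI [{x0},{x0 + width}) x [{y0},{y0 + height}) exceeds image "
            f"bounds {w_img} x {h_img}; check landmarks"
        )
    return ROI(x0=x0, y0=y0, width=width, height=height, area_cm2=width * height * scale**2)


def detect_spots(
    image: np.ndarray,
    roi: ROI,
    scale: float,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area_cm2: float = 0.005,
) -> DetectedSpots:
    """Threshold the ROI and count dark 8-connected components as spots.

    Pipeline: grayscale conversion (RGB images are averaged) -> binarisation
    with spots as the dark foreground -> 8-connected component labelling ->
    components smaller than ``min_area_cm2`` discarded.

    Parameters
    ----------
    image
        2-D grayscale or 3-D RGB array.
    roi
        Region to analyse; must lie within the image.
    scale
        cm per pixel.
    method
        ``"otsu"`` (threshold from the ROI histogram) or ``"fixed"``.
    fixed_threshold
        Required when ``method="fixed"``; must lie within the representable
        intensity range of the image dtype.
    min_area_cm2
        Particle-size filter; components with area strictly below it are
        dropped.
    """
    if min_area_cm2 < 0:
        raise ValueError("min_area_cm2 must be non-negative")
    if image.ndim == 3:
        image = image.mean(axis=2)
    h_img, w_img = image.shape
    if roi.width <= 0 or roi.height <= 0:
        raise ValueError("empty ROI")
    if roi.x0 < 0 or roi.y0 < 0 or roi.x0 + roi.width > w_img or roi.y0 + roi.height > h_img:
        raise ValueError("ROI exceeds image bounds")

    patch = np.asarray(image[roi.slices], dtype=float)
    if method == "otsu":
        if patch.min() == patch.max():
            # Uniform ROI: no spots by definition.
            return DetectedSpots(0, np.empty(0), np.empty((0, 2)), float(patch.min()))
        thr = float(threshold_otsu(patch))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for method='fixed'")
        info_lo, info_hi = _dtype_range(image.dtype)
        if not (info_lo <= fixed_threshold <= info_hi):
            raise ValueError(
                f"threshold {fixed_threshold} outside intensity range [{info_lo}, {info_hi}]"
            )
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    mask = patch < thr
    labelled = label(mask, connectivity=2)
    areas = []
    cents = []
    for region in regionprops(labelled):
        area = region.area * scale**2
        if area < min_area_cm2:
            continue
        r, c = region.centroid
        areas.append(area)
        cents.append((c * scale, r * scale))
    areas_arr = np.asarray(areas, dtype=float)
    cents_arr = np.asarray(cents, dtype=float).reshape(len(cents), 2)
    return DetectedSpots(len(areas), areas_arr, cents_arr, thr)


def _dtype_range(dtype: np.dtype) -> tuple[float, float]:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0


def spot_density(count: int, roi_area_cm2: float) -> float | None:
    """Spots per cm^2, or ``None`` when the fish has no spots.

    Zero-spot fish are excluded (not assigned density 0) because the ROI
    itself depends on the presence of spots in the source protocol.
    """
    if roi_area_cm2 <= 0:
        raise ValueError("ROI area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return None
    return count / roi_area_cm2


def head_density(head_count: float | None, weight_g: float) -> float | None:
    """Head spots per gram of body weight; missing counts propagate."""
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    if head_count is None or (isinstance(head_count, float) and np.isnan(head_count)):
        return None
    if head_count < 0:
        raise ValueError("head count must be non-negative")
    return head_count / weight_g


_PURPOSES = ("density", "ann", "family_model")


def apply_exclusions(
    table: pd.DataFrame, purpose: str, min_spots_for_ann: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis-specific exclusion rules and log every drop.

    * ``density`` — fish with zero spots are removed (densities undefined).
    * ``ann`` — fish with fewer than ``min_spots_for_ann`` spots are removed
      (nearest-neighbour distances are uninformative at low counts).
    * ``family_model`` — families with a single member are removed.

    Returns the filtered table and a log DataFrame (id, reason), in input
    order, so exclusion counts are reproducible and order-independent.
    """
    if purpose not in _PURPOSES:
        raise ValueError(f"purpose must be one of {_PURPOSES}")
    required = {"density": ["id", "spot_count"], "ann": ["id", "spot_count"],
                "family_model": ["id", "family"]}[purpose]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks required column(s) for {purpose!r}: {missing}")

    if purpose == "density":
        drop = table["spot_count"] == 0
        reason = "zero spots"
    elif purpose == "ann":
        drop = table["spot_count"] < min_spots_for_ann
        reason = f"fewer than {min_spots_for_ann} spots"
    else:
        sizes = table.groupby("family")["id"].transform("size")
        drop = sizes == 1
        reason = "single-member family"

    log = pd.DataFrame({"id": table.loc[drop, "id"].to_numpy(), "reason": reason})
    return table.loc[~drop].copy(), log
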