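"""Render synthetic spot patterns as photograph-like grayscale images.

Spots become dark disks on a light "skin" background; anatomical landmarks
are placed so that :func:`salmospot.spots.construct_roi` recovers a rectangle
that exactly covers the pattern's observation window.  This ties the image
pipeline to a known ground truth: the spots detected inside the standardized
ROI are exactly the simulated pattern points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .patterns import PointPattern
from .spots import Landmarks

__all__ = ["SpotImage", "render_spot_image"]

_BACKGROUND = 210
_SPOT = 35


@dataclass(frozen=True)
class SpotImage:
    """Grayscale raster with physical scale and embedded landmarks."""

    pixels: np.ndarray  # uint8, shape (rows, cols)
    scale: float  # cm per pixel
    landmarks: Landmarks

    def save(self, path: str | Path) -> None:
        """Write the raster as PNG or TIFF (by extension); lossless."""
        iio.imwrite(Path(path), self.pixels)

    @staticmethod
    def load(path: str | Path, scale: float, landmarks: Landmarks) -> "SpotImage":
        pixels = np.asarray(iio.imread(Path(path)))
        if pixels.ndim == 3:
            pixels = pixels.mean(axis=2).astype(np.uint8)
        return SpotImage(pixels=pixels, scale=scale, landmarks=landmarks)


def render_spot_image(
    pattern: PointPattern,
    scale: float = 0.02,
    radius_mean: float = 0.08,
    radius_sd: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpotImage:
    """Draw a pattern's spots as dark disks and embed consistent landmarks.

    Parameters
    ----------
    pattern
        Spot centroids with their observation window (cm).
    scale
        cm per pixel; smaller values give higher resolution.
    radius_mean, radius_sd
        Spot radius distribution in cm (truncated below at one pixel).
    noise_sd
        Standard deviation of additive Gaussian pixel noise (intensity
        units on the 0-255 scale); 0 gives a noise-free image that
        round-trips losslessly through PNG.
    seed
        Seed for radii and noise.

    Raises
    ------
    ValueError
        If scale or radius is non-positive, or pattern points fall outside
        the renderable window.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if radius_mean <= 0:
        raise ValueError("radius_mean must be positive")
    if pattern.n and (
        pattern.x.min() < 0
        or pattern.y.min() < 0
        or pattern.x.max() >= pattern.width
        or pattern.y.max() >= pattern.height
    ):
        raise ValueError("pattern points outside the renderable window")

    rng = np.random.default_rng(seed)
    w_px = int(round(pattern.width / scale))
    h_px = int(round(pattern.height / scale))
    h_px += h_px % 2  # even height so the ROI re-centring is exact
    max_r_px = int(np.ceil((radius_mean + 4 * radius_sd) / scale)) + 1
    margin = max_r_px + 4

    # The ROI landmarks: the initial landmark rectangle spans from the
    # lateral line down to the pectoral-fin top (height h_px); re-centring
    # about the lateral line then lands exactly on the pattern window.
    x0 = margin
    y_top = margin
    lateral_line_y = y_top + h_px // 2
    landmarks = Landmarks(
        pectoral_fin_top=(x0 + w_px // 2, lateral_line_y + h_px),
        gill_crease_x=x0,
        lateral_line_y=lateral_line_y,
        dorsal_fin_front_x=x0 + w_px,
    )

    rows = y_top + h_px + h_px // 2 + margin
    cols = x0 + w_px + margin
    img = np.full((rows, cols), float(_BACKGROUND))

    if pattern.n:
        radii = np.maximum(
            rng.normal(radius_mean, radius_sd, size=pattern.n) if radius_sd > 0
            else np.full(pattern.n, radius_mean),
            scale,
        )
        yy, xx = np.mgrid[0:rows, 0:cols]
        for px, py, r in zip(pattern.x, pattern.y, radii):
            cx = x0 + px / scale
            cy = y_top + py / scale
            r_px = r / scale
            lo_r = max(int(cy - r_px) - 1, 0)
            hi_r = min(int(cy + r_px) + 2, rows)
            lo_c = max(int(cx - r_px) - 1, 0)
            hi_c = min(int(cx + r_px) + 2, cols)
            sub_y = yy[lo_r:hi_r, lo_c:hi_c]
            sub_x = xx[lo_r:hi_r, lo_c:hi_c]
            disk = (sub_x - cx) ** 2 + (sub_y - cy) ** 2 <= r_px**2
            img[lo_r:hi_r, lo_c:hi_c][disk] = _SPOT

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SpotImage(pixels=pixels, scale=scale, landmarks=landmarks)
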