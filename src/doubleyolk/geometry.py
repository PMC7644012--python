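"""Image-based measurement of the egg's geometric indicator.

An egg photographed on a contrasting (green) background is measured by
the classic machine-vision chain: luminance grayscale conversion, Canny
edge detection, extraction of the largest closed contour, and the
minimum-area *rotated* rectangle enclosing it.  The rectangle's longer
and shorter sides are the egg's major and minor axes in pixels; their
ratio is the geometric indicator, which needs no pixel-to-millimetre
calibration because it is scale-free.

For testing without a camera, :func:`render_egg_image` draws synthetic
eggs — filled ellipses (optionally slightly ovoid-tapered) of known axes
and orientation on a green background, with optional pixel noise — so
ground truth is available to sub-pixel precision.

Conventions: raster origin at the top-left, row-major; axis lengths in
pixels; angles in degrees, counterclockwise from the horizontal image
axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint
from skimage import feature, filters, measure
from skimage.color import rgb2gray

__all__ = ["EggImage", "GeometryMeasurement", "render_egg_image", "extract_geometry",
           "NoEggFoundError"]

logger = logging.getLogger(__name__)

_EGG_RGB = (223, 200, 160)  # pale brown shell
_BACKGROUND_RGB = (40, 150, 60)  # green stage


class NoEggFoundError(RuntimeError):
    """No foreground contour could be detected in the image."""


@dataclass(frozen=True)
class EggImage:
    """A raster plus, for synthetic renders, the ground-truth geometry.

    ``truth_major_px`` / ``truth_minor_px`` are the *full* axis lengths
    (twice the semi-axes of the rendered ellipse); ``truth_angle_deg`` is
    the major axis' orientation, CCW from horizontal.
    """

    pixels: np.ndarray
    truth_major_px: float | None = None
    truth_minor_px: float | None = None
    truth_angle_deg: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D grayscale or 3-D RGB raster")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("image must be at least 32x32 pixels")
        if self.truth_major_px is not None and self.truth_minor_px is not None:
            if self.truth_major_px < self.truth_minor_px:
                raise ValueError("truth major axis must be >= minor axis")

    @property
    def truth_ratio(self) -> float | None:
        if self.truth_major_px is None or self.truth_minor_px is None:
            return None
        return self.truth_major_px / self.truth_minor_px


@dataclass(frozen=True)
class GeometryMeasurement:
    """Axes of the minimum-area enclosing rectangle, in pixels."""

    major_px: float
    minor_px: float
    rect_angle_deg: float
    contour_point_count: int

    @property
    def ratio(self) -> float:
        return self.major_px / self.minor_px


def render_egg_image(semi_major_px: float, semi_minor_px: float, angle_deg: float = 0.0,
                     canvas: tuple[int, int] = (320, 240), noise_sd: float = 0.0,
                     seed: int = 0, taper: float = 0.0) -> EggImage:
    """Draw a synthetic egg of known geometry on a green background.

    Parameters
    ----------
    semi_major_px, semi_minor_px
        Semi-axis lengths; the rendered egg's full axes (and the stored
        ground truth) are twice these.
    angle_deg
        Major-axis orientation, CCW from horizontal.
    canvas
        (width, height) in pixels; the ellipse must fit with a 5 px margin.
    noise_sd
        SD of additive Gaussian noise per 8-bit channel (clipped to 0-255).
    taper
        Ovoid asymmetry in [0, 0.3): the half-width shrinks linearly by
        this fraction toward one pole, approximating a real egg's narrow
        end.  0 gives an exact ellipse.
    seed
        Seeds the noise; renders are reproducible.
    """
    if semi_major_px < semi_minor_px:
        raise ValueError("semi-major axis must be >= semi-minor axis")
    if semi_minor_px <= 1:
        raise ValueError("semi-minor axis must exceed 1 px")
    if not 0.0 <= taper < 0.3:
        raise ValueError("taper must lie in [0, 0.3)")
    w, h = canvas
    cx, cy = w / 2.0, h / 2.0
    phi = math.radians(angle_deg)
    # bounding half-extents of the rotated ellipse
    bx = math.hypot(semi_major_px * math.cos(phi), semi_minor_px * math.sin(phi))
    by = math.hypot(semi_major_px * math.sin(phi), semi_minor_px * math.cos(phi))
    if bx + 5 > w / 2 or by + 5 > h / 2:
        raise ValueError("ellipse does not fit inside the canvas with a 5 px margin")

    yy, xx = np.mgrid[0:h, 0:w]
    # rotate into the ellipse frame (image y points down, so CCW flips sign)
    u = (xx - cx) * math.cos(phi) - (yy - cy) * math.sin(phi)
    v = (xx - cx) * math.sin(phi) + (yy - cy) * math.cos(phi)
    half_width = semi_minor_px * (1.0 - taper * np.clip(u / semi_major_px, -1, 1))
    inside = (u / semi_major_px) ** 2 + (v / half_width) ** 2 <= 1.0

    img = np.empty((h, w, 3), dtype=float)
    img[:] = _BACKGROUND_RGB
    img[inside] = _EGG_RGB
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return EggImage(
        pixels=img,
        truth_major_px=2.0 * semi_major_px,
        truth_minor_px=2.0 * semi_minor_px,
        truth_angle_deg=float(angle_deg) % 180.0,
    )


def _auto_canny_thresholds(gray: np.ndarray) -> tuple[float, float]:
    """High threshold from Otsu on the Sobel gradient magnitude, low = half."""
    grad = filters.sobel(gray)
    positive = grad[grad > 1e-6]
    if positive.size == 0:
        return 0.1, 0.2
    high = filters.threshold_otsu(positive)
    return 0.5 * high, high


def extract_geometry(image: EggImage | np.ndarray, sigma: float = 2.0,
                     low_threshold: float | None = None,
                     high_threshold: float | None = None) -> GeometryMeasurement:
    """Measure the egg's axes via edges, contour and minimum-area rectangle.

    Canny thresholds default to automatic values derived from the image's
    gradient-magnitude distribution.  If several contours are present the
    one with the most edge points is measured.

    Raises
    ------
    NoEggFoundError
        If edge detection yields no contour.
    """
    px = image.pixels if isinstance(image, EggImage) else np.asarray(image)
    gray = rgb2gray(px) if px.ndim == 3 else px.astype(float) / (255.0 if px.dtype == np.uint8 else 1.0)
    if low_threshold is None or high_threshold is None:
        auto_low, auto_high = _auto_canny_thresholds(gray)
        low_threshold = auto_low if low_threshold is None else low_threshold
        high_threshold = auto_high if high_threshold is None else high_threshold
    edges = feature.canny(gray, sigma=sigma, low_threshold=low_threshold,
                          high_threshold=high_threshold)
    if not edges.any():
        raise NoEggFoundError("no edges detected")
    # trace the boundary with sub-pixel (marching-squares) contours at the
    # foreground/background iso-level; binary edge pixels alone quantize the
    # boundary by ~1 px, and the minimum-area criterion is flat enough in
    # rotation that this tilts the rectangle and biases the aspect ratio
    smooth = filters.gaussian(gray, sigma=sigma)
    level = filters.threshold_otsu(smooth)
    contours = measure.find_contours(smooth, level)
    if not contours:
        raise NoEggFoundError("no iso-level contour found")
    if len(contours) > 1:
        logger.info("%d contours found; measuring the largest", len(contours))
    contour = max(contours, key=len)
    if len(contour) < 5:
        raise NoEggFoundError("largest contour too small to measure")
    # contour coordinates are (row, col); rectangle works in (x, y)
    points = MultiPoint(np.column_stack([contour[:, 1], contour[:, 0]]))
    rect = shapely.minimum_rotated_rectangle(points)
    corners = np.asarray(rect.exterior.coords)[:4]
    side_a = float(np.linalg.norm(corners[1] - corners[0]))
    side_b = float(np.linalg.norm(corners[2] - corners[1]))
    if side_a >= side_b:
        major, minor, vec = side_a, side_b, corners[1] - corners[0]
    else:
        major, minor, vec = side_b, side_a, corners[2] - corners[1]
    if minor <= 0:
        raise NoEggFoundError("degenerate enclosing rectangle")
    # image y grows downward; negate for a CCW-from-horizontal angle
    angle = math.degrees(math.atan2(-vec[1], vec[0])) % 180.0
    return GeometryMeasurement(
        major_px=major,
        minor_px=minor,
        rect_angle_deg=angle,
        contour_point_count=len(contour),
    )
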