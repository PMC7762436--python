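"""Single-particle segmentation and pixel-scale shape measurement.

The measurement chain transforms one bright-field frame containing a single
particle into a sub-pixel height/width estimate::

    raw frame -> resize to 120x120 -> Gaussian blur -> Canny edges
              -> morphological cleanup -> largest-component contour
              -> least-squares ellipse fit -> (height_px, width_px, angle)

All intermediate stages are exposed as standalone functions so they can be
validated independently against brute-force oracles.  Heights and widths are
always reported in ORIGINAL-image pixels: the per-axis resize factors are
carried through on :class:`GrayImage` and applied when the contour is mapped
back, so a downstream micrometre conversion sees pixel counts at the native
sensor pitch.

Intensity convention: after :func:`preprocess` rasters are floating point on
the 0-255 scale.  Coordinates are 0-based with x growing rightwards (columns)
and y downwards (rows); contour points sit at pixel centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.draw import polygon as draw_polygon
from skimage.measure import EllipseModel, find_contours
from skimage.transform import resize as _resize

from .errors import InvalidInputError, InvalidParameterError, NoParticleError

__all__ = [
    "GrayImage",
    "GaussianKernelSpec",
    "EdgeMap",
    "Contour",
    "ParticleShape",
    "SegmentationConfig",
    "preprocess",
    "gaussian_kernel",
    "gaussian_blur",
    "canny_edges",
    "morph_erode",
    "morph_dilate",
    "find_particle_contour",
    "estimate_shape",
    "measure_pixels",
    "contour_to_mask",
]

#: Luminance weights used to collapse RGB frames to grey (ITU-R BT.601).
_RGB_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grey intensity raster plus the resize bookkeeping.

    Parameters
    ----------
    pixels
        Float raster on the 0-255 scale.
    scale_factor
        ``(row_factor, col_factor)``: original pixel pitch divided by current
        pixel pitch per axis.  A 240x360 frame resized to 120x120 carries
        ``(2.0, 3.0)``; multiplying a measurement in the resized frame by the
        relevant factor recovers original-frame pixels.
    """

    pixels: np.ndarray
    scale_factor: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidInputError("GrayImage requires a nonempty 2-D raster")
        if min(self.scale_factor) <= 0:
            raise InvalidInputError("scale factors must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Square, unit-sum Gaussian smoothing kernel.

    ``size`` must be odd so the anchor sits on a pixel centre; the amplitude
    is fixed by normalisation (entries sum to one), which preserves constant
    rasters and mean intensity.
    """

    size: int = 5
    sigma_i: float = 1.4
    sigma_j: float = 1.4

    def __post_init__(self) -> None:
        if self.size % 2 == 0 or self.size < 3:
            raise InvalidParameterError(f"kernel size must be odd and >= 3, got {self.size}")
        if self.sigma_i <= 0 or self.sigma_j <= 0:
            raise InvalidParameterError("kernel sigmas must be positive")


@dataclass(frozen=True)
class EdgeMap:
    """Binary edge raster together with the hysteresis thresholds that made it."""

    pixels: np.ndarray
    low_threshold: float
    high_threshold: float


@dataclass(frozen=True)
class Contour:
    """Ordered boundary points ``(x, y)`` of one connected component."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        if self.closed and len(self.points) < 3:
            raise InvalidInputError("a closed contour needs at least 3 points")


@dataclass(frozen=True)
class ParticleShape:
    """Fitted particle geometry in ORIGINAL-image pixels.

    ``height_px`` is the major extent and ``width_px`` the minor extent of the
    fitted ellipse (or fallback rectangle); ``angle_deg`` orients the height
    axis, measured from the +x axis towards +y.
    """

    contour: Contour
    center: tuple[float, float]
    height_px: float
    width_px: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (self.height_px >= self.width_px > 0):
            raise InvalidInputError("particle must satisfy height_px >= width_px > 0")


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the measurement chain (YAML-mappable)."""

    resize_side: int = 120
    blur: GaussianKernelSpec = field(default_factory=GaussianKernelSpec)
    canny_low: float = 50.0
    canny_high: float = 150.0
    morph_kernel: int = 3
    erode_iter: int = 1
    dilate_iter: int = 1
    # "dilate_first" closes the gaps in the edge ring before thinning it
    # back (morphological closing).  "erode_first" follows the alternative
    # ordering but annihilates one-pixel-wide edge chains, so closing is the
    # default.
    morph_order: str = "dilate_first"
    min_area: float = 20.0

    def __post_init__(self) -> None:
        if self.morph_order not in ("dilate_first", "erode_first"):
            raise InvalidParameterError(f"unknown morph_order {self.morph_order!r}")


def _to_gray(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        if image.shape[2] == 4:  # drop alpha
            image = image[..., :3]
        if image.shape[2] != 3:
            raise InvalidInputError(f"cannot interpret raster of shape {image.shape} as image")
        image = image @ _RGB_WEIGHTS
    elif image.ndim != 2:
        raise InvalidInputError(f"cannot interpret raster of shape {image.shape} as image")
    image = np.asarray(image, dtype=float)
    # normalise declared 0-1 floats onto the working 0-255 scale
    if image.max(initial=0.0) <= 1.0:
        image = image * 255.0
    return image


def preprocess(image: np.ndarray, target_side: int = 120) -> GrayImage:
    """Convert to grey, rescale to ``target_side`` square, record axis factors.

    Non-square inputs are resized anisotropically (no cropping); the per-axis
    factors retained on the result let measurements be mapped back to the
    original pixel pitch exactly.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("empty image")
    gray = _to_gray(image)
    orig_h, orig_w = gray.shape
    if (orig_h, orig_w) == (target_side, target_side):
        return GrayImage(gray, (1.0, 1.0))
    resized = _resize(gray, (target_side, target_side), order=1, preserve_range=True,
                      anti_aliasing=(orig_h > target_side or orig_w > target_side))
    return GrayImage(np.asarray(resized), (orig_h / target_side, orig_w / target_side))


def gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Realise the unit-sum kernel h(i, j) = A exp(-((i-i0)^2/2si^2 + (j-j0)^2/2sj^2))."""
    half = spec.size // 2
    i = np.arange(spec.size)[:, None] - half
    j = np.arange(spec.size)[None, :] - half
    k = np.exp(-(i**2 / (2 * spec.sigma_i**2) + j**2 / (2 * spec.sigma_j**2)))
    return k / k.sum()


def gaussian_blur(image: GrayImage, kernel: GaussianKernelSpec | None = None) -> GrayImage:
    """Discrete convolution with a normalised Gaussian; reflect border policy."""
    kernel = kernel or GaussianKernelSpec()
    out = ndimage.convolve(image.pixels, gaussian_kernel(kernel), mode="reflect")
    return replace(image, pixels=out)


# neighbour offsets (dy, dx) along each quantised gradient direction;
# the first entry is the "forward" neighbour used for the plateau tie-break
_NMS_OFFSETS = {
    0: ((0, 1), (0, -1)),
    45: ((1, 1), (-1, -1)),
    90: ((1, 0), (-1, 0)),
    135: ((1, -1), (-1, 1)),
}


def canny_edges(image: GrayImage, low: float = 50.0, high: float = 150.0) -> EdgeMap:
    """Edge detection: Sobel gradient, direction-quantised NMS, hysteresis.

    The gradient direction theta = arctan(Gy/Gx) is quantised to the nearest
    of {0, 45, 90, 135} degrees (22.5-67.5 maps to 45, and so on); each pixel
    survives non-maximum suppression only if its gradient magnitude beats its
    two neighbours along that direction.  Plateaus are broken asymmetrically
    (strict comparison against the forward neighbour) so an ideal step edge
    yields a single-pixel line.  Hysteresis keeps weak edges (>= low) only
    when 8-connected to a strong edge (>= high).
    """
    if not (0 <= low <= high):
        raise InvalidParameterError(f"need 0 <= low <= high, got low={low}, high={high}")
    p = image.pixels
    gx = ndimage.sobel(p, axis=1, mode="reflect")
    gy = ndimage.sobel(p, axis=0, mode="reflect")
    g = np.hypot(gx, gy)
    theta = np.rad2deg(np.arctan2(gy, gx)) % 180.0

    quant = np.zeros(theta.shape, dtype=np.int16)
    quant[(theta >= 22.5) & (theta < 67.5)] = 45
    quant[(theta >= 67.5) & (theta < 112.5)] = 90
    quant[(theta >= 112.5) & (theta < 157.5)] = 135

    gpad = np.pad(g, 1, mode="constant")
    keep = np.zeros(g.shape, dtype=bool)
    for direction, ((fy, fx), (by, bx)) in _NMS_OFFSETS.items():
        sel = quant == direction
        fwd = gpad[1 + fy:gpad.shape[0] - 1 + fy, 1 + fx:gpad.shape[1] - 1 + fx]
        back = gpad[1 + by:gpad.shape[0] - 1 + by, 1 + bx:gpad.shape[1] - 1 + bx]
        keep |= sel & (g > fwd) & (g >= back)
    keep &= g > 0

    candidate = keep & (g >= low)
    strong = keep & (g >= high)
    labels, n = ndimage.label(candidate, structure=np.ones((3, 3), dtype=int))
    if n:
        strong_labels = np.unique(labels[strong])
        strong_labels = strong_labels[strong_labels > 0]
        edges = np.isin(labels, strong_labels)
    else:
        edges = np.zeros(g.shape, dtype=bool)
    return EdgeMap(edges.astype(np.uint8), low, high)


def _check_morph_params(kernel_side: int, iterations: int) -> None:
    if kernel_side % 2 == 0 or kernel_side < 1:
        raise InvalidParameterError(f"kernel side must be odd >= 1, got {kernel_side}")
    if iterations < 0:
        raise InvalidParameterError("iterations must be >= 0")


def morph_erode(raster: np.ndarray, kernel_side: int = 3, iterations: int = 1) -> np.ndarray:
    """Grey erosion: each pixel replaced by the minimum over the square kernel."""
    _check_morph_params(kernel_side, iterations)
    out = np.asarray(raster)
    for _ in range(iterations):
        out = ndimage.grey_erosion(out, size=(kernel_side, kernel_side), mode="reflect")
    return out


def morph_dilate(raster: np.ndarray, kernel_side: int = 3, iterations: int = 1) -> np.ndarray:
    """Grey dilation: dual of :func:`morph_erode`, maximum over the kernel."""
    _check_morph_params(kernel_side, iterations)
    out = np.asarray(raster)
    for _ in range(iterations):
        out = ndimage.grey_dilation(out, size=(kernel_side, kernel_side), mode="reflect")
    return out


def find_particle_contour(blob: np.ndarray, min_area: float = 20.0) -> Contour:
    """Closed boundary of the largest filled connected component.

    Components whose filled area falls below ``min_area`` square pixels are
    rejected as specks before selection; among survivors the largest filled
    area wins, ties broken by centroid distance to the frame centre.  The
    component's holes are filled before tracing so the contour is the outer
    boundary of the particle, not of any internal edge ring.
    """
    blob = np.asarray(blob) > 0
    labels, n = ndimage.label(blob, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoParticleError("mask contains no foreground component")

    center = (np.array(blob.shape) - 1) / 2.0
    best_fill = None
    best_key: tuple[float, float] | None = None
    for idx in range(1, n + 1):
        comp = labels == idx
        filled = ndimage.binary_fill_holes(comp)
        area = float(filled.sum())
        if area < min_area:
            continue
        centroid = np.array(ndimage.center_of_mass(filled))
        dist = float(np.linalg.norm(centroid - center))
        key = (-area, dist)  # larger area first, then closer to centre
        if best_key is None or key < best_key:
            best_key, best_fill = key, filled
    if best_fill is None:
        raise NoParticleError(f"no component with filled area >= {min_area} px^2")

    contours = find_contours(best_fill.astype(float), 0.5)
    if not contours:
        raise NoParticleError("degenerate component: no traceable boundary")
    rc = max(contours, key=len)  # outer boundary is the longest
    closed = bool(np.allclose(rc[0], rc[-1]))
    if closed:
        rc = rc[:-1]
    points = np.column_stack([rc[:, 1], rc[:, 0]])  # (row, col) -> (x, y)
    if len(points) < 3:
        raise NoParticleError("degenerate component: boundary has < 3 points")
    return Contour(points=points, closed=closed)


def _min_area_rect_shape(points: np.ndarray, contour: Contour) -> ParticleShape:
    """Fallback estimator: minimum-area rotated rectangle of the points."""
    hull = MultiPoint([tuple(p) for p in points]).minimum_rotated_rectangle
    if hull.geom_type != "Polygon":  # collinear or single point
        raise NoParticleError("degenerate contour: no area to measure")
    xy = np.asarray(hull.exterior.coords)[:-1]
    sides = np.diff(np.vstack([xy, xy[:1]]), axis=0)
    lengths = np.linalg.norm(sides, axis=1)
    height, width = float(lengths.max()), float(lengths.min())
    if width <= 0:
        raise NoParticleError("degenerate contour: zero-width rectangle")
    major_side = sides[int(np.argmax(lengths))]
    angle = float(np.rad2deg(np.arctan2(major_side[1], major_side[0])) % 180.0)
    cx, cy = xy.mean(axis=0)
    return ParticleShape(contour=contour, center=(float(cx), float(cy)),
                         height_px=height, width_px=width, angle_deg=angle)


def estimate_shape(contour: Contour, scale_factor: tuple[float, float] = (1.0, 1.0)) -> ParticleShape:
    """Fit an ellipse to the contour and report its axis extents.

    The contour points are first mapped to original-frame pixels via the
    per-axis resize factors, then an algebraic least-squares conic fit gives
    centre, axes and orientation.  ``height_px`` is the full major-axis
    length, ``width_px`` the minor-axis length — the side lengths of the
    rotated rectangle snugly bounding the ellipse.  Contours with fewer than
    five points (ellipse fit under-determined) fall back to the minimum-area
    rotated rectangle.
    """
    sy, sx = scale_factor
    pts = contour.points * np.array([sx, sy])
    scaled = Contour(points=pts, closed=contour.closed)

    if len(pts) >= 5:
        with np.errstate(divide="ignore", invalid="ignore"):
            model = EllipseModel.from_estimate(pts)
        if model:
            (xc, yc) = model.center
            a, b = model.axis_lengths
            theta = float(model.theta)
            height, width = 2.0 * max(a, b), 2.0 * min(a, b)
            if b > a:
                theta += np.pi / 2.0
            # guard against wild fits on ragged contours: the ellipse must not
            # dwarf the point cloud it claims to describe
            span = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
            if np.isfinite(height) and 0 < width <= height <= 4.0 * max(span, 1.0):
                return ParticleShape(
                    contour=scaled,
                    center=(float(xc), float(yc)),
                    height_px=float(height),
                    width_px=float(width),
                    angle_deg=float(np.rad2deg(theta) % 180.0),
                )
        warnings.warn("ellipse fit failed; falling back to minimum-area rectangle",
                      stacklevel=2)
    return _min_area_rect_shape(pts, scaled)


def measure_pixels(image: np.ndarray, config: SegmentationConfig | None = None) -> ParticleShape:
    """Run the full chain on one raw frame; result in original-image pixels.

    Stages: resize/grey -> Gaussian blur -> Canny -> morphological cleanup of
    the edge map -> largest-component contour -> ellipse fit.  Raises
    :class:`NoParticleError` for frames with no segmentable particle.
    """
    config = config or SegmentationConfig()
    frame = preprocess(image, target_side=config.resize_side)
    blurred = gaussian_blur(frame, config.blur)
    edges = canny_edges(blurred, config.canny_low, config.canny_high)
    blob = edges.pixels
    if config.morph_order == "erode_first":
        blob = morph_erode(blob, config.morph_kernel, config.erode_iter)
        blob = morph_dilate(blob, config.morph_kernel, config.dilate_iter)
    else:
        blob = morph_dilate(blob, config.morph_kernel, config.dilate_iter)
        blob = morph_erode(blob, config.morph_kernel, config.erode_iter)
    contour = find_particle_contour(blob, min_area=config.min_area)
    return estimate_shape(contour, frame.scale_factor)


def contour_to_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise the filled contour polygon into a binary mask of ``shape``."""
    rr, cc = draw_polygon(contour.points[:, 1], contour.points[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rr, cc] = 1
    return mask
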