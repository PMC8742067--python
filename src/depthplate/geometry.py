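"""Plate localisation and pixel-to-millimetre calibration.

The plate is the only metric reference in the scene: its physical diameter
``d`` (default 259 mm for the standard dinner plate used at acquisition) and
its apparent radius ``r_hat`` in pixels give the lateral scale
``delta_x = d / (2 * r_hat)`` in mm/px.  Detection is classical: Canny edges
on the luminance channel followed by a circle Hough transform over the range
of plausible plate radii; the highest-vote circle wins.

Coordinate convention: 0-based (row, col) array indices; circle parameters
are carried as ``center_x`` (col) and ``center_y`` (row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import DegenerateGeometry, PlateNotFound

DEFAULT_PLATE_DIAMETER_MM = 259.0

# ITU-R 601 luma weights; the acquisition pipeline is colour but edges are
# computed on luminance.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class PlateGeometry:
    """Detected plate circle plus the derived lateral scale."""

    center_x: float
    center_y: float
    radius_hat: float
    diameter_mm: float = DEFAULT_PLATE_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.radius_hat <= 0:
            raise DegenerateGeometry(f"radius_hat must be > 0, got {self.radius_hat}")

    @property
    def scale_mm_per_px(self) -> float:
        return pixel_to_mm(self)

    @property
    def center(self) -> tuple[float, float]:
        """(col, row) center."""
        return (self.center_x, self.center_y)


@dataclass(frozen=True)
class EdgeDetectorParams:
    """Canny + circle-Hough configuration.

    ``gaussian_sigma`` and the hysteresis thresholds (8-bit intensity units)
    follow the acquisition protocol: sigma=3, thresholds 10/50.
    ``radius_range`` defaults to 0.25-0.48 x min(image dims), spanning
    common plate framing (a 259 mm plate at 1 mm/px in a 480-row frame has
    radius fraction 0.27); ``min_vote_fraction`` is the fraction of the
    theoretical accumulator maximum a peak must clear to count as a plate.
    """

    gaussian_sigma: float = 3.0
    hysteresis_low: float = 10.0
    hysteresis_high: float = 50.0
    radius_range: tuple[int, int] | None = None
    radius_step: int = 1
    min_vote_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.hysteresis_low < self.hysteresis_high):
            raise ValueError("require 0 < hysteresis_low < hysteresis_high")
        if self.radius_range is not None and self.radius_range[0] >= self.radius_range[1]:
            raise ValueError("radius_range min must be < max")


def _to_luminance(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim == 3:
        arr = arr @ _LUMA
    return arr


def detect_plate(
    rgb: np.ndarray,
    params: EdgeDetectorParams | None = None,
    diameter_mm: float = DEFAULT_PLATE_DIAMETER_MM,
) -> PlateGeometry:
    """Locate the plate circle in an RGB (or grayscale) image.

    Runs Canny on luminance, then a circle Hough transform over
    ``params.radius_range``.  The returned circle is the accumulator peak
    with the most votes; ties break toward the smaller radius so the rim's
    outer shadow is not preferred over the rim itself.

    Raises
    ------
    PlateNotFound
        If no accumulator peak exceeds ``min_vote_fraction`` of the
        theoretical maximum (a normalised vote of 1.0).
    """
    params = params or EdgeDetectorParams()
    gray = _to_luminance(rgb)
    h, w = gray.shape

    if params.radius_range is None:
        m = min(h, w)
        radius_range = (int(0.25 * m), int(0.48 * m))
    else:
        radius_range = params.radius_range

    edges = canny(
        gray,
        sigma=params.gaussian_sigma,
        low_threshold=params.hysteresis_low,
        high_threshold=params.hysteresis_high,
    )
    if not edges.any():
        raise PlateNotFound("no edges detected; cannot run circle Hough transform")

    radii = np.arange(radius_range[0], radius_range[1] + 1, params.radius_step)
    # hough_circle returns accumulators normalised to [0, 1] per radius
    accum = hough_circle(edges, radii, normalize=True)
    peaks = hough_circle_peaks(accum, radii, total_num_peaks=8)
    accums, cxs, cys, rs = (np.asarray(a) for a in peaks)
    if accums.size == 0 or accums.max() < params.min_vote_fraction:
        raise PlateNotFound(
            f"best normalised vote {0.0 if accums.size == 0 else accums.max():.3f} "
            f"below threshold {params.min_vote_fraction}"
        )
    # highest vote wins; among near-equal votes prefer the smaller radius
    order = np.lexsort((rs, -accums))
    best = order[0]
    top = accums[best]
    tied = np.flatnonzero((top - accums) < 1e-6)
    best = tied[np.argmin(rs[tied])]
    return PlateGeometry(
        center_x=float(cxs[best]),
        center_y=float(cys[best]),
        radius_hat=float(rs[best]),
        diameter_mm=diameter_mm,
    )


def pixel_to_mm(geometry: PlateGeometry) -> float:
    """Lateral scale delta_x = d / (2 * r_hat) in mm/px."""
    if geometry.radius_hat <= 0:
        raise DegenerateGeometry("radius_hat must be positive")
    return geometry.diameter_mm / (2.0 * geometry.radius_hat)


def plate_interior_mask(geometry: PlateGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels strictly inside the plate circle.

    Strict ``< r_hat``; no rim erosion — boundary artefacts are handled by
    the 5x5 median filter on the height map, not here.
    """
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    d2 = (cols - geometry.center_x) ** 2 + (rows - geometry.center_y) ** 2
    return d2 < geometry.radius_hat**2
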