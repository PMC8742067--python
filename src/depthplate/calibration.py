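"""Depth calibration: from raw depth bursts to a food height map.

Two acquisitions feed the pipeline: a calibration shot of the empty plate
(depth map ``d_C``) and a plate shot with food (``d_P``), both top-down and
in millimetres camera-to-surface.  The processing order is

1. average the burst of depth frames (noise suppression),
2. translate ``d_C`` so the detected plate centers coincide
   (``T = (x_P - x_C, y_P - y_C)``),
3. per-pixel subtraction ``h_i = d_C,i - d_P,i`` (food rises toward the
   camera, so food height is positive),
4. row-wise planar tilt correction anchored on the table strips left and
   right of the plate,
5. a 5x5 median filter against spurious values at the plate rim.

Heights may be negative (depth noise below the plate); they are retained by
default so zero-mean noise cancels in volume sums.  Pixels shifted out of
frame by registration are NaN and excluded everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter

from .errors import EmptyBurst, NoTablePixels, ShapeMismatch
from .geometry import PlateGeometry


@dataclass(frozen=True)
class RegistrationTransform:
    """Integer pixel translation applied to the calibration map."""

    t_x: int
    t_y: int


@dataclass(frozen=True)
class HeightMap:
    """Per-pixel food height in mm relative to the calibration plate.

    ``values`` is float mm with NaN marking invalid (unregistered) pixels.
    Provenance flags record which corrections have been applied.
    """

    values: np.ndarray
    registered: bool = False
    tilt_corrected: bool = False
    filtered: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def average_depth_frames(frames: list[np.ndarray]) -> np.ndarray:
    """Arithmetic per-pixel mean of a burst of depth maps (mm)."""
    if len(frames) == 0:
        raise EmptyBurst("cannot average zero depth frames")
    shape = np.asarray(frames[0]).shape
    for i, f in enumerate(frames):
        if np.asarray(f).shape != shape:
            raise ShapeMismatch(f"frame {i} has shape {np.asarray(f).shape}, expected {shape}")
    return np.mean(np.stack([np.asarray(f, dtype=float) for f in frames]), axis=0)


def registration_translation(
    calib_geom: PlateGeometry, plate_geom: PlateGeometry
) -> RegistrationTransform:
    """T = (x_P - x_C, y_P - y_C), rounded to integer pixels."""
    return RegistrationTransform(
        t_x=int(round(plate_geom.center_x - calib_geom.center_x)),
        t_y=int(round(plate_geom.center_y - calib_geom.center_y)),
    )


def register_calibration(
    calib: np.ndarray,
    calib_geom: PlateGeometry,
    plate_geom: PlateGeometry,
) -> np.ndarray:
    """Translate the calibration depth map so the plate centers coincide.

    Sub-pixel offsets are rounded to whole pixels (depth texture is smooth
    at plate scale; interpolation at the rim would smear the step edge).
    Pixels with no source value after the shift are NaN.
    """
    t = registration_translation(calib_geom, plate_geom)
    out = np.full(np.asarray(calib).shape, np.nan, dtype=float)
    h, w = out.shape
    src = np.asarray(calib, dtype=float)
    # output pixel (r, c) takes calibration pixel (r - t_y, c - t_x)
    r0, r1 = max(0, t.t_y), min(h, h + t.t_y)
    c0, c1 = max(0, t.t_x), min(w, w + t.t_x)
    out[r0:r1, c0:c1] = src[r0 - t.t_y : r1 - t.t_y, c0 - t.t_x : c1 - t.t_x]
    return out


def compute_height_map(calib_registered: np.ndarray, plate: np.ndarray) -> HeightMap:
    """h_i = d_C,i - d_P,i wherever the calibration value is valid."""
    calib_registered = np.asarray(calib_registered, dtype=float)
    plate = np.asarray(plate, dtype=float)
    if calib_registered.shape != plate.shape:
        raise ShapeMismatch(
            f"calibration {calib_registered.shape} vs plate {plate.shape}"
        )
    return HeightMap(values=calib_registered - plate, registered=True)


def tilt_correct(h: HeightMap, plate_geom: PlateGeometry) -> HeightMap:
    """Row-wise planar tilt correction anchored on the table strips.

    For each row, table pixels are the valid pixels outside the plate
    circle, split into a left and a right strip at the plate center.  Let
    ``(x_bar_L, h_bar_L)`` and ``(x_bar_R, h_bar_R)`` be each strip's mean
    column and mean height; the correction subtracted at column x is the
    line through those two anchor points.  This is exact on planar tilt
    (table strips of a corrected empty scene average 0 mm) and idempotent.
    Rows with a missing strip inherit the nearest row's strip statistics —
    tilt varies slowly, so borrowing across a few rows is safe.

    Raises
    ------
    NoTablePixels
        If no row in the image has any table pixel on either side.
    """
    values = h.values
    n_rows, n_cols = values.shape
    rows_idx, cols_idx = np.ogrid[:n_rows, :n_cols]
    outside = (cols_idx - plate_geom.center_x) ** 2 + (
        rows_idx - plate_geom.center_y
    ) ** 2 >= plate_geom.radius_hat**2
    valid = np.isfinite(values)
    left = outside & valid & (cols_idx < plate_geom.center_x)
    right = outside & valid & (cols_idx >= plate_geom.center_x)

    cols = np.arange(n_cols, dtype=float)

    def strip_stats(strip: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = strip.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_h = np.where(strip, values, 0.0).sum(axis=1) / n
            mean_x = (strip * cols).sum(axis=1) / n
        return n > 0, mean_h, mean_x

    ok_l, mh_l, mx_l = strip_stats(left)
    ok_r, mh_r, mx_r = strip_stats(right)

    def fill_nearest(ok: np.ndarray, *arrays: np.ndarray) -> None:
        if not ok.any():
            raise NoTablePixels("no table pixels beside the plate in any row")
        good = np.flatnonzero(ok)
        nearest = good[np.argmin(np.abs(np.arange(len(ok))[:, None] - good[None, :]), axis=1)]
        for a in arrays:
            a[~ok] = a[nearest[~ok]]

    fill_nearest(ok_l, mh_l, mx_l)
    fill_nearest(ok_r, mh_r, mx_r)

    dx = mx_r - mx_l
    dx[np.abs(dx) < 1e-9] = 1e-9
    slope = (mh_r - mh_l) / dx
    correction = mh_l[:, None] + slope[:, None] * (cols[None, :] - mx_l[:, None])
    return replace(h, values=values - correction, tilt_corrected=True)


def median_filter_heights(h: HeightMap, window: int = 5) -> HeightMap:
    """Per-pixel median over a square window with edge replication.

    Corrects spurious measurements at plate boundaries.  Invalid pixels are
    zero-filled for the filter and restored to NaN afterwards; they sit in
    a thin border strip created by registration, outside the plate.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return replace(h, filtered=True)
    invalid = ~h.valid
    filled = np.where(invalid, 0.0, h.values)
    out = median_filter(filled, size=window, mode="nearest")
    out[invalid] = np.nan
    return replace(h, values=out, filtered=True)


def build_height_map(
    calib_frames: list[np.ndarray],
    plate_frames: list[np.ndarray],
    calib_geom: PlateGeometry,
    plate_geom: PlateGeometry,
    median_window: int = 5,
) -> HeightMap:
    """Full calibration chain: average, register, subtract, tilt-correct, filter."""
    d_c = average_depth_frames(calib_frames)
    d_p = average_depth_frames(plate_frames)
    d_c = register_calibration(d_c, calib_geom, plate_geom)
    h = compute_height_map(d_c, d_p)
    h = tilt_correct(h, plate_geom)
    return median_filter_heights(h, window=median_window)
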