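"""Synthetic top-down RGB-D plate scenes with analytically known truths.

Every stage of the pipeline is testable without real acquisitions: a scene
is a circular plate of known physical diameter on a table plane, carrying
parametric food items whose volumes have closed forms —

* ``dome``  — spherical cap of footprint radius ``a`` and peak height
  ``h0``:  V = pi * h0 * (3 a^2 + h0^2) / 6
* ``mound`` — flat cylinder:  V = pi * a^2 * h0
* ``smear`` — a thin mound (default 1 mm peak), the visually salient but
  volumetrically negligible residue that motivates depth refinement.

Depth semantics are camera-to-surface distance in mm: the table sits at a
constant depth, the plate surface slightly above it (shallower), and food
subtracts its height from the plate-surface depth.  The plate acquisition
may be translated, tilted (a planar depth ramp emulating a camera-tilt
change between calibration and plate shots) and corrupted with per-frame
Gaussian depth noise.  The RGB rendering draws a rim ring so edge + circle
Hough detection works realistically; the depth interior is flat (a constant
plate-well offset would cancel in the calibration subtraction anyway).

All randomness flows from the seed in the spec; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SpecError

TABLE_COLOR = (150, 110, 70)
PLATE_COLOR = (242, 242, 240)
# the rim is a subtle decoration: its contrast against the plate stays below
# the Canny hysteresis band so the only circular edge is the plate-table
# boundary at the true radius
RIM_COLOR = (232, 232, 230)


@dataclass(frozen=True)
class FoodItem:
    """One parametric food item, positioned relative to the plate center."""

    shape: str  # dome | mound | smear
    center_mm: tuple[float, float] = (0.0, 0.0)  # (x, y) offset from plate center
    radius_mm: float = 30.0
    peak_height_mm: float = 20.0
    color: tuple[int, int, int] = (180, 40, 35)
    # vertical scaling of the rendered height field; volume scales linearly
    # with it (unlike rescaling peak_height_mm, which reshapes a dome)
    height_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("dome", "mound", "smear"):
            raise SpecError(f"unknown food shape {self.shape!r}")
        if self.peak_height_mm < 0 or self.radius_mm <= 0 or self.height_scale < 0:
            raise SpecError(
                "food item needs radius_mm > 0, peak_height_mm >= 0, height_scale >= 0"
            )

    def analytic_volume_ml(self) -> float:
        """Closed-form solid volume in mL."""
        a, h0 = self.radius_mm, self.peak_height_mm
        if self.shape == "dome":
            v = np.pi * h0 * (3 * a**2 + h0**2) / 6.0
        else:  # mound and smear are cylinders
            v = np.pi * a**2 * h0
        return float(v) * self.height_scale / 1000.0

    def height_profile(self, r_mm: np.ndarray) -> np.ndarray:
        """Height in mm at radial distance ``r_mm`` from the item center."""
        a, h0 = self.radius_mm, self.peak_height_mm
        inside = r_mm <= a
        if h0 == 0 or self.height_scale == 0:
            return np.zeros_like(r_mm)
        if self.shape == "dome":
            # sphere radius of the cap with footprint a and peak h0
            rs = (a**2 + h0**2) / (2.0 * h0)
            prof = np.sqrt(np.maximum(rs**2 - r_mm**2, 0.0)) - (rs - h0)
            return np.where(inside, np.maximum(prof, 0.0), 0.0) * self.height_scale
        return np.where(inside, h0 * self.height_scale, 0.0)


@dataclass(frozen=True)
class SceneSpec:
    """Full parametric description of one acquisition pair."""

    shape: tuple[int, int] = (480, 640)
    plate_diameter_mm: float = 259.0
    mm_per_px: float = 1.0
    table_depth_mm: float = 600.0
    plate_lift_mm: float = 4.0
    items: tuple[FoodItem, ...] = ()
    plate_offset_px: tuple[int, int] = (0, 0)  # (dx, dy) of the plate shot
    tilt_mm_per_px: tuple[float, float] = (0.0, 0.0)  # planar ramp on the plate shot
    noise_sigma_mm: float = 0.0
    frames: int = 10
    seed: int = 0

    @property
    def plate_radius_px(self) -> float:
        return self.plate_diameter_mm / 2.0 / self.mm_per_px

    def validate(self) -> None:
        h, w = self.shape
        r = self.plate_radius_px
        cx, cy = w / 2.0, h / 2.0
        if r + max(abs(self.plate_offset_px[0]), abs(self.plate_offset_px[1])) > min(cx, cy):
            raise SpecError("plate (plus offset) does not fit in the frame")
        for item in self.items:
            ox, oy = item.center_mm
            if np.hypot(ox, oy) + item.radius_mm > self.plate_diameter_mm / 2.0:
                raise SpecError(f"item footprint leaves the plate: {item}")


@dataclass(frozen=True)
class RGBDFrame:
    """Co-registered 8-bit RGB image and float depth map in mm."""

    rgb: np.ndarray
    depth: np.ndarray


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one rendered scene."""

    mask: np.ndarray  # bool, food footprint (height > 0)
    height_mm: np.ndarray  # float, per-pixel food height
    volume_ml: float  # analytic total
    item_volumes_ml: tuple[float, ...]
    portion: str = "P1"


@dataclass(frozen=True)
class Scene:
    calibration: list[RGBDFrame]
    plate: list[RGBDFrame]
    truth: SceneTruth
    spec: SceneSpec


def _render(
    spec: SceneSpec,
    items: tuple[FoodItem, ...],
    center_px: tuple[float, float],
    tilted: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render (rgb, clean_depth, food_height, food_mask) for one acquisition."""
    h, w = spec.shape
    cy, cx = center_px[1], center_px[0]
    rows, cols = np.mgrid[:h, :w].astype(float)
    r_px = np.hypot(cols - cx, rows - cy)
    r_plate = spec.plate_radius_px

    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[:] = TABLE_COLOR
    rgb[r_px < r_plate] = PLATE_COLOR
    rim = (r_px >= r_plate - 4) & (r_px < r_plate)
    rgb[rim] = RIM_COLOR

    depth = np.full((h, w), spec.table_depth_mm, dtype=float)
    depth[r_px < r_plate] -= spec.plate_lift_mm

    height = np.zeros((h, w), dtype=float)
    for item in items:
        ix = cx + item.center_mm[0] / spec.mm_per_px
        iy = cy + item.center_mm[1] / spec.mm_per_px
        r_mm = np.hypot(cols - ix, rows - iy) * spec.mm_per_px
        prof = item.height_profile(r_mm)
        np.maximum(height, prof, out=height)  # items may abut; no stacking
        rgb[prof > 0] = item.color
    depth -= height

    if tilted:
        ax, ay = spec.tilt_mm_per_px
        depth += ax * (cols - w / 2.0) + ay * (rows - h / 2.0)

    return rgb, depth, height, height > 0


def _burst(depth: np.ndarray, rgb: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> list[RGBDFrame]:
    frames = []
    for _ in range(spec.frames):
        noisy = depth
        if spec.noise_sigma_mm > 0:
            noisy = depth + rng.normal(0.0, spec.noise_sigma_mm, depth.shape)
        frames.append(RGBDFrame(rgb=rgb, depth=noisy))
    return frames


def generate_scene(spec: SceneSpec, portion: str = "P1") -> Scene:
    """Render the calibration (empty plate) and plate (with food) bursts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    calib_center = (w / 2.0, h / 2.0)
    plate_center = (w / 2.0 + spec.plate_offset_px[0], h / 2.0 + spec.plate_offset_px[1])

    rgb_c, depth_c, _, _ = _render(spec, (), calib_center, tilted=False)
    rgb_p, depth_p, height, mask = _render(spec, spec.items, plate_center, tilted=True)

    item_vols = tuple(i.analytic_volume_ml() for i in spec.items)
    truth = SceneTruth(
        mask=mask,
        height_mm=height,
        volume_ml=float(sum(item_vols)),
        item_volumes_ml=item_vols,
        portion=portion,
    )
    return Scene(
        calibration=_burst(depth_c, rgb_c, spec, rng),
        plate=_burst(depth_p, rgb_p, spec, rng),
        truth=truth,
        spec=spec,
    )


def generate_intake_series(
    spec: SceneSpec,
    fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
) -> list[Scene]:
    """Simulated intake series P1..Pn by vertical height scaling.

    Portion k scales every item's height profile by (1 - fraction_k), which
    scales each analytic volume by exactly the same factor; fraction 0 is
    the full reference portion P1 and fraction 1 an empty plate.
    """
    if any(not 0 <= f <= 1 for f in fractions):
        raise SpecError("fractions must lie in [0, 1]")
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise SpecError("fractions must be strictly increasing")
    scenes = []
    for k, f in enumerate(fractions):
        items = tuple(
            replace(i, height_scale=i.height_scale * (1.0 - f)) for i in spec.items
        )
        sub = replace(spec, items=items, seed=spec.seed + k)
        scenes.append(generate_scene(sub, portion=f"P{k + 1}"))
    return scenes


def _cap_peak_for_volume(volume_ml: float, footprint_radius_mm: float) -> float:
    """Peak height of a spherical cap of given footprint radius and volume."""
    v_mm3 = volume_ml * 1000.0
    a = footprint_radius_mm
    # pi*h*(3a^2 + h^2)/6 = V  ->  h^3 + 3 a^2 h - 6 V / pi = 0
    roots = np.roots([1.0, 0.0, 3.0 * a**2, -6.0 * v_mm3 / np.pi])
    real = roots[np.isreal(roots)].real
    h0 = float(real[real > 0].min())
    return h0


def make_discordance_pair(
    seed: int = 0,
    volume_ml: float = 15.0,
    mound_radius_mm: float = 28.0,
    smear_height_mm: float = 1.0,
) -> tuple[Scene, Scene]:
    """Two scenes of equal analytic volume with wildly different footprints.

    Scene A piles the volume (one tablespoon, 15 mL, by default) into a
    compact dome; scene B spreads the same volume as a sub-2-mm smear
    across a large fraction of the plate.  The smear is visually salient
    but should be eliminated entirely by superpixel depth refinement.
    """
    peak = _cap_peak_for_volume(volume_ml, mound_radius_mm)
    dome = FoodItem("dome", radius_mm=mound_radius_mm, peak_height_mm=peak)
    smear_radius = float(np.sqrt(volume_ml * 1000.0 / (np.pi * smear_height_mm)))
    smear = FoodItem(
        "smear", radius_mm=smear_radius, peak_height_mm=smear_height_mm,
        color=(200, 60, 40),
    )
    a = generate_scene(SceneSpec(items=(dome,), seed=seed))
    b = generate_scene(SceneSpec(items=(smear,), seed=seed + 1))
    return a, b
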