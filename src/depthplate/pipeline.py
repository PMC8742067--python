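"""End-to-end orchestration: RGB-D acquisitions to intake reports.

The chain per plate is: detect the plate circle in both acquisitions,
average and register the depth bursts, build the tilt-corrected median-
filtered height map, produce an initial food mask (colour baseline, seeded
graph cut, the neural segmenter, or the ground-truth mask), depth-refine it
superpixel-wise, and integrate volume.  A series of plates (P1..Pn) yields
intake volumes and percent intake relative to the first (full) portion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import calibration, refinement, volumetrics
from .baselines import (
    ColorBaselineParams,
    GraphCutParams,
    SeedAnnotation,
    segment_color_baseline,
    segment_graph_cut,
    synthesize_seeds,
)
from .errors import ConfigError
from .geometry import (
    DEFAULT_PLATE_DIAMETER_MM,
    EdgeDetectorParams,
    PlateGeometry,
    detect_plate,
    pixel_to_mm,
    plate_interior_mask,
)
from .refinement import RefinementParams, SuperpixelParams
from .synthetic import Scene
from .volumetrics import IntakeReport


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    segmenter: str = "color"  # color | graph_cut | edfn | truth
    refine: bool = True
    plate_diameter_mm: float = DEFAULT_PLATE_DIAMETER_MM
    edge: EdgeDetectorParams = field(default_factory=EdgeDetectorParams)
    color: ColorBaselineParams = field(default_factory=ColorBaselineParams)
    graph_cut: GraphCutParams = field(default_factory=GraphCutParams)
    superpixels: SuperpixelParams = field(default_factory=SuperpixelParams)
    refinement: RefinementParams = field(default_factory=RefinementParams)
    median_window: int = 5
    clamp_negative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segmenter not in ("color", "graph_cut", "edfn", "truth"):
            raise ConfigError(f"unknown segmenter {self.segmenter!r}")


@dataclass
class PlateResult:
    """Everything the pipeline derives for one plate acquisition."""

    portion: str
    geometry: PlateGeometry
    height: calibration.HeightMap
    initial_mask: np.ndarray
    refined_mask: np.ndarray
    volume_ml: float  # from the refined mask if refinement is on
    volume_unrefined_ml: float
    scale_mm_per_px: float


def _initial_mask(
    rgb: np.ndarray,
    geom: PlateGeometry,
    config: PipelineConfig,
    truth_mask: np.ndarray | None,
    seeds: SeedAnnotation | None,
    model=None,
) -> np.ndarray:
    if config.segmenter == "color":
        return segment_color_baseline(rgb, geom, config.color)
    if config.segmenter == "graph_cut":
        if seeds is None:
            if truth_mask is None:
                raise ConfigError("graph_cut segmenter needs seeds or a truth mask")
            seeds = synthesize_seeds(truth_mask)
        return segment_graph_cut(rgb, seeds, geom, config.graph_cut)
    if config.segmenter == "edfn":
        if model is None:
            raise ConfigError("edfn segmenter needs a model instance")
        small = resize(
            np.asarray(rgb, dtype=float) / 255.0,
            model.config.input_shape,
            order=1,
            anti_aliasing=True,
        )
        mask_small = model.predict_mask(small)
        full = resize(
            mask_small.astype(float), rgb.shape[:2], order=0, anti_aliasing=False
        ) > 0.5
        return full & plate_interior_mask(geom, rgb.shape[:2])
    # truth
    if truth_mask is None:
        raise ConfigError("truth segmenter needs a ground-truth mask")
    return np.asarray(truth_mask, dtype=bool) & plate_interior_mask(geom, rgb.shape[:2])


def process_scene(
    scene: Scene,
    config: PipelineConfig | None = None,
    seeds: SeedAnnotation | None = None,
    model=None,
    calib_geometry: PlateGeometry | None = None,
) -> PlateResult:
    """Run the full pipeline on one in-memory scene.

    ``calib_geometry`` may be passed to reuse a detection across a series
    sharing one calibration acquisition.
    """
    config = config or PipelineConfig()
    calib_rgb = scene.calibration[0].rgb
    plate_rgb = scene.plate[0].rgb
    calib_geom = calib_geometry or detect_plate(
        calib_rgb, config.edge, config.plate_diameter_mm
    )
    plate_geom = detect_plate(plate_rgb, config.edge, config.plate_diameter_mm)

    height = calibration.build_height_map(
        [f.depth for f in scene.calibration],
        [f.depth for f in scene.plate],
        calib_geom,
        plate_geom,
        median_window=config.median_window,
    )

    initial = _initial_mask(
        plate_rgb, plate_geom, config, scene.truth.mask if scene.truth else None, seeds, model
    )
    if config.refine:
        partition = refinement.superpixel_partition(plate_rgb, config.superpixels)
        refined = refinement.refine_mask(initial, height, partition, config.refinement)
    else:
        refined = initial

    scale = pixel_to_mm(plate_geom)
    vol_refined = volumetrics.food_volume(height, refined, scale, config.clamp_negative)
    vol_initial = volumetrics.food_volume(height, initial, scale, config.clamp_negative)
    return PlateResult(
        portion=scene.truth.portion if scene.truth else "",
        geometry=plate_geom,
        height=height,
        initial_mask=initial,
        refined_mask=refined,
        volume_ml=vol_refined if config.refine else vol_initial,
        volume_unrefined_ml=vol_initial,
        scale_mm_per_px=scale,
    )


@dataclass
class SeriesResult:
    results: list[PlateResult]
    reports: list[IntakeReport]

    @property
    def volumes_ml(self) -> np.ndarray:
        return np.array([r.volume_ml for r in self.results])


def run_series(
    scenes: list[Scene],
    config: PipelineConfig | None = None,
    plate_id: str = "plate",
    model=None,
) -> SeriesResult:
    """Process an intake series; the first scene is the full reference."""
    config = config or PipelineConfig()
    results = [process_scene(s, config, model=model) for s in scenes]
    full = results[0].volume_ml
    reports = [
        IntakeReport(
            plate_id=plate_id,
            portion=r.portion or f"P{k + 1}",
            plate_volume_ml=r.volume_ml,
            full_portion_volume_ml=full,
            mask_source=config.segmenter,
            refined=config.refine,
        )
        for k, r in enumerate(results)
    ]
    return SeriesResult(results=results, reports=reports)
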