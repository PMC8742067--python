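"""Colour-baseline and seeded graph-cut segmenters."""

import itertools

import numpy as np
import pytest

from depthplate.baselines import (
    GraphCutParams,
    SeedAnnotation,
    _fit_color_model,
    graph_cut_energy,
    segment_color_baseline,
    segment_graph_cut,
    synthesize_seeds,
)
from depthplate.errors import DegenerateSeeds
from depthplate.geometry import PlateGeometry, detect_plate, plate_interior_mask
from depthplate.metrics import iou
from depthplate.synthetic import SceneSpec, generate_scene

WHOLE_IMAGE_GEOM = PlateGeometry(center_x=80, center_y=60, radius_hat=500)


def blob_image(rng=None, shape=(120, 160), center=(60, 80), radius=30):
    rgb = np.full((*shape, 3), 245.0)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    blob = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2
    rgb[blob] = (200, 40, 30)
    if rng is not None:
        rgb = np.clip(rgb + rng.normal(0, 3, rgb.shape), 0, 255)
    return rgb.astype(np.uint8), blob


class TestColorBaseline:
    def test_red_dome_high_iou(self, red_dome_scene):
        geom = detect_plate(red_dome_scene.plate[0].rgb)
        mask = segment_color_baseline(red_dome_scene.plate[0].rgb, geom)
        assert iou(red_dome_scene.truth.mask, mask) > 0.9

    def test_empty_plate_empty_mask(self, empty_scene):
        geom = detect_plate(empty_scene.plate[0].rgb)
        mask = segment_color_baseline(empty_scene.plate[0].rgb, geom)
        assert mask.sum() == 0

    def test_food_outside_plate_excluded(self, red_dome_scene):
        """Chromatic outliers beyond the rim never enter the mask."""
        rgb = red_dome_scene.plate[0].rgb.copy()
        rgb[10:40, 10:40] = (200, 40, 30)  # red patch on the table
        geom = detect_plate(rgb)
        mask = segment_color_baseline(rgb, geom)
        assert not mask[10:40, 10:40].any()
        assert not mask[~plate_interior_mask(geom, mask.shape)].any()

    def test_deterministic(self, red_dome_scene):
        rgb = red_dome_scene.plate[0].rgb
        geom = detect_plate(rgb)
        assert np.array_equal(
            segment_color_baseline(rgb, geom), segment_color_baseline(rgb, geom)
        )


class TestGraphCut:
    def test_two_region_image_recovered(self, rng):
        rgb, blob = blob_image(rng)
        seeds = synthesize_seeds(blob)
        mask = segment_graph_cut(rgb, seeds, WHOLE_IMAGE_GEOM)
        assert iou(blob, mask) > 0.95

    def test_seed_pixels_keep_their_label(self, rng):
        rgb, blob = blob_image(rng)
        seeds = synthesize_seeds(blob)
        mask = segment_graph_cut(rgb, seeds, WHOLE_IMAGE_GEOM)
        fg, bg = seeds.rasterize(mask.shape)
        assert mask[fg].all()
        assert not mask[bg].any()

    def test_too_few_seed_pixels(self, rng):
        rgb, _ = blob_image(rng)
        seeds = SeedAnnotation(foreground=(((60, 80),),), background=((2, 2), (2, 100)))
        with pytest.raises(DegenerateSeeds):
            segment_graph_cut(rgb, seeds, WHOLE_IMAGE_GEOM)

    def test_identical_color_models_warn(self):
        rgb = np.full((40, 60, 3), 128, np.uint8)
        seeds = SeedAnnotation(
            foreground=(((20, 10), (20, 30)),), background=((5, 5), (5, 55))
        )
        with pytest.warns(UserWarning, match="low-confidence"):
            segment_graph_cut(rgb, seeds, WHOLE_IMAGE_GEOM)

    def test_deterministic(self, rng):
        rgb, blob = blob_image(rng)
        seeds = synthesize_seeds(blob)
        a = segment_graph_cut(rgb, seeds, WHOLE_IMAGE_GEOM)
        b = segment_graph_cut(rgb, seeds, WHOLE_IMAGE_GEOM)
        assert np.array_equal(a, b)

    def test_energy_optimal_on_toy_lattice(self, rng):
        """The returned cut attains the exhaustive minimum on a 3x4 image."""
        shape = (3, 4)
        rgb = np.full((*shape, 3), 240.0)
        rgb[:, :2] = (180, 50, 40)
        rgb += rng.normal(0, 5, rgb.shape)
        params = GraphCutParams(n_components=1, min_seed_pixels=1)
        seeds = SeedAnnotation(foreground=(((1, 0),),), background=((1, 3),))
        mask = segment_graph_cut(
            rgb, seeds, PlateGeometry(center_x=2, center_y=1, radius_hat=100), params
        )
        fg_model = _fit_color_model(rgb[1:2, 0:1].reshape(-1, 3), 1)
        bg_model = _fit_color_model(rgb[1:2, 3:4].reshape(-1, 3), 1)
        flat = rgb.reshape(-1, 3)
        cost_fg = -fg_model.score_samples(flat).reshape(shape)
        cost_bg = -bg_model.score_samples(flat).reshape(shape)

        best = np.inf
        for bits in itertools.product([False, True], repeat=12):
            lab = np.array(bits).reshape(shape)
            if not lab[1, 0] or lab[1, 3]:  # respect the hard constraints
                continue
            best = min(best, graph_cut_energy(lab, rgb, cost_fg, cost_bg, params))
        e_cut = graph_cut_energy(mask, rgb, cost_fg, cost_bg, params)
        assert e_cut <= best + 0.5  # slack for integer capacity quantisation
        # and certainly no worse than the trivial labelings
        all_fg = np.ones(shape, bool)
        assert e_cut <= graph_cut_energy(all_fg, rgb, cost_fg, cost_bg, params)
        assert e_cut <= graph_cut_energy(~all_fg, rgb, cost_fg, cost_bg, params)
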