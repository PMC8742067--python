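"""Initial (pre-refinement) food segmenters.

Two sources of initial masks feed the depth-refinement stage:

* a colour-distance baseline — pixels chromatically far from the estimated
  plate colour are food.  It is deliberately simple plumbing: a stand-in
  mask source for exercising the depth pipeline on synthetic scenes, not a
  general food segmenter;
* a seeded graph cut, the semi-automatic comparator ("applied ground
  truth"): a two-label min-cut on the pixel lattice with Gaussian-mixture
  colour models fit to user strokes as unary terms, hard constraints at the
  seeds and a contrast-sensitive pairwise smoothness term.

Both outputs are restricted to the plate interior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from skimage.draw import line as draw_line
from skimage.morphology import closing, disk, opening
from sklearn.mixture import GaussianMixture

from .errors import DegenerateSeeds, ShapeMismatch
from .geometry import PlateGeometry, plate_interior_mask


@dataclass(frozen=True)
class ColorBaselineParams:
    """Colour-distance segmenter configuration.

    The plate colour is estimated as the median RGB over an annulus at
    0.5-0.8 plate radii (assumed mostly food-free); pixels farther than
    ``distance_threshold`` (8-bit Euclidean RGB units) are food.
    """

    distance_threshold: float = 60.0
    annulus_inner: float = 0.5
    annulus_outer: float = 0.8
    morphology_radius: int = 2


@dataclass(frozen=True)
class GraphCutParams:
    """Energy parameterisation of the seeded graph cut.

    Unary terms are negative log-likelihoods under per-label RGB Gaussian
    mixtures fit to the seed pixels; the pairwise term between 4-connected
    neighbours is lam * exp(-beta * ||c_i - c_j||^2) with beta defaulting
    to the Boykov-Jolly 1 / (2 <||c_i - c_j||^2>) contrast normalisation.
    """

    n_components: int = 3
    lam: float = 10.0
    beta: float | None = None
    min_seed_pixels: int = 5


@dataclass(frozen=True)
class SeedAnnotation:
    """Stroke seeds: one polyline per food item, one background polyline.

    Polylines are sequences of (row, col) vertices; consecutive vertices
    are connected with rasterised line segments.
    """

    foreground: tuple[tuple[tuple[int, int], ...], ...]
    background: tuple[tuple[int, int], ...]

    def rasterize(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        fg = np.zeros(shape, dtype=bool)
        for stroke in self.foreground:
            _rasterize_stroke(stroke, fg)
        bg = np.zeros(shape, dtype=bool)
        _rasterize_stroke(self.background, bg)
        if (fg & bg).any():
            raise DegenerateSeeds("foreground and background strokes overlap")
        return fg, bg


def _rasterize_stroke(stroke, out: np.ndarray) -> None:
    pts = list(stroke)
    if len(pts) == 1:
        out[pts[0]] = True
        return
    for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        out[rr, cc] = True


def segment_color_baseline(
    rgb: np.ndarray,
    plate_geom: PlateGeometry,
    params: ColorBaselineParams | None = None,
) -> np.ndarray:
    """Chromatic-outlier mask inside the plate, morphologically cleaned."""
    params = params or ColorBaselineParams()
    rgb = np.asarray(rgb, dtype=float)
    shape = rgb.shape[:2]
    interior = plate_interior_mask(plate_geom, shape)

    rows, cols = np.ogrid[: shape[0], : shape[1]]
    r = np.hypot(cols - plate_geom.center_x, rows - plate_geom.center_y)
    annulus = (r >= params.annulus_inner * plate_geom.radius_hat) & (
        r < params.annulus_outer * plate_geom.radius_hat
    )
    plate_color = np.median(rgb[annulus], axis=0)

    dist = np.linalg.norm(rgb - plate_color, axis=-1)
    mask = (dist > params.distance_threshold) & interior
    if params.morphology_radius > 0:
        footprint = disk(params.morphology_radius)
        mask = closing(opening(mask, footprint), footprint)
    return mask & interior


def _fit_color_model(pixels: np.ndarray, n_components: int) -> GaussianMixture:
    if len(pixels) < 2:  # a 1-px stroke still defines a (degenerate) model
        pixels = np.repeat(pixels, 2, axis=0)
    n_components = min(n_components, len(np.unique(pixels, axis=0)))
    gmm = GaussianMixture(
        n_components=max(n_components, 1),
        covariance_type="full",
        reg_covar=1.0,
        random_state=0,
    )
    gmm.fit(pixels)
    return gmm


def _pairwise_weights(rgb: np.ndarray, params: GraphCutParams):
    """Contrast-sensitive 4-connectivity edge weights (horizontal, vertical)."""
    diff_h = np.sum((rgb[:, 1:] - rgb[:, :-1]) ** 2, axis=-1)
    diff_v = np.sum((rgb[1:, :] - rgb[:-1, :]) ** 2, axis=-1)
    beta = params.beta
    if beta is None:
        mean_diff = (diff_h.sum() + diff_v.sum()) / (diff_h.size + diff_v.size)
        beta = 1.0 / (2.0 * max(mean_diff, 1e-9))
    w_h = params.lam * np.exp(-beta * diff_h)
    w_v = params.lam * np.exp(-beta * diff_v)
    return w_h, w_v


_CAP_SCALE = 100.0  # float energy -> integer capacities for the max-flow solver
_HARD = np.int32(10**9)


def segment_graph_cut(
    rgb: np.ndarray,
    seeds: SeedAnnotation,
    plate_geom: PlateGeometry,
    params: GraphCutParams | None = None,
) -> np.ndarray:
    """Seeded two-label min-cut segmentation, restricted to the plate.

    Hard constraints guarantee seed pixels keep their stroke's label.  If
    the foreground and background colour models are indistinguishable the
    cut is near-arbitrary; a low-confidence warning is emitted.

    Raises
    ------
    DegenerateSeeds
        If a stroke rasterises to fewer than ``min_seed_pixels`` pixels.
    """
    params = params or GraphCutParams()
    rgb = np.asarray(rgb, dtype=float)
    shape = rgb.shape[:2]
    fg_seed, bg_seed = seeds.rasterize(shape)
    for name, seed in (("foreground", fg_seed), ("background", bg_seed)):
        if seed.sum() < params.min_seed_pixels:
            raise DegenerateSeeds(
                f"{name} strokes cover {int(seed.sum())} pixels "
                f"(< {params.min_seed_pixels})"
            )

    fg_model = _fit_color_model(rgb[fg_seed], params.n_components)
    bg_model = _fit_color_model(rgb[bg_seed], params.n_components)
    flat = rgb.reshape(-1, 3)
    cost_fg = -fg_model.score_samples(flat).reshape(shape)  # cost of labeling food
    cost_bg = -bg_model.score_samples(flat).reshape(shape)
    if np.mean(np.abs(cost_fg - cost_bg)) < 0.05:
        warnings.warn(
            "foreground and background colour models are nearly identical; "
            "the graph-cut labeling is low-confidence",
            stacklevel=2,
        )

    labels = _min_cut(rgb, cost_fg, cost_bg, fg_seed, bg_seed, params)
    return labels & plate_interior_mask(plate_geom, shape)


def _min_cut(rgb, cost_fg, cost_bg, fg_seed, bg_seed, params: GraphCutParams) -> np.ndarray:
    h, w = cost_fg.shape
    n = h * w
    source, sink = n, n + 1
    idx = np.arange(n).reshape(h, w)

    # terminal links: the source->pixel capacity is paid when the pixel falls
    # on the sink (background) side, so it carries the background cost; the
    # pixel->sink capacity is paid by food pixels and carries the food cost
    t_src = np.clip((cost_bg - cost_bg.min()) * _CAP_SCALE, 0, 1e8).astype(np.int64)
    t_snk = np.clip((cost_fg - cost_fg.min()) * _CAP_SCALE, 0, 1e8).astype(np.int64)
    t_src[bg_seed], t_snk[bg_seed] = 0, _HARD
    t_src[fg_seed], t_snk[fg_seed] = _HARD, 0

    w_h, w_v = _pairwise_weights(rgb, params)
    w_h = (w_h * _CAP_SCALE).astype(np.int64)
    w_v = (w_v * _CAP_SCALE).astype(np.int64)

    rows = np.concatenate(
        [
            np.full(n, source),
            idx.ravel(),
            idx[:, :-1].ravel(),
            idx[:, 1:].ravel(),
            idx[:-1, :].ravel(),
            idx[1:, :].ravel(),
        ]
    )
    cols = np.concatenate(
        [
            idx.ravel(),
            np.full(n, sink),
            idx[:, 1:].ravel(),
            idx[:, :-1].ravel(),
            idx[1:, :].ravel(),
            idx[:-1, :].ravel(),
        ]
    )
    caps = np.concatenate(
        [
            t_src.ravel(),
            t_snk.ravel(),
            w_h.ravel(),
            w_h.ravel(),
            w_v.ravel(),
            w_v.ravel(),
        ]
    )
    keep = caps > 0
    graph = coo_matrix(
        (np.minimum(caps[keep], _HARD).astype(np.int32), (rows[keep], cols[keep])),
        shape=(n + 2, n + 2),
    ).tocsr()

    flow = maximum_flow(graph, source, sink).flow
    residual = graph - flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, source, return_predecessors=False)
    labels = np.zeros(n + 2, dtype=bool)
    labels[reachable] = True  # source side of the cut = food
    return labels[:n].reshape(h, w)


def graph_cut_energy(
    labeling: np.ndarray,
    rgb: np.ndarray,
    cost_fg: np.ndarray,
    cost_bg: np.ndarray,
    params: GraphCutParams,
) -> float:
    """Energy of an arbitrary labeling under the graph-cut objective.

    Exposed so small lattices can be checked against exhaustive
    enumeration; uses the same shifted unary terms and pairwise weights as
    the solver (up to the integer capacity scaling).
    """
    labeling = np.asarray(labeling, dtype=bool)
    unary_fg = cost_fg - cost_fg.min()
    unary_bg = cost_bg - cost_bg.min()
    e = float(np.where(labeling, unary_fg, unary_bg).sum())
    w_h, w_v = _pairwise_weights(np.asarray(rgb, dtype=float), params)
    e += float(w_h[labeling[:, 1:] != labeling[:, :-1]].sum())
    e += float(w_v[labeling[1:, :] != labeling[:-1, :]].sum())
    return e


def synthesize_seeds(
    truth_mask: np.ndarray, margin: int = 4
) -> SeedAnnotation:
    """Batch-test seed synthesis mimicking the manual protocol.

    One straight horizontal stroke through each connected food item's
    centroid (spanning the middle half of the item's width) and one
    background squiggle along the top and right margins.
    """
    from scipy.ndimage import label as cc_label

    truth_mask = np.asarray(truth_mask, dtype=bool)
    h, w = truth_mask.shape
    lab, n = cc_label(truth_mask)
    strokes = []
    for i in range(1, n + 1):
        rr, cc = np.nonzero(lab == i)
        r0 = int(rr.mean())
        row_cols = cc[rr == r0]
        if row_cols.size == 0:
            row_cols = cc
        c_lo, c_hi = int(np.percentile(row_cols, 25)), int(np.percentile(row_cols, 75))
        strokes.append(((r0, c_lo), (r0, max(c_hi, c_lo + 1))))
    background = (
        (margin, margin),
        (margin, w - 1 - margin),
        (h - 1 - margin, w - 1 - margin),
    )
    return SeedAnnotation(foreground=tuple(strokes), background=background)
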