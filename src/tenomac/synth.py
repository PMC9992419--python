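"""Synthetic-data generator with known ground truth.

Produces every input the quantification pipeline consumes: multi-channel
fluorescence section images with nuclei in linear arrays, RGB duplex
chromogenic ISH images mixed by a Beer-Lambert forward model, explant
cell-suspension marker-intensity tables, and Fluidigm-style CT matrices.
Presets encode the study conditions (tendon, age, reporter fractions)
under which the pipeline's recovery behaviour is tested.

All randomness flows from explicit integer ``seed`` fields; there is no
global RNG state.  The cell-sampling recipe used by ``generate_section``
is documented step by step in its docstring so that it can be re-executed
independently of the renderer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .section import SectionImage, require_simple_polygon

__all__ = [
    "SectionSpec", "IshSpec", "SuspensionSpec", "QpcrSpec", "MarkerModel",
    "generate_section", "generate_duplex_ish", "generate_suspension",
    "generate_ct_matrix", "generate_single_color_controls", "beer_lambert",
    "sample_cells", "preset", "PRESET_NAMES",
]

HOUSEKEEPING_DEFAULT = ("18s", "Abl1", "Rps17")


# ---------------------------------------------------------------------------
# spec dataclasses
# ---------------------------------------------------------------------------

def _default_channel_models() -> dict:
    # mean/SD of per-nucleus fluorescence by class; GFP separates the
    # reporter-positive macrophages from the dim fibroblast autofluorescence
    return {
        "macrophage": {"hoechst": (160.0, 15.0), "gfp": (180.0, 12.0)},
        "fibroblast": {"hoechst": (160.0, 15.0), "gfp": (12.0, 4.0)},
    }


def _rect_polygon(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@dataclass
class SectionSpec:
    """Parameters of one synthetic tendon section.

    The fascicle is a closed polygon in um; anterior/posterior surface
    polylines default to the long edges of an axis-aligned rectangular
    fascicle.  ``depth_bias`` = 0 places cells uniformly over the
    fascicle; values > 0 bias placement toward the surfaces with
    acceptance weight exp(-depth_bias * d / d_max).
    """

    width_um: float = 700.0
    height_um: float = 300.0
    pixel_size_um: float = 0.5
    fascicle_polygon: np.ndarray | None = None
    anterior_polyline: np.ndarray | None = None
    posterior_polyline: np.ndarray | None = None
    peritenon_band_um: float = 25.0
    peritenon_density_factor: float = 1.0
    peritenon_macrophage_fraction: float = 0.30
    cell_density_per_mm2: float = 2000.0
    macrophage_fraction: float = 0.05
    edu_fraction_macrophage: float = 0.0
    edu_fraction_fibroblast: float = 0.0
    depth_bias: float = 0.0
    nucleus_major_um: float = 10.0
    nucleus_minor_um: float = 5.0
    orientation_jitter_deg: float = 8.0
    row_spacing_um: float = 9.0
    channel_models: dict = field(default_factory=_default_channel_models)
    edu_intensity: tuple[float, float] = (200.0, 8.0)
    background_level: float = 3.0
    background_sd: float = 2.0
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fascicle_polygon is None:
            # rectangle centred in the canvas, leaving a margin for the
            # peritenon band on every side
            m = self.peritenon_band_um + 10.0
            self.fascicle_polygon = _rect_polygon(
                m, m, self.width_um - m, self.height_um - m)
            self.anterior_polyline = self.fascicle_polygon[[0, 1]].copy()
            self.posterior_polyline = self.fascicle_polygon[[3, 2]].copy()

    def validate(self) -> None:
        for name in ("macrophage_fraction", "edu_fraction_macrophage",
                     "edu_fraction_fibroblast",
                     "peritenon_macrophage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.cell_density_per_mm2 <= 0:
            raise ValueError("cell_density_per_mm2 must be positive")
        if self.depth_bias < 0:
            raise ValueError("depth_bias must be >= 0")
        if self.nucleus_minor_um / self.pixel_size_um < 2.0:
            raise ValueError(
                "nucleus minor axis spans < 2 px at this pixel size; "
                "the nucleus is unresolvable")
        require_simple_polygon(self.fascicle_polygon, "fascicle_polygon")


def _default_stain_od_matrix() -> np.ndarray:
    # columns: green chromogen, red chromogen, nuclear counterstain;
    # each a unit optical-density direction in (R, G, B)
    cols = np.array([
        [0.68, 0.10, 0.72],   # green stain absorbs red + blue
        [0.15, 0.76, 0.63],   # red stain absorbs green + blue
        [0.62, 0.66, 0.42],   # counterstain
    ], dtype=float).T
    return cols / np.linalg.norm(cols, axis=0, keepdims=True)


@dataclass
class IshSpec:
    """Forward model of a duplex chromogenic ISH field.

    Fibroblasts and macrophages are point processes on the ROI; a
    ``csf1_high_fraction`` of fibroblasts carry Csf1 transcript and each
    macrophage is, with probability ``coloc_kappa``, placed within
    ``adjacency_radius_um`` of a random Csf1-high fibroblast (uniformly
    otherwise).  Transcript load is rendered as chromogenic puncta whose
    summed amounts A feed the Beer-Lambert mixing law
    I_c = I0_c * 10**(-sum_s M[c, s] * A_s).
    """

    width_um: float = 420.0
    height_um: float = 420.0
    pixel_size_um: float = 1.0
    roi_polygon: np.ndarray | None = None
    cell_density_per_mm2: float = 1500.0
    macrophage_fraction: float = 0.12
    csf1_high_fraction: float = 0.35
    coloc_kappa: float = 0.0
    adjacency_radius_um: float = 15.0
    puncta_per_expression_unit: float = 6.0
    punctum_radius_um: float = 1.8
    punctum_od: float = 0.22
    nucleus_radius_um: float = 3.2
    nucleus_od: float = 0.35
    stain_od_matrix: np.ndarray = field(default_factory=_default_stain_od_matrix)
    background_white: tuple[float, float, float] = (255.0, 255.0, 255.0)
    noise_sd: float = 0.0
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roi_polygon is None:
            m = 10.0
            self.roi_polygon = _rect_polygon(
                m, m, self.width_um - m, self.height_um - m)
        self.stain_od_matrix = np.asarray(self.stain_od_matrix, dtype=float)

    def validate(self) -> None:
        if not 0.0 <= self.coloc_kappa <= 1.0:
            raise ValueError("coloc_kappa must be in [0, 1]")
        if not 0.0 <= self.csf1_high_fraction <= 1.0:
            raise ValueError("csf1_high_fraction must be in [0, 1]")
        M = self.stain_od_matrix
        if M.shape != (3, 3):
            raise ValueError("stain_od_matrix must be 3x3")
        norms = np.linalg.norm(M, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("stain_od_matrix columns must be unit-norm")
        require_simple_polygon(self.roi_polygon, "roi_polygon")


@dataclass
class MarkerModel:
    """Mixture model of one marker channel within one cell class.

    A cell is marker-positive with probability ``p_pos``; its measured
    intensity is drawn from the positive or negative Gaussian component
    accordingly.
    """

    p_pos: float
    pos_mean: float
    pos_sd: float
    neg_mean: float
    neg_sd: float


MARKER_CHANNELS = ("CFP", "CD206", "F4/80", "DQ")


def _default_marker_models() -> dict:
    hi = dict(pos_mean=200.0, pos_sd=12.0, neg_mean=6.0, neg_sd=3.0)
    return {
        "fibroblast": {
            "CFP": MarkerModel(p_pos=0.995, **hi),
            "CD206": MarkerModel(p_pos=0.004, **hi),
            "F4/80": MarkerModel(p_pos=0.013, **hi),
        },
        "macrophage": {
            "CFP": MarkerModel(p_pos=0.0, **hi),
            "CD206": MarkerModel(p_pos=0.85, **hi),
            "F4/80": MarkerModel(p_pos=0.95, **hi),
        },
        "other": {
            "CFP": MarkerModel(p_pos=0.0, **hi),
            "CD206": MarkerModel(p_pos=0.01, **hi),
            "F4/80": MarkerModel(p_pos=0.02, **hi),
        },
    }


@dataclass
class SuspensionSpec:
    """Explant-derived single-cell suspension imaged on chamber slides.

    DQ-collagen positivity is class-conditional; within the macrophage
    class it additionally depends on CD206 state (receptor-mediated
    internalization), via ``dq_positive_prob_cd206neg_macrophage``.
    """

    n_cells: int = 20000
    class_fractions: dict = field(default_factory=lambda: {
        "fibroblast": 0.80, "macrophage": 0.14, "other": 0.06})
    marker_models: dict = field(default_factory=_default_marker_models)
    dq_positive_prob: dict = field(default_factory=lambda: {
        "fibroblast": 0.005, "macrophage": 0.754, "other": 0.01})
    # chosen so the DQ+ rate of the full F4/80+ pool (85% CD206+ at
    # 0.754, 15% CD206- at this rate, plus rare non-macrophage
    # contaminants) matches the reported 67.9%
    dq_positive_prob_cd206neg_macrophage: float = 0.646
    dq_intensity: tuple[float, float, float, float] = (180.0, 15.0, 5.0, 3.0)
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        tot = sum(self.class_fractions.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_fractions must sum to 1, got {tot}")
        for cls, p in self.dq_positive_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dq_positive_prob[{cls}] not in [0, 1]")
        if not 0.0 <= self.dq_positive_prob_cd206neg_macrophage <= 1.0:
            raise ValueError("dq_positive_prob_cd206neg_macrophage not in [0, 1]")


@dataclass
class QpcrSpec:
    """Design of a synthetic high-throughput qPCR plate.

    ``gene_panel`` maps gene -> {(population, tissue, age): dCT offset}.
    Panel CT = ct_baseline - offset + noise, so a +2 offset means the
    gene amplifies two cycles earlier (higher expression) in that group.
    Housekeeping CTs sit at per-gene levels centred on ``ct_baseline``.
    Every sample is emitted as two technical duplicate columns; CT above
    ``detection_limit_ct`` is emitted as missing.
    """

    gene_panel: dict = field(default_factory=dict)
    housekeeping_genes: tuple[str, str, str] = HOUSEKEEPING_DEFAULT
    housekeeping_levels: dict = field(default_factory=lambda: {
        "18s": 12.0, "Abl1": 26.0, "Rps17": 22.0})
    ct_baseline: float = 20.0
    noise_sd: float = 0.3
    n_samples_per_group: int = 5
    populations: tuple[str, ...] = ("macrophage", "fibroblast")
    tissues: tuple[str, ...] = ("limb", "tail")
    ages: tuple[str, ...] = ("P14", "P56")
    detection_limit_ct: float = 40.0
    duplicate_jitter_sd: float = 0.1
    seed: int = 0
    notes: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.housekeeping_genes) != 3:
            raise ValueError("exactly 3 housekeeping genes are required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        for hk in self.housekeeping_genes:
            offsets = self.gene_panel.get(hk)
            if offsets and any(v != 0 for v in offsets.values()):
                raise ValueError(
                    f"housekeeping gene {hk} listed in panel with "
                    "nonzero offset")


# ---------------------------------------------------------------------------
# section generation
# ---------------------------------------------------------------------------

def _surface_geometry(spec: SectionSpec):
    """The geometry whose distance defines a cell's true depth."""
    if spec.anterior_polyline is not None and spec.posterior_polyline is not None:
        return shapely.union(LineString(spec.anterior_polyline),
                             LineString(spec.posterior_polyline))
    return Polygon(spec.fascicle_polygon).exterior


def _surface_distances(spec: SectionSpec, xs, ys) -> np.ndarray:
    """Distances (um) from points to the nearest fascicle surface."""
    geom = _surface_geometry(spec)
    return shapely.distance(shapely.points(np.column_stack([xs, ys])), geom)


def _clearance_grid(sep_x: float, sep_y: float):
    """Hash-grid membership test for anisotropic minimum separation."""
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(x: float, y: float) -> bool:
        gx, gy = int(x // sep_x), int(y // sep_y)
        for ix in (gx - 1, gx, gx + 1):
            for iy in (gy - 1, gy, gy + 1):
                for px_, py_ in grid.get((ix, iy), ()):
                    if abs(px_ - x) < sep_x and abs(py_ - y) < sep_y:
                        return False
        return True

    def add(x: float, y: float) -> None:
        grid.setdefault((int(x // sep_x), int(y // sep_y)), []).append((x, y))

    return ok, add


def sample_cells(spec: SectionSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Sample ground-truth cell positions and labels (no rendering).

    The recipe, in RNG-stream order:

    1. ``n = rng.poisson(cell_density_per_mm2 * fascicle_area_mm2)``.
    2. Class labels: ``rng.uniform(size=n) < macrophage_fraction``.
    3. For each of the n cells: repeatedly draw a candidate
       ``(x, y) ~ Uniform(fascicle bounding box)`` (one ``rng.uniform``
       call of size 2), snap y to the nearest row centre (rows spaced
       ``row_spacing_um`` from the bbox top) plus ``rng.normal`` lateral
       jitter of SD ``0.15 * row_spacing_um``; accept if the point lies
       inside the polygon, survives — for macrophages only — a
       ``rng.uniform()`` depth-bias thinning draw with weight
       exp(-depth_bias * d / d_max) (fibroblast placement is always
       depth-uniform: the bias models surface infiltration of
       macrophages, the hypothesis the enrichment ratio tests), and
       keeps anisotropic clearance (|dx| >= 1.15 * major OR
       |dy| >= 1.35 * minor) from all previously accepted cells.
    4. EdU labels: one ``rng.uniform(size=n)`` compared with the
       class-specific labelling probability.
    5. Peritenon cells: ``rng.poisson`` count in the band, then uniform
       rejection placement in the band and class/EdU draws as above.
    """
    poly = require_simple_polygon(spec.fascicle_polygon)
    area_mm2 = poly.area / 1e6
    n = int(rng.poisson(spec.cell_density_per_mm2 * area_mm2))

    minx, miny, maxx, maxy = poly.bounds
    rows = np.arange(miny + spec.row_spacing_um / 2.0, maxy,
                     spec.row_spacing_um)
    # d_max for the depth-bias weight: half the bbox height is the
    # largest possible surface distance for ribbon-like fascicles
    d_max = max((maxy - miny) / 2.0, 1e-9)
    sep_x = 1.15 * spec.nucleus_major_um
    sep_y = 1.35 * spec.nucleus_minor_um

    is_mac = rng.uniform(size=n) < spec.macrophage_fraction

    xs = np.empty(n)
    ys = np.empty(n)
    max_attempts = 4000 * max(n, 1)
    placed = 0
    attempts = 0
    clearance_ok, clearance_add = _clearance_grid(sep_x, sep_y)
    surface = _surface_geometry(spec) if spec.depth_bias > 0 else None
    while placed < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not place all cells at the requested density; "
                "reduce cell_density_per_mm2 or nucleus size")
        cand = rng.uniform((minx, miny), (maxx, maxy))
        x = cand[0]
        y = rows[np.argmin(np.abs(rows - cand[1]))] + rng.normal(
            0.0, 0.15 * spec.row_spacing_um)
        if not shapely.contains_xy(poly, x, y):
            continue
        if surface is not None and is_mac[placed]:
            d = shapely.distance(Point(x, y), surface)
            if rng.uniform() > math.exp(-spec.depth_bias * d / d_max):
                continue
        if not clearance_ok(x, y):
            continue
        xs[placed], ys[placed] = x, y
        clearance_add(x, y)
        placed += 1

    p_edu = np.where(is_mac, spec.edu_fraction_macrophage,
                     spec.edu_fraction_fibroblast)
    edu = rng.uniform(size=n) < p_edu

    records = [pd.DataFrame({
        "x_um": xs, "y_um": ys,
        "cell_class": np.where(is_mac, "macrophage", "fibroblast"),
        "edu_label": edu, "in_fascicle": True,
    })]

    if spec.peritenon_band_um > 0 and spec.peritenon_density_factor > 0:
        band = poly.buffer(spec.peritenon_band_um).difference(poly)
        band_area_mm2 = band.area / 1e6
        nb = int(rng.poisson(spec.peritenon_density_factor *
                             spec.cell_density_per_mm2 * band_area_mm2))
        bminx, bminy, bmaxx, bmaxy = band.bounds
        bx, by = [], []
        attempts = 0
        band_ok, band_add = _clearance_grid(sep_x, sep_y)
        while len(bx) < nb and attempts < 4000 * max(nb, 1):
            attempts += 1
            cand = rng.uniform((bminx, bminy), (bmaxx, bmaxy))
            if not shapely.contains_xy(band, cand[0], cand[1]):
                continue
            if not (0 <= cand[0] < spec.width_um and
                    0 <= cand[1] < spec.height_um):
                continue
            if not band_ok(cand[0], cand[1]):
                continue
            bx.append(cand[0])
            by.append(cand[1])
            band_add(cand[0], cand[1])
        nb = len(bx)
        bmac = rng.uniform(size=nb) < spec.peritenon_macrophage_fraction
        bp_edu = np.where(bmac, spec.edu_fraction_macrophage,
                          spec.edu_fraction_fibroblast)
        bedu = rng.uniform(size=nb) < bp_edu
        records.append(pd.DataFrame({
            "x_um": bx, "y_um": by,
            "cell_class": np.where(bmac, "macrophage", "fibroblast"),
            "edu_label": bedu, "in_fascicle": False,
        }))

    truth = pd.concat(records, ignore_index=True)
    truth.insert(0, "cell_id", np.arange(len(truth)))
    truth["true_depth_um"] = _surface_distances(
        spec, truth["x_um"].to_numpy(), truth["y_um"].to_numpy())
    return truth


def _paint_ellipse(img: np.ndarray, cx_px: float, cy_px: float,
                   a_px: float, b_px: float, theta: float,
                   value: float) -> None:
    """Paint a filled rotated ellipse, keeping the max at overlaps."""
    h, w = img.shape
    r = int(math.ceil(max(a_px, b_px))) + 1
    x0 = max(int(cx_px) - r, 0)
    x1 = min(int(cx_px) + r + 1, w)
    y0 = max(int(cy_px) - r, 0)
    y1 = min(int(cy_px) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx_px
    dy = yy - cy_px
    c, s = math.cos(theta), math.sin(theta)
    u = (dx * c + dy * s) / a_px
    v = (-dx * s + dy * c) / b_px
    mask = u * u + v * v <= 1.0
    patch = img[y0:y1, x0:x1]
    patch[mask] = np.maximum(patch[mask], value)


def generate_section(spec: SectionSpec) -> tuple[SectionImage, pd.DataFrame]:
    """Render a synthetic section and its ground-truth cell table.

    Channels: ``hoechst`` (all nuclei), ``gfp`` (reporter), and ``edu``
    when either EdU labelling fraction is positive.  Each cell is a
    rotated filled ellipse with per-cell intensities drawn from the
    class-conditional ``channel_models``; additive Gaussian background
    noise is applied last.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = sample_cells(spec, rng)
    n = len(truth)

    px = spec.pixel_size_um
    shape = (int(round(spec.height_um / px)), int(round(spec.width_um / px)))
    channels = ["hoechst", "gfp"]
    has_edu = (spec.edu_fraction_macrophage > 0 or
               spec.edu_fraction_fibroblast > 0)
    if has_edu:
        channels.append("edu")
    imgs = {c: np.full(shape, spec.background_level, dtype=np.float64)
            for c in channels}

    # per-cell draws, in a fixed order so outputs are seed-reproducible
    theta = np.deg2rad(rng.normal(0.0, spec.orientation_jitter_deg, size=n))
    intens = {}
    for ch in ("hoechst", "gfp"):
        vals = np.empty(n)
        for cls in ("macrophage", "fibroblast"):
            mean, sd = spec.channel_models[cls][ch]
            sel = (truth["cell_class"] == cls).to_numpy()
            vals[sel] = rng.normal(mean, sd, size=int(sel.sum()))
        intens[ch] = np.clip(vals, 0.0, None)
    if has_edu:
        mean, sd = spec.edu_intensity
        intens["edu"] = np.clip(rng.normal(mean, sd, size=n), 0.0, None)

    a_px = spec.nucleus_major_um / 2.0 / px
    b_px = spec.nucleus_minor_um / 2.0 / px
    xs = truth["x_um"].to_numpy() / px
    ys = truth["y_um"].to_numpy() / px
    edu_flags = truth["edu_label"].to_numpy()
    for i in range(n):
        _paint_ellipse(imgs["hoechst"], xs[i], ys[i], a_px, b_px, theta[i],
                       intens["hoechst"][i])
        _paint_ellipse(imgs["gfp"], xs[i], ys[i], a_px, b_px, theta[i],
                       intens["gfp"][i])
        if has_edu and edu_flags[i]:
            _paint_ellipse(imgs["edu"], xs[i], ys[i], a_px, b_px, theta[i],
                           intens["edu"][i])

    if spec.background_sd > 0:
        for c in channels:
            imgs[c] = np.clip(
                imgs[c] + rng.normal(0.0, spec.background_sd, size=shape),
                0.0, None)

    polylines = {}
    if spec.anterior_polyline is not None:
        polylines["anterior"] = np.asarray(spec.anterior_polyline, float)
    if spec.posterior_polyline is not None:
        polylines["posterior"] = np.asarray(spec.posterior_polyline, float)
    image = SectionImage(
        channels=imgs, pixel_size_um=px,
        polygons={"fascicle": np.asarray(spec.fascicle_polygon, float)},
        polylines=polylines,
        meta={"seed": spec.seed})
    return image, truth


# ---------------------------------------------------------------------------
# duplex ISH generation
# ---------------------------------------------------------------------------

def _uniform_in_polygon(poly: Polygon, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    k = 0
    while k < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(n - k, 8), 2))
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        m = int(keep.sum())
        out[k:k + m] = cand[keep][: n - k]
        k += min(m, n - k)
    return out


def _stamp_disks(amount: np.ndarray, centers_px: np.ndarray,
                 radius_px: float, od_each: np.ndarray) -> None:
    h, w = amount.shape
    r = int(math.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (xx * xx + yy * yy) <= radius_px * radius_px
    for (cx, cy), od in zip(centers_px, od_each):
        x0, y0 = int(round(cx)) - r, int(round(cy)) - r
        xs0, ys0 = max(x0, 0), max(y0, 0)
        xs1, ys1 = min(x0 + 2 * r + 1, w), min(y0 + 2 * r + 1, h)
        if xs0 >= xs1 or ys0 >= ys1:
            continue
        sub = disk[ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0]
        amount[ys0:ys1, xs0:xs1][sub] += od


def beer_lambert(amounts: np.ndarray, stain_od_matrix: np.ndarray,
                 background_white) -> np.ndarray:
    """Mix stain amounts into transmitted RGB by the Beer-Lambert law.

    I_c = I0_c * 10**(-sum_s M[c, s] * A_s) per pixel; ``amounts`` has
    shape (n_stains, H, W), the result (H, W, 3).
    """
    M = np.asarray(stain_od_matrix, dtype=float)
    od = np.einsum("cs,shw->chw", M, np.asarray(amounts, dtype=float))
    i0 = np.asarray(background_white, dtype=float).reshape(3, 1, 1)
    return np.moveaxis(i0 * np.power(10.0, -od), 0, -1)


def generate_duplex_ish(spec: IshSpec) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Render an RGB duplex ISH image by Beer-Lambert mixing.

    Returns ``(rgb, truth, extras)`` where ``rgb`` is a float array of
    shape (H, W, 3) on the 0..I0 scale, ``truth`` records each cell's
    class, position and stain load, and ``extras`` carries the per-stain
    amount rasters (keys ``amount_green``, ``amount_red``,
    ``amount_counter``) for closure testing.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    poly = require_simple_polygon(spec.roi_polygon)
    area_mm2 = poly.area / 1e6

    n_total = int(rng.poisson(spec.cell_density_per_mm2 * area_mm2))
    n_mac = int(rng.binomial(n_total, spec.macrophage_fraction))
    n_fib = n_total - n_mac

    fib_xy = _uniform_in_polygon(poly, n_fib, rng)
    csf1_high = rng.uniform(size=n_fib) < spec.csf1_high_fraction
    high_xy = fib_xy[csf1_high]

    mac_xy = np.empty((n_mac, 2))
    for i in range(n_mac):
        if len(high_xy) and rng.uniform() < spec.coloc_kappa:
            anchor = high_xy[rng.integers(len(high_xy))]
            for _ in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                rad = spec.adjacency_radius_um * math.sqrt(rng.uniform())
                cand = anchor + rad * np.array([math.cos(ang), math.sin(ang)])
                if poly.contains(Point(*cand)):
                    mac_xy[i] = cand
                    break
            else:
                mac_xy[i] = _uniform_in_polygon(poly, 1, rng)[0]
        else:
            mac_xy[i] = _uniform_in_polygon(poly, 1, rng)[0]

    px = spec.pixel_size_um
    shape = (int(round(spec.height_um / px)), int(round(spec.width_um / px)))
    a_green = np.zeros(shape)
    a_red = np.zeros(shape)
    a_counter = np.zeros(shape)

    def render_expression(amount, centers_um, expr_levels):
        loads = np.zeros(len(centers_um))
        for j, (c, e) in enumerate(zip(centers_um, expr_levels)):
            k = int(rng.poisson(spec.puncta_per_expression_unit * e))
            if k == 0:
                continue
            offsets = rng.normal(0.0, 4.0, size=(k, 2))
            pts = (c + offsets) / px
            ods = np.full(k, spec.punctum_od)
            _stamp_disks(amount, pts, spec.punctum_radius_um / px, ods)
            loads[j] = k * spec.punctum_od
        return loads

    mac_expr = rng.lognormal(0.0, 0.3, size=n_mac)
    fib_expr = np.zeros(n_fib)
    fib_expr[csf1_high] = rng.lognormal(0.0, 0.3, size=int(csf1_high.sum()))

    green_load = render_expression(a_green, mac_xy, mac_expr)
    red_load_high = render_expression(a_red, fib_xy[csf1_high],
                                      fib_expr[csf1_high])
    red_load = np.zeros(n_fib)
    red_load[csf1_high] = red_load_high

    all_xy = np.vstack([mac_xy, fib_xy]) if n_total else np.empty((0, 2))
    _stamp_disks(a_counter, all_xy / px, spec.nucleus_radius_um / px,
                 np.full(n_total, spec.nucleus_od))

    amounts = np.stack([a_green, a_red, a_counter])       # (3, H, W)
    rgb = beer_lambert(amounts, spec.stain_od_matrix, spec.background_white)
    if spec.noise_sd > 0:
        rgb = np.clip(rgb + rng.normal(0, spec.noise_sd, rgb.shape), 0, None)

    truth = pd.DataFrame({
        "cell_id": np.arange(n_total),
        "x_um": all_xy[:, 0], "y_um": all_xy[:, 1],
        "cell_class": ["macrophage"] * n_mac + ["fibroblast"] * n_fib,
        "csf1_high": [False] * n_mac + list(csf1_high),
        "stain_load_green": np.concatenate([green_load, np.zeros(n_fib)]),
        "stain_load_red": np.concatenate([np.zeros(n_mac), red_load]),
    })
    extras = {"amount_green": a_green, "amount_red": a_red,
              "amount_counter": a_counter}
    return rgb, truth, extras


def generate_single_color_controls(spec: IshSpec) -> dict[str, np.ndarray]:
    """Render the three single-stain control images for vector estimation.

    Each control contains only one stain at graded amounts (plus clean
    background), so the optical-density direction of every stained pixel
    is exactly the generating column.
    """
    spec.validate()
    i0 = np.asarray(spec.background_white, float).reshape(1, 1, 3)
    controls = {}
    names = ("green", "red", "counter")
    for k, name in enumerate(names):
        amount = np.zeros((64, 64))
        # graded patches keep max OD < 1.5 so no channel clips below 1
        amount[8:24, 8:56] = 0.4
        amount[32:48, 8:56] = 1.0
        od = spec.stain_od_matrix[:, k].reshape(1, 1, 3) * amount[..., None]
        controls[name] = i0 * np.power(10.0, -od)
    return controls


# ---------------------------------------------------------------------------
# suspension generation
# ---------------------------------------------------------------------------

def generate_suspension(spec: SuspensionSpec) -> pd.DataFrame:
    """Draw a per-cell marker-intensity table with hidden truth columns.

    Output columns: one intensity per channel in ``MARKER_CHANNELS``
    plus ``true_class`` and per-marker ``true_*`` state booleans.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_fractions)
    probs = np.array([spec.class_fractions[c] for c in classes])
    cls_idx = rng.choice(len(classes), size=spec.n_cells, p=probs)
    cls = np.array(classes, dtype=object)[cls_idx]

    out = {"true_class": cls}
    states = {}
    for ch in ("CFP", "CD206", "F4/80"):
        state = np.zeros(spec.n_cells, dtype=bool)
        inten = np.zeros(spec.n_cells)
        for ci, cname in enumerate(classes):
            sel = cls_idx == ci
            m = spec.marker_models[cname][ch]
            k = int(sel.sum())
            s = rng.uniform(size=k) < m.p_pos
            vals = np.where(s, rng.normal(m.pos_mean, m.pos_sd, k),
                            rng.normal(m.neg_mean, m.neg_sd, k))
            state[sel] = s
            inten[sel] = np.clip(vals, 0.0, None)
        states[ch] = state
        out[ch] = inten
        out[f"true_{ch}"] = state

    # DQ state: class-conditional, with the macrophage rate split by
    # CD206 state (CD206-dependent collagen internalization)
    dq_p = np.empty(spec.n_cells)
    for ci, cname in enumerate(classes):
        sel = cls_idx == ci
        if cname == "macrophage":
            p_pos = spec.dq_positive_prob["macrophage"]
            p_neg = spec.dq_positive_prob_cd206neg_macrophage
            dq_p[sel] = np.where(states["CD206"][sel], p_pos, p_neg)
        else:
            dq_p[sel] = spec.dq_positive_prob[cname]
    dq_state = rng.uniform(size=spec.n_cells) < dq_p
    pm, ps, nm, ns = spec.dq_intensity
    dq_vals = np.where(dq_state,
                       rng.normal(pm, ps, spec.n_cells),
                       rng.normal(nm, ns, spec.n_cells))
    out["DQ"] = np.clip(dq_vals, 0.0, None)
    out["true_DQ"] = dq_state

    df = pd.DataFrame(out)
    df.insert(0, "cell_id", np.arange(spec.n_cells))
    return df


# ---------------------------------------------------------------------------
# CT matrix generation
# ---------------------------------------------------------------------------

def generate_ct_matrix(spec: QpcrSpec) -> tuple[pd.DataFrame, pd.DataFrame,
                                                pd.DataFrame]:
    """Emit a raw CT table with technical duplicate columns.

    Returns ``(ct_raw, sample_meta, truth)``:

    * ``ct_raw`` — genes x (samples x 2) CT values, columns named
      ``<sample_id>::d1`` / ``::d2``; values above the detection limit
      are missing (NaN).
    * ``sample_meta`` — one row per duplicate column (sample_id,
      population, tissue, age, replicate, duplicate).
    * ``truth`` — the generating dCT offset per gene x group.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_panel) + [g for g in spec.housekeeping_genes
                                     if g not in spec.gene_panel]
    samples = []
    for pop in spec.populations:
        for tis in spec.tissues:
            for age in spec.ages:
                for rep in range(1, spec.n_samples_per_group + 1):
                    samples.append((f"{pop}_{tis}_{age}_r{rep}",
                                    pop, tis, age, rep))

    data = {}
    meta_rows = []
    for sid, pop, tis, age, rep in samples:
        base_ct = {}
        for g in genes:
            if g in spec.housekeeping_genes:
                level = spec.housekeeping_levels.get(g, spec.ct_baseline)
                ct = level + rng.normal(0.0, spec.noise_sd)
            else:
                offset = spec.gene_panel[g].get((pop, tis, age), 0.0)
                ct = spec.ct_baseline - offset + rng.normal(0.0, spec.noise_sd)
            base_ct[g] = ct
        for dup in (1, 2):
            col = f"{sid}::d{dup}"
            vals = []
            for g in genes:
                ct = base_ct[g] + rng.normal(0.0, spec.duplicate_jitter_sd)
                vals.append(np.nan if ct > spec.detection_limit_ct else ct)
            data[col] = vals
            meta_rows.append({"column": col, "sample_id": sid,
                              "population": pop, "tissue": tis, "age": age,
                              "replicate": rep, "duplicate": dup})

    ct_raw = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    sample_meta = pd.DataFrame(meta_rows)
    truth_rows = [
        {"gene": g, "population": pop, "tissue": tis, "age": age,
         "offset": spec.gene_panel[g].get((pop, tis, age), 0.0)}
        for g in spec.gene_panel
        for pop in spec.populations
        for tis in spec.tissues
        for age in spec.ages]
    truth = pd.DataFrame(truth_rows)
    return ct_raw, sample_meta, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _abundance_preset(frac: float, density: float, note: str,
                      seed: int = 0) -> SectionSpec:
    return SectionSpec(
        width_um=2600.0, height_um=1280.0,
        fascicle_polygon=_rect_polygon(50.0, 40.0, 2550.0, 1240.0),
        anterior_polyline=np.array([[50.0, 40.0], [2550.0, 40.0]]),
        posterior_polyline=np.array([[50.0, 1240.0], [2550.0, 1240.0]]),
        cell_density_per_mm2=density,
        macrophage_fraction=frac,
        seed=seed,
        notes={"macrophage_fraction": note,
               "cell_density_per_mm2":
                   "free parameter; total cell density declines during "
                   "postnatal matrix-driven growth, so presets decrease "
                   "with age"},
    )


def _qpcr_panel() -> dict:
    """Gene panel with per-group dCT offsets for the qpcr-study preset."""
    pops = ("macrophage", "fibroblast")
    tissues = ("limb", "tail")
    ages = ("P14", "P56")

    def groups(pop=None, tissue=None, age=None, value=0.0):
        return {(p, t, a): value
                for p in (pops if pop is None else (pop,))
                for t in (tissues if tissue is None else (tissue,))
                for a in (ages if age is None else (age,))}

    def merge(*ds):
        out = {}
        for d in ds:
            for k, v in d.items():
                out[k] = out.get(k, 0.0) + v
        return out

    panel = {}
    # classical macrophage markers: high in macrophages everywhere
    for g in ("Adgre1", "Mrc1", "Csf1r", "Cx3cr1", "C1qc", "Lyve1", "Folr2"):
        panel[g] = merge(groups(pop="macrophage", value=6.0),
                         groups(pop="fibroblast", value=-2.0))
    # fibroblast/tendon markers
    for g in ("Col1a1", "Scx", "Tnmd", "Prg4"):
        panel[g] = merge(groups(pop="fibroblast", value=6.0),
                         groups(pop="macrophage", value=-2.0))
    # cytokines up in aged macrophages
    for g in ("Tnf", "Il1b", "Il10"):
        panel[g] = merge(groups(pop="macrophage", age="P14", value=1.0),
                         groups(pop="macrophage", age="P56", value=3.5),
                         groups(pop="fibroblast", value=-1.0))
    # ligand-receptor axes (sender -> receiver)
    panel["Csf1"] = merge(groups(pop="fibroblast", age="P14", value=2.0),
                          groups(pop="fibroblast", age="P56", value=4.0))
    panel["Il6"] = groups(pop="fibroblast", value=2.0)
    panel["Il6ra"] = groups(pop="macrophage", value=3.0)
    panel["Cx3cl1"] = groups(pop="fibroblast", value=2.5)
    panel["Gas6"] = groups(pop="macrophage", value=3.0)
    panel["Axl"] = groups(pop="fibroblast", value=2.0)
    panel["Tgfb1"] = groups(pop="macrophage", value=3.0)
    panel["Tgfbr2"] = groups(pop="fibroblast", value=2.5)
    panel["Pdgfb"] = groups(pop="macrophage", value=2.5)
    panel["Pdgfra"] = groups(pop="fibroblast", value=4.0)
    # tissue divergence of limb vs tail macrophages
    panel["Ccr2"] = merge(groups(pop="macrophage", tissue="limb", value=3.0),
                          groups(pop="macrophage", tissue="tail", value=1.0))
    # undetectable across both populations -> exercises the exclusion rule
    panel["Il2"] = groups(value=-25.0)
    panel["Il2ra"] = groups(value=-25.0)
    # flagged manually in the study config (aberrant amplification)
    panel["Sema4c"] = groups(value=1.0)
    return panel


def _build_presets() -> dict:
    presets: dict[str, object] = {}
    pct_note = ("reported mean GFP-reporter-positive percentage among "
                "fascicle cells for this tendon and age")
    presets["P4-patellar"] = _abundance_preset(0.016, 3500.0, pct_note)
    presets["P14-patellar"] = _abundance_preset(
        0.035, 2500.0, "interpolated between the reported P4 and P56 "
        "patellar percentages (figure-only value)")
    presets["P28-patellar"] = _abundance_preset(
        0.055, 1800.0, "interpolated between the reported P4 and P56 "
        "patellar percentages (figure-only value)")
    presets["P56-patellar"] = _abundance_preset(0.079, 1200.0, pct_note)
    presets["P4-achilles"] = _abundance_preset(0.014, 3500.0, pct_note)
    presets["P56-achilles"] = _abundance_preset(0.048, 1200.0, pct_note)

    p1 = SectionSpec(
        width_um=900.0, height_um=420.0,
        fascicle_polygon=_rect_polygon(40.0, 35.0, 860.0, 385.0),
        anterior_polyline=np.array([[40.0, 35.0], [860.0, 35.0]]),
        posterior_polyline=np.array([[40.0, 385.0], [860.0, 385.0]]),
        cell_density_per_mm2=4500.0,
        macrophage_fraction=0.016,
        edu_fraction_macrophage=0.50,
        edu_fraction_fibroblast=0.20,
        notes={"edu_fraction_macrophage":
                   "reported macrophage:fibroblast proliferation-rate "
                   "ratio of 2.5 pins the ratio of the two labelling "
                   "fractions; absolute levels are free parameters for "
                   "the highly proliferative neonatal tendon",
               "macrophage_fraction":
                   "neonatal value unreported; set to the earliest "
                   "reported (P4) percentage"},
    )
    presets["P1-edu"] = p1

    ish_common = dict(cell_density_per_mm2=2500.0, macrophage_fraction=0.2)
    presets["ish-colocalized"] = IshSpec(
        coloc_kappa=0.9, **ish_common,
        notes={"coloc_kappa": "models the reported macrophage placement "
                              "adjacent to Csf1-expressing fibroblasts; "
                              "density chosen so the grid correlation "
                              "matches the reported strength (~0.44)"})
    presets["ish-uniform"] = IshSpec(
        coloc_kappa=0.0, **ish_common,
        notes={"coloc_kappa": "uniform-placement null"})

    presets["explant-dq"] = SuspensionSpec(
        n_cells=40000,
        notes={"dq_positive_prob":
                   "reported DQ-collagen positivity: 75.4% of CD206+ "
                   "cells, 0.5% of Col1CFP+ cells",
               "marker_models":
                   "CD206+ and F4/80+ rates among CFP+ fibroblasts set "
                   "to the reported 0.4% and 1.3%"})

    presets["qpcr-study"] = QpcrSpec(
        gene_panel=_qpcr_panel(),
        notes={"design": "2 populations x 2 tissues x 2 ages x 5 "
                         "replicates = 40 samples loaded in duplicate"})
    return presets


_PRESETS = _build_presets()
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int | None = None):
    """Return a fully populated spec for a documented preset name."""
    if name not in _PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    spec = _PRESETS[name]
    spec = replace(spec)
    if seed is not None:
        spec.seed = seed
    return spec
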