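"""Duplex chromogenic ISH quantification.

Stain vectors are estimated from single-color control sections in
optical-density space (OD = -log10(I / I0), the Beer-Lambert transform),
the duplex image is linearly unmixed with the inverse stain matrix,
per-stain amounts are averaged on a 50 x 50 um grid inside the tendon
ROI, and grid-unit intensities are compared by Spearman rank
correlation.  Because ranks are invariant to monotone transforms, the
correlation is identical whether grid means are taken on amounts or on
inverted 8-bit renderings, which is why Spearman is the only statistic
offered here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .section import polygon_mask

__all__ = ["StainMatrix", "estimate_stain_vectors", "deconvolve",
           "grid_intensities", "coloc_spearman", "aggregate_sections"]

STAIN_NAMES = ("green", "red", "counter")


@dataclass
class StainMatrix:
    """Three unit optical-density column vectors and their conditioning."""

    matrix: np.ndarray          # (3, 3), columns = stains in STAIN_NAMES order

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(M, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain matrix columns must be unit-norm")
        self.matrix = M

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))


def optical_density(rgb: np.ndarray, background_white) -> np.ndarray:
    """Per-pixel OD = -log10(clip(I, 1, I0) / I0), shape (H, W, 3).

    The clip floor of 1 avoids log of zero on 8-bit-scaled images.
    """
    i0 = np.asarray(background_white, dtype=float).reshape(1, 1, 3)
    if (i0 <= 0).any():
        raise ValueError("background_white must be positive per channel")
    rgb = np.asarray(rgb, dtype=float)
    return -np.log10(np.clip(rgb, 1.0, i0) / i0)


def estimate_stain_vectors(control_images: dict[str, np.ndarray],
                           background_white,
                           od_floor: float = 0.05,
                           condition_bound: float = 50.0) -> StainMatrix:
    """Estimate the stain matrix from single-color control sections.

    For each control, the unit-normalized mean OD direction over pixels
    whose OD norm exceeds ``od_floor`` becomes that stain's column.
    """
    cols = []
    for name in STAIN_NAMES:
        if name not in control_images:
            raise KeyError(f"missing single-color control {name!r}")
        od = optical_density(control_images[name], background_white)
        norm = np.linalg.norm(od, axis=-1)
        sel = norm > od_floor
        if not sel.any():
            raise ValueError(f"control {name!r} has no stained pixels "
                             f"(no OD above {od_floor})")
        mean_od = od[sel].mean(axis=0)
        cols.append(mean_od / np.linalg.norm(mean_od))
    sm = StainMatrix(np.column_stack(cols))
    if sm.condition_number > condition_bound:
        raise ValueError(
            f"stain vectors are near-collinear (condition number "
            f"{sm.condition_number:.1f} > {condition_bound})")
    return sm


def deconvolve(rgb: np.ndarray, matrix: StainMatrix,
               background_white) -> dict[str, np.ndarray]:
    """Unmix an RGB image into per-stain amount rasters.

    A = M^-1 . OD per pixel; negative amounts are clipped to zero.
    Larger values mean stronger staining.
    """
    M = matrix.matrix
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValueError("stain matrix is singular")
    od = optical_density(rgb, background_white)
    amounts = np.einsum("sc,hwc->hws", np.linalg.inv(M), od)
    amounts = np.clip(amounts, 0.0, None)
    return {name: np.ascontiguousarray(amounts[..., k])
            for k, name in enumerate(STAIN_NAMES)}


def grid_intensities(rasters: dict[str, np.ndarray], roi_polygon: np.ndarray,
                     pixel_size_um: float, unit_um: float = 50.0,
                     min_coverage: float = 0.5) -> pd.DataFrame:
    """Mean channel intensities per 50 x 50 um grid unit inside the ROI.

    The grid is axis-aligned and anchored at the ROI bounding-box
    origin.  A unit is included iff at least ``min_coverage`` of its
    pixels lie inside the ROI; means are taken over in-ROI pixels only.
    """
    shapes = {r.shape for r in rasters.values()}
    if len(shapes) != 1:
        raise ValueError("all rasters must share one shape")
    shape = shapes.pop()
    roi = polygon_mask(roi_polygon, shape, pixel_size_um)
    poly = np.asarray(roi_polygon, dtype=float)
    x0_px = int(math.floor(poly[:, 0].min() / pixel_size_um))
    y0_px = int(math.floor(poly[:, 1].min() / pixel_size_um))
    x1_px = int(math.ceil(poly[:, 0].max() / pixel_size_um))
    y1_px = int(math.ceil(poly[:, 1].max() / pixel_size_um))
    unit_px = unit_um / pixel_size_um
    n_cols = max(int(math.ceil((x1_px - x0_px) / unit_px)), 1)
    n_rows = max(int(math.ceil((y1_px - y0_px) / unit_px)), 1)

    rows = []
    unit_area = int(round(unit_px)) ** 2
    for ur in range(n_rows):
        for uc in range(n_cols):
            ya = y0_px + int(round(ur * unit_px))
            yb = min(y0_px + int(round((ur + 1) * unit_px)), shape[0])
            xa = x0_px + int(round(uc * unit_px))
            xb = min(x0_px + int(round((uc + 1) * unit_px)), shape[1])
            ya, xa = max(ya, 0), max(xa, 0)
            if ya >= yb or xa >= xb:
                continue
            sub_roi = roi[ya:yb, xa:xb]
            n_in = int(sub_roi.sum())
            if n_in < min_coverage * unit_area:
                continue
            row = {"unit_row": ur, "unit_col": uc, "area_px": n_in}
            for name, raster in rasters.items():
                row[f"mean_{name}"] = float(raster[ya:yb, xa:xb][sub_roi].mean())
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 1:
        import warnings
        warnings.warn("ROI smaller than one grid unit; single-unit table",
                      stacklevel=2)
    return df


def _spearman_exact_p(a: np.ndarray, b: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of rank pairings (n <= 8)."""
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    n = len(ra)
    obs = abs(rho)
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = stats.spearmanr(ra, rb[list(perm)]).statistic
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def coloc_spearman(table: pd.DataFrame, channel_a: str,
                   channel_b: str) -> dict:
    """Spearman rank correlation between two grid channels.

    Tie-corrected ranks; exact two-sided p by enumeration for n <= 8
    grid units, asymptotic beyond.  A constant channel yields an
    undefined (NaN) correlation.
    """
    a = table[f"mean_{channel_a}"].to_numpy(dtype=float)
    b = table[f"mean_{channel_b}"].to_numpy(dtype=float)
    n = len(a)
    if n < 5:
        raise ValueError("need >= 5 grid units for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return {"rho": float("nan"), "p": float("nan"), "n_units": n}
    res = stats.spearmanr(a, b)
    rho = float(res.statistic)
    if n <= 8:
        p = _spearman_exact_p(a, b, rho)
    else:
        p = float(res.pvalue)
    return {"rho": rho, "p": p, "n_units": n}


def aggregate_sections(per_section: list[dict]) -> dict:
    """Arithmetic mean of per-section rho and of per-section p."""
    rhos = [s["rho"] for s in per_section if np.isfinite(s["rho"])]
    ps = [s["p"] for s in per_section if np.isfinite(s["p"])]
    return {
        "n_sections": len(per_section),
        "mean_rho": float(np.mean(rhos)) if rhos else float("nan"),
        "mean_p": float(np.mean(ps)) if ps else float("nan"),
    }
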