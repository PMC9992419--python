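"""Euclidean-distance-map depth profiling.

Each pixel of the EDM holds the distance (um) to the nearest point on
either the anterior or posterior tendon surface polyline.  A cell's
depth is the mean EDM over its nuclear mask; depths are normalized by
the maximum in-ROI EDM value and binned into four quartiles, Q1 being
the outermost.  Enrichment ratios divide each quartile's positive
percentage by the whole-section positive percentage, so a spatially
uniform population has all ratios equal to 1.

Distances are computed in floating point rather than quantized to a
16-bit raster; the quantized depth map of interactive tooling is an
implementation artifact, not part of the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from .section import polygon_mask
from .stats import compare_groups

__all__ = ["DepthProfile", "build_edm", "assign_depth", "quartile_profile",
           "test_uniformity"]

QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class DepthProfile:
    section_id: str
    edm_max_um: float
    n_pos: dict = field(default_factory=dict)       # quartile -> count
    n_neg: dict = field(default_factory=dict)
    pct_pos: dict = field(default_factory=dict)     # % positive within q
    ratio_pos: dict = field(default_factory=dict)   # pct_pos_q / pct_pos_whole
    ratio_neg: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "section_id": self.section_id, "quartile": q,
            "edm_max_um": self.edm_max_um,
            "n_pos": self.n_pos[q], "n_neg": self.n_neg[q],
            "pct_pos": self.pct_pos[q],
            "ratio_pos": self.ratio_pos[q], "ratio_neg": self.ratio_neg[q],
        } for q in QUARTILES]
        return pd.DataFrame(rows)


def _segment_distances(px_points: np.ndarray, polyline_px: np.ndarray,
                       ) -> np.ndarray:
    """Min distance from each (x, y) point to a polyline's segments."""
    p = np.asarray(px_points, dtype=float)          # (N, 2)
    v = np.asarray(polyline_px, dtype=float)
    best = np.full(len(p), np.inf)
    for a, b in zip(v[:-1], v[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.hypot(*(p - a).T)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.hypot(*(p - proj).T)
        np.minimum(best, d, out=best)
    return best


def build_edm(shape: tuple[int, int], anterior_polyline: np.ndarray,
              posterior_polyline: np.ndarray,
              pixel_size_um: float) -> np.ndarray:
    """Distance raster (um) to the nearest point on either surface polyline.

    Distance is the true point-to-segment minimum over all segments of
    both polylines, evaluated at pixel centres; pixels crossed by the
    rasterized polylines are exactly zero.
    """
    for name, pl in (("anterior", anterior_polyline),
                     ("posterior", posterior_polyline)):
        pl = np.asarray(pl, dtype=float)
        if pl.ndim != 2 or pl.shape[0] < 2:
            raise ValueError(f"{name} polyline needs >= 2 vertices")
        px = pl / pixel_size_um
        if (px < -0.5).any() or (px[:, 0] > shape[1] - 0.5).any() \
                or (px[:, 1] > shape[0] - 0.5).any():
            raise ValueError(f"{name} polyline lies outside the raster")

    h, w = shape
    edm = np.empty(shape, dtype=np.float64)
    xs = np.arange(w, dtype=float)
    chunk = max(1, int(2e6 // max(w, 1)))
    for y0 in range(0, h, chunk):
        y1 = min(y0 + chunk, h)
        yy, xx = np.mgrid[y0:y1, 0:w]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        d = np.minimum(
            _segment_distances(pts, np.asarray(anterior_polyline) / pixel_size_um),
            _segment_distances(pts, np.asarray(posterior_polyline) / pixel_size_um))
        edm[y0:y1] = d.reshape(y1 - y0, w)
    edm *= pixel_size_um

    # exact zero on rasterized polyline pixels
    for pl in (anterior_polyline, posterior_polyline):
        px = np.asarray(pl, dtype=float) / pixel_size_um
        for a, b in zip(px[:-1], px[1:]):
            rr, cc = draw_line(int(round(a[1])), int(round(a[0])),
                               int(round(b[1])), int(round(b[0])))
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            edm[rr[keep], cc[keep]] = 0.0
    return edm


def assign_depth(records: pd.DataFrame, labels: np.ndarray, edm: np.ndarray,
                 roi_polygon: np.ndarray,
                 pixel_size_um: float) -> tuple[pd.DataFrame, float]:
    """Attach ``depth_um`` (mean EDM over the nuclear mask) and ``d_norm``.

    ``d_norm`` = depth / EDM_max, with EDM_max the maximum EDM over
    in-ROI pixels (the deepest point of the map, not of any cell).
    """
    if labels.shape != edm.shape:
        raise ValueError("labels and EDM must share shape")
    roi = polygon_mask(roi_polygon, edm.shape, pixel_size_um)
    edm_max = float(edm[roi].max()) if roi.any() else 0.0
    if edm_max <= 0:
        raise ValueError("EDM_max is zero inside the ROI")

    out = records.copy()
    idx = out["label"].to_numpy()
    depth = ndi.mean(edm, labels, idx)
    out["depth_um"] = depth
    out["d_norm"] = np.clip(depth / edm_max, 0.0, 1.0)
    return out, edm_max


def quartile_profile(records: pd.DataFrame, flag: str = "gfp_pos",
                     edm_max_um: float = float("nan"),
                     section_id: str = "section",
                     convention: str = "composition") -> DepthProfile:
    """Bin cells into normalized-depth quartiles and compute enrichment.

    Bins: Q1=[0, .25), Q2=[.25, .5), Q3=[.5, .75), Q4=[.75, 1] (closed
    upper edge); Q1 is the outermost increment.

    ``convention="composition"`` (default): pct_pos_q is the percentage
    of positive cells among cells in the quartile, and the ratio divides
    it by the whole-section positive percentage.
    ``convention="population"``: the alternative reading — the fraction
    of the positive population falling in the quartile, divided by the
    fraction of all cells falling in the quartile (identical ratios,
    different pct bookkeeping).
    """
    if len(records) == 0:
        raise ValueError("empty record set")
    if convention not in ("composition", "population"):
        raise ValueError(f"unknown convention {convention!r}")
    d = records["d_norm"].to_numpy()
    pos = records[flag].to_numpy().astype(bool)
    qidx = np.clip((d * 4).astype(int), 0, 3)       # d_norm = 1 -> Q4

    n_pos, n_neg, pct_pos, ratio_pos, ratio_neg = {}, {}, {}, {}, {}
    n_all = len(records)
    pos_all = int(pos.sum())
    pct_whole_pos = 100.0 * pos_all / n_all
    pct_whole_neg = 100.0 - pct_whole_pos
    for k, q in enumerate(QUARTILES):
        sel = qidx == k
        nq = int(sel.sum())
        npos = int(pos[sel].sum())
        nneg = nq - npos
        n_pos[q] = npos
        n_neg[q] = nneg
        if convention == "composition":
            pq = 100.0 * npos / nq if nq else float("nan")
            pct_pos[q] = pq
            ratio_pos[q] = (pq / pct_whole_pos
                            if nq and pct_whole_pos > 0 else float("nan"))
            qn = 100.0 * nneg / nq if nq else float("nan")
            ratio_neg[q] = (qn / pct_whole_neg
                            if nq and pct_whole_neg > 0 else float("nan"))
        else:
            frac_pos_q = npos / pos_all if pos_all else float("nan")
            frac_all_q = nq / n_all
            pct_pos[q] = 100.0 * frac_pos_q if pos_all else float("nan")
            ratio_pos[q] = (frac_pos_q / frac_all_q
                            if frac_all_q > 0 and pos_all else float("nan"))
            neg_all = n_all - pos_all
            frac_neg_q = nneg / neg_all if neg_all else float("nan")
            ratio_neg[q] = (frac_neg_q / frac_all_q
                            if frac_all_q > 0 and neg_all else float("nan"))
    return DepthProfile(section_id=section_id, edm_max_um=edm_max_um,
                        n_pos=n_pos, n_neg=n_neg, pct_pos=pct_pos,
                        ratio_pos=ratio_pos, ratio_neg=ratio_neg)


def test_uniformity(profiles_by_animal: dict[str, list[DepthProfile]],
                    population: str = "pos") -> dict:
    """ANOVA/Tukey across the four quartiles on per-animal mean ratios.

    Animals with any empty quartile (NaN ratio) are excluded with a
    warning entry in the report.
    """
    if len(profiles_by_animal) < 2:
        raise ValueError("need >= 2 animals")
    attr = "ratio_pos" if population == "pos" else "ratio_neg"
    per_quartile: dict[str, list[float]] = {q: [] for q in QUARTILES}
    excluded = []
    for animal, profiles in profiles_by_animal.items():
        means = {}
        ok = True
        for q in QUARTILES:
            vals = [getattr(p, attr)[q] for p in profiles]
            m = float(np.mean(vals))
            if not np.isfinite(m):
                ok = False
                break
            means[q] = m
        if not ok:
            excluded.append(animal)
            continue
        for q in QUARTILES:
            per_quartile[q].append(means[q])
    report = compare_groups(per_quartile)
    report["population"] = population
    report["excluded_animals"] = excluded
    return report
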