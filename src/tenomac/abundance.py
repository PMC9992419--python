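"""Reporter-positive abundance and density within the fascicle ROI.

Only cells whose centroid lies strictly inside the manually drawn
fascicle polygon are counted — the peritenon, which carries its own
dense macrophage population, is excluded from all abundance statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .section import require_simple_polygon
from .stats import compare_groups  # noqa: F401  (re-exported surface)

__all__ = ["AbundanceResult", "quantify_section", "compare_groups",
           "in_roi_mask"]


@dataclass
class AbundanceResult:
    section_id: str
    n_total: int
    n_pos: int
    pct_pos: float          # NaN when n_total == 0
    density_total: float    # cells / mm^2
    density_pos: float
    density_neg: float
    roi_area_mm2: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def in_roi_mask(records: pd.DataFrame, polygon_um: np.ndarray) -> np.ndarray:
    """Boolean mask of records whose centroid is strictly inside the ROI."""
    poly = require_simple_polygon(polygon_um, "fascicle_polygon")
    return shapely.contains_xy(poly, records["x_um"].to_numpy(),
                               records["y_um"].to_numpy())


def quantify_section(records: pd.DataFrame, fascicle_polygon: np.ndarray,
                     flag: str = "gfp_pos",
                     section_id: str = "section") -> AbundanceResult:
    """Count positive/total cells inside the fascicle and derive densities.

    ``flag`` names the boolean positivity column of ``records``.
    Densities are cells per mm^2 of ROI area (um^2 / 1e6).
    """
    poly: Polygon = require_simple_polygon(fascicle_polygon,
                                           "fascicle_polygon")
    area_mm2 = poly.area / 1e6
    if area_mm2 <= 0:
        raise ValueError("fascicle polygon has zero area")

    inside = in_roi_mask(records, fascicle_polygon)
    sub = records.loc[inside]
    n_total = int(len(sub))
    n_pos = int(sub[flag].sum()) if n_total else 0
    pct = 100.0 * n_pos / n_total if n_total else float("nan")
    return AbundanceResult(
        section_id=section_id,
        n_total=n_total,
        n_pos=n_pos,
        pct_pos=pct,
        density_total=n_total / area_mm2,
        density_pos=n_pos / area_mm2,
        density_neg=(n_total - n_pos) / area_mm2,
        roi_area_mm2=area_mm2,
    )
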