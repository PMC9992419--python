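"""Core in-memory containers for section images and regions of interest.

All physical coordinates are micrometres, 0-based, y-down.  Pixel
coordinates never leave module boundaries: conversion happens at the
edge of every operation that touches a raster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon


@dataclass
class SectionImage:
    """Multi-channel raster with physical calibration and named ROIs.

    Parameters
    ----------
    channels
        Mapping channel name -> 2-D float array.  All channels share one
        shape (rows = y, cols = x).
    pixel_size_um
        Physical size of one pixel edge, micrometres per pixel.
    polygons
        Named closed ROI polygons, each an (N, 2) array of (x, y) in um.
    polylines
        Named open polylines (e.g. anterior/posterior tendon surfaces),
        each an (N, 2) array of (x, y) in um.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    polygons: dict[str, np.ndarray] = field(default_factory=dict)
    polylines: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def um_to_px(self, coords_um: np.ndarray) -> np.ndarray:
        """Convert (x, y) um coordinates to fractional pixel coordinates."""
        return np.asarray(coords_um, dtype=float) / self.pixel_size_um

    def px_to_um(self, coords_px: np.ndarray) -> np.ndarray:
        return np.asarray(coords_px, dtype=float) * self.pixel_size_um


def polygon_mask(polygon_um: np.ndarray, shape: tuple[int, int],
                 pixel_size_um: float) -> np.ndarray:
    """Boolean raster mask of pixels whose centres lie inside the polygon."""
    from skimage.draw import polygon2mask

    poly = np.asarray(polygon_um, dtype=float) / pixel_size_um
    # polygon2mask wants (row, col) = (y, x); pixel centre at integer index
    return polygon2mask(shape, poly[:, ::-1])


def require_simple_polygon(polygon_um: np.ndarray, name: str = "polygon") -> Polygon:
    """Validate a closed polygon and return it as a shapely object."""
    arr = np.asarray(polygon_um, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError(f"{name} must be an (N>=3, 2) coordinate array")
    poly = Polygon(arr)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"{name} must be a simple (non-self-intersecting) "
                         "polygon with positive area")
    return poly
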