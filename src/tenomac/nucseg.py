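"""Nuclear segmentation, per-nucleus measurement, and reporter classification.

The nuclear channel is globally thresholded (Otsu by default), touching
nuclei are split by a watershed seeded from maxima of the internal
distance transform, and components outside physical area bounds are
removed.  Measurements are per-label channel means; classification is a
single run-level intensity threshold applied uniformly to every image of
a comparison set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.segmentation import watershed

from .section import SectionImage

__all__ = ["segment_nuclei", "measure_nuclei", "classify_by_threshold",
           "segment_and_measure"]

THRESHOLD_MODES = ("otsu", "fixed")


def segment_nuclei(hoechst: np.ndarray, pixel_size_um: float,
                   min_area_um2: float = 8.0, max_area_um2: float = 200.0,
                   threshold_mode: str = "otsu",
                   threshold: float | None = None,
                   seed_min_distance_um: float = 2.0,
                   seed_smooth_um: float = 1.5) -> np.ndarray:
    """Segment nuclei from a single-channel raster into a label image.

    Parameters
    ----------
    hoechst
        Calibrated nuclear-stain channel.
    min_area_um2, max_area_um2
        Physical area bounds; components outside are discarded.
    threshold_mode
        ``"otsu"`` (automatic global threshold) or ``"fixed"`` (use
        ``threshold``).
    seed_min_distance_um
        Minimum separation of watershed seeds, in um.

    Returns
    -------
    Integer label image; background is 0.
    """
    if threshold_mode not in THRESHOLD_MODES:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}; "
                         f"expected one of {THRESHOLD_MODES}")
    if not 0 < min_area_um2 < max_area_um2:
        raise ValueError("need 0 < min_area_um2 < max_area_um2")
    hoechst = np.asarray(hoechst, dtype=float)

    if hoechst.max() == hoechst.min():
        return np.zeros(hoechst.shape, dtype=np.int32)
    if threshold_mode == "fixed":
        if threshold is None:
            raise ValueError("threshold_mode='fixed' requires a threshold")
        thr = float(threshold)
    else:
        thr = float(threshold_otsu(hoechst))
    fg = hoechst > thr
    if not fg.any():
        return np.zeros(hoechst.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(fg)
    # smoothing collapses the flat medial ridge of elongated nuclei to a
    # single regional maximum; without it every plateau point seeds
    smooth = ndi.gaussian_filter(distance, seed_smooth_um / pixel_size_um) \
        if seed_smooth_um > 0 else distance
    min_dist_px = max(int(round(seed_min_distance_um / pixel_size_um)), 1)
    peaks = peak_local_max(smooth, min_distance=min_dist_px, labels=fg,
                           exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # components without any peak (thin slivers) keep one marker so the
    # watershed covers every foreground component
    comp, n_comp = ndi.label(fg)
    has_peak = np.zeros(n_comp + 1, dtype=bool)
    has_peak[comp[tuple(peaks.T)]] = True
    missing = np.nonzero(~has_peak[1:])[0] + 1
    if missing.size:
        pos = ndi.maximum_position(distance, comp, missing)
        for k, p in enumerate(np.atleast_2d(pos)):
            markers[tuple(p)] = len(peaks) + 1 + k
    labels = watershed(-distance, markers, mask=fg).astype(np.int32)

    px_area = pixel_size_um ** 2
    sizes = np.bincount(labels.ravel())
    bad = np.nonzero((sizes * px_area < min_area_um2) |
                     (sizes * px_area > max_area_um2))[0]
    bad = bad[bad != 0]
    if bad.size:
        labels[np.isin(labels, bad)] = 0
    # relabel densely, preserving order
    uniq = np.unique(labels)
    uniq = uniq[uniq != 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[uniq] = np.arange(1, len(uniq) + 1)
    return lut[labels]


def measure_nuclei(labels: np.ndarray, channels: dict[str, np.ndarray],
                   pixel_size_um: float) -> pd.DataFrame:
    """Measure one record per label: centroid (um), area (um^2), and the
    mean intensity of every channel over the label's pixels.

    Also flags ``on_border`` for labels touching the raster edge.
    """
    for name, ch in channels.items():
        if ch.shape != labels.shape:
            raise ValueError(f"channel {name!r} shape {ch.shape} does not "
                             f"match labels shape {labels.shape}")
    n = int(labels.max())
    if n == 0:
        cols = ["label", "x_um", "y_um", "area_um2", "on_border"]
        cols += [f"mean_{c}" for c in channels]
        return pd.DataFrame(columns=cols)

    props = regionprops_table(labels, properties=("label", "centroid", "area"))
    df = pd.DataFrame({
        "label": props["label"],
        "x_um": props["centroid-1"] * pixel_size_um,
        "y_um": props["centroid-0"] * pixel_size_um,
        "area_um2": props["area"] * pixel_size_um ** 2,
    })
    idx = df["label"].to_numpy()
    for name, ch in channels.items():
        df[f"mean_{name}"] = ndi.mean(np.asarray(ch, float), labels, idx)

    border = np.zeros(n + 1, dtype=bool)
    for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
        border[np.unique(edge)] = True
    df["on_border"] = border[idx]
    return df


def classify_by_threshold(records: pd.DataFrame, channel: str,
                          threshold: float,
                          flag: str | None = None) -> pd.DataFrame:
    """Set a boolean positivity flag from a run-level intensity threshold.

    The same threshold must be applied to every image of a comparison
    set; callers pass it once per run, never per image.
    """
    col = f"mean_{channel}"
    if col not in records.columns:
        raise KeyError(f"channel {channel!r} not measured in records")
    if not np.isfinite(threshold):
        if threshold == np.inf:
            out = records.copy()
            out[flag or f"{channel}_pos"] = False
            return out
        raise ValueError("threshold must be finite or +inf")
    out = records.copy()
    out[flag or f"{channel}_pos"] = out[col] > threshold
    return out


def segment_and_measure(image: SectionImage, nuclear_channel: str = "hoechst",
                        **seg_kwargs) -> tuple[np.ndarray, pd.DataFrame]:
    """Convenience: segment the nuclear channel and measure all channels."""
    labels = segment_nuclei(image.channels[nuclear_channel],
                            image.pixel_size_um, **seg_kwargs)
    records = measure_nuclei(labels, image.channels, image.pixel_size_um)
    return labels, records
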