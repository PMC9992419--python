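"""File I/O: calibrated multi-channel TIFFs, ROI JSON, configs.

Images travel as multi-page TIFF with channel names and pixel size in
the image description; ROIs as JSON sidecars of the form
``{"polygons": {name: [[x, y], ...]}, "polylines": {...}}`` in um
coordinates, 0-based, y-down.  Tabular results are CSV, reports JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .section import SectionImage

__all__ = ["write_section", "read_section", "write_roi_json",
           "read_roi_json", "load_config", "write_report"]


def write_roi_json(path, polygons: dict, polylines: dict) -> None:
    payload = {
        "polygons": {k: np.asarray(v, float).tolist()
                     for k, v in polygons.items()},
        "polylines": {k: np.asarray(v, float).tolist()
                      for k, v in polylines.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_roi_json(path) -> tuple[dict, dict]:
    data = json.loads(Path(path).read_text())
    polygons = {k: np.asarray(v, float) for k, v in
                data.get("polygons", {}).items()}
    polylines = {k: np.asarray(v, float) for k, v in
                 data.get("polylines", {}).items()}
    return polygons, polylines


def write_section(image: SectionImage, path, roi_path=None) -> None:
    """Write a SectionImage as a multi-page float32 TIFF.

    Channel names and pixel size go into the TIFF description as JSON;
    ROIs go to ``roi_path`` (default: ``<path>.roi.json``).
    """
    path = Path(path)
    stack = np.stack([image.channels[c] for c in image.channel_names]
                     ).astype(np.float32)
    desc = json.dumps({
        "channels": image.channel_names,
        "pixel_size_um": image.pixel_size_um,
    }, sort_keys=True)
    tifffile.imwrite(path, stack, description=desc)
    if roi_path is None:
        roi_path = path.with_suffix(path.suffix + ".roi.json")
    write_roi_json(roi_path, image.polygons, image.polylines)


def read_section(path, pixel_size_um: float | None = None,
                 roi_path=None, channel_names: list[str] | None = None,
                 ) -> SectionImage:
    """Read a calibrated multi-channel TIFF into a SectionImage.

    A missing pixel size in the metadata is a hard error unless
    ``pixel_size_um`` overrides it; a channel-name list that does not
    match the page count is a hard error too.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
    except FileNotFoundError:
        raise
    except Exception as exc:   # corrupt/truncated files raise many types
        raise IOError(f"cannot read TIFF at {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    px = meta.get("pixel_size_um", pixel_size_um)
    if pixel_size_um is not None:
        px = pixel_size_um
    if px is None:
        raise ValueError(
            f"{path} carries no pixel-size metadata; pass pixel_size_um")
    names = channel_names or meta.get("channels")
    if names is None:
        names = [f"ch{i}" for i in range(stack.shape[0])]
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"{path}: {stack.shape[0]} channel pages but {len(names)} "
            "channel names configured")
    polygons, polylines = {}, {}
    if roi_path is None:
        candidate = path.with_suffix(path.suffix + ".roi.json")
        if candidate.exists():
            roi_path = candidate
    if roi_path is not None:
        polygons, polylines = read_roi_json(roi_path)
    return SectionImage(
        channels={n: stack[i].astype(np.float64)
                  for i, n in enumerate(names)},
        pixel_size_um=float(px), polygons=polygons, polylines=polylines)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if v != v else v      # NaN -> null for valid JSON
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(path, report: dict) -> None:
    """Write a machine-readable JSON report (sorted keys, NaN as null)."""
    Path(path).write_text(
        json.dumps(_jsonify(report), indent=1, sort_keys=True))
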