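"""Stage runner tying the quantification stages into a file pipeline.

Every stage reads its inputs from disk, writes CSV artifacts plus a
JSON report of all parameters actually used, and is byte-reproducible
from config + seed alone (reports carry no timestamps or machine
state).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import abundance, depthmap, internalization, ishcoloc, nucseg, qpcr
from . import proliferation as prolif
from . import synth
from .io import read_roi_json, read_section, write_report, write_section

STAGES = ("synth", "segment", "abundance", "depth", "edu", "ish", "qpcr",
          "internalize", "all")

__all__ = ["run_stage", "demo_config", "STAGES"]


def demo_config(seed: int = 0) -> dict:
    """A small, fast end-to-end configuration for smoke runs."""
    return {
        "seed": seed,
        "section": {
            "preset": "P1-edu",
            "n_sections": 2,
            "overrides": {"width_um": 420.0, "height_um": 240.0,
                          "cell_density_per_mm2": 1500.0,
                          "macrophage_fraction": 0.15},
        },
        "segment": {"min_area_um2": 8.0, "max_area_um2": 200.0,
                    "threshold_mode": "otsu"},
        "classify": {"gfp_threshold": 80.0, "edu_threshold": 100.0},
        "depth": {"convention": "composition"},
        "edu": {"sections_per_animal": 1},
        "ish": {"preset": "ish-colocalized", "n_sections": 1,
                "overrides": {"width_um": 220.0, "height_um": 220.0}},
        "qpcr": {"preset": "qpcr-study",
                 "overrides": {"n_samples_per_group": 3},
                 "manual_exclusions": ["Sema4c"],
                 "contrast": {
                     "a": {"population": "macrophage", "tissue": "limb",
                           "age": "P56"},
                     "b": {"population": "macrophage", "tissue": "limb",
                           "age": "P14"}}},
        "internalize": {"preset": "explant-dq",
                        "overrides": {"n_cells": 4000},
                        "thresholds": {"CFP": 100.0, "CD206": 100.0,
                                       "F4/80": 100.0, "DQ": 90.0}},
    }


def _apply_overrides(spec, overrides: dict | None):
    if not overrides:
        return spec
    geometry_keys = {"width_um", "height_um"}
    kwargs = dict(overrides)
    if isinstance(spec, synth.SectionSpec) and \
            geometry_keys & kwargs.keys() and \
            "fascicle_polygon" not in kwargs:
        # rebuild default fascicle/surfaces for the new canvas
        kwargs.setdefault("fascicle_polygon", None)
        kwargs.setdefault("anterior_polyline", None)
        kwargs.setdefault("posterior_polyline", None)
    if isinstance(spec, synth.IshSpec) and geometry_keys & kwargs.keys() \
            and "roi_polygon" not in kwargs:
        kwargs.setdefault("roi_polygon", None)
    return dataclasses.replace(spec, **kwargs)


def _section_paths(out: Path) -> list[Path]:
    return sorted((out / "synth").glob("section_*.tif"))


def _stage_synth(cfg: dict, out: Path, seed: int) -> dict:
    scfg = cfg.get("section", {})
    n = int(scfg.get("n_sections", 1))
    stage_out = out / "synth"
    stage_out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n):
        spec = synth.preset(scfg["preset"])
        spec = _apply_overrides(spec, scfg.get("overrides"))
        spec.seed = int(seed) + i
        image, truth = synth.generate_section(spec)
        p = stage_out / f"section_{i:02d}.tif"
        write_section(image, p)
        truth.to_csv(stage_out / f"truth_{i:02d}.csv", index=False)
        paths.append(str(p.relative_to(out)))    # relative: reproducible
    report = {"stage": "synth", "preset": scfg["preset"], "seed": seed,
              "n_sections": n, "overrides": scfg.get("overrides") or {},
              "outputs": paths}
    write_report(stage_out / "report.json", report)
    return report


def _stage_segment(cfg: dict, out: Path, seed: int) -> dict:
    seg = cfg.get("segment", {})
    cls = cfg.get("classify", {})
    stage_out = out / "segment"
    stage_out.mkdir(parents=True, exist_ok=True)
    outputs = []
    for p in _section_paths(out):
        image = read_section(p)
        labels, records = nucseg.segment_and_measure(
            image,
            min_area_um2=float(seg.get("min_area_um2", 8.0)),
            max_area_um2=float(seg.get("max_area_um2", 200.0)),
            threshold_mode=seg.get("threshold_mode", "otsu"),
            threshold=seg.get("threshold"))
        records = nucseg.classify_by_threshold(
            records, "gfp", float(cls.get("gfp_threshold", 80.0)))
        if "edu" in image.channels:
            records = nucseg.classify_by_threshold(
                records, "edu", float(cls.get("edu_threshold", 100.0)))
        if "fascicle" in image.polygons:
            records["in_roi"] = abundance.in_roi_mask(
                records, image.polygons["fascicle"])
        stem = p.stem.replace("section", "records")
        rec_path = stage_out / f"{stem}.csv"
        records.to_csv(rec_path, index=False)
        tifffile.imwrite(stage_out / f"labels_{p.stem.split('_')[1]}.tif",
                         labels.astype(np.uint16))
        outputs.append(str(rec_path.relative_to(out)))
    report = {"stage": "segment", "params": {**seg, **cls}, "seed": seed,
              "outputs": outputs}
    write_report(stage_out / "report.json", report)
    return report


def _records_with_roi(out: Path) -> list[tuple[str, pd.DataFrame, dict, dict]]:
    items = []
    for p in sorted((out / "segment").glob("records_*.csv")):
        idx = p.stem.split("_")[1]
        records = pd.read_csv(p)
        roi_p = out / "synth" / f"section_{idx}.tif.roi.json"
        polygons, polylines = read_roi_json(roi_p)
        items.append((idx, records, polygons, polylines))
    return items


def _stage_abundance(cfg: dict, out: Path, seed: int) -> dict:
    stage_out = out / "abundance"
    stage_out.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, records, polygons, _ in _records_with_roi(out):
        res = abundance.quantify_section(
            records, polygons["fascicle"], flag="gfp_pos",
            section_id=f"section_{idx}")
        rows.append(res.to_dict())
    df = pd.DataFrame(rows)
    df.to_csv(stage_out / "abundance.csv", index=False)
    report = {"stage": "abundance", "seed": seed, "flag": "gfp_pos",
              "n_sections": len(rows),
              "mean_pct_pos": float(df["pct_pos"].mean()) if len(df) else None}
    write_report(stage_out / "report.json", report)
    return report


def _stage_depth(cfg: dict, out: Path, seed: int) -> dict:
    dcfg = cfg.get("depth", {})
    stage_out = out / "depth"
    stage_out.mkdir(parents=True, exist_ok=True)
    frames = []
    for idx, records, polygons, polylines in _records_with_roi(out):
        image = read_section(out / "synth" / f"section_{idx}.tif")
        labels = tifffile.imread(out / "segment" / f"labels_{idx}.tif")
        edm = depthmap.build_edm(labels.shape, polylines["anterior"],
                                 polylines["posterior"],
                                 image.pixel_size_um)
        recs = records[records["in_roi"]].reset_index(drop=True)
        recs, edm_max = depthmap.assign_depth(
            recs, labels, edm, polygons["fascicle"], image.pixel_size_um)
        profile = depthmap.quartile_profile(
            recs, flag="gfp_pos", edm_max_um=edm_max,
            section_id=f"section_{idx}",
            convention=dcfg.get("convention", "composition"))
        frames.append(profile.to_frame())
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(stage_out / "depth_profiles.csv", index=False)
    report = {"stage": "depth", "seed": seed,
              "convention": dcfg.get("convention", "composition"),
              "n_sections": len(frames)}
    write_report(stage_out / "report.json", report)
    return report


def _stage_edu(cfg: dict, out: Path, seed: int) -> dict:
    ecfg = cfg.get("edu", {})
    per_animal = int(ecfg.get("sections_per_animal", 1))
    stage_out = out / "edu"
    stage_out.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[pd.DataFrame]] = {}
    for i, (idx, records, _, _) in enumerate(_records_with_roi(out)):
        if "edu_pos" not in records.columns:
            continue
        animal = f"A{i // per_animal + 1}"
        groups.setdefault(animal, []).append(records[records["in_roi"]])
    if not groups:
        report = {"stage": "edu", "seed": seed,
                  "note": "no EdU channel in inputs"}
        write_report(stage_out / "report.json", report)
        return report
    pooled = {a: pd.concat(dfs, ignore_index=True)
              for a, dfs in groups.items()}
    results = prolif.edu_fractions(pooled)
    df = pd.DataFrame([r.to_dict() for r in results])
    df.to_csv(stage_out / "proliferation.csv", index=False)
    report = {"stage": "edu", "seed": seed,
              "sections_per_animal": per_animal,
              "n_animals": len(results)}
    if len(results) >= 2:
        report["paired_test"] = prolif.compare_proliferation(results)
    write_report(stage_out / "report.json", report)
    return report


def _stage_ish(cfg: dict, out: Path, seed: int) -> dict:
    icfg = cfg.get("ish", {})
    stage_out = out / "ish"
    stage_out.mkdir(parents=True, exist_ok=True)
    n = int(icfg.get("n_sections", 1))
    per_section = []
    for i in range(n):
        spec = synth.preset(icfg["preset"])
        spec = _apply_overrides(spec, icfg.get("overrides"))
        spec.seed = int(seed) + 100 + i
        rgb, truth, _ = synth.generate_duplex_ish(spec)
        controls = synth.generate_single_color_controls(spec)
        sm = ishcoloc.estimate_stain_vectors(controls, spec.background_white)
        rasters = ishcoloc.deconvolve(rgb, sm, spec.background_white)
        table = ishcoloc.grid_intensities(
            rasters, spec.roi_polygon, spec.pixel_size_um,
            unit_um=float(icfg.get("unit_um", 50.0)))
        table.to_csv(stage_out / f"grid_{i:02d}.csv", index=False)
        truth.to_csv(stage_out / f"truth_{i:02d}.csv", index=False)
        per_section.append(ishcoloc.coloc_spearman(table, "green", "red"))
    report = {"stage": "ish", "seed": seed, "preset": icfg["preset"],
              "unit_um": float(icfg.get("unit_um", 50.0)),
              "per_section": per_section,
              "aggregate": ishcoloc.aggregate_sections(per_section)}
    write_report(stage_out / "report.json", report)
    return report


def _stage_qpcr(cfg: dict, out: Path, seed: int) -> dict:
    qcfg = cfg.get("qpcr", {})
    stage_out = out / "qpcr"
    stage_out.mkdir(parents=True, exist_ok=True)
    spec = synth.preset(qcfg["preset"])
    spec = _apply_overrides(spec, qcfg.get("overrides"))
    spec.seed = int(seed) + 200
    ct_raw, sample_meta, truth = synth.generate_ct_matrix(spec)
    ct_raw.to_csv(stage_out / "ct_raw.csv")
    em = qpcr.collapse_duplicates(
        ct_raw, sample_meta, housekeeping_genes=spec.housekeeping_genes,
        detection_limit_ct=spec.detection_limit_ct)
    em = qpcr.apply_exclusions(
        em, tuple(qcfg.get("manual_exclusions", ())))
    em = qpcr.delta_ct(em)
    em.dct.to_csv(stage_out / "dct.csv")
    contrast = qcfg.get("contrast")
    report = {"stage": "qpcr", "seed": seed, "preset": qcfg["preset"],
              "manual_exclusions": list(qcfg.get("manual_exclusions", ())),
              "excluded_genes": sorted(
                  em.gene_meta.loc[em.gene_meta["role"] == "excluded",
                                   "gene"])}
    if contrast:
        volcano = qpcr.ddct_contrast(em, contrast["a"], contrast["b"])
        volcano.to_csv(stage_out / "volcano.csv", index=False)
        report["contrast"] = contrast
    pca = qpcr.pca_and_cluster(em)
    pca["scores"].to_csv(stage_out / "pca_scores.csv")
    pca["loadings"].to_csv(stage_out / "pca_loadings.csv")
    report["pct_variance_pc1"] = float(pca["pct_variance"].iloc[0])
    lr = qpcr.ligand_receptor_report(em)
    lr.to_csv(stage_out / "ligand_receptor.csv", index=False)
    write_report(stage_out / "report.json", report)
    return report


def _stage_internalize(cfg: dict, out: Path, seed: int) -> dict:
    icfg = cfg.get("internalize", {})
    stage_out = out / "internalize"
    stage_out.mkdir(parents=True, exist_ok=True)
    spec = synth.preset(icfg["preset"])
    spec = _apply_overrides(spec, icfg.get("overrides"))
    spec.seed = int(seed) + 300
    table = synth.generate_suspension(spec)
    flagged = internalization.classify_markers(table, icfg["thresholds"])
    flagged.to_csv(stage_out / "cells.csv", index=False)
    summary = internalization.dq_positivity(flagged)
    report = {"stage": "internalize", "seed": seed, "preset": icfg["preset"],
              "thresholds": icfg["thresholds"], "summary": summary}
    write_report(stage_out / "report.json", report)
    return report


_STAGE_FNS = {
    "synth": _stage_synth,
    "segment": _stage_segment,
    "abundance": _stage_abundance,
    "depth": _stage_depth,
    "edu": _stage_edu,
    "ish": _stage_ish,
    "qpcr": _stage_qpcr,
    "internalize": _stage_internalize,
}

_REQUIRED_BLOCKS = {
    "synth": ["section"],
    "segment": [],
    "abundance": [],
    "depth": [],
    "edu": [],
    "ish": ["ish"],
    "qpcr": ["qpcr"],
    "internalize": ["internalize"],
}


def run_stage(name: str, config: dict, out_dir=None,
              seed: int | None = None) -> dict:
    """Run one pipeline stage (or ``"all"``) from a config mapping.

    Returns the stage's JSON report (for ``"all"``, a mapping
    stage -> report).  Outputs land under ``out_dir`` (default: the
    config's ``out_dir`` or ``./out``).
    """
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    out = Path(out_dir or config.get("out_dir", "out"))
    eff_seed = int(seed if seed is not None else config.get("seed", 0))
    names = [s for s in STAGES if s != "all"] if name == "all" else [name]
    missing = [blk for n in names for blk in _REQUIRED_BLOCKS[n]
               if blk not in config]
    if missing:
        raise ValueError(f"config missing required blocks: {sorted(set(missing))}")
    reports = {}
    for n in names:
        reports[n] = _STAGE_FNS[n](config, out, eff_seed)
    return reports if name == "all" else reports[name]
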