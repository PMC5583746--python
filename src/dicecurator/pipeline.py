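"""End-to-end workflow: simulate -> extract -> fp-filter -> select ->
calibrate -> estimate -> qc.

Each stage reads its inputs from, and writes its reports to, a working
directory, so stages can run together or be resumed from any contiguous
subset.  Every object- or image-removal decision is attributable in the
reports to the named filter(s) that caused it.  Identical inputs, config
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import dosimetry, io, synthetic
from .fp_filters import apply_filters, score_candidate
from .image_selection import compute_image_features, select_images, statistical_filter_pass
from .morphology import MorphologyParams, analyze_image

log = logging.getLogger("dicecurator")

STAGES = ("simulate", "extract", "fp-filter", "select", "calibrate",
          "estimate", "qc")


def _check_stages(stages) -> list[str]:
    idx = [STAGES.index(s) for s in stages]
    if sorted(idx) != idx or any(b - a != 1 for a, b in zip(idx, idx[1:])):
        raise ValueError(f"stages must be a contiguous ordered subset of {STAGES}")
    return list(stages)


def stage_simulate(outdir: Path, config: io.PipelineConfig,
                   simulate_spec: dict) -> Path:
    """Render dose-response samples to PNG images plus truth and manifest."""
    rng = np.random.default_rng(config.seed)
    doses = simulate_spec.get("doses", [0, 0.5, 1, 2, 3, 4])
    n_cells = simulate_spec.get("n_cells", 20)
    curve = tuple(simulate_spec.get("curve", (0.001, 0.01, 0.05)))
    quality_mix = simulate_spec.get("quality_mix")
    cell_spec = synthetic.CellSpec(**simulate_spec.get("cell_spec", {}))
    test_doses = simulate_spec.get("test_doses", [])
    rows = []
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    for dose, is_test in [(d, False) for d in doses] + [(d, True) for d in test_doses]:
        sid = f"{'test' if is_test else 'cal'}{dose:g}Gy"
        sample = synthetic.generate_dose_sample(
            dose, curve, n_cells, seed=rng, quality_mix=quality_mix,
            render=True, cell_spec=cell_spec, sample_id=sid)
        sdir = outdir / "images" / sid
        sdir.mkdir(exist_ok=True)
        truths = []
        for k, (img, tr) in enumerate(zip(sample.images, sample.truths)):
            p = sdir / f"cell{k:04d}.png"
            iio.imwrite(p, (img * 255).astype(np.uint8))
            truths.append({"classes": tr.classes, "dc_count": tr.dc_count,
                           "quality": tr.quality})
            rows.append({"sample_id": sid, "image_path": str(p),
                         "dose_gy": "" if is_test else dose})
        (outdir / "truth" / f"{sid}.json").write_text(
            json.dumps(truths, indent=1))
        log.info("simulate: %s, %d cells, %d true DCs", sid, n_cells,
                 int(sample.dc_counts.sum()))
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def stage_extract(manifest: pd.DataFrame, outdir: Path,
                  config: io.PipelineConfig) -> None:
    params = MorphologyParams(min_area=config.min_area)
    (outdir / "objects").mkdir(parents=True, exist_ok=True)
    (outdir / "features").mkdir(exist_ok=True)
    for sid, grp in manifest.groupby("sample_id", sort=True):
        frames, feats = [], []
        for _, row in grp.iterrows():
            img = iio.imread(row["image_path"])
            objects = analyze_image(img, params)
            frames.append(io.objects_to_frame(objects, row["image_path"]))
            feats.append(compute_image_features(
                objects, image_id=row["image_path"], sex=config.selection.sex,
                thresholds=config.selection.thresholds_genome))
        io.write_objects_csv(outdir / "objects" / f"{sid}.csv", frames)
        io.features_to_frame(feats).to_csv(
            outdir / "features" / f"{sid}.csv", index=False, float_format="%.6g")
        n_dc = sum(f.classified_count for f in feats)
        log.info("extract: %s, %d images, %d classified objects",
                 sid, len(feats), n_dc)


def stage_fp_filter(manifest: pd.DataFrame, outdir: Path,
                    config: io.PipelineConfig) -> None:
    """Score every predicted DC with the FP filters and write verdicts."""
    (outdir / "fp").mkdir(parents=True, exist_ok=True)
    th = config.fp_thresholds
    for sid in sorted(manifest["sample_id"].unique()):
        per_image = io.read_objects_csv(outdir / "objects" / f"{sid}.csv")
        rows = []
        n_removed = 0
        for image_id, objects in per_image.items():
            for obj in objects:
                if obj.label != "DC":
                    continue
                scores = score_candidate(obj, objects)
                verdict, trig = apply_filters(scores, th)
                n_removed += verdict == "FP-removed"
                rows.append({"image_id": image_id, "object_id": obj.id,
                             **{f"s_{k}": v for k, v in scores.as_dict().items()},
                             "verdict": verdict, "triggered": "+".join(trig)})
        cols = (["image_id", "object_id"]
                + [f"s_{k}" for k in ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii")]
                + ["verdict", "triggered"])
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(outdir / "fp" / f"{sid}.csv", index=False, float_format="%.6g")
        log.info("fp-filter: %s, %d DC candidates, %d FP-removed",
                 sid, len(rows), n_removed)


def _dc_counts_per_image(outdir: Path, sid: str,
                         image_ids: list) -> np.ndarray:
    """DCs per image after FP filtering (before it if no fp report exists)."""
    objects = pd.read_csv(outdir / "objects" / f"{sid}.csv")
    dc = objects[objects["label"] == "DC"].groupby("image_id").size()
    fp_path = outdir / "fp" / f"{sid}.csv"
    if fp_path.exists():
        fp = pd.read_csv(fp_path)
        if len(fp):
            removed = fp[fp["verdict"] == "FP-removed"].groupby("image_id").size()
            dc = dc.sub(removed, fill_value=0)
    return np.array([int(dc.get(i, 0)) for i in image_ids])


def stage_select(manifest: pd.DataFrame, outdir: Path,
                 config: io.PipelineConfig) -> None:
    (outdir / "selection").mkdir(parents=True, exist_ok=True)
    for sid in sorted(manifest["sample_id"].unique()):
        feats = io.frame_to_features(
            pd.read_csv(outdir / "features" / f"{sid}.csv"))
        flags = statistical_filter_pass(feats, config.selection)
        chosen = select_images(feats, config.selection_method, config.selection)
        rank = {i: r + 1 for r, i in enumerate(chosen)}
        rows = []
        for i, f in enumerate(feats):
            rows.append({"image_id": f.image_id,
                         "kept": i in rank,
                         "reasons": "+".join(flags[i][1]),
                         "combined_z": f.combined_z,
                         "group_bin_distance": f.group_bin_distance,
                         "rank": rank.get(i, "")})
        pd.DataFrame(rows).to_csv(outdir / "selection" / f"{sid}.csv",
                                  index=False, float_format="%.6g")
        log.info("select: %s, kept %d of %d images (%s)",
                 sid, len(chosen), len(feats), config.selection_method)


def _selected_ids(outdir: Path, sid: str) -> list:
    sel = pd.read_csv(outdir / "selection" / f"{sid}.csv")
    kept = sel[sel["kept"]]
    return list(kept["image_id"])


def stage_calibrate(manifest: pd.DataFrame, outdir: Path,
                    config: io.PipelineConfig) -> None:
    doses, freqs = [], []
    for sid, grp in manifest.groupby("sample_id", sort=True):
        dose = pd.to_numeric(grp["dose_gy"], errors="coerce").iloc[0]
        if math.isnan(dose):
            continue
        ids = _selected_ids(outdir, sid)
        counts = _dc_counts_per_image(outdir, sid, ids)
        doses.append(float(dose))
        freqs.append(dosimetry.dc_frequency(counts))
    curve = dosimetry.fit_calibration(doses, freqs, weights=config.weighting)
    io.write_curve_json(outdir / "curve.json", curve)
    log.info("calibrate: %d points, c0=%.4g alpha=%.4g beta=%.4g",
             len(doses), curve.c0, curve.alpha, curve.beta)


def stage_estimate(manifest: pd.DataFrame, outdir: Path,
                   config: io.PipelineConfig) -> None:
    curve_path = outdir / "curve.json"
    if not curve_path.exists():
        raise ValueError("estimate stage requires a calibration curve "
                         f"({curve_path} is missing)")
    curve = io.read_curve_json(curve_path)
    rows = []
    for sid, grp in manifest.groupby("sample_id", sort=True):
        dose = pd.to_numeric(grp["dose_gy"], errors="coerce").iloc[0]
        if not math.isnan(dose):
            continue
        ids = _selected_ids(outdir, sid)
        counts = _dc_counts_per_image(outdir, sid, ids)
        freq = dosimetry.dc_frequency(counts)
        est, flag = dosimetry.estimate_dose(curve, freq)
        rows.append({"sample_id": sid, "n_cells": len(counts),
                     "dc_freq": freq, "est_dose_gy": est, "flag": flag})
        log.info("estimate: %s -> %.2f Gy (%s)", sid, est, flag)
    pd.DataFrame(rows).to_csv(outdir / "estimates.csv", index=False,
                              float_format="%.6g")


def stage_qc(manifest: pd.DataFrame, outdir: Path,
             config: io.PipelineConfig) -> None:
    rows = []
    for sid, grp in manifest.groupby("sample_id", sort=True):
        sel_path = outdir / "selection" / f"{sid}.csv"
        if sel_path.exists():
            ids = _selected_ids(outdir, sid)
        else:
            ids = list(grp["image_path"])
        counts = _dc_counts_per_image(outdir, sid, ids)
        res = dosimetry.poisson_quality_test(counts, seed=config.seed)
        rows.append({"sample_id": sid, "n_cells": res.n_cells,
                     "dc_freq": res.lam,
                     "chi_square": res.chi_square,
                     "p_asymptotic": res.p_asymptotic,
                     "p_value": res.p_value,
                     "reject_0.01": res.rejects.get(0.01, ""),
                     "reject_0.005": res.rejects.get(0.005, ""),
                     "note": res.note})
    pd.DataFrame(rows).to_csv(outdir / "qc.csv", index=False,
                              float_format="%.6g")


def run_pipeline(manifest_path, config: io.PipelineConfig, stages,
                 outdir, simulate_spec: dict | None = None) -> int:
    """Execute the requested contiguous stages; returns 0 on success.

    Raises ValueError for data errors (missing inputs, bad manifests) and
    RuntimeError for numerical failures, letting callers map them to exit
    codes.
    """
    stages = _check_stages(stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    if "simulate" in stages:
        manifest_path = stage_simulate(outdir, config, simulate_spec or {})
    manifest = None
    rest = [s for s in stages if s != "simulate"]
    if rest:
        if manifest_path is None:
            raise ValueError("a manifest is required for stages beyond simulate")
        manifest = io.read_manifest(manifest_path)
        if manifest.empty:
            raise ValueError("manifest lists no images")
        missing = [p for p in manifest["image_path"]
                   if "extract" in rest and not Path(p).exists()]
        if missing:
            raise ValueError(f"{len(missing)} manifest image paths do not exist, "
                             f"first: {missing[0]}")
    for stage in rest:
        {"extract": stage_extract, "fp-filter": stage_fp_filter,
         "select": stage_select, "calibrate": stage_calibrate,
         "estimate": stage_estimate, "qc": stage_qc}[stage](manifest, outdir, config)
    return 0
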