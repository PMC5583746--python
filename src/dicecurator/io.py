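"""Readers and writers for the pipeline's file formats.

All artifacts are plain text (CSV / JSON / YAML) with stable, versioned
schemas so reports round-trip losslessly and identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fp_filters import FpThresholds
from .image_selection import ImageFeatures, SelectionConfig
from .morphology import ChromosomeObject

SCHEMA_VERSION = 1

OBJECT_COLUMNS = [
    "image_id", "object_id", "area", "w_mean", "w_med", "w_max", "w_cent",
    "rect_min", "rect_max", "half_arc_min", "half_arc_max",
    "ic_arc_min", "ic_arc_max", "n_candidates", "label",
]


def _pair(t, idx):
    return float("nan") if t is None else float(t[idx])


def objects_to_frame(objects: list[ChromosomeObject], image_id) -> pd.DataFrame:
    rows = []
    for o in objects:
        rows.append({
            "image_id": image_id,
            "object_id": o.id,
            "area": o.area,
            "w_mean": o.w_mean, "w_med": o.w_med, "w_max": o.w_max,
            "w_cent": o.w_cent,
            "rect_min": _pair(o.rect_sides, 0), "rect_max": _pair(o.rect_sides, 1),
            "half_arc_min": _pair(o.contour_halves, 0),
            "half_arc_max": _pair(o.contour_halves, 1),
            "ic_arc_min": _pair(o.intercandidate_arcs, 0),
            "ic_arc_max": _pair(o.intercandidate_arcs, 1),
            "n_candidates": o.n_candidates,
            "label": o.label or "",
        })
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def write_objects_csv(path, frames: list[pd.DataFrame]) -> None:
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=OBJECT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_objects_csv(path) -> dict[object, list[ChromosomeObject]]:
    """Rebuild per-image feature-only objects from a CSV export.

    Masks/contours are not stored; the returned objects carry the summary
    features needed by the FP filters, with ``label_source="external"`` so
    the heuristic classifier will not overwrite their labels.
    """
    df = pd.read_csv(path)
    out: dict[object, list[ChromosomeObject]] = {}
    empty = np.zeros((0, 2))
    for _, r in df.iterrows():
        def _p(a, b):
            if math.isnan(r[a]) or math.isnan(r[b]):
                return None
            return (float(r[a]), float(r[b]))

        ncand = int(r["n_candidates"])
        obj = ChromosomeObject(
            id=int(r["object_id"]), mask=np.zeros((0, 0), bool), origin=(0, 0),
            contour=empty, area=int(r["area"]),
            w_mean=float(r["w_mean"]), w_med=float(r["w_med"]),
            w_max=float(r["w_max"]), w_cent=float(r["w_cent"]),
            rect_sides=_p("rect_min", "rect_max"),
            contour_halves=_p("half_arc_min", "half_arc_max"),
            intercandidate_arcs=_p("ic_arc_min", "ic_arc_max"),
            label=(r["label"] if isinstance(r["label"], str) and r["label"] else None),
            label_source="external",
        )
        obj.candidates = [None] * ncand  # count is what downstream consumers use
        out.setdefault(r["image_id"], []).append(obj)
    return out


FEATURE_COLUMNS = [
    "image_id", "mw", "cd", "wd", "obj_count", "seg_obj_count",
    "classified_count", "classified_ratio", "ab", "c", "dg",
    "group_bin_distance", "combined_z",
]


def features_to_frame(features: list[ImageFeatures]) -> pd.DataFrame:
    rows = []
    for f in features:
        ab, c, dg = f.group_counts
        rows.append({
            "image_id": f.image_id, "mw": f.mw, "cd": f.cd, "wd": f.wd,
            "obj_count": f.obj_count, "seg_obj_count": f.seg_obj_count,
            "classified_count": f.classified_count,
            "classified_ratio": f.classified_ratio,
            "ab": ab, "c": c, "dg": dg,
            "group_bin_distance": f.group_bin_distance,
            "combined_z": f.combined_z,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def frame_to_features(df: pd.DataFrame) -> list[ImageFeatures]:
    out = []
    for _, r in df.iterrows():
        out.append(ImageFeatures(
            image_id=r["image_id"], mw=r["mw"], cd=r["cd"], wd=r["wd"],
            obj_count=int(r["obj_count"]), seg_obj_count=int(r["seg_obj_count"]),
            classified_count=int(r["classified_count"]),
            classified_ratio=float(r["classified_ratio"]),
            group_counts=(int(r["ab"]), int(r["c"]), int(r["dg"])),
            group_bin_distance=float(r["group_bin_distance"]),
            combined_z=float(r["combined_z"]),
        ))
    return out


def write_thresholds_json(path, thresholds: FpThresholds) -> None:
    data = {k: v for k, v in asdict(thresholds).items() if k != "subset"}
    data["subset"] = sorted(thresholds.subset)
    data["schema_version"] = SCHEMA_VERSION
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_thresholds_json(path) -> FpThresholds:
    data = json.loads(Path(path).read_text())
    data.pop("schema_version", None)
    data["subset"] = frozenset(data.get("subset", []))
    return FpThresholds(**data)


def write_curve_json(path, curve, lab_id: str | None = None) -> None:
    data = {
        "schema_version": SCHEMA_VERSION,
        "lab_id": lab_id,
        "c0": curve.c0, "alpha": curve.alpha, "beta": curve.beta,
        "dose_range": list(curve.dose_range),
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_curve_json(path):
    from .dosimetry import CalibrationCurve

    data = json.loads(Path(path).read_text())
    return CalibrationCurve(c0=data["c0"], alpha=data["alpha"],
                            beta=data["beta"],
                            dose_range=tuple(data["dose_range"]))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "image_path"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    if "dose_gy" not in df.columns:
        df["dose_gy"] = np.nan
    return df


# ---------------------------------------------------------------------------
# pipeline configuration


_CONFIG_KEYS = {"seed", "log_level", "fp_thresholds", "selection",
                "min_area", "selection_method", "weighting"}


class PipelineConfig:
    """Validated, versioned pipeline configuration (YAML on disk)."""

    def __init__(self, seed: int = 0, log_level: str = "INFO",
                 fp_thresholds: FpThresholds | None = None,
                 selection: SelectionConfig | None = None,
                 min_area: int = 50, selection_method: str = "combined_z",
                 weighting=None):
        self.seed = seed
        self.log_level = log_level
        self.fp_thresholds = fp_thresholds or FpThresholds()
        self.selection = selection or SelectionConfig()
        self.min_area = min_area
        self.selection_method = selection_method
        self.weighting = weighting

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _CONFIG_KEYS - {"schema_version"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        for key in ("seed", "log_level", "min_area", "selection_method", "weighting"):
            if key in data:
                kw[key] = data[key]
        if "fp_thresholds" in data:
            t = dict(data["fp_thresholds"])
            t["subset"] = frozenset(t.get("subset", sorted(FpThresholds().subset)))
            kw["fp_thresholds"] = FpThresholds(**t)
        if "selection" in data:
            s = dict(data["selection"])
            for tup in ("obj_count_range", "seg_obj_count_range", "weights",
                        "thresholds_genome", "enabled_filters"):
                if tup in s:
                    s[tup] = tuple(s[tup])
            kw["selection"] = SelectionConfig(**s)
        return cls(**kw)

    def to_yaml(self, path) -> None:
        data = {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "log_level": self.log_level,
            "min_area": self.min_area,
            "selection_method": self.selection_method,
            "weighting": self.weighting,
            "fp_thresholds": {**{k: v for k, v in asdict(self.fp_thresholds).items()
                                 if k != "subset"},
                              "subset": sorted(self.fp_thresholds.subset)},
            "selection": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(self.selection).items()},
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
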