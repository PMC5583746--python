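"""Image-level quality filtering, ranking and selection.

Metaphase images within one sample are compared through six features:

* ``LW``  -- mean centerline-length / mean-width ratio of the chromosomes
  (high in prometaphase cells with long thin chromosomes);
* ``CD``  -- mean centromere-candidate count per unit centerline length
  (high for bent/twisted chromosomes and noisy profiles);
* ``FD``  -- mean absolute first difference of the range-normalized width
  profile (LOW for smooth non-chromosomal contours such as nuclei);
* object count, segmented object count, and the classified-to-segmented
  ratio.

Statistical filters remove images whose LW/CD lie more than T standard
deviations above the sample mean (FD: below), whose counts fall outside
fixed ranges, or whose classified ratio is too low.  The Combined Z Score
aggregates the six features into a single weighted quality score (smaller
is better); the group-bin distance ranks images by how closely their
chromosome size distribution matches the reference karyotype.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import karyotype
from .morphology import ChromosomeObject

__all__ = [
    "ImageFeatures",
    "SelectionConfig",
    "compute_image_features",
    "statistical_filter_pass",
    "combined_z_score",
    "group_bin_distance",
    "select_images",
    "optimize_weights",
    "SelectionSample",
]

STAT_FILTERS = ("I", "II", "III", "IV", "V", "VI")


@dataclass
class ImageFeatures:
    """Per-image statistics consumed by the six selection filters."""

    image_id: int | str = 0
    mw: float = math.nan            # mean length/width ratio, MW(I)
    cd: float = math.nan            # candidate density per unit length, CD(I)
    wd: float = math.nan            # width-profile roughness, WD(I)
    obj_count: int = 0
    seg_obj_count: int = 0
    classified_count: int = 0
    classified_ratio: float = 0.0
    group_counts: tuple[int, int, int] = (0, 0, 0)
    group_bin_distance: float = math.nan
    combined_z: float = math.nan


@dataclass
class SelectionConfig:
    T: float = 1.5
    obj_count_range: tuple[int, int] = (40, 60)
    seg_obj_count_range: tuple[int, int] = (35, 50)
    classified_ratio_min: float = 0.6   # 0.6 or 0.7 depending on stringency
    weights: tuple[int, ...] = (1, 1, 1, 1, 1, 1)
    top_n: int = 250
    sex: str = "auto"                   # "female" | "male" | "auto"
    thresholds_genome: tuple[float, float] = (karyotype.AB_THRESHOLD,
                                              karyotype.DG_THRESHOLD)
    enabled_filters: tuple[str, ...] = STAT_FILTERS

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be > 0")
        if len(self.weights) != 6 or any(not 1 <= w <= 5 for w in self.weights):
            raise ValueError("weights must be six integers in [1, 5]")
        unknown = set(self.enabled_filters) - set(STAT_FILTERS)
        if unknown:
            raise ValueError(f"unknown filters: {unknown}")


def _classified(objects: list[ChromosomeObject]) -> list[ChromosomeObject]:
    return [o for o in objects if o.label in ("MC", "DC")]


def _segmented(objects: list[ChromosomeObject]) -> list[ChromosomeObject]:
    """Objects that passed width-profile feature computation."""
    return [o for o in objects
            if o.width_profile is not None and len(o.width_profile) > 0
            and not math.isnan(o.w_mean)]


def group_bin_distance(objects: list[ChromosomeObject] | np.ndarray,
                       sex: str = "auto",
                       thresholds: tuple[float, float] = (karyotype.AB_THRESHOLD,
                                                          karyotype.DG_THRESHOLD)
                       ) -> tuple[tuple[int, int, int], float]:
    """Bin retained chromosome areas into (AB, C, DG) and measure the
    Euclidean distance to the ideal karyotype vector.

    ``objects`` may be ChromosomeObjects (non-chromosomal and
    unprocessable objects are excluded first) or a bare array of areas.
    With ``sex="auto"`` the smaller of the female/male distances is used.
    Larger distances indicate poorer segmentation quality; an empty
    retained set scores the norm of the ideal vector itself.
    """
    if len(objects) and isinstance(objects[0], ChromosomeObject):
        areas = np.array([o.area for o in _classified(objects)], float)
    else:
        areas = np.asarray(objects, float)
    sexes = ("female", "male") if sex == "auto" else (sex,)
    if areas.size == 0 or areas.sum() <= 0:
        warnings.warn("no retained chromosomes; group-bin distance is maximal",
                      stacklevel=2)
        dists = {s: float(np.linalg.norm(karyotype.IDEAL_COUNTS[s])) for s in sexes}
        best = min(dists, key=dists.get)
        return (0, 0, 0), dists[best]
    counts = karyotype.group_counts(areas / areas.sum(), thresholds)
    dist = min(
        float(np.linalg.norm(np.subtract(counts, karyotype.IDEAL_COUNTS[s])))
        for s in sexes)
    return counts, dist


def compute_image_features(objects: list[ChromosomeObject],
                           image_id: int | str = 0,
                           sex: str = "auto",
                           thresholds: tuple[float, float] = (karyotype.AB_THRESHOLD,
                                                              karyotype.DG_THRESHOLD)
                           ) -> ImageFeatures:
    """Aggregate one image's objects into the six selection features.

    Unprocessable and non-chromosomal objects are excluded from the
    MW/CD/WD means but still counted in ``obj_count``.
    """
    feats = ImageFeatures(image_id=image_id)
    feats.obj_count = len(objects)
    seg = _segmented(objects)
    feats.seg_obj_count = len(seg)
    chrom = _classified(objects)
    feats.classified_count = len(chrom)
    feats.classified_ratio = (len(chrom) / len(seg)) if seg else 0.0
    if chrom:
        lw, cd, wd = [], [], []
        for o in chrom:
            if o.centerline_length > 0 and o.w_mean > 0:
                lw.append(o.centerline_length / o.w_mean)
                cd.append(o.n_candidates / o.centerline_length)
            nw = o.width_profile.normalized_widths
            if len(nw) >= 2:
                wd.append(float(np.mean(np.abs(np.diff(nw)))))
        feats.mw = float(np.mean(lw)) if lw else math.nan
        feats.cd = float(np.mean(cd)) if cd else math.nan
        feats.wd = float(np.mean(wd)) if wd else math.nan
    feats.group_counts, feats.group_bin_distance = group_bin_distance(
        objects, sex, thresholds)
    return feats


def _zscores(values: np.ndarray) -> np.ndarray:
    """Within-sample z-scores; a constant (or undefined) feature maps to 0."""
    v = np.asarray(values, float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        return np.zeros_like(v)
    mean = v[ok].mean()
    sd = v[ok].std(ddof=1)
    z = np.zeros_like(v)
    # guard against rounding residue in the SD of a constant feature
    if sd > 1e-9 * max(1.0, abs(mean)):
        z[ok] = (v[ok] - mean) / sd
    return z


def statistical_filter_pass(sample_features: list[ImageFeatures],
                            cfg: SelectionConfig | None = None
                            ) -> list[tuple[bool, list[str]]]:
    """Apply the six filters to every image of a sample.

    Returns one ``(keep, reasons)`` pair per image; ``reasons`` lists the
    filters (I-VI) that rejected it.  Filters I/II remove images above
    mean + T*SD of MW/CD, filter III below mean - T*SD of WD; IV/V are
    range filters on the object counts; VI thresholds the classified
    ratio.  A feature with zero spread cannot fire its z-filter.
    """
    cfg = cfg or SelectionConfig()
    n = len(sample_features)
    if n < 3 and any(f in cfg.enabled_filters for f in ("I", "II", "III")):
        warnings.warn("fewer than 3 images; z-based filters are unreliable",
                      stacklevel=2)
    mw = np.array([f.mw for f in sample_features])
    cd = np.array([f.cd for f in sample_features])
    wd = np.array([f.wd for f in sample_features])

    def _bounds(v):
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            return math.nan, math.nan
        return v[ok].mean(), v[ok].std(ddof=1)

    def _spread(m, s):
        # a constant feature (sd = rounding residue) cannot flag outliers
        return not math.isnan(m) and s > 1e-9 * max(1.0, abs(m))

    mw_m, mw_s = _bounds(mw)
    cd_m, cd_s = _bounds(cd)
    wd_m, wd_s = _bounds(wd)
    out = []
    for i, f in enumerate(sample_features):
        reasons = []
        if "I" in cfg.enabled_filters and _spread(mw_m, mw_s) \
                and not math.isnan(mw[i]) and mw[i] > mw_m + cfg.T * mw_s:
            reasons.append("I")
        if "II" in cfg.enabled_filters and _spread(cd_m, cd_s) \
                and not math.isnan(cd[i]) and cd[i] > cd_m + cfg.T * cd_s:
            reasons.append("II")
        if "III" in cfg.enabled_filters and _spread(wd_m, wd_s) \
                and not math.isnan(wd[i]) and wd[i] < wd_m - cfg.T * wd_s:
            reasons.append("III")
        if "IV" in cfg.enabled_filters and not \
                cfg.obj_count_range[0] <= f.obj_count <= cfg.obj_count_range[1]:
            reasons.append("IV")
        if "V" in cfg.enabled_filters and not \
                cfg.seg_obj_count_range[0] <= f.seg_obj_count <= cfg.seg_obj_count_range[1]:
            reasons.append("V")
        if "VI" in cfg.enabled_filters and f.classified_ratio < cfg.classified_ratio_min:
            reasons.append("VI")
        out.append((not reasons, reasons))
    return out


#: Sign pattern of the Combined Z Score terms; ObjCount/SegObjCount terms
#: use |z|.
_Z_SIGNS = np.array([+1.0, +1.0, -1.0, +1.0, +1.0, -1.0])


def _z_matrix(sample_features: list[ImageFeatures]) -> np.ndarray:
    """(M, 6) matrix of the per-image z-terms, before signing/weighting:
    columns are z(LW), z(CD), z(FD), |z(ObjCount)|, |z(SegObjCount)|,
    z(ClassifiedRatio)."""
    cols = [
        _zscores([f.mw for f in sample_features]),
        _zscores([f.cd for f in sample_features]),
        _zscores([f.wd for f in sample_features]),
        np.abs(_zscores([float(f.obj_count) for f in sample_features])),
        np.abs(_zscores([float(f.seg_obj_count) for f in sample_features])),
        _zscores([f.classified_ratio for f in sample_features]),
    ]
    return np.stack(cols, axis=1)


def combined_z_score(sample_features: list[ImageFeatures],
                     weights=(1, 1, 1, 1, 1, 1)) -> np.ndarray:
    """Weighted Combined Z Score per image; smaller = higher quality.

    score = w_LW z(LW) + w_CD z(CD) - w_FD z(FD)
          + w_Obj |z(Obj)| + w_Seg |z(Seg)| - w_CR z(ClassifiedRatio)
    """
    weights = np.asarray(weights, float)
    if len(weights) != 6 or (weights <= 0).any():
        raise ValueError("need 6 positive weights")
    if len(sample_features) == 1:
        warnings.warn("single-image sample: all z-scores are 0", stacklevel=2)
    z = _z_matrix(sample_features)
    scores = z @ (weights * _Z_SIGNS)
    for f, s in zip(sample_features, scores):
        f.combined_z = float(s)
    return scores


def select_images(sample_features: list[ImageFeatures],
                  method: str = "combined_z",
                  cfg: SelectionConfig | None = None) -> list[int]:
    """Rank a sample's images and return the indices of the selected ones.

    Methods: ``combined_z`` and ``group_bin`` sort all images by the
    respective score (ascending; ties broken by image id) and keep the
    top ``cfg.top_n``; ``filters_only`` applies the enabled statistical
    filters and returns all survivors in order; ``filters_then_group_bin``
    prefilters with filters I-III then ranks survivors by group-bin
    distance.
    """
    cfg = cfg or SelectionConfig()
    idx = np.arange(len(sample_features))
    if method == "filters_only":
        flags = statistical_filter_pass(sample_features, cfg)
        return [int(i) for i in idx if flags[i][0]]
    if method == "combined_z":
        scores = combined_z_score(sample_features, cfg.weights)
        survivors = idx
    elif method == "group_bin":
        scores = np.array([f.group_bin_distance for f in sample_features])
        survivors = idx
    elif method == "filters_then_group_bin":
        pre = SelectionConfig(**{**cfg.__dict__,
                                 "enabled_filters": ("I", "II", "III")})
        flags = statistical_filter_pass(sample_features, pre)
        survivors = np.array([i for i in idx if flags[i][0]], int)
        scores = np.array([sample_features[i].group_bin_distance for i in survivors])
    else:
        raise ValueError(f"unknown method {method!r}")
    if len(survivors) < min(cfg.top_n, 300):
        warnings.warn(
            f"only {len(survivors)} images survive selection; dose estimates "
            "from fewer than ~250-500 cells fall below the recommended "
            "minimum cell count for dicentric scoring", stacklevel=2)
    order = np.lexsort((survivors, np.asarray(scores, float)))
    return [int(survivors[k]) for k in order[: cfg.top_n]]


# ---------------------------------------------------------------------------
# weight optimization


@dataclass
class SelectionSample:
    """One calibration sample: per-image features, per-image DC counts and
    the known physical dose."""

    sample_id: str
    features: list[ImageFeatures]
    dc_counts: np.ndarray
    dose_gy: float


def optimize_weights(calibration_samples: list[SelectionSample],
                     cfg: SelectionConfig | None = None,
                     grid: list[tuple[int, ...]] | None = None
                     ) -> list[tuple[tuple[int, ...], float]]:
    """Grid-search Combined Z Score weights against calibration samples.

    For every candidate weight vector the top ``cfg.top_n`` images of each
    sample are selected by Combined Z Score, per-sample DC frequencies are
    fit to the linear-quadratic curve, and the vector is scored by the sum
    of squared residuals between re-estimated and physical doses.  Returns
    all vectors sorted ascending by that residual (degenerate fits rank
    last with score +inf).
    """
    from itertools import product

    from . import dosimetry

    cfg = cfg or SelectionConfig()
    doses = [s.dose_gy for s in calibration_samples]
    if len(calibration_samples) < 3 or len(set(doses)) < 2:
        raise ValueError("need >= 3 calibration samples spanning >= 2 doses")
    if grid is None:
        grid = list(product(range(1, 6), repeat=6))
    zs = [_z_matrix(s.features) for s in calibration_samples]
    counts = [np.asarray(s.dc_counts, float) for s in calibration_samples]
    ids = [np.arange(len(s.features)) for s in calibration_samples]
    results = []
    for w in grid:
        wv = np.asarray(w, float) * _Z_SIGNS
        freqs = []
        for z, cnt, idx in zip(zs, counts, ids):
            scores = z @ wv
            order = np.lexsort((idx, scores))[: cfg.top_n]
            freqs.append(cnt[order].mean())
        try:
            curve = dosimetry.fit_calibration(doses, freqs)
            resid = 0.0
            for d, f in zip(doses, freqs):
                est, _ = dosimetry.estimate_dose(curve, f)
                resid += (est - d) ** 2
        except (ValueError, RuntimeError):
            resid = math.inf
        results.append((tuple(w), float(resid)))
    results.sort(key=lambda t: (t[1], t[0]))
    return results
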