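"""False-positive dicentric filters.

A predicted dicentric is scored against the other chromosomes of its own
metaphase image with eight scale-invariant morphological filters:

===  =======================  =====================================  =========
id   name                     score                                  threshold
===  =======================  =====================================  =========
i    area                     A(c*) / median A                       0.74
ii   mean width               W_mean(c*) / median W_mean             0.80
iii  median width             W_med(c*) / median W_med               0.77
iv   max width                W_max(c*) / median W_max               0.83
v    centromere width         W_cent(c*) / median W_cent             0.72
vi   oblongness               1 - min(S)/max(S)                      0.28
vii  contour symmetry         min(L)/max(L)                          0.51
viii intercandidate symmetry  min(L_C)/max(L_C)                      0.42
===  =======================  =====================================  =========

A candidate is reclassified as a false positive when ANY enabled filter's
score falls strictly below its threshold (inclusive disjunction).  False
positives — sister-chromatid-separation artifacts, chromosome fragments,
debris — score low (smaller, thinner, less oblong, more asymmetric than
true dicentrics), so thresholds set at the minimum score observed among
true positives remove FPs without sacrificing TPs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace
from itertools import combinations

import numpy as np

from .morphology import ChromosomeObject

__all__ = [
    "FILTER_IDS",
    "DEFAULT_SUBSET",
    "FpFilterScores",
    "FpThresholds",
    "score_candidate",
    "apply_filters",
    "derive_thresholds",
    "forward_select",
    "ks_filter_separation",
]

FILTER_IDS = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii")

#: The forward-selected optimal subset.
DEFAULT_SUBSET = frozenset({"i", "iv", "v", "vi", "viii"})

_SCORE_FIELDS = {
    "i": "r_area", "ii": "r_wmean", "iii": "r_wmed", "iv": "r_wmax",
    "v": "r_wcent", "vi": "oblongness", "vii": "half_symmetry",
    "viii": "ic_symmetry",
}


@dataclass
class FpFilterScores:
    """Per-candidate filter scores; NaN marks a score whose prerequisites
    (e.g. two ranked candidates for filter viii) are missing."""

    r_area: float = math.nan
    r_wmean: float = math.nan
    r_wmed: float = math.nan
    r_wmax: float = math.nan
    r_wcent: float = math.nan
    oblongness: float = math.nan
    half_symmetry: float = math.nan
    ic_symmetry: float = math.nan

    def score(self, filter_id: str) -> float:
        return getattr(self, _SCORE_FIELDS[filter_id])

    def as_dict(self) -> dict[str, float]:
        return {fid: self.score(fid) for fid in FILTER_IDS}


@dataclass
class FpThresholds:
    """Filter thresholds (strict ``<`` comparisons) and the enabled subset."""

    t_area: float = 0.74
    t_wmean: float = 0.80
    t_wmed: float = 0.77
    t_wmax: float = 0.83
    t_wcent: float = 0.72
    t_oblong: float = 0.28
    t_half: float = 0.51
    t_ic: float = 0.42
    subset: frozenset = field(default_factory=lambda: DEFAULT_SUBSET)

    _FIELDS = {
        "i": "t_area", "ii": "t_wmean", "iii": "t_wmed", "iv": "t_wmax",
        "v": "t_wcent", "vi": "t_oblong", "vii": "t_half", "viii": "t_ic",
    }

    def threshold(self, filter_id: str) -> float:
        return getattr(self, self._FIELDS[filter_id])

    def __post_init__(self) -> None:
        self.subset = frozenset(self.subset)
        if not self.subset <= set(FILTER_IDS):
            raise ValueError(f"unknown filter ids in subset: {self.subset}")
        for fid in FILTER_IDS:
            t = self.threshold(fid)
            if not 0 < t < 1:
                raise ValueError(f"threshold for {fid} must lie in (0, 1), got {t}")


def _median_of(objects: list[ChromosomeObject], attr: str) -> float:
    vals = [getattr(o, attr) for o in objects]
    vals = [v for v in vals if v is not None and not math.isnan(v)]
    return float(np.median(vals)) if vals else math.nan


def _valid_objects(objects: list[ChromosomeObject]) -> list[ChromosomeObject]:
    """The chromosome set {c_1..c_N} of an image: objects whose width
    profile was measurable (for feature tables loaded from CSV, objects
    carrying a finite mean width)."""
    return [o for o in objects
            if (o.width_profile is not None and len(o.width_profile) > 0)
            or (o.width_profile is None and not math.isnan(o.w_mean))]


def score_candidate(candidate: ChromosomeObject,
                    image_objects: list[ChromosomeObject]) -> FpFilterScores:
    """Compute all eight filter scores for one candidate dicentric.

    Ratio filters i-v normalize the candidate's value by the within-image
    median over all valid objects (the candidate included).  With fewer
    than 3 valid objects the medians are unreliable; ratio scores are left
    unset and the candidate passes by default.
    """
    scores = FpFilterScores()
    valid = _valid_objects(image_objects)
    if candidate not in image_objects:
        raise ValueError("image_objects must include the candidate itself")
    if len(valid) >= 3:
        for attr, sfield in (("area", "r_area"), ("w_mean", "r_wmean"),
                             ("w_med", "r_wmed"), ("w_max", "r_wmax"),
                             ("w_cent", "r_wcent")):
            med = _median_of(valid, attr)
            val = getattr(candidate, attr)
            if med and not math.isnan(med) and val is not None and not math.isnan(float(val)):
                setattr(scores, sfield, float(val) / med)
    else:
        warnings.warn("fewer than 3 valid objects in image; "
                      "ratio filters left unset", stacklevel=2)
    if candidate.rect_sides is not None:
        lo, hi = candidate.rect_sides
        if hi > 0:
            scores.oblongness = 1.0 - lo / hi
    if candidate.contour_halves is not None:
        lo, hi = candidate.contour_halves
        if hi > 0:
            scores.half_symmetry = lo / hi
    if candidate.intercandidate_arcs is not None:
        lo, hi = candidate.intercandidate_arcs
        if hi > 0:
            scores.ic_symmetry = lo / hi
    return scores


def apply_filters(scores: FpFilterScores,
                  thresholds: FpThresholds | None = None) -> tuple[str, list[str]]:
    """Verdict for one candidate: ``("FP-removed", triggering ids)`` when any
    enabled filter's score is strictly below its threshold, else
    ``("TP-retained", [])``.  Unset (NaN) scores never trigger."""
    thresholds = thresholds or FpThresholds()
    triggered = []
    for fid in sorted(thresholds.subset, key=FILTER_IDS.index):
        s = scores.score(fid)
        if not math.isnan(s) and s < thresholds.threshold(fid):
            triggered.append(fid)
    return ("FP-removed", triggered) if triggered else ("TP-retained", [])


def _floor_2sig(x: float) -> float:
    """Round down to 2 significant digits (floor preserves TP retention)."""
    if x <= 0 or math.isnan(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - 1)
    return math.floor(x / q + 1e-9) * q


def derive_thresholds(tp_scores: list[FpFilterScores],
                      subset=DEFAULT_SUBSET) -> FpThresholds:
    """Set each filter's threshold to the minimum score observed among
    training true positives, rounded down to 2 significant digits.

    Filters with no defined TP scores keep their published default, with a
    warning.  Requires at least 10 TP records.
    """
    if len(tp_scores) < 10:
        raise ValueError("need >= 10 TP score records to derive thresholds")
    out = FpThresholds(subset=subset)
    for fid, tfield in FpThresholds._FIELDS.items():
        vals = [s.score(fid) for s in tp_scores]
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            warnings.warn(f"no TP scores for filter {fid}; keeping default "
                          f"threshold {out.threshold(fid)}", stacklevel=2)
            continue
        t = _floor_2sig(min(vals))
        t = min(max(t, 1e-6), 1 - 1e-9)  # keep inside the valid open interval
        setattr(out, tfield, t)
    return out


def _removed_mask(scored: list[FpFilterScores], subset,
                  thresholds: FpThresholds) -> np.ndarray:
    th = replace(thresholds, subset=frozenset(subset)) if subset is not None else thresholds
    return np.array([apply_filters(s, th)[0] == "FP-removed" for s in scored])


def forward_select(labeled: list[tuple[FpFilterScores, bool]],
                   thresholds: FpThresholds | None = None
                   ) -> tuple[list[str], list[float]]:
    """Greedy forward selection of the filter subset maximizing cumulative
    FP removal.

    Filters are added one at a time, each step taking the filter that most
    increases the fraction of FPs removed by the disjunction of the chosen
    set (ties broken by lower filter id); selection stops when no filter
    adds removals.  Returns the ordered subset and the cumulative FP
    removal fraction after each addition.
    """
    thresholds = thresholds or FpThresholds()
    fp_scores = [s for s, is_fp in labeled if is_fp]
    if not fp_scores:
        return [], []
    removed_by = {fid: _removed_mask(fp_scores, {fid}, thresholds)
                  for fid in FILTER_IDS}
    chosen: list[str] = []
    cumulative: list[float] = []
    covered = np.zeros(len(fp_scores), bool)
    remaining = list(FILTER_IDS)
    while remaining:
        gains = [(int((covered | removed_by[f]).sum()), FILTER_IDS.index(f), f)
                 for f in remaining]
        best_count, _, best = max(gains, key=lambda t: (t[0], -t[1]))
        if best_count <= covered.sum():
            break
        chosen.append(best)
        remaining.remove(best)
        covered |= removed_by[best]
        cumulative.append(covered.sum() / len(fp_scores))
    return chosen, cumulative


def exhaustive_best_subset(labeled: list[tuple[FpFilterScores, bool]],
                           thresholds: FpThresholds | None = None,
                           max_size: int | None = None) -> tuple[frozenset, float]:
    """Brute force over all filter subsets; the oracle for forward_select."""
    thresholds = thresholds or FpThresholds()
    fp_scores = [s for s, is_fp in labeled if is_fp]
    if not fp_scores:
        return frozenset(), 0.0
    removed_by = {fid: _removed_mask(fp_scores, {fid}, thresholds)
                  for fid in FILTER_IDS}
    best, best_frac = frozenset(), 0.0
    sizes = range(1, (max_size or len(FILTER_IDS)) + 1)
    for k in sizes:
        for combo in combinations(FILTER_IDS, k):
            mask = np.zeros(len(fp_scores), bool)
            for fid in combo:
                mask |= removed_by[fid]
            frac = mask.sum() / len(fp_scores)
            if frac > best_frac:
                best, best_frac = frozenset(combo), frac
    return best, best_frac


def ks_filter_separation(tp_scores: list[FpFilterScores],
                         fp_scores: list[FpFilterScores]) -> dict[str, float]:
    """Two-sample Kolmogorov-Smirnov p-value per filter, comparing TP and FP
    score distributions (two-sided)."""
    from scipy.stats import ks_2samp

    out = {}
    for fid in FILTER_IDS:
        a = np.array([s.score(fid) for s in tp_scores])
        b = np.array([s.score(fid) for s in fp_scores])
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) >= 2 and len(b) >= 2:
            out[fid] = float(ks_2samp(a, b).pvalue)
        else:
            out[fid] = math.nan
    return out
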