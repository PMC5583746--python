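import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicecurator.fp_filters import (DEFAULT_SUBSET, FILTER_IDS, FpFilterScores,
                                    FpThresholds, _floor_2sig, apply_filters,
                                    derive_thresholds, exhaustive_best_subset,
                                    forward_select, score_candidate)
from dicecurator.morphology import ChromosomeObject


def _feature_obj(oid, area=100, w=8.0, w_cent=4.0, rect=(10.0, 100.0),
                 halves=(100.0, 110.0), arcs=(40.0, 45.0)):
    """Feature-only object (as if loaded from CSV)."""
    return ChromosomeObject(
        id=oid, mask=np.zeros((0, 0), bool), origin=(0, 0),
        contour=np.zeros((0, 2)), area=area,
        w_mean=w, w_med=w, w_max=w * 1.2, w_cent=w_cent,
        rect_sides=rect, contour_halves=halves, intercandidate_arcs=arcs,
        label="DC", label_source="external")


def test_ratio_scores_relative_to_image_median():
    objs = [_feature_obj(0, area=50), _feature_obj(1, area=100),
            _feature_obj(2, area=100), _feature_obj(3, area=150)]
    s = score_candidate(objs[0], objs)
    assert s.r_area == 0.5
    assert s.r_wmean == 1.0


def test_median_object_scores_unity():
    objs = [_feature_obj(i) for i in range(5)]
    s = score_candidate(objs[2], objs)
    for fid in ("i", "ii", "iii", "iv", "v"):
        assert s.score(fid) == 1.0


def test_square_footprint_has_zero_oblongness():
    objs = [_feature_obj(i, rect=(50.0, 50.0)) for i in range(3)]
    assert score_candidate(objs[0], objs).oblongness == 0.0


def test_candidate_must_be_in_image():
    objs = [_feature_obj(i) for i in range(3)]
    with pytest.raises(ValueError):
        score_candidate(_feature_obj(9), objs)


def test_small_image_leaves_ratios_unset():
    objs = [_feature_obj(0), _feature_obj(1)]
    with pytest.warns(UserWarning):
        s = score_candidate(objs[0], objs)
    assert math.isnan(s.r_area)
    assert apply_filters(s)[0] == "TP-retained"


@pytest.mark.parametrize("r_area, verdict, trig", [
    (0.5, "FP-removed", ["i"]),
    (0.74, "TP-retained", []),   # strict inequality at the threshold
    (0.739, "FP-removed", ["i"]),
    (1.0, "TP-retained", []),
])
def test_area_filter_strict_threshold(r_area, verdict, trig):
    s = FpFilterScores(r_area=r_area, r_wmax=1.0, r_wcent=1.0,
                       oblongness=0.9, ic_symmetry=1.0)
    v, t = apply_filters(s, FpThresholds(subset={"i"}))
    if r_area < 0.74:
        assert (v, t) == ("FP-removed", ["i"])
    else:
        assert v == "TP-retained"


def test_ideal_oblong_chromosome_retained():
    s = FpFilterScores(r_area=1.0, r_wmean=1.0, r_wmed=1.0, r_wmax=1.0,
                       r_wcent=1.0, oblongness=0.9, half_symmetry=1.0,
                       ic_symmetry=1.0)
    assert apply_filters(s, FpThresholds(subset=set(FILTER_IDS)))[0] == "TP-retained"


def test_unset_scores_never_trigger():
    assert apply_filters(FpFilterScores(),
                         FpThresholds(subset=set(FILTER_IDS)))[0] == "TP-retained"


@pytest.mark.parametrize("x, expected", [
    (0.747, 0.74),
    (0.805, 0.80),
    (0.4449, 0.44),
    (0.9, 0.90),
    (0.1234, 0.12),
])
def test_floor_to_two_significant_digits(x, expected):
    assert _floor_2sig(x) == pytest.approx(expected)


def test_derive_thresholds_floor_and_defaults():
    tps = [FpFilterScores(r_area=v, oblongness=0.5) for v in
           np.linspace(0.747, 1.4, 12)]
    with pytest.warns(UserWarning):  # filters with no TP scores keep defaults
        th = derive_thresholds(tps, subset=set(FILTER_IDS))
    assert th.t_area == pytest.approx(0.74)
    assert th.t_oblong == pytest.approx(0.50)
    assert th.t_wmean == FpThresholds().t_wmean  # untouched default
    with pytest.raises(ValueError):
        derive_thresholds(tps[:5])


def test_derived_thresholds_retain_their_training_set(pool_scores):
    """Thresholds floored at the training-TP minimum remove none of the
    TPs they were derived from."""
    tp_scores, _ = pool_scores
    th = derive_thresholds(tp_scores, subset=set(FILTER_IDS))
    removed = sum(apply_filters(s, th)[0] == "FP-removed" for s in tp_scores)
    assert removed == 0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.tuples(*[st.floats(0.0, 1.5) for _ in range(8)]),
                min_size=1, max_size=40),
       st.sets(st.sampled_from(FILTER_IDS), min_size=1, max_size=8))
def test_enlarging_subset_monotone_in_removals(rows, subset):
    scores = [FpFilterScores(*r) for r in rows]
    th_small = FpThresholds(subset=subset)
    th_full = FpThresholds(subset=set(FILTER_IDS))
    removed_small = sum(apply_filters(s, th_small)[0] == "FP-removed" for s in scores)
    removed_full = sum(apply_filters(s, th_full)[0] == "FP-removed" for s in scores)
    assert removed_full >= removed_small


def test_forward_select_skips_redundant_filter():
    # filters i and iv remove exactly the same candidates
    fps = [FpFilterScores(r_area=0.5, r_wmax=0.5) for _ in range(10)]
    labeled = [(s, True) for s in fps]
    chosen, cum = forward_select(labeled)
    assert chosen == ["i"]
    assert cum == [1.0]


def test_forward_select_orders_by_marginal_gain():
    # filter i removes 5 FPs, filter iv removes 3 different FPs
    fps = ([FpFilterScores(r_area=0.5) for _ in range(5)]
           + [FpFilterScores(r_wmax=0.5) for _ in range(3)]
           + [FpFilterScores() for _ in range(2)])
    chosen, cum = forward_select([(s, True) for s in fps])
    assert chosen == ["i", "iv"]
    assert cum == [0.5, 0.8]


def test_forward_select_no_fps_returns_empty():
    labeled = [(FpFilterScores(r_area=1.0), False)]
    assert forward_select(labeled) == ([], [])


def test_greedy_final_removal_matches_bruteforce(rng):
    """Greedy forward selection reaches the exhaustive-best subset's
    cumulative removal on random candidate pools."""
    for _ in range(5):
        labeled = []
        for _ in range(100):
            is_fp = rng.random() < 0.5
            base = rng.uniform(0.2, 0.7, 8) if is_fp else rng.uniform(0.85, 1.4, 8)
            mask = rng.random(8) < (0.4 if is_fp else 1.0)
            vals = np.where(mask, base, rng.uniform(0.9, 1.4, 8))
            labeled.append((FpFilterScores(*vals), is_fp))
        chosen, cum = forward_select(labeled)
        _, best = exhaustive_best_subset(labeled)
        assert cum[-1] == pytest.approx(best)


def test_default_thresholds_match_published_values():
    th = FpThresholds()
    printed = dict(zip(FILTER_IDS, (0.74, 0.80, 0.77, 0.83, 0.72, 0.28, 0.51, 0.42)))
    for fid, val in printed.items():
        assert th.threshold(fid) == val
    assert th.subset == DEFAULT_SUBSET == {"i", "iv", "v", "vi", "viii"}


def test_ks_separation_distinguishes_tp_and_fp_scores(rng):
    from dicecurator.fp_filters import ks_filter_separation

    tps = [FpFilterScores(*rng.uniform(0.9, 1.4, 8)) for _ in range(80)]
    fps = [FpFilterScores(*rng.uniform(0.2, 0.7, 8)) for _ in range(80)]
    pvals = ks_filter_separation(tps, fps)
    assert set(pvals) == set(FILTER_IDS)
    assert all(p < 0.01 for p in pvals.values())
    same = ks_filter_separation(tps, tps)
    assert all(p > 0.5 for p in same.values())


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        FpThresholds(t_area=1.5)
    with pytest.raises(ValueError):
        FpThresholds(subset={"ix"})
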