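import math

import numpy as np
import pytest

from dicecurator.image_selection import (ImageFeatures, SelectionConfig,
                                         SelectionSample, combined_z_score,
                                         compute_image_features,
                                         group_bin_distance, optimize_weights,
                                         select_images, statistical_filter_pass)
from dicecurator.karyotype import relative_lengths
from dicecurator.morphology import analyze_image


def _features(**kw):
    base = dict(mw=10.0, cd=0.05, wd=0.1, obj_count=46, seg_obj_count=46,
                classified_count=44, classified_ratio=0.95,
                group_counts=(10, 16, 20), group_bin_distance=0.0)
    base.update(kw)
    return ImageFeatures(**base)


def _sample(n=10, **kw):
    return [_features(image_id=i, **kw) for i in range(n)]


# ---------------------------------------------------------------------------
# feature computation


def test_identical_bars_have_expected_length_width_ratio():
    img = np.zeros((200, 200), bool)
    for r in (20, 60, 100, 140):          # four 100x10 bars
        img[r:r + 10, 40:140] = True
    objs = analyze_image(img)
    # constant-width bars carry no constriction: force-classify for the mean
    for o in objs:
        o.label = "MC"
    feats = compute_image_features(objs)
    assert feats.obj_count == feats.seg_obj_count == 4
    assert abs(feats.mw - 10.0) <= 1.0
    assert feats.classified_ratio == 1.0


def test_smooth_blobs_yield_zero_classified_ratio(rng):
    from dicecurator.synthetic import generate_nucleus

    img = np.zeros((300, 300), bool)
    for k in range(2):
        m, _ = generate_nucleus(rng)
        img[10 + 140 * k:10 + 140 * k + m.shape[0], 10:10 + m.shape[1]] |= m
    feats = compute_image_features(analyze_image(img))
    assert feats.classified_ratio == 0.0
    assert math.isnan(feats.mw)


# ---------------------------------------------------------------------------
# statistical filters


def test_identical_images_all_kept():
    flags = statistical_filter_pass(_sample(10))
    assert all(keep for keep, _ in flags)


def test_inflated_mw_outlier_removed_at_T_1_5():
    feats = _sample(9)
    mws = [f.mw for f in feats]
    outlier = _features(image_id=9)
    outlier.mw = np.mean(mws) + 10.0  # >> 1.5 SD once spread exists
    feats[0].mw += 0.3                # give the sample a little spread
    feats.append(outlier)
    flags = statistical_filter_pass(feats)
    assert flags[-1] == (False, ["I"])
    assert all(keep for keep, _ in flags[:-1])


def test_object_count_range_filter():
    feats = _sample(5)
    feats[2].obj_count = 80
    flags = statistical_filter_pass(feats)
    assert flags[2][0] is False and "IV" in flags[2][1]


def test_classified_ratio_filter_threshold_choice():
    feats = _sample(5)
    feats[1].classified_ratio = 0.65
    assert statistical_filter_pass(feats, SelectionConfig())[1][0] is True
    strict = SelectionConfig(classified_ratio_min=0.7)
    assert statistical_filter_pass(feats, strict)[1] == (False, ["VI"])


def test_removal_set_monotone_in_T(rng):
    feats = _sample(20)
    for f in feats:
        f.mw = rng.normal(10, 1)
        f.cd = rng.normal(0.05, 0.01)
        f.wd = rng.normal(0.1, 0.02)
    removed = {}
    for T in (1.0, 1.5, 2.5):
        flags = statistical_filter_pass(feats, SelectionConfig(T=T))
        removed[T] = {i for i, (k, _) in enumerate(flags) if not k}
    assert removed[2.5] <= removed[1.5] <= removed[1.0]


# ---------------------------------------------------------------------------
# combined z


def test_homogeneous_sample_scores_zero():
    scores = combined_z_score(_sample(8))
    assert np.allclose(scores, 0.0)


def test_sign_conventions_of_combined_z():
    feats = _sample(9)
    # an image above the sample mean in LW scores its (positive) z-score
    mws = np.array([8, 8, 8, 8, 12, 8, 8, 8, 8], float)
    z = (mws - mws.mean()) / mws.std(ddof=1)
    for f, v in zip(feats, mws):
        f.mw = v
    scores = combined_z_score(feats)
    assert scores[4] == pytest.approx(z[4])
    # classified ratio enters with a negative sign (higher ratio = better)
    feats = _sample(9)
    ratios = np.array([0.9] * 8 + [0.99])
    zr = (ratios - ratios.mean()) / ratios.std(ddof=1)
    for f, v in zip(feats, ratios):
        f.classified_ratio = v
    scores = combined_z_score(feats)
    assert scores[8] == pytest.approx(-zr[8])


def test_combined_z_invariant_to_affine_feature_transform():
    feats_a = _sample(12)
    rngl = np.random.default_rng(3)
    mws = rngl.normal(10, 2, 12)
    for f, v in zip(feats_a, mws):
        f.mw = v
    sa = combined_z_score(feats_a)
    feats_b = _sample(12)
    for f, v in zip(feats_b, 5.0 * mws + 40.0):
        f.mw = v
    sb = combined_z_score(feats_b)
    assert np.allclose(sa, sb)


def test_single_image_sample_warns_and_scores_zero():
    with pytest.warns(UserWarning):
        scores = combined_z_score(_sample(1))
    assert scores[0] == 0.0


def test_weight_validation():
    with pytest.raises(ValueError):
        combined_z_score(_sample(3), weights=(1, 1, 1))
    with pytest.raises(ValueError):
        SelectionConfig(weights=(0, 1, 1, 1, 1, 1))


# ---------------------------------------------------------------------------
# group bins


def test_reference_karyotype_distances():
    f = relative_lengths("female")
    counts, dist = group_bin_distance(f * 1000.0, sex="female")
    assert counts == (10, 16, 20) and dist == 0.0
    m = relative_lengths("male")
    counts, dist = group_bin_distance(m, sex="male")
    assert counts == (10, 15, 21) and dist == 0.0


def test_observed_vector_euclidean_distance():
    # (12, 16, 18) vs female ideal (10, 16, 20): distance sqrt(8)
    areas = np.concatenate([np.full(12, 0.035), np.full(16, 0.025),
                            np.full(18, 0.01)])
    counts, dist = group_bin_distance(areas / areas.sum() * 5.0, sex="female")
    assert counts == (12, 16, 18)
    assert dist == pytest.approx(math.sqrt(8))


def test_group_bin_permutation_and_scale_invariance(rng):
    areas = relative_lengths("female") * 7777.0
    c1, d1 = group_bin_distance(areas, "auto")
    c2, d2 = group_bin_distance(rng.permutation(areas) * 3.3, "auto")
    assert c1 == c2 and d1 == d2


def test_custom_genome_thresholds_shift_group_boundaries():
    areas = relative_lengths("female")
    counts, _ = group_bin_distance(areas, "female", thresholds=(0.035, 0.025))
    assert counts[0] < 10  # stricter AB cut moves chromosomes into C


def test_empty_object_set_scores_maximal_distance():
    with pytest.warns(UserWarning):
        counts, dist = group_bin_distance(np.array([]), sex="female")
    assert counts == (0, 0, 0)
    assert dist == pytest.approx(np.linalg.norm([10, 16, 20]))


# ---------------------------------------------------------------------------
# selection


def test_selection_contract_top_n(rng):
    feats = _sample(500)
    for f in feats:
        f.mw = rng.normal(10, 1)
    cfg = SelectionConfig(top_n=250)
    chosen = select_images(feats, "combined_z", cfg)
    assert len(chosen) == 250
    scores = [feats[i].combined_z for i in chosen]
    assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))


def test_filters_only_preserves_order():
    feats = _sample(6)
    feats[3].obj_count = 99
    chosen = select_images(feats, "filters_only", SelectionConfig(top_n=250))
    assert chosen == [0, 1, 2, 4, 5]


def test_selecting_all_images_reproduces_unfiltered_dc_frequency(rng):
    """With top_n = all images, ranking excludes nothing, so the DC
    frequency equals the unfiltered value exactly."""
    m = 40
    feats = _sample(m)
    for f in feats:
        f.mw = rng.normal(10, 1)
    counts = rng.poisson(0.3, m)
    cfg = SelectionConfig(top_n=m)
    chosen = select_images(feats, "combined_z", cfg)
    assert sorted(chosen) == list(range(m))
    assert counts[chosen].mean() == counts.mean()


def test_unknown_method_rejected():
    with pytest.raises(ValueError):
        select_images(_sample(3), "best_images")


# ---------------------------------------------------------------------------
# weight optimization


def _calibration_set(rng, confound=False):
    """Synthetic calibration samples; with ``confound`` some doses carry
    images whose spurious extra DCs correlate with a high LW score.  The
    planted burden alternates across doses so the linear-quadratic fit
    cannot absorb it, and a second feature (object count) has deliberate
    outliers so a ranking that does not emphasise LW keeps part of the
    planted set.  Fully deterministic by construction."""
    samples = []
    # 40% planted gives the planted group a fixed LW z of sqrt(0.6/0.4)=1.22
    # (total score 1.64 with the within-group count z of 0.42); 10% clean
    # count-outliers score -0.81+3.0 = 2.19, so a unit LW weight ranks the
    # planted images ahead of them while an LW weight of 5 reverses that
    n_bad = {0.5: 40, 1.5: 0, 2.5: 40, 3.5: 0}
    for dose in (0.5, 1.5, 2.5, 3.5):
        lam = 0.001 + 0.05 * dose + 0.05 * dose * dose
        m = 100
        feats = _sample(m)
        counts = np.zeros(m)
        good = list(range(m - (n_bad[dose] if confound else 0)))
        total = round(lam * m)
        for k in range(total):           # spread the baseline DCs evenly
            counts[good[k % len(good)]] += 1
        if confound:
            for i in range(m):
                feats[i].mw = 10.0
                feats[i].obj_count = 46
            for i in range(40, 50):      # good images with outlier counts
                feats[i].obj_count = 60
            for i in range(m - n_bad[dose], m):  # planted high-LW images
                feats[i].mw = 13.0
                counts[i] += 4
        samples.append(SelectionSample(f"{dose}Gy", feats, counts, dose))
    return samples


def test_uniform_quality_makes_weights_indifferent(rng):
    samples = _calibration_set(rng, confound=False)
    grid = [(1, 1, 1, 1, 1, 1), (5, 1, 1, 1, 1, 1), (1, 5, 3, 2, 4, 1)]
    res = optimize_weights(samples, SelectionConfig(top_n=100), grid=grid)
    vals = [r for _, r in res]
    assert max(vals) - min(vals) <= 1e-9  # identical selections, z ~ 0


def test_lw_weight_preferred_under_lw_confound(rng):
    samples = _calibration_set(rng, confound=True)
    grid = [(1, 1, 1, 1, 1, 1), (5, 1, 1, 1, 1, 1)]
    res = optimize_weights(samples, SelectionConfig(top_n=60), grid=grid)
    assert res[0][0] == (5, 1, 1, 1, 1, 1)
    assert res[0][1] < res[1][1]


def test_optimize_weights_requires_calibration_span(rng):
    samples = _calibration_set(rng)[:1]
    with pytest.raises(ValueError):
        optimize_weights(samples, SelectionConfig())
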