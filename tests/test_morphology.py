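import numpy as np
import pytest

from dicecurator.morphology import (ChromosomeObject, WidthProfile,
                                    _trace_contour, analyze_image,
                                    analyze_object,
                                    detect_centromere_candidates,
                                    extract_objects)
from dicecurator.synthetic import (ChromosomeSpec, _stamp_tube,
                                   generate_chromosome, generate_nucleus)


def _bar(width, length=100, pad=20):
    img = np.zeros((width + 2 * pad, length + 2 * pad), bool)
    img[pad:pad + width, pad:pad + length] = True
    return img


def _analyzed(mask):
    obj = ChromosomeObject(0, mask, (0, 0), _trace_contour(mask, (0, 0)),
                           int(mask.sum()))
    return analyze_object(obj)


# ---------------------------------------------------------------------------
# extraction


def test_blank_raster_yields_no_objects():
    assert extract_objects(np.zeros((30, 30), bool)) == []


def test_two_disjoint_blobs_counted_with_min_area():
    img = np.zeros((60, 60), bool)
    img[5:15, 5:25] = True    # 200 px
    img[35:45, 30:50] = True  # 200 px
    objs = extract_objects(img, min_area=50)
    assert len(objs) == 2
    assert sorted(o.area for o in objs) == [200, 200]
    assert extract_objects(img, min_area=300) == []


def test_all_foreground_flagged_non_chromosome():
    objs = extract_objects(np.ones((20, 20), bool))
    assert len(objs) == 1
    assert objs[0].label == "non-chromosome"


def test_area_conservation_on_random_raster(rng):
    img = rng.random((120, 120)) > 0.7
    objs = extract_objects(img, min_area=1)
    assert sum(o.area for o in objs) == int(img.sum())


def test_grayscale_input_is_otsu_thresholded():
    img = np.full((60, 60), 200, np.uint8)
    img[20:30, 10:50] = 30  # dark bar on light background
    objs = extract_objects(img)
    assert len(objs) == 1
    assert objs[0].area == 400


# ---------------------------------------------------------------------------
# centerline / width profile oracles


@pytest.mark.parametrize("width", [6, 10, 16])
def test_constant_width_bar_oracle(width):
    """Rendered bars of known width: profile statistics within 10%."""
    obj = analyze_image(_bar(width))[0]
    for stat in (obj.w_mean, obj.w_med, obj.w_max):
        assert abs(stat - width) / width <= 0.10
    assert 90 <= obj.centerline_length <= 104
    lo, hi = obj.rect_sides
    assert abs(lo - width) <= 1 and abs(hi - 100) <= 1
    assert obj.n_candidates == 0


def test_disc_is_unprocessable():
    yy, xx = np.mgrid[-25:26, -25:26]
    obj = analyze_image((yy ** 2 + xx ** 2) <= 400)[0]
    assert obj.label == "unprocessable"
    assert obj.centerline_length <= 4


def test_bent_tube_centerline_tracks_spine_length(rng):
    mask, _ = generate_chromosome(ChromosomeSpec(120, 10, curvature=0.3), rng)
    obj = _analyzed(mask)
    assert abs(obj.centerline_length - 120) / 120 <= 0.10


def test_constriction_width_drop_measured(rng):
    """A 60% Gaussian constriction renders and measures near 40% of the
    shoulder width at the detected candidate."""
    mask, _ = generate_chromosome(
        ChromosomeSpec(150, 12, 0.05, ((0.5, 0.6),)), rng)
    obj = _analyzed(mask)
    shoulder = obj.w_max
    assert abs(shoulder - 12) / 12 <= 0.15
    assert obj.n_candidates >= 1
    w_c = obj.candidates[0].width_at
    assert abs(w_c - 0.4 * shoulder) / (0.4 * shoulder) <= 0.25


def test_constant_profile_normalizes_to_zeros():
    wp = WidthProfile(np.linspace(0, 1, 9), np.full(9, 7.0))
    assert (wp.normalized_widths == 0).all()


# ---------------------------------------------------------------------------
# candidates


def test_flat_profile_has_no_candidates():
    wp = WidthProfile(np.linspace(0, 1, 41), np.full(41, 8.0))
    assert detect_centromere_candidates(wp) == []


def test_two_constrictions_ranked_by_depth(rng):
    mask, _ = generate_chromosome(
        ChromosomeSpec(200, 10, 0.05, ((0.3, 0.6), (0.7, 0.45))), rng)
    obj = _analyzed(mask)
    assert obj.n_candidates >= 2
    assert abs(obj.candidates[0].position - 0.3) <= 0.05
    assert abs(obj.candidates[1].position - 0.7) <= 0.05
    assert obj.candidates[0].depth >= obj.candidates[1].depth
    assert obj.label == "DC"
    assert obj.w_cent == obj.candidates[0].width_at


def test_single_constriction_localization(rng):
    """Mean localization error over simulated single-constriction tubes
    stays below 0.03 arc fraction."""
    errs = []
    for _ in range(30):
        pos = rng.uniform(0.3, 0.7)
        mask, _ = generate_chromosome(
            ChromosomeSpec(120, 10, 0.12, ((pos, 0.5),)), rng)
        obj = _analyzed(mask)
        assert obj.label == "MC"
        det = obj.candidates[0].position
        errs.append(min(abs(det - pos), abs((1 - det) - pos)))
    assert np.mean(errs) <= 0.03


def test_min_depth_threshold_excludes_shallow_dips(rng):
    mask, _ = generate_chromosome(
        ChromosomeSpec(150, 12, 0.05, ((0.5, 0.5),)), rng)
    obj = ChromosomeObject(0, mask, (0, 0), _trace_contour(mask, (0, 0)),
                           int(mask.sum()))
    analyze_object(obj)
    deep = detect_centromere_candidates(obj.width_profile, min_depth=0.2)
    shallow = detect_centromere_candidates(obj.width_profile, min_depth=0.9)
    assert len(deep) >= 1 and shallow == []


# ---------------------------------------------------------------------------
# geometry


def test_symmetric_tube_contour_halves_balance(rng):
    mask, _ = generate_chromosome(ChromosomeSpec(120, 10, 0.0, ()), rng)
    obj = _analyzed(mask)
    lo, hi = obj.contour_halves
    assert lo / hi >= 0.9
    perimeter = np.linalg.norm(
        np.diff(np.vstack([obj.contour, obj.contour[:1]]), axis=0), axis=1).sum()
    assert abs((lo + hi) - perimeter) / perimeter <= 0.01


def test_intercandidate_arcs_symmetric_on_symmetric_dicentric(rng):
    mask, _ = generate_chromosome(
        ChromosomeSpec(200, 10, 0.0, ((0.3, 0.5), (0.7, 0.5))), rng)
    obj = _analyzed(mask)
    assert obj.intercandidate_arcs is not None
    lo, hi = obj.intercandidate_arcs
    assert lo / hi >= 0.9


def test_rotation_invariance_of_shape_ratios():
    """Bounding-rectangle aspect and area change by <= 2% under a 30-degree
    rotation of the same tube geometry."""
    t = np.linspace(0, 120, 241)
    base = np.stack([np.zeros_like(t), t], axis=1)
    radii = np.full(len(t), 5.0)

    def _rot(deg):
        a = np.deg2rad(deg)
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    feats = []
    for s in (base @ _rot(10).T, base @ _rot(40).T):
        obj = _analyzed(_stamp_tube(s - s.min(axis=0), radii))
        lo, hi = obj.rect_sides
        feats.append((lo / hi, obj.area))
    (r0, a0), (r1, a1) = feats
    assert abs(r1 - r0) / r0 <= 0.02
    assert abs(a1 - a0) / a0 <= 0.02


def test_smooth_ellipse_labelled_non_chromosome(rng):
    mask, _ = generate_nucleus(rng)
    obj = _analyzed(mask)
    assert obj.label == "non-chromosome"
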