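"""Ground-truthed synthetic chromosomes, metaphase images and dose samples.

The generator emulates the object classes that drive false-positive
dicentric calls and image-quality filtering in real Giemsa metaphase
preparations: monocentric and dicentric chromosomes rendered as smooth
tubes with Gaussian width constrictions at centromeres, sister-chromatid
separation (SCS) rendered as pairs of thin parallel tubes, acentric
fragments as truncated tubes, overlapped clusters as unions of crossing
tubes, and nuclei/debris as smooth blobs.  Object sizes follow the bundled
reference-genome relative chromosome lengths so that area-based group
binning behaves as it does on real karyotypes, and per-cell dicentric
counts follow a Poisson law whose mean is linear-quadratic in dose.

All randomness flows through one explicitly passed ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import karyotype

__all__ = [
    "ChromosomeSpec",
    "CellSpec",
    "SyntheticTruth",
    "generate_chromosome",
    "generate_scs_pair",
    "generate_scs_chromatid",
    "generate_fragment",
    "generate_debris",
    "generate_nucleus",
    "generate_overlap_cluster",
    "generate_metaphase",
    "generate_dose_sample",
    "generate_candidate_pool",
    "linear_quadratic",
]

#: Default rendering geometry: pixels of spine length per unit of relative
#: genome length, and tube width in pixels.  At these values a mid-sized
#: chromosome (~2.2% of the genome) is ~100 px long and 8 px wide,
#: comparable to a 1040x1392 metaphase capture.
LENGTH_SCALE = 4500.0
BASE_WIDTH = 8.0
CONSTRICTION_SIGMA = 0.05  # arc-fraction width of the centromeric dip


def linear_quadratic(dose: float, c0: float, alpha: float, beta: float) -> float:
    """Expected dicentrics per cell at ``dose`` Gy."""
    return c0 + alpha * dose + beta * dose * dose


def _length_for_area(target_area: float, width: float, constrictions) -> float:
    """Spine length making the rendered tube area equal ``target_area``.

    A stamped tube's area is L*w + pi*(w/2)^2 (end caps) minus the Gaussian
    constriction dips, each removing ~ sqrt(2 pi)*sigma*L*w*depth.  Group
    binning compares *relative* areas against percent-level thresholds, so
    rendered areas must track the karyotype proportions, not just lengths.
    """
    import math

    dip = math.sqrt(2 * math.pi) * CONSTRICTION_SIGMA * sum(d for _, d in constrictions)
    L = (target_area - math.pi * width * width / 4) / (width * (1 - dip))
    return max(L, 4 * width)


@dataclass
class ChromosomeSpec:
    spine_length: float
    base_width: float = BASE_WIDTH
    curvature: float = 0.15           # sagitta as a fraction of spine length
    constrictions: tuple = ()         # (arc position, depth) pairs


@dataclass
class CellSpec:
    """Composition of one synthetic metaphase cell."""

    sex: str = "female"
    n_dc: int = 0
    n_scs_pairs: int = 0
    n_fragments: int = 0
    n_overlaps: int = 0
    n_nuclei: int = 0
    n_debris: int = 0
    condensation: float = 1.0
    canvas: tuple[int, int] = (1040, 1392)
    base_width: float = BASE_WIDTH
    length_scale: float = LENGTH_SCALE


@dataclass
class SyntheticTruth:
    """Generator ground truth for one image or object pool."""

    classes: list[str] = field(default_factory=list)
    centromere_positions: list[tuple[float, ...]] = field(default_factory=list)
    relative_areas: list[float] = field(default_factory=list)
    dc_count: int = 0
    quality: str = "clean"
    seed: int | None = None


# ---------------------------------------------------------------------------
# primitive rendering


def _bezier_spine(length: float, curvature: float, rng: np.random.Generator,
                  step: float = 0.5) -> np.ndarray:
    """Arc-length sampled quadratic Bezier of the requested length with a
    perpendicular midpoint offset of ``curvature * length`` (random side),
    randomly rotated."""
    sag = curvature * length * rng.choice([-1.0, 1.0])
    p0 = np.array([0.0, 0.0])
    p2 = np.array([0.0, length])
    p1 = np.array([sag * 2.0, length / 2.0])  # control point; sagitta ~ sag
    t = np.linspace(0, 1, max(int(length * 4), 32))
    pts = ((1 - t) ** 2)[:, None] * p0 + (2 * t * (1 - t))[:, None] * p1 + (t ** 2)[:, None] * p2
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    pts = pts * (length / s[-1])  # rescale so arc length equals request
    s = s * (length / s[-1])
    targets = np.arange(0, length + step / 2, step)
    out = np.empty((len(targets), 2))
    for j in range(2):
        out[:, j] = np.interp(targets, s, pts[:, j])
    ang = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return out @ rot.T


def _stamp_tube(spine: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Rasterize the union of discs centred on the spine."""
    rmax = radii.max()
    lo = np.floor(spine.min(axis=0) - rmax - 1).astype(int)
    hi = np.ceil(spine.max(axis=0) + rmax + 2).astype(int)
    shape = tuple(hi - lo)
    mask = np.zeros(shape, bool)
    for p, r in zip(spine - lo, radii):
        rr = int(np.ceil(r))
        r0, c0 = int(np.floor(p[0])) - rr, int(np.floor(p[1])) - rr
        size = 2 * rr + 2
        ys = np.arange(r0, r0 + size)
        xs = np.arange(c0, c0 + size)
        yy, xx = np.meshgrid(ys, xs, indexing="ij")
        disc = (yy - p[0]) ** 2 + (xx - p[1]) ** 2 <= r * r
        ys_ok = (ys >= 0) & (ys < shape[0])
        xs_ok = (xs >= 0) & (xs < shape[1])
        mask[np.ix_(ys[ys_ok], xs[xs_ok])] |= disc[np.ix_(ys_ok, xs_ok)]
    return mask


def _width_function(positions: np.ndarray, base: float,
                    constrictions) -> np.ndarray:
    w = np.full_like(positions, base, dtype=float)
    for pos, depth in constrictions:
        w *= 1.0 - depth * np.exp(-((positions - pos) ** 2) / (2 * CONSTRICTION_SIGMA ** 2))
    return w


def _self_intersects(spine: np.ndarray, width: float) -> bool:
    """Non-adjacent spine points closer than the tube width merge the tube."""
    n = len(spine)
    if n < 20:
        return False
    sub = spine[::4]
    d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2)
    idx = np.abs(np.arange(len(sub))[:, None] - np.arange(len(sub))[None, :])
    bad = (d < width) & (idx > max(4, int(2 * width)))
    return bool(bad.any())


def generate_chromosome(spec: ChromosomeSpec, rng: np.random.Generator,
                        max_retries: int = 10) -> tuple[np.ndarray, dict]:
    """Render one chromosome-like tube; returns (mask, truth).

    Truth records the spine length, the constriction loci (arc fractions)
    and the implied class: DC for two constrictions, MC for one, "tube"
    for none.
    """
    if spec.spine_length < 4 * spec.base_width:
        raise ValueError("spine length must be at least 4x base width")
    for depth in (d for _, d in spec.constrictions):
        if not 0 < depth < 1:
            raise ValueError("constriction depths must lie in (0, 1)")
    for attempt in range(max_retries):
        spine = _bezier_spine(spec.spine_length, spec.curvature, rng)
        if not _self_intersects(spine, spec.base_width):
            break
    else:
        raise RuntimeError("could not draw a non-self-intersecting spine")
    t = np.linspace(0, 1, len(spine))
    widths = _width_function(t, spec.base_width, spec.constrictions)
    mask = _stamp_tube(spine, widths / 2)
    n_con = len(spec.constrictions)
    truth = {
        "class": "DC" if n_con == 2 else ("MC" if n_con == 1 else "tube"),
        "centromeres": tuple(p for p, _ in spec.constrictions),
        "spine_length": spec.spine_length,
        "base_width": spec.base_width,
    }
    return mask, truth


def generate_scs_pair(spine_length: float, base_width: float,
                      rng: np.random.Generator,
                      curvature: float = 0.1) -> tuple[np.ndarray, dict]:
    """Two thin parallel half-width tubes: a chromosome whose sister
    chromatids have separated.  Rendered in one raster with a gap, so the
    chromatids label as two objects in a full image."""
    spine = _bezier_spine(spine_length, curvature, rng)
    tang = np.gradient(spine, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1), 1e-9)[:, None]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offset = 0.55 * base_width
    w = np.full(len(spine), 0.4 * base_width)
    m1 = _stamp_tube(spine + offset * normal, w / 2)
    m2 = _stamp_tube(spine - offset * normal, w / 2)
    shape = (max(m1.shape[0], m2.shape[0]) + 2, max(m1.shape[1], m2.shape[1]) + 2)
    mask = np.zeros(shape, bool)
    mask[: m1.shape[0], : m1.shape[1]] |= m1
    mask[: m2.shape[0], : m2.shape[1]] |= m2
    return mask, {"class": "SCS-fragment", "centromeres": (), "spine_length": spine_length}


def generate_scs_chromatid(spine_length: float, base_width: float,
                           rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """A single separated chromatid: thin tube at ~40% of normal width."""
    spine = _bezier_spine(spine_length, 0.12, rng)
    w = np.full(len(spine), 0.4 * base_width)
    return _stamp_tube(spine, w / 2), {
        "class": "SCS-fragment", "centromeres": (), "spine_length": spine_length}


def generate_fragment(parent_length: float, base_width: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Acentric chromosome fragment: a short constriction-free tube."""
    frac = rng.uniform(0.15, 0.4)
    length = max(parent_length * frac, 4 * base_width)
    spine = _bezier_spine(length, 0.08, rng)
    w = np.full(len(spine), base_width)
    return _stamp_tube(spine, w / 2), {
        "class": "fragment", "centromeres": (), "spine_length": length}


def generate_debris(rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Small irregular blob of cellular debris."""
    n = rng.integers(2, 5)
    centers = rng.uniform(0, 12, size=(n, 2))
    radii = rng.uniform(2.5, 5.0, size=n)
    return _stamp_tube(centers, radii), {"class": "debris", "centromeres": ()}


def generate_nucleus(rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Smooth interphase nucleus: a filled ellipse."""
    a = rng.uniform(35, 55)
    b = a * rng.uniform(0.55, 0.8)
    ang = rng.uniform(0, np.pi)
    n = int(np.ceil(a)) + 2
    yy, xx = np.meshgrid(np.arange(-n, n + 1), np.arange(-n, n + 1), indexing="ij")
    ca, sa = np.cos(ang), np.sin(ang)
    u = ca * yy + sa * xx
    v = -sa * yy + ca * xx
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask, {"class": "nucleus", "centromeres": ()}


def generate_overlap_cluster(l1: float, l2: float, base_width: float,
                             rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Two chromosomes crossing at a wide angle, segmented as one object."""
    s1 = _bezier_spine(l1, 0.1, rng)
    s2 = _bezier_spine(l2, 0.1, rng)
    s2 = s2 - s2.mean(axis=0) + s1.mean(axis=0)  # force intersection
    both = np.vstack([s1, s2])
    lo = both.min(axis=0)
    m = _stamp_tube(both - lo, np.full(len(both), base_width / 2))
    return m, {"class": "overlap-cluster", "centromeres": ()}


# ---------------------------------------------------------------------------
# whole cells


def _centromere_layout(rng: np.random.Generator) -> tuple[float, float]:
    """(position, depth) of a normal chromosome's centromere."""
    pos = rng.uniform(0.25, 0.5)
    if rng.random() < 0.5:
        pos = 1.0 - pos
    return pos, rng.uniform(0.3, 0.5)


def _dicentric_spec(l1: float, l2: float, base_width: float,
                    rng: np.random.Generator,
                    target_area: float | None = None) -> ChromosomeSpec:
    """Fusion of two full chromosomes, one centromere kept from each."""
    total = l1 + l2
    u1 = rng.uniform(0.3, 0.6)
    u2 = rng.uniform(0.4, 0.7)
    c1 = u1 * l1 / total
    c2 = (l1 + u2 * l2) / total
    # centromeric constrictions of a dicentric are the same structure as a
    # monocentric's; depths share one distribution
    depths = rng.uniform(0.3, 0.5, size=2)
    cons = ((c1, depths[0]), (c2, depths[1]))
    if target_area is not None:
        total = _length_for_area(target_area, base_width, cons)
    return ChromosomeSpec(
        spine_length=total, base_width=base_width, curvature=0.12,
        constrictions=cons)


def _place(canvas: np.ndarray, occupancy: np.ndarray, mask: np.ndarray,
           rng: np.random.Generator, margin: int = 3,
           max_tries: int = 300) -> tuple[int, int]:
    """Drop ``mask`` at a random position that keeps a ``margin``-pixel gap
    to already placed objects (dilated-occupancy rejection sampling)."""
    from scipy import ndimage as ndi

    h, w = mask.shape
    H, W = canvas.shape
    if h + 2 > H or w + 2 > W:
        raise ValueError(
            f"canvas {canvas.shape} too small for an object of {mask.shape}; "
            "increase the canvas size")
    dil = ndi.binary_dilation(mask, iterations=margin)
    for _ in range(max_tries):
        r = int(rng.integers(1, H - h - 1))
        c = int(rng.integers(1, W - w - 1))
        if not (occupancy[r:r + h, c:c + w] & dil).any():
            canvas[r:r + h, c:c + w] |= mask
            occupancy[r:r + h, c:c + w] |= dil
            return r, c
    raise ValueError(
        f"could not place an object of {mask.shape} on canvas {canvas.shape}; "
        "increase the canvas size or reduce object counts")


def generate_metaphase(spec: CellSpec, seed=None) -> tuple[np.ndarray, SyntheticTruth]:
    """Render one metaphase cell and its ground truth.

    The 46-chromosome complement is drawn with areas proportional to the
    bundled reference relative lengths; dicentrics consume two chromosomes
    each (fusion partners drawn with probability proportional to length,
    as breakage probability scales with DNA content) and contribute one
    reciprocal acentric fragment; SCS pairs consume one chromosome and
    render two thin chromatids; overlaps consume two; nuclei, debris and
    extra fragments are additive.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fracs = karyotype.relative_lengths(spec.sex)
    lengths = fracs * spec.length_scale / spec.condensation
    width = spec.base_width * spec.condensation
    area_scale = spec.length_scale * spec.base_width  # invariant to condensation
    available = list(range(46))
    truth = SyntheticTruth(seed=seed if isinstance(seed, int) else None,
                           dc_count=spec.n_dc)
    pieces: list[tuple[np.ndarray, dict]] = []

    def consume_weighted() -> int:
        w = np.array([lengths[i] for i in available])
        i = rng.choice(len(available), p=w / w.sum())
        return available.pop(int(i))

    def consume_uniform() -> int:
        return available.pop(int(rng.integers(len(available))))

    for _ in range(spec.n_dc):
        i, j = consume_weighted(), consume_weighted()
        pieces.append(generate_chromosome(
            _dicentric_spec(lengths[i], lengths[j], width, rng,
                            target_area=(fracs[i] + fracs[j]) * area_scale), rng))
        pieces.append(generate_fragment(min(lengths[i], lengths[j]), width, rng))
    for _ in range(spec.n_scs_pairs):
        i = consume_uniform()
        for _ in range(2):
            pieces.append(generate_scs_chromatid(lengths[i], width, rng))
    for _ in range(spec.n_overlaps):
        i, j = consume_uniform(), consume_uniform()
        pieces.append(generate_overlap_cluster(lengths[i], lengths[j], width, rng))
    for _ in range(spec.n_fragments):
        i = consume_uniform()
        for _ in range(2):
            pieces.append(generate_fragment(lengths[i], width, rng))
    for i in available:
        pos, depth = _centromere_layout(rng)
        cons = ((pos, depth),)
        pieces.append(generate_chromosome(
            ChromosomeSpec(spine_length=_length_for_area(fracs[i] * area_scale,
                                                         width, cons),
                           base_width=width, curvature=rng.uniform(0.05, 0.2),
                           constrictions=cons), rng))
    for _ in range(spec.n_nuclei):
        pieces.append(generate_nucleus(rng))
    for _ in range(spec.n_debris):
        pieces.append(generate_debris(rng))

    canvas = np.zeros(spec.canvas, bool)
    occupancy = np.zeros(spec.canvas, bool)
    order = rng.permutation(len(pieces))  # large objects need not go first
    total_area = sum(int(m.sum()) for m, _ in pieces)
    for k in order:
        mask, info = pieces[k]
        _place(canvas, occupancy, mask, rng)
    for mask, info in pieces:
        truth.classes.append(info["class"])
        truth.centromere_positions.append(info.get("centromeres", ()))
        truth.relative_areas.append(int(mask.sum()) / total_area)
    artifacts = spec.n_scs_pairs + spec.n_fragments + spec.n_overlaps + spec.n_debris
    truth.quality = "clean" if artifacts == 0 else "degraded"
    return canvas, truth


# ---------------------------------------------------------------------------
# dose-response samples


@dataclass
class DoseSample:
    sample_id: str
    dose_gy: float
    dc_counts: np.ndarray
    images: list | None = None
    truths: list | None = None


def generate_dose_sample(dose_gy: float, curve: tuple[float, float, float],
                         n_cells: int, seed=None, quality_mix: dict | None = None,
                         render: bool = False,
                         cell_spec: CellSpec | None = None,
                         sample_id: str | None = None) -> DoseSample:
    """Per-cell dicentric counts drawn Poisson(c0 + alpha D + beta D^2),
    optionally rendering each cell with that many true dicentrics.

    ``quality_mix`` maps artifact fields of :class:`CellSpec`
    (``n_scs_pairs`` etc.) to the value used in a randomly chosen "poor"
    subset of cells; key ``p_poor`` gives that subset's fraction.
    """
    if dose_gy < 0 or n_cells < 1:
        raise ValueError("dose must be >= 0 and n_cells >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lam = linear_quadratic(dose_gy, *curve)
    counts = rng.poisson(lam, size=n_cells)
    sample = DoseSample(sample_id or f"D{dose_gy:g}Gy", dose_gy, counts)
    if render:
        base = cell_spec or CellSpec()
        mix = dict(quality_mix or {})
        p_poor = mix.pop("p_poor", 0.0)
        images, truths = [], []
        for k in range(n_cells):
            kw = {"n_dc": int(counts[k])}
            if rng.random() < p_poor:
                kw.update(mix)
            cs = CellSpec(**{**base.__dict__, **kw})
            img, tr = generate_metaphase(cs, seed=rng)
            images.append(img)
            truths.append(tr)
        sample.images, sample.truths = images, truths
    return sample


# ---------------------------------------------------------------------------
# candidate pools for FP-filter studies


def generate_candidate_pool(seed, n_images: int = 10, n_mc: int = 36,
                            n_dc: int = 5, n_fp: int = 10,
                            sex: str = "female",
                            analyze: bool = True):
    """Pseudo-images of individually rendered, analyzed objects for
    false-positive filter studies.

    Each pseudo-image holds ``n_mc`` normal monocentrics (a random subset
    of the complement), ``n_dc`` true dicentrics (the TP candidates) and
    ``n_fp`` false-positive objects drawn evenly from SCS chromatids,
    fragments and debris.  Returns a list of dicts with keys ``objects``
    (ChromosomeObject list), ``candidate_idx`` (indices of scored
    candidates) and ``is_fp`` (parallel truth flags).
    """
    from .morphology import ChromosomeObject, analyze_object, _trace_contour

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fracs = karyotype.relative_lengths(sex)
    lengths = fracs * LENGTH_SCALE
    images = []
    for _ in range(n_images):
        masks: list[tuple[np.ndarray, str, bool]] = []  # (mask, class, is_candidate)
        avail = list(range(46))

        def take_weighted():
            w = np.array([lengths[i] for i in avail])
            j = int(rng.choice(len(avail), p=w / w.sum()))
            return avail.pop(j)

        area_scale = LENGTH_SCALE * BASE_WIDTH
        for _ in range(n_dc):
            i, j = take_weighted(), take_weighted()
            m, _t = generate_chromosome(
                _dicentric_spec(lengths[i], lengths[j], BASE_WIDTH, rng,
                                target_area=(fracs[i] + fracs[j]) * area_scale),
                rng)
            masks.append((m, "DC", True))
        picks = rng.choice(avail, size=min(n_mc, len(avail)), replace=False)
        for i in picks:
            pos, depth = _centromere_layout(rng)
            cons = ((pos, depth),)
            m, _t = generate_chromosome(
                ChromosomeSpec(_length_for_area(fracs[i] * area_scale,
                                                BASE_WIDTH, cons),
                               BASE_WIDTH, rng.uniform(0.05, 0.2), cons), rng)
            masks.append((m, "MC", False))
        fp_kinds = ["SCS", "fragment", "debris"]
        for k in range(n_fp):
            kind = fp_kinds[k % 3]
            i = int(rng.integers(46))
            if kind == "SCS":
                m, _t = generate_scs_chromatid(max(lengths[i], 4 * BASE_WIDTH),
                                               BASE_WIDTH, rng)
            elif kind == "fragment":
                m, _t = generate_fragment(max(lengths[i], 6 * BASE_WIDTH),
                                          BASE_WIDTH, rng)
            else:
                m, _t = generate_debris(rng)
            masks.append((m, kind, True))

        objects, cand_idx, is_fp = [], [], []
        for oid, (m, cls, cand) in enumerate(masks):
            obj = ChromosomeObject(id=oid, mask=m, origin=(0, 0),
                                   contour=_trace_contour(m, (0, 0)),
                                   area=int(m.sum()))
            if analyze:
                analyze_object(obj)
            objects.append(obj)
            if cand:
                cand_idx.append(oid)
                is_fp.append(cls != "DC")
        images.append({"objects": objects, "candidate_idx": cand_idx,
                       "is_fp": is_fp,
                       "classes": [c for _, c, _ in masks]})
    return images
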