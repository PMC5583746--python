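"""Per-object chromosome morphometry from binary masks.

Each segmented object is reduced to the geometric quantities the downstream
false-positive filters and image-quality scores consume: a closed contour,
a long-axis centerline, a width profile sampled orthogonally along that
centerline ("tracelines"), centromere candidates at width constrictions,
the minimum-area bounding rectangle, and contour arc-length partitions.

Coordinates are 0-based (row, col).  Connected components use
8-connectivity; contours are traced with the pixel-corner convention of
``skimage.measure.find_contours``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "WidthProfile",
    "CentromereCandidate",
    "ChromosomeObject",
    "MorphologyParams",
    "extract_objects",
    "compute_centerline",
    "compute_width_profile",
    "detect_centromere_candidates",
    "geometry_features",
    "classify_dc_heuristic",
    "analyze_object",
    "analyze_image",
]

LABELS = ("MC", "DC", "unprocessable", "non-chromosome")


@dataclass
class WidthProfile:
    """Chromosome widths sampled at arc-length positions along the centerline."""

    positions: np.ndarray  # arc-length fractions in [0, 1], strictly increasing
    widths: np.ndarray     # pixels, one per position
    endpoints: np.ndarray | None = None  # (n, 2, 2) traceline exits, (row, col)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def normalized_widths(self) -> np.ndarray:
        """Widths rescaled to [0, 1]; an exactly constant profile maps to all
        zeros (zero-range convention)."""
        w = self.widths
        rng = w.max() - w.min()
        if rng <= 0:
            return np.zeros_like(w)
        return (w - w.min()) / rng


@dataclass
class CentromereCandidate:
    position: float            # arc-length fraction along centerline
    width_at: float            # pixels
    depth: float               # 1 - width / local shoulder width
    rank: int                  # 1-based, rank 1 = deepest constriction
    traceline_endpoints: np.ndarray | None = None  # (2, 2) contour exits


@dataclass
class ChromosomeObject:
    """One segmented object plus its derived morphometric features."""

    id: int
    mask: np.ndarray                 # local boolean raster
    origin: tuple[int, int]          # (row, col) of mask[0, 0] in the image
    contour: np.ndarray              # closed polygon, image coordinates
    area: int
    centerline: np.ndarray | None = None     # open polyline, image coordinates
    centerline_length: float = 0.0
    width_profile: WidthProfile | None = None
    w_mean: float = float("nan")
    w_med: float = float("nan")
    w_max: float = float("nan")
    candidates: list[CentromereCandidate] = field(default_factory=list)
    w_cent: float = float("nan")
    rect_sides: tuple[float, float] | None = None
    contour_halves: tuple[float, float] | None = None
    intercandidate_arcs: tuple[float, float] | None = None
    label: str | None = None
    label_source: str = "heuristic"  # "heuristic" or "external"

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def solidity(self) -> float:
        if len(self.contour) < 3:
            return 1.0
        poly = Polygon(self.contour)
        if not poly.is_valid:
            poly = poly.buffer(0)
        hull = poly.convex_hull
        return poly.area / hull.area if hull.area > 0 else 1.0


@dataclass
class MorphologyParams:
    """Tunables for the feature-extraction pipeline."""

    min_area: int = 50
    n_width_samples: int = 41
    smooth_window: int = 5        # moving-average window for minima detection
    min_depth: float = 0.2        # minimum constriction depth for a candidate
    min_separation: float = 0.15  # minimum arc-fraction spacing of candidates
    solidity_threshold: float = 0.95
    width_flatness: float = 1.1   # w_max/w_mean bound for smooth blobs
    profile_trim: float = 0.15    # fraction trimmed per end for the flatness test


# ---------------------------------------------------------------------------
# object extraction


def _trace_contour(mask: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2))
    contour = max(contours, key=len)
    return contour - 1.0 + np.asarray(origin, float)


def extract_objects(image: np.ndarray, min_area: int = 50) -> list[ChromosomeObject]:
    """Label connected components of a binary/grayscale raster.

    Grayscale input is thresholded with Otsu's method, taking the minority
    side as foreground (chromosomes are sparse on the background).  Returns
    one object per 8-connected component with ``area >= min_area``; objects
    carry mask, contour and area only — the remaining features are filled in
    by :func:`analyze_object`.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    image = np.asarray(image)
    if image.size == 0:
        return []
    if image.dtype == bool:
        fg = image
    else:
        vals = np.unique(image)
        if len(vals) == 1:
            fg = image > 0
        else:
            if len(vals) == 2:
                high = image == vals.max()
            else:
                high = image > threshold_otsu(image)
            # chromosomes are sparse: foreground is the minority side
            fg = high if high.sum() <= high.size / 2 else ~high
    if not fg.any():
        return []
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    objects: list[ChromosomeObject] = []
    whole_frame = fg.all()
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        mask = labels[sl] == i
        area = int(mask.sum())
        if area < min_area:
            continue
        origin = (sl[0].start, sl[1].start)
        obj = ChromosomeObject(
            id=len(objects),
            mask=mask,
            origin=origin,
            contour=_trace_contour(mask, origin),
            area=area,
        )
        if whole_frame:
            obj.label = "non-chromosome"
            obj.label_source = "heuristic"
        objects.append(obj)
    return objects


# ---------------------------------------------------------------------------
# centerline


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pix:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in pix:
                    g.add_edge((r, c), q, weight=math.hypot(dr, dc))
    if not g and pix:
        g.add_nodes_from(pix)
    return g


def _farthest(g: nx.Graph, source) -> tuple:
    dist = nx.single_source_dijkstra_path_length(g, source)
    return max(dist, key=dist.get)


def _smooth_polyline(path: np.ndarray, window: int = 5) -> np.ndarray:
    if len(path) < window:
        return path
    kernel = np.ones(window) / window
    out = path.astype(float).copy()
    for j in range(2):
        out[:, j] = np.convolve(np.pad(path[:, j], window // 2, mode="edge"),
                                kernel, mode="valid")
    return out


def _inside(mask: np.ndarray, p: np.ndarray) -> bool:
    r, c = int(round(p[0])), int(round(p[1]))
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])


def _extend_to_boundary(mask: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Prolong both endpoints along the local direction until leaving the mask."""
    out = [path]
    for end in (0, -1):
        k = min(5, len(path) - 1)
        d = path[end] - (path[k] if end == 0 else path[-1 - k])
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        d = d / norm
        p = path[end].astype(float)
        ext = []
        for _ in range(200):
            p = p + 0.5 * d
            if not _inside(mask, p):
                break
            ext.append(p.copy())
        if ext:
            if end == 0:
                out.insert(0, np.array(ext[::-1]))
            else:
                out.append(np.array(ext))
    return np.vstack(out)


def polyline_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path, axis=0), axis=1).sum())


def compute_centerline(obj: ChromosomeObject) -> np.ndarray:
    """Longest geodesic path through the morphological skeleton of the mask,
    side branches pruned implicitly, extended to the mask boundary at both
    ends.  Returns the polyline in image coordinates and stores its arc
    length on the object.  A degenerate (point-like) skeleton yields a
    zero-length centerline and the object is flagged unprocessable.
    """
    skel = skeletonize(obj.mask)
    if skel.sum() <= 2:
        obj.centerline = np.zeros((0, 2))
        obj.centerline_length = 0.0
        obj.label = "unprocessable"
        return obj.centerline
    g = _skeleton_graph(skel)
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    start = next(iter(comp))
    u = _farthest(sub, start)
    v = _farthest(sub, u)
    path = nx.dijkstra_path(sub, u, v)
    path = np.array(path, float)
    if len(path) < 3:
        obj.centerline = np.zeros((0, 2))
        obj.centerline_length = 0.0
        obj.label = "unprocessable"
        return obj.centerline
    path = _smooth_polyline(path)
    path = _extend_to_boundary(obj.mask, path)
    path = path + np.asarray(obj.origin, float)
    obj.centerline = path
    obj.centerline_length = polyline_length(path)
    return path


# ---------------------------------------------------------------------------
# width profile


def _resample_polyline(path: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0, total, n)
    out = np.empty((n, 2))
    for j in range(2):
        out[:, j] = np.interp(targets, s, path[:, j])
    return out


def _ray_exit(maskf: np.ndarray, p: np.ndarray, d: np.ndarray,
              step: float = 0.25, max_dist: float = 200.0) -> tuple[float, np.ndarray] | None:
    """March from p along d until leaving the mask (bilinear subpixel
    boundary); return (distance, exit point).

    ``maskf`` is the float mask zero-padded by one pixel (so the 1 -> 0
    edge transition is interpolable) and ``p`` is given in the padded
    frame.
    """
    ts = np.arange(step, max_dist, step)
    pts = p[None, :] + ts[:, None] * d[None, :]
    vals = ndimage.map_coordinates(maskf, pts.T, order=1,
                                   mode="constant", cval=0.0)
    out = np.nonzero(vals < 0.5)[0]
    if len(out) == 0:
        return None
    k = out[0]
    # linear interpolation of the 0.5 crossing between samples k-1 and k
    v1 = vals[k]
    v0 = vals[k - 1] if k > 0 else 1.0
    frac = (v0 - 0.5) / (v0 - v1) if v0 != v1 else 0.5
    t_exit = (ts[k - 1] if k > 0 else 0.0) + frac * step
    return float(t_exit), p + t_exit * d


def compute_width_profile(obj: ChromosomeObject, n_samples: int = 41) -> WidthProfile:
    """Sample chromosome width at evenly spaced centerline points.

    Width at a point is the chord length of the local normal line's
    intersection with the mask (the traceline).  Samples whose center falls
    outside the mask or whose traceline fails to close are dropped; if more
    than half are dropped the object is flagged unprocessable.  Summary
    statistics W_mean / W_med / W_max are stored on the object.
    """
    if n_samples < 5:
        raise ValueError("n_samples must be >= 5")
    if obj.centerline is None or obj.centerline_length <= 0:
        raise ValueError("centerline must be computed and non-degenerate")
    local = obj.centerline - np.asarray(obj.origin, float)
    pts = _resample_polyline(local, n_samples)
    # tangents from central differences on the resampled polyline
    tang = np.gradient(pts, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang = tang / norms[:, None]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)

    maskf = np.pad(obj.mask.astype(np.float32), 1)
    max_dist = float(np.hypot(*obj.mask.shape))
    positions, widths, endpoints = [], [], []
    for i in range(n_samples):
        p = pts[i]
        if not _inside(obj.mask, p):
            continue
        pp = p + 1.0  # padded frame
        a = _ray_exit(maskf, pp, normal[i], max_dist=max_dist)
        b = _ray_exit(maskf, pp, -normal[i], max_dist=max_dist)
        if a is None or b is None:
            continue
        positions.append(i / (n_samples - 1))
        widths.append(a[0] + b[0])
        ep = np.stack([a[1], b[1]]) - 1.0 + np.asarray(obj.origin, float)
        endpoints.append(ep)

    if len(positions) < n_samples / 2 or len(positions) < 5:
        obj.label = "unprocessable"
        profile = WidthProfile(np.array(positions), np.array(widths),
                               np.array(endpoints) if endpoints else None)
        obj.width_profile = profile
        return profile

    profile = WidthProfile(np.array(positions), np.array(widths), np.array(endpoints))
    obj.width_profile = profile
    obj.w_mean = float(np.mean(profile.widths))
    obj.w_med = float(np.median(profile.widths))
    obj.w_max = float(np.max(profile.widths))
    return profile


# ---------------------------------------------------------------------------
# centromere candidates


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(x) < window:
        return x.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(np.pad(x, window // 2, mode="edge"), kernel, mode="valid")


def detect_centromere_candidates(
    profile: WidthProfile,
    min_depth: float = 0.2,
    min_separation: float = 0.15,
    smooth_window: int = 5,
) -> list[CentromereCandidate]:
    """Find width-profile constrictions that may be centromeres.

    Local minima of the moving-average smoothed profile qualify when their
    constriction depth (1 - width / shoulder, shoulder = the lower of the
    maximum smoothed widths on either side) reaches ``min_depth``;
    candidates closer than ``min_separation`` (arc fraction) to a deeper
    one are suppressed.  Candidates are ranked by descending depth and the
    traceline endpoints of the top two are recorded.
    """
    if not 0 < min_depth < 1:
        raise ValueError("min_depth must be in (0, 1)")
    if len(profile) == 0:
        return []
    w = _moving_average(profile.widths, smooth_window)
    n = len(w)
    minima = [i for i in range(1, n - 1)
              if w[i] <= w[i - 1] and w[i] <= w[i + 1]
              and (w[i] < w[i - 1] or w[i] < w[i + 1])]
    scored = []
    half = smooth_window // 2
    for i in minima:
        left = w[: i + 1].max()
        right = w[i:].max()
        shoulder = min(left, right)
        if shoulder <= 0:
            continue
        # smoothing locates the constriction; its depth is taken from the
        # raw profile at the local argmin, which short chromosomes need
        lo, hi = max(0, i - half), min(n, i + half + 1)
        j = lo + int(np.argmin(profile.widths[lo:hi]))
        depth = float(np.clip(1.0 - profile.widths[j] / shoulder, 0.0, 1.0))
        if depth >= min_depth:
            scored.append((depth, j))
    best: dict[int, float] = {}
    for depth, j in scored:
        best[j] = max(best.get(j, 0.0), depth)
    scored = [(d, j) for j, d in best.items()]
    scored.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[tuple[float, int]] = []
    for depth, i in scored:
        pos = profile.positions[i]
        if all(abs(pos - profile.positions[j]) >= min_separation for _, j in chosen):
            chosen.append((depth, i))
    out = []
    for rank, (depth, i) in enumerate(chosen, start=1):
        ep = None
        if rank <= 2 and profile.endpoints is not None:
            ep = profile.endpoints[i]
        # the constriction width is a 3-sample local mean: the argmin alone
        # carries the downward bias of a minimum statistic over pixel jitter
        lo, hi = max(0, i - 1), min(n, i + 2)
        out.append(CentromereCandidate(
            position=float(profile.positions[i]),
            width_at=float(np.mean(profile.widths[lo:hi])),
            depth=depth,
            rank=rank,
            traceline_endpoints=ep,
        ))
    return out


# ---------------------------------------------------------------------------
# contour geometry


def _contour_cumlen(contour: np.ndarray) -> np.ndarray:
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])  # length n+1, last = perimeter


def _nearest_vertex(contour: np.ndarray, point: np.ndarray) -> int:
    return int(np.argmin(np.linalg.norm(contour - point, axis=1)))


def _arc_between(cum: np.ndarray, i: int, j: int) -> float:
    """Arc length walking forward from vertex i to vertex j."""
    total = cum[-1]
    d = cum[j] - cum[i]
    return d if d >= 0 else d + total


def geometry_features(obj: ChromosomeObject) -> ChromosomeObject:
    """Fill rect_sides, contour_halves and (given >= 2 candidates)
    intercandidate_arcs.

    ``rect_sides`` comes from the minimum-area (rotated) bounding rectangle
    of the contour.  ``contour_halves`` splits the closed contour at the two
    vertices nearest the centerline endpoints.  ``intercandidate_arcs`` are
    the two lateral contour arcs lying between the traceline endpoint pairs
    of the top two candidates (the two inter-endpoint "caps" belonging to a
    single candidate are excluded).
    """
    contour = obj.contour
    if len(contour) >= 3:
        rect = MultiPoint(contour).minimum_rotated_rectangle
        coords = np.asarray(rect.exterior.coords) if rect.geom_type == "Polygon" else None
        if coords is not None and len(coords) >= 4:
            s1 = float(np.linalg.norm(coords[1] - coords[0]))
            s2 = float(np.linalg.norm(coords[2] - coords[1]))
            lo, hi = sorted((s1, s2))
            obj.rect_sides = (lo, hi) if lo > 0 else (max(lo, 1e-9), max(hi, 1e-9))
    if obj.centerline is not None and len(obj.centerline) >= 2 and len(contour) >= 3:
        cum = _contour_cumlen(contour)
        i = _nearest_vertex(contour, obj.centerline[0])
        j = _nearest_vertex(contour, obj.centerline[-1])
        if i != j:
            a = _arc_between(cum, i, j)
            b = _arc_between(cum, j, i)
            obj.contour_halves = tuple(sorted((a, b)))
    if obj.n_candidates >= 2 and len(contour) >= 3:
        c1, c2 = obj.candidates[0], obj.candidates[1]
        if c1.traceline_endpoints is not None and c2.traceline_endpoints is not None:
            cum = _contour_cumlen(contour)
            verts = []
            for cand_idx, cand in enumerate((c1, c2)):
                for ep in cand.traceline_endpoints:
                    verts.append((_nearest_vertex(contour, ep), cand_idx))
            verts.sort()
            arcs = []
            for k in range(4):
                i1, owner1 = verts[k]
                i2, owner2 = verts[(k + 1) % 4]
                if owner1 != owner2:  # lateral arc joins the two candidates
                    arcs.append(_arc_between(cum, i1, i2))
            if len(arcs) == 2 and min(arcs) > 0:
                obj.intercandidate_arcs = tuple(sorted(arcs))
    return obj


# ---------------------------------------------------------------------------
# classification


def classify_dc_heuristic(
    obj: ChromosomeObject,
    depth_threshold: float = 0.2,
    separation_threshold: float = 0.15,
    solidity_threshold: float = 0.95,
    width_flatness: float = 1.1,
    profile_trim: float = 0.15,
) -> str:
    """Rule-based monocentric/dicentric call.

    DC when at least two candidates reach ``depth_threshold`` (candidate
    spacing is already enforced at detection); MC when exactly one does;
    non-chromosome for smooth high-solidity blobs (nuclei, debris), judged
    on the central portion of the width profile so that natural end
    tapering does not mask true flatness; otherwise unprocessable.

    Externally supplied labels (``label_source == "external"``) are never
    overwritten.
    """
    if obj.label_source == "external" and obj.label is not None:
        return obj.label
    if obj.label in ("unprocessable", "non-chromosome"):
        return obj.label
    strong = [c for c in obj.candidates if c.depth >= depth_threshold]
    if len(strong) >= 2:
        obj.label = "DC"
        return obj.label
    if len(strong) == 1:
        obj.label = "MC"
        return obj.label
    solidity = obj.solidity
    if solidity > solidity_threshold:
        flat = not obj.candidates
        wp = obj.width_profile
        if wp is not None and len(wp) >= 5:
            k = max(1, int(len(wp) * profile_trim))
            central = wp.widths[k:-k] if len(wp) > 2 * k else wp.widths
            if central.mean() > 0 and central.max() / central.mean() < width_flatness:
                flat = True
        if flat:
            obj.label = "non-chromosome"
            return obj.label
    obj.label = "unprocessable"
    return obj.label


# ---------------------------------------------------------------------------
# orchestration


def analyze_object(obj: ChromosomeObject, params: MorphologyParams | None = None) -> ChromosomeObject:
    """Run the full feature pipeline on one extracted object."""
    params = params or MorphologyParams()
    compute_centerline(obj)
    if obj.centerline_length > 0:
        compute_width_profile(obj, params.n_width_samples)
    if obj.width_profile is not None and obj.label != "unprocessable":
        obj.candidates = detect_centromere_candidates(
            obj.width_profile, params.min_depth, params.min_separation,
            params.smooth_window)
        if obj.candidates:
            obj.w_cent = obj.candidates[0].width_at
    geometry_features(obj)
    classify_dc_heuristic(
        obj, params.min_depth, params.min_separation,
        params.solidity_threshold, params.width_flatness, params.profile_trim)
    return obj


def analyze_image(image: np.ndarray, params: MorphologyParams | None = None) -> list[ChromosomeObject]:
    """Extract and fully analyze every object of a metaphase image."""
    params = params or MorphologyParams()
    objects = extract_objects(image, params.min_area)
    for obj in objects:
        analyze_object(obj, params)
    return objects
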