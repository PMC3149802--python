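"""Semiautomatic initialization: locate the 2N anterior vertebra corners.

Given only two user clicks — the upper anterior corner of the first
vertebra (l_1) and the lower anterior corner of the last (l_2N) — the
initializer:

1. crops the search window around the clicks;
2. detects Canny edges and Harris interest points in the window;
3. discards Harris points that are isolated from any sufficiently long
   edge (an isolated point, or one on a too-short fragment, cannot be a
   vertebra corner);
4. discards points whose contour angle falls outside [10°, 160°]
   (nearly straight contours and needle-like artefacts);
5. searches for the shortest alternating path l_1, lower, upper, ...,
   l_2N of 2N points whose step lengths match the spine geometry prior:
   an upper→lower step must be close to the vertebra height alpha, a
   lower→upper step close to the intervertebral gap beta.

The geometry prior comes from the anchor distance d: with N vertebrae,
d ≈ N*alpha + (N-1)*beta and, empirically, alpha = 4*beta, giving
alpha = 4d/(5N-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import canny, corner_harris, corner_peaks

__all__ = [
    "SpineGeometry",
    "CornerSequence",
    "estimate_geometry",
    "reduce_window",
    "detect_candidates",
    "filter_isolated",
    "filter_angle",
    "find_corner_sequence",
    "detect_corners",
    "InitializationError",
]


class InitializationError(RuntimeError):
    """No admissible corner sequence could be constructed."""


@dataclass
class SpineGeometry:
    """Spine geometry prior derived from the two anchor clicks.

    alpha is the vertebra height, beta the intervertebral gap (alpha =
    4*beta), d the anchor distance, and delta_alpha / delta_beta the
    half-widths of the acceptance windows on upper→lower and
    lower→upper steps.
    """

    n_vertebrae: int
    d: float
    alpha: float
    beta: float
    delta_alpha: float
    delta_beta: float


@dataclass
class CornerSequence:
    """Alternating sequence of 2N anterior corners, l_1 ... l_2N."""

    points: np.ndarray  # (2N, 2)
    path_length: float
    types: list[str] = field(default_factory=list)
    candidate_indices: tuple = ()

    def __post_init__(self) -> None:
        if not self.types:
            self.types = ["upper" if i % 2 == 0 else "lower"
                          for i in range(len(self.points))]

    def corner_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-vertebra (upper, lower) anterior corner pairs."""
        return [(self.points[2 * v], self.points[2 * v + 1])
                for v in range(len(self.points) // 2)]


def estimate_geometry(
    l1: np.ndarray,
    l2n: np.ndarray,
    n_vertebrae: int,
    delta_alpha_frac: float = 0.4,
    delta_beta_frac: float = 0.75,
) -> SpineGeometry:
    """Derive alpha, beta and the step windows from the anchors.

    alpha = 4d/(5N-1) and beta = alpha/4, which satisfy
    N*alpha + (N-1)*beta = d exactly.  The window half-widths are
    fractions of alpha and beta (they must be fixed empirically; 0.4 and
    0.75 are the defaults here).
    """
    if n_vertebrae < 1:
        raise ValueError("need at least one vertebra")
    d = float(np.linalg.norm(np.asarray(l2n, float) - np.asarray(l1, float)))
    if d <= 0:
        raise ValueError("anchor points must be distinct")
    alpha = 4.0 * d / (5.0 * n_vertebrae - 1.0)
    beta = alpha / 4.0
    return SpineGeometry(
        n_vertebrae=n_vertebrae,
        d=d,
        alpha=alpha,
        beta=beta,
        delta_alpha=delta_alpha_frac * alpha,
        delta_beta=delta_beta_frac * beta,
    )


def reduce_window(
    image: np.ndarray,
    click_top: np.ndarray,
    click_bottom: np.ndarray,
    margin_px: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the image to the anchor bounding box expanded by a margin.

    Returns (window, offset) where offset maps window (0,0) back to the
    full-image frame: full = window_coord + offset.
    """
    top = np.asarray(click_top, float)
    bot = np.asarray(click_bottom, float)
    if np.allclose(top, bot):
        raise ValueError("anchor clicks coincide")
    if top[1] > bot[1]:
        warnings.warn("anchor clicks given bottom-first; swapping", RuntimeWarning)
        top, bot = bot, top
    h, w = image.shape
    x0 = int(max(0, np.floor(min(top[0], bot[0]) - margin_px)))
    x1 = int(min(w, np.ceil(max(top[0], bot[0]) + margin_px) + 1))
    y0 = int(max(0, np.floor(top[1] - margin_px)))
    y1 = int(min(h, np.ceil(bot[1] + margin_px) + 1))
    return image[y0:y1, x0:x1], np.array([x0, y0], float)


def detect_candidates(
    window: np.ndarray,
    canny_sigma: float = 1.5,
    canny_low_quantile: float = 0.70,
    canny_high_quantile: float = 0.90,
    harris_k: float = 0.04,
    harris_sigma: float = 2.0,
    nms_radius: int = 3,
    response_rel: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canny edge map + Harris corner candidates in a grey window.

    Returns (edge_map bool (h,w), candidates (m,2) as (x,y),
    responses (m,)).  Harris runs on the grey window directly; the
    association with edges happens in the downstream filters.
    """
    window = np.asarray(window, float)
    if window.size == 0 or np.ptp(window) == 0:
        return (
            np.zeros(window.shape, bool),
            np.empty((0, 2)),
            np.empty(0),
        )
    edges = canny(
        window,
        sigma=canny_sigma,
        low_threshold=canny_low_quantile,
        high_threshold=canny_high_quantile,
        use_quantiles=True,
    )
    response = corner_harris(window, method="k", k=harris_k, sigma=harris_sigma)
    peaks = corner_peaks(
        response, min_distance=nms_radius, threshold_rel=response_rel
    )
    cands = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    return edges, cands, response[peaks[:, 0], peaks[:, 1]]


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _snap_to_edge(
    edge_map: np.ndarray, pt: np.ndarray, snap_radius: float
) -> tuple[int, int] | None:
    """Nearest edge pixel (row, col) within snap_radius of pt=(x,y)."""
    h, w = edge_map.shape
    r = int(np.ceil(snap_radius))
    cx, cy = pt
    r0, r1 = max(0, int(cy) - r), min(h, int(cy) + r + 2)
    c0, c1 = max(0, int(cx) - r), min(w, int(cx) + r + 2)
    rows, cols = np.nonzero(edge_map[r0:r1, c0:c1])
    if rows.size == 0:
        return None
    rows, cols = rows + r0, cols + c0
    d2 = (cols - cx) ** 2 + (rows - cy) ** 2
    k = int(np.argmin(d2))
    if d2[k] > snap_radius**2:
        return None
    return int(rows[k]), int(cols[k])


def _trace_distances(
    edge_map: np.ndarray, start: tuple[int, int], max_dist: float
) -> dict[tuple[int, int], float]:
    """Geodesic distance along the 8-connected edge, Dijkstra-style,
    out to max_dist (axis steps cost 1, diagonal sqrt(2))."""
    import heapq

    h, w = edge_map.shape
    dist: dict[tuple[int, int], float] = {start: 0.0}
    heap = [(0.0, start)]
    while heap:
        d, (r, c) = heapq.heappop(heap)
        if d > dist.get((r, c), np.inf):
            continue
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and edge_map[rr, cc]:
                nd = d + (1.4142135623730951 if dr and dc else 1.0)
                if nd <= max_dist and nd < dist.get((rr, cc), np.inf):
                    dist[(rr, cc)] = nd
                    heapq.heappush(heap, (nd, (rr, cc)))
    return dist


def filter_isolated(
    candidates: np.ndarray,
    edge_map: np.ndarray,
    reach_px: float,
    snap_radius: float = 3.0,
    coverage_frac: float = 0.9,
) -> np.ndarray:
    """Keep candidates whose edge extends at least ~reach_px away.

    A candidate survives iff it lies within ``snap_radius`` of an edge
    pixel and, tracing that edge, some pixel sits at geodesic distance
    >= coverage_frac * reach_px (default reach: the estimated vertebra
    height; the fraction absorbs the pixel or two that hysteresis
    thresholding shaves off edge ends).  Points off any contour or on
    short fragments are eliminated.
    """
    if reach_px <= 0:
        raise ValueError("reach must be positive")
    keep = []
    for i, pt in enumerate(np.atleast_2d(candidates)):
        start = _snap_to_edge(edge_map, pt, snap_radius)
        if start is None:
            continue
        dist = _trace_distances(edge_map, start, reach_px + 2.0)
        if max(dist.values()) >= coverage_frac * reach_px:
            keep.append(i)
    return np.atleast_2d(candidates)[keep] if keep else np.empty((0, 2))


def filter_angle(
    candidates: np.ndarray,
    edge_map: np.ndarray,
    neighbor_dist_px: float,
    angle_min_deg: float = 10.0,
    angle_max_deg: float = 160.0,
    snap_radius: float = 3.0,
    band_px: float = 1.5,
) -> np.ndarray:
    """Keep candidates whose contour angle lies in [angle_min, angle_max].

    For each candidate the two contour neighbours are the edge pixels at
    geodesic distance ~= neighbor_dist_px on either side of the (snapped)
    candidate; the angle between the segments joining them to the
    candidate is measured.  Straight runs (~180°) and needle artefacts
    (<10°) are rejected; candidates with fewer than two traceable
    neighbours are treated as isolated and removed.
    """
    lo, hi = np.deg2rad(angle_min_deg), np.deg2rad(angle_max_deg)
    keep = []
    for i, pt in enumerate(np.atleast_2d(candidates)):
        start = _snap_to_edge(edge_map, pt, snap_radius)
        if start is None:
            continue
        dist = _trace_distances(edge_map, start, neighbor_dist_px + band_px)
        band = [
            p for p, d in dist.items()
            if abs(d - neighbor_dist_px) <= band_px
        ]
        if len(band) < 2:
            continue
        pts = np.array([(c, r) for r, c in band], float)
        # the two neighbours on opposite arcs are the most separated pair
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        a_idx, b_idx = np.unravel_index(np.argmax(d2), d2.shape)
        c = np.array([start[1], start[0]], float)
        va, vb = pts[a_idx] - c, pts[b_idx] - c
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na < 1e-9 or nb < 1e-9:
            continue
        ang = np.arccos(np.clip(va @ vb / (na * nb), -1.0, 1.0))
        if lo <= ang <= hi:
            keep.append(i)
    return np.atleast_2d(candidates)[keep] if keep else np.empty((0, 2))


def find_corner_sequence(
    candidates: np.ndarray,
    l1: np.ndarray,
    l2n: np.ndarray,
    geometry: SpineGeometry,
    max_branch: int = 8,
    max_sequences: int = 10_000,
    literal_y: bool = False,
) -> CornerSequence:
    """Shortest alternating 2N-corner path from l_1 to l_2N.

    Depth-first recursion: starting from l_1 (an upper corner), extend
    an upper point with candidates at distance in
    (alpha - delta_alpha, alpha + delta_alpha) — these become lower
    corners — and a lower point with candidates at distance in
    (beta - delta_beta, beta + delta_beta) — these become upper corners.
    Each extension must progress monotonically from l_1 toward l_2N
    (strictly increasing projection on the l_1→l_2N axis; with
    ``literal_y`` the rule is instead strictly increasing image y, i.e.
    moving down the image).  When 2N-1 points are placed, l_2N is
    appended and the completed sequence stored; the sequence of minimal
    total path length wins, ties broken by lexicographic candidate
    index.  Branching is capped at the ``max_branch`` nearest feasible
    candidates per extension and at ``max_sequences`` stored sequences.
    """
    l1 = np.asarray(l1, float)
    l2n = np.asarray(l2n, float)
    cands = np.atleast_2d(np.asarray(candidates, float)) if len(candidates) else np.empty((0, 2))
    two_n = 2 * geometry.n_vertebrae
    axis = l2n - l1
    axis = axis / np.linalg.norm(axis)

    def progress(pt: np.ndarray) -> float:
        return float(pt[1]) if literal_y else float((pt - l1) @ axis)

    proj = np.array([progress(p) for p in cands]) if len(cands) else np.empty(0)
    dists_cache: dict[int, np.ndarray] = {}

    best: list = [np.inf, None]  # [path length, (indices, points)]
    complete: list[int] = [0]

    def extend(seq_idx: tuple, seq_pts: list, length: float, last_type: str):
        if complete[0] >= max_sequences:
            return
        i = len(seq_pts)
        if i == two_n - 1:
            total = length + float(np.linalg.norm(l2n - seq_pts[-1]))
            complete[0] += 1
            if total < best[0] - 1e-12 or (
                abs(total - best[0]) <= 1e-12
                and best[1] is not None
                and seq_idx < best[1][0]
            ):
                best[0] = total
                best[1] = (seq_idx, list(seq_pts))
            return
        last = seq_pts[-1]
        if last_type == "upper":
            lo, hi = geometry.alpha - geometry.delta_alpha, geometry.alpha + geometry.delta_alpha
            new_type = "lower"
        else:
            lo, hi = geometry.beta - geometry.delta_beta, geometry.beta + geometry.delta_beta
            new_type = "upper"
        if len(cands) == 0:
            return
        d = np.linalg.norm(cands - last, axis=1)
        p_last = progress(last)
        feas = np.nonzero((d > lo) & (d < hi) & (proj > p_last + 1e-12))[0]
        if feas.size == 0:
            return
        order = feas[np.argsort(d[feas], kind="stable")][:max_branch]
        for j in order:
            extend(
                seq_idx + (int(j),),
                seq_pts + [cands[j]],
                length + float(d[j]),
                new_type,
            )

    extend((), [l1], 0.0, "upper")
    if best[1] is None:
        raise InitializationError(
            f"no admissible {two_n}-corner sequence: {len(cands)} candidates, "
            f"alpha={geometry.alpha:.1f}±{geometry.delta_alpha:.1f}, "
            f"beta={geometry.beta:.1f}±{geometry.delta_beta:.1f}"
        )
    idx, pts = best[1]
    points = np.vstack([pts, l2n])
    return CornerSequence(
        points=points,
        path_length=float(best[0]),
        candidate_indices=idx,
    )


def detect_corners(
    image: np.ndarray,
    anchor_top: np.ndarray,
    anchor_bottom: np.ndarray,
    n_vertebrae: int,
    margin_px: int = 20,
    delta_alpha_frac: float = 0.4,
    delta_beta_frac: float = 0.75,
    angle_neighbor_frac: float = 0.25,
    literal_y: bool = False,
    **detector_kwargs,
) -> tuple[CornerSequence, dict]:
    """Full semiautomatic pipeline from two clicks to 2N corners.

    Returns the corner sequence in full-image coordinates plus a
    diagnostics dict with candidate counts after each stage.
    """
    geometry = estimate_geometry(
        anchor_top, anchor_bottom, n_vertebrae, delta_alpha_frac, delta_beta_frac
    )
    window, offset = reduce_window(image, anchor_top, anchor_bottom, margin_px)
    edges, cands, responses = detect_candidates(window, **detector_kwargs)
    n_raw = len(cands)
    cands = filter_isolated(cands, edges, reach_px=geometry.alpha)
    n_isolated = len(cands)
    cands = filter_angle(
        cands, edges, neighbor_dist_px=angle_neighbor_frac * geometry.alpha
    )
    n_angle = len(cands)
    seq = find_corner_sequence(
        cands + offset if len(cands) else cands,
        np.asarray(anchor_top, float),
        np.asarray(anchor_bottom, float),
        geometry,
        literal_y=literal_y,
    )
    diagnostics = {
        "n_harris": n_raw,
        "n_after_isolated_filter": n_isolated,
        "n_after_angle_filter": n_angle,
        "geometry": geometry,
    }
    return seq, diagnostics
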