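"""Iterative Active Shape Model search.

The mean shape is placed on the image from the per-vertebra anterior
corner pairs (detected or clicked), then refined iteratively: every
landmark moves along its contour normal to the candidate position whose
grey-level profile is closest to the trained profile (minimal
Mahalanobis distance), and the moved point cloud is regularised by
fitting the point-distribution model — pose plus clamped mode weights —
so the shape can never leave the space of plausible vertebrae.

Convergence uses the 10% rule: writing c_i for the number of landmarks
that changed position (by more than a jitter threshold) between
iterations i-1 and i, the search stops when c_i <= 0.10 * c_{i-1}, or
when no landmark moved at all, or at the iteration cap (250 by
default; convergence is typically reached between 50 and 250
iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import SimilarityTransform, align_pair
from .pdm import PointDistributionModel, clamp_b, project, reconstruct
from .profiles import (
    ProfileModel,
    landmark_normal,
    landmark_spacings,
    mahalanobis,
    sample_profile,
)
from .shapes import Shape, from_vector

__all__ = [
    "place_mean_shape",
    "best_move",
    "fit_model_to_points",
    "converged",
    "segment",
    "SearchDiagnostics",
]


@dataclass
class SearchDiagnostics:
    """Per-iteration record of one ASM search."""

    moved_counts: list[int] = field(default_factory=list)
    mean_mahalanobis: list[float] = field(default_factory=list)
    poses: list[SimilarityTransform] = field(default_factory=list)
    b_history: list[np.ndarray] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False
    hit_iteration_cap: bool = False


def place_mean_shape(
    model: PointDistributionModel,
    corner_pairs: list[tuple[np.ndarray, np.ndarray]],
) -> Shape:
    """Pose the mean shape on the image from anterior corner pairs.

    For a vertebra model each (upper, lower) pair places one instance
    of the single-vertebra mean (the two-point similarity fit is
    exact); the result is a multi-block shape with one block per pair.
    For a column model one similarity transform is fitted jointly, by
    least squares, to all 2N corners.
    """
    mean = model.mean_shape
    L = model.n_per_vertebra
    up_idx, lo_idx = 0, L // 4
    if model.model_kind == "vertebra":
        if model.n_vertebrae != 1:
            raise ValueError("vertebra model must have a single block")
        blocks = []
        src = mean.points[[up_idx, lo_idx]]
        for up, lo in corner_pairs:
            T = align_pair(src, np.array([up, lo], float))
            blocks.append(T.apply(mean.points))
        return Shape(np.vstack(blocks), len(corner_pairs), L)
    if model.model_kind == "column":
        if len(corner_pairs) != model.n_vertebrae:
            raise ValueError(
                f"column model expects {model.n_vertebrae} corner pairs, "
                f"got {len(corner_pairs)}"
            )
        src = np.vstack(
            [mean.points[[v * L + up_idx, v * L + lo_idx]]
             for v in range(model.n_vertebrae)]
        )
        dst = np.vstack([np.array([up, lo], float) for up, lo in corner_pairs])
        T = align_pair(src, dst)
        return Shape(T.apply(mean.points), model.n_vertebrae, L)
    raise ValueError(f"unknown model kind {model.model_kind!r}")


def best_move(
    image: np.ndarray,
    shape: Shape,
    index: int,
    profile_model: ProfileModel,
    search_extent: int = 5,
    step_px: float = 1.0,
    spacing_px: float | None = None,
) -> tuple[np.ndarray, float]:
    """Best position for one landmark along its normal.

    Evaluates offsets {-m..m} * step_px along the landmark normal and
    returns (position, D) minimising the Mahalanobis profile distance;
    ties prefer the smallest |offset|, then the negative one.  If every
    candidate falls outside the image the landmark stays put.
    """
    if search_extent < 0 or step_px <= 0:
        raise ValueError("invalid search parameters")
    if spacing_px is None:
        spacing_px = landmark_spacings(shape, profile_model.spacing_fraction)[index]
    n = landmark_normal(shape, index)
    p = shape.points[index]
    offsets = np.arange(-search_extent, search_extent + 1) * step_px
    # tie-break order: smallest |offset| first, negative before positive
    order = sorted(range(len(offsets)), key=lambda i: (abs(offsets[i]), offsets[i]))
    best_pos, best_d = p, np.inf
    for i in order:
        cand = p + offsets[i] * n
        try:
            g = sample_profile(
                image, cand, n, profile_model.k_p, spacing_px, profile_model.norm
            )
        except ValueError:
            continue
        d = mahalanobis(
            g, profile_model.mean[index], profile_model.inv_covariance[index]
        )
        if d < best_d - 1e-15:
            best_pos, best_d = cand, d
    if not np.isfinite(best_d):
        return p, np.inf
    return best_pos, best_d


def _best_moves_vectorized(
    image: np.ndarray,
    shape: Shape,
    profile_model: ProfileModel,
    search_extent: int,
    steps_px: np.ndarray,
    spacings_px: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """All-landmark profile search in one interpolation call."""
    from scipy.ndimage import map_coordinates

    n_lm = shape.n_landmarks
    k_p = profile_model.k_p
    normals = np.stack([landmark_normal(shape, i) for i in range(n_lm)])
    m = search_extent
    offs = np.arange(-m, m + 1)  # (C,)
    centers = (
        shape.points[:, None, :]
        + (offs[None, :, None] * steps_px[:, None, None]) * normals[:, None, :]
    )  # (n, C, 2)
    t = np.arange(k_p + 1) - k_p / 2  # (K+1,)
    samples = (
        centers[:, :, None, :]
        + (t[None, None, :, None] * spacings_px[:, None, None, None])
        * normals[:, None, None, :]
    )  # (n, C, K+1, 2)
    flat = samples.reshape(-1, 2)
    grey = map_coordinates(
        np.asarray(image, float), [flat[:, 1], flat[:, 0]], order=1, mode="nearest"
    ).reshape(n_lm, len(offs), k_p + 1)
    grad = np.diff(grey, axis=2)  # (n, C, K)
    denom = grey.sum(axis=2)
    if profile_model.norm == "grey_sum":
        pass
    elif profile_model.norm == "abs_grad_sum":
        denom = np.abs(grad).sum(axis=2)
    else:
        denom = np.ones_like(denom)
    safe = np.where(np.abs(denom) < 1e-12, 1.0, denom)
    g = np.where(np.abs(denom[..., None]) < 1e-12, 0.0, grad / safe[..., None])
    diff = g - profile_model.mean[:, None, :]
    D = np.einsum("ncj,njk,nck->nc", diff, profile_model.inv_covariance, diff)

    # candidates whose centre is out of the image are infeasible
    h, w = image.shape
    reach = (k_p / 2) * spacings_px[:, None]
    cx, cy = centers[..., 0], centers[..., 1]
    infeasible = (
        (cx < -reach) | (cx > w - 1 + reach) | (cy < -reach) | (cy > h - 1 + reach)
    )
    D = np.where(infeasible, np.inf, D)

    # argmin with tie-break (|offset| then negative offset)
    tie1 = np.abs(offs)[None, :].repeat(n_lm, 0)
    tie2 = offs[None, :].repeat(n_lm, 0)
    best = np.lexsort((tie2, tie1, D), axis=1)[:, 0]
    all_inf = ~np.isfinite(D.min(axis=1))
    new_pts = centers[np.arange(n_lm), best]
    new_pts[all_inf] = shape.points[all_inf]
    best_d = D[np.arange(n_lm), best]
    return new_pts, best_d


def fit_model_to_points(
    model: PointDistributionModel,
    moved: Shape,
    tol: float = 1e-6,
    max_inner: int = 20,
    fixed_pose: SimilarityTransform | None = None,
) -> tuple[SimilarityTransform, np.ndarray, Shape]:
    """Regularise a moved point cloud by the PDM.

    Alternates a similarity pose fit (model frame -> image) with the
    clamped mode-weight projection until both stabilise.  With
    ``fixed_pose`` the pose stays frozen and only b is fitted.  Returns
    (pose, b, regularised shape in the image frame).
    """
    b = np.zeros(model.n_modes)
    pose = fixed_pose
    prev = None
    for _ in range(max_inner):
        x_model = reconstruct(model, b)
        model_shape = from_vector(x_model, model.n_vertebrae, model.n_per_vertebra)
        if fixed_pose is None:
            pose = align_pair(model_shape, moved)
        y = pose.inverse().apply(moved.points)
        b = clamp_b(model, project(model, y.reshape(-1)))
        state = np.concatenate(
            [[pose.scale, pose.rotation], pose.translation, b]
        )
        if prev is not None and np.max(np.abs(state - prev)) < tol:
            break
        prev = state
    x_final = reconstruct(model, b)
    out = pose.apply(x_final.reshape(-1, 2))
    return pose, b, Shape(out, moved.n_vertebrae, moved.n_per_vertebra)


def converged(moved_counts: list[int], ratio: float = 0.10) -> bool:
    """10% stopping rule on the history of moved-landmark counts.

    True when the latest count is zero (full stability) or is at most
    ``ratio`` times the previous count.
    """
    if not moved_counts:
        return False
    if moved_counts[-1] == 0:
        return True
    if len(moved_counts) < 2:
        return False
    return moved_counts[-1] <= ratio * moved_counts[-2]


def segment(
    image: np.ndarray,
    model: PointDistributionModel,
    profile_model: ProfileModel,
    initial_shape: Shape,
    max_iter: int = 250,
    search_extent: int = 5,
    step_px: float | None = None,
    move_threshold_px: float = 0.5,
    pose_update: bool = True,
) -> tuple[Shape, SearchDiagnostics]:
    """Run the iterative ASM search from an initial shape placement.

    Each iteration moves every landmark to its best profile match along
    the normal (candidate offsets {-m..m} * step, step defaulting to
    the profile spacing) and then projects the result back onto the
    model.  A landmark counts as "moved" when it is displaced by more
    than ``move_threshold_px`` between consecutive regularised shapes,
    so subpixel jitter cannot defeat the stopping rule.
    """
    if model.model_kind == "vertebra" and initial_shape.n_vertebrae != 1:
        # each vertebra instance evolves independently
        blocks, diags = [], []
        for v in range(initial_shape.n_vertebrae):
            blk, dg = segment(
                image, model, profile_model, initial_shape.vertebra(v),
                max_iter, search_extent, step_px, move_threshold_px, pose_update,
            )
            blocks.append(blk.points)
            diags.append(dg)
        combined = Shape(
            np.vstack(blocks), initial_shape.n_vertebrae, initial_shape.n_per_vertebra
        )
        merged = SearchDiagnostics(
            moved_counts=[sum(x) for x in zip(*(d.moved_counts for d in diags))]
            if diags else [],
            n_iterations=max(d.n_iterations for d in diags),
            converged=all(d.converged for d in diags),
            hit_iteration_cap=any(d.hit_iteration_cap for d in diags),
        )
        return combined, merged

    shape = initial_shape.copy()
    diag = SearchDiagnostics()
    fixed_pose = None
    if not pose_update:
        fixed_pose = align_pair(model.mean_shape, shape)
    for _ in range(max_iter):
        spacings = landmark_spacings(shape, profile_model.spacing_fraction)
        steps = np.full(shape.n_landmarks, step_px) if step_px else spacings
        moved_pts, best_d = _best_moves_vectorized(
            image, shape, profile_model, search_extent, steps, spacings
        )
        pose, b, new_shape = fit_model_to_points(
            model, shape.with_points(moved_pts), fixed_pose=fixed_pose
        )
        disp = np.linalg.norm(new_shape.points - shape.points, axis=1)
        diag.moved_counts.append(int(np.sum(disp > move_threshold_px)))
        finite = best_d[np.isfinite(best_d)]
        diag.mean_mahalanobis.append(float(finite.mean()) if finite.size else np.nan)
        diag.poses.append(pose)
        diag.b_history.append(b)
        shape = new_shape
        diag.n_iterations += 1
        if converged(diag.moved_counts):
            diag.converged = True
            break
    else:
        diag.hit_iteration_cap = True
    return shape, diag
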