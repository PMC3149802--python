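"""Similarity transforms and generalized Procrustes alignment.

Training shapes are annotated at arbitrary positions, orientations and
scales; before any statistics can be pooled they are brought into a
common frame by similarity transforms (rotation + isotropic scale +
translation) chosen to minimise a weighted sum of squared distances
between corresponding landmarks.  The group alignment iterates:
align everything to the first shape, then repeatedly (re)compute the
mean, re-anchor the mean's pose to the first shape, and re-align every
shape to the mean, until the mean stops moving.

The pairwise fit is solved in closed form via the complex-number
least-squares formulation (rotation+scale ≡ one complex multiplier),
which is exact and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .shapes import Shape, TrainingSet

__all__ = ["SimilarityTransform", "align_pair", "generalized_procrustes"]


class AlignmentError(ValueError):
    pass


@dataclass
class SimilarityTransform:
    """x' = s * R(theta) @ x + t, with R a counter-clockwise rotation."""

    scale: float = 1.0
    rotation: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        return pts @ self.matrix.T + self.translation

    def apply_shape(self, shape: Shape) -> Shape:
        return shape.with_points(self.apply(shape.points))

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equal to applying ``inner`` first, then ``self``."""
        return SimilarityTransform(
            scale=self.scale * inner.scale,
            rotation=self.rotation + inner.rotation,
            translation=self.matrix @ inner.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        R_inv = inv_scale * np.array([[c, -s], [s, c]])
        return SimilarityTransform(
            scale=inv_scale, rotation=-self.rotation,
            translation=-R_inv @ self.translation,
        )


def align_pair(
    shape: Shape | np.ndarray,
    reference: Shape | np.ndarray,
    weights: np.ndarray | None = None,
) -> SimilarityTransform:
    """Least-squares similarity transform mapping ``shape`` onto ``reference``.

    Minimises ``sum_k w_k ||T(p_k) - q_k||^2`` in closed form.  Weights
    default to uniform; the classic formulation is weighted but leaves
    the weights open, so per-landmark weights (e.g. inverse landmark
    variance) are accepted here.
    """
    p = shape.points if isinstance(shape, Shape) else np.asarray(shape, float)
    q = (
        reference.points
        if isinstance(reference, Shape)
        else np.asarray(reference, float)
    )
    if p.shape != q.shape:
        raise ValueError("shapes must have equal landmark counts")
    if weights is None:
        w = np.ones(len(p))
    else:
        w = np.asarray(weights, float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    zp = p[:, 0] + 1j * p[:, 1]
    zq = q[:, 0] + 1j * q[:, 1]
    mp = np.sum(w * zp)
    mq = np.sum(w * zq)
    zp_c = zp - mp
    zq_c = zq - mq
    denom = np.sum(w * np.abs(zp_c) ** 2)
    if denom < 1e-300:
        raise AlignmentError("degenerate shape: all landmarks coincide")
    z = np.sum(w * np.conj(zp_c) * zq_c) / denom
    if np.abs(z) < 1e-300:
        raise AlignmentError("degenerate alignment: zero optimal scale")
    t = mq - z * mp
    return SimilarityTransform(
        scale=float(np.abs(z)),
        rotation=float(np.angle(z)),
        translation=np.array([t.real, t.imag]),
    )


def _mean_shape(shapes: list[Shape]) -> Shape:
    pts = np.mean([s.points for s in shapes], axis=0)
    return shapes[0].with_points(pts)


def _objective(shapes: list[Shape], mean: Shape) -> float:
    total = 0.0
    for s in shapes:
        T = align_pair(s, mean)
        total += float(np.sum((T.apply(s.points) - mean.points) ** 2))
    return total


def generalized_procrustes(
    ts: TrainingSet,
    tol: float = 1e-6,
    max_iter: int = 100,
    weights: np.ndarray | None = None,
) -> tuple[TrainingSet, Shape, dict]:
    """Generalized Procrustes analysis of a training set.

    Returns the aligned training set, the mean shape (posed like the
    first input shape), and a diagnostics dict with per-iteration mean
    displacement and alignment objective.  ``tol`` is the RMS mean-shape
    displacement, in units normalised by the mean's RMS size.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    first = ts.shapes[0]
    aligned = [align_pair(s, first, weights).apply_shape(s) for s in ts.shapes]
    mean = _mean_shape(aligned)
    diagnostics = {"mean_displacement": [], "objective": [], "converged": False}

    for _ in range(max_iter):
        prev_mean = mean
        # pin the mean's pose to the first (original) shape
        anchored = align_pair(mean, first, weights).apply_shape(mean)
        aligned = [align_pair(s, anchored, weights).apply_shape(s) for s in ts.shapes]
        mean = _mean_shape(aligned)
        # fixed point: successive post-averaging means coincide
        scale = np.sqrt(np.mean((mean.points - mean.centroid()) ** 2))
        move = np.sqrt(np.mean((mean.points - prev_mean.points) ** 2))
        rel_move = move / scale if scale > 0 else move
        diagnostics["mean_displacement"].append(rel_move)
        diagnostics["objective"].append(_objective(ts.shapes, mean))
        if rel_move < tol:
            diagnostics["converged"] = True
            break
    else:
        warnings.warn(
            "generalized Procrustes did not converge within max_iter; "
            "returning best result",
            RuntimeWarning,
        )
    # final anchoring applied to mean AND aligned shapes together: a
    # similarity transform commutes with averaging, so the mean stays
    # the exact arithmetic average while landing in shape 1's pose
    T = align_pair(mean, first, weights)
    mean = T.apply_shape(mean)
    aligned = [T.apply_shape(s) for s in aligned]
    return TrainingSet(aligned, list(ts.image_ids)), mean, diagnostics
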