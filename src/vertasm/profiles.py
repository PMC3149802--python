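"""Grey-level gradient profiles along landmark normals.

During search, each landmark is judged by the intensity pattern on a
short segment perpendicular to the contour.  A profile g holds k_p
normalized first differences of grey level sampled along that normal;
per landmark, the training set yields a mean profile ḡ and covariance
S_g, and a candidate position is scored by the Mahalanobis distance

    D = (g - ḡ)^T S_g^{-1} (g - ḡ).

Grey values are sampled with bilinear interpolation (edge-clamped) at
k_p + 1 half-integer offsets symmetric about the landmark, producing
k_p differences centred on it.  Following the source formulation, each
difference is normalized by the sum of the sampled grey levels; the
more common ASM normalizer (sum of |differences|) and no normalization
are available as options.  Profile spacing is a fixed fraction
(default 5%) of the vertebra size — the distance between the upper and
lower anterior corner landmarks — so it adapts to image scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .shapes import Shape

__all__ = [
    "landmark_normal",
    "sample_profile",
    "build_profile_model",
    "mahalanobis",
    "ProfileModel",
]

_NORMS = ("grey_sum", "abs_grad_sum", "none")


def landmark_normal(shape: Shape, index: int) -> np.ndarray:
    """Outward unit normal of the closed contour at landmark ``index``.

    The contour direction is approximated by the chord joining the two
    neighbouring landmarks (wrap-around); the normal is its
    perpendicular, oriented away from the shape centroid.  For a
    multi-vertebra shape the contour wraps within the landmark's own
    vertebra block.
    """
    L = shape.n_per_vertebra
    v, k = divmod(index, L)
    block = shape.points[v * L : (v + 1) * L]
    prev_pt = block[(k - 1) % L]
    next_pt = block[(k + 1) % L]
    chord = next_pt - prev_pt
    norm = np.linalg.norm(chord)
    if norm < 1e-12:
        raise ValueError(f"coincident neighbours at landmark {index}")
    n = np.array([-chord[1], chord[0]]) / norm
    centroid = block.mean(axis=0)
    if np.dot(n, centroid - block[k]) > 0:
        n = -n
    return n


def _sample_grey(image: np.ndarray, pts: np.ndarray) -> np.ndarray:
    # map_coordinates expects (row, col) = (y, x)
    return map_coordinates(
        np.asarray(image, float), [pts[:, 1], pts[:, 0]], order=1, mode="nearest"
    )


def sample_profile(
    image: np.ndarray,
    center: np.ndarray,
    normal: np.ndarray,
    k_p: int = 7,
    spacing_px: float = 1.0,
    norm: str = "grey_sum",
) -> np.ndarray:
    """Sample the normalized gradient profile at ``center``.

    Grey levels are read at offsets (j - k_p/2) * spacing_px along the
    normal for j = 0..k_p, then differenced (I_j - I_{j-1}) and
    normalized.  If the normalizing sum is zero the profile is all-zero.
    """
    if k_p < 2:
        raise ValueError("profile needs at least 2 points")
    if spacing_px <= 0:
        raise ValueError("spacing must be positive")
    if norm not in _NORMS:
        raise ValueError(f"norm must be one of {_NORMS}")
    center = np.asarray(center, float)
    normal = np.asarray(normal, float)
    h, w = image.shape
    reach = (k_p / 2) * spacing_px
    if (
        center[0] < -reach
        or center[0] > w - 1 + reach
        or center[1] < -reach
        or center[1] > h - 1 + reach
    ):
        raise ValueError("profile centre too far outside the image")
    offsets = (np.arange(k_p + 1) - k_p / 2) * spacing_px
    pts = center[None, :] + offsets[:, None] * normal[None, :]
    grey = _sample_grey(image, pts)
    grad = np.diff(grey)
    if norm == "grey_sum":
        denom = grey.sum()
    elif norm == "abs_grad_sum":
        denom = np.abs(grad).sum()
    else:
        denom = 1.0
    if abs(denom) < 1e-12:
        return np.zeros(k_p)
    return grad / denom


@dataclass
class ProfileModel:
    """Per-landmark profile statistics learned from the training set.

    ``mean`` is (n_landmarks, k_p); ``covariance`` and ``inv_covariance``
    are (n_landmarks, k_p, k_p).  The inverse is computed on
    S_g + eps*I with eps = 1e-6 * trace(S_g)/k_p (1e-6 if the trace is
    zero) to tolerate singular covariances; the eps used per landmark is
    recorded.
    """

    mean: np.ndarray
    covariance: np.ndarray
    inv_covariance: np.ndarray
    epsilons: np.ndarray
    k_p: int = 7
    spacing_fraction: float = 0.05
    norm: str = "grey_sum"

    @property
    def n_landmarks(self) -> int:
        return self.mean.shape[0]


def _regularized_inverse(S: np.ndarray) -> tuple[np.ndarray, float]:
    k = S.shape[0]
    tr = float(np.trace(S))
    eps = 1e-6 * tr / k if tr > 1e-30 else 1e-6
    return np.linalg.inv(S + eps * np.eye(k)), eps


def landmark_spacings(shape: Shape, spacing_fraction: float) -> np.ndarray:
    """Per-landmark profile spacing in px: fraction of the landmark's
    vertebra size."""
    L = shape.n_per_vertebra
    sizes = np.array(
        [shape.vertebra_size(v) for v in range(shape.n_vertebrae)]
    )
    return np.repeat(sizes * spacing_fraction, L)


def profiles_for_shape(
    image: np.ndarray,
    shape: Shape,
    k_p: int,
    spacing_fraction: float,
    norm: str = "grey_sum",
) -> np.ndarray:
    """(n_landmarks, k_p) profile matrix for one annotated image."""
    spacings = landmark_spacings(shape, spacing_fraction)
    out = np.empty((shape.n_landmarks, k_p))
    for i in range(shape.n_landmarks):
        n = landmark_normal(shape, i)
        out[i] = sample_profile(image, shape.points[i], n, k_p, spacings[i], norm)
    return out


def build_profile_model(
    images: list[np.ndarray],
    shapes: list[Shape],
    k_p: int = 7,
    spacing_fraction: float = 0.05,
    norm: str = "grey_sum",
) -> ProfileModel:
    """Learn per-landmark profile mean and covariance over the training set."""
    if len(images) != len(shapes) or len(images) < 2:
        raise ValueError("need >= 2 paired training images and shapes")
    all_p = np.stack(
        [
            profiles_for_shape(im, sh, k_p, spacing_fraction, norm)
            for im, sh in zip(images, shapes)
        ]
    )  # (f, n_landmarks, k_p)
    mean = all_p.mean(axis=0)
    centred = all_p - mean
    f = len(images)
    n_lm = mean.shape[0]
    cov = np.einsum("fij,fik->ijk", centred, centred) / (f - 1)
    cov = 0.5 * (cov + cov.transpose(0, 2, 1))  # enforce exact symmetry
    inv = np.empty_like(cov)
    eps = np.empty(n_lm)
    for i in range(n_lm):
        inv[i], eps[i] = _regularized_inverse(cov[i])
    return ProfileModel(
        mean=mean,
        covariance=cov,
        inv_covariance=inv,
        epsilons=eps,
        k_p=k_p,
        spacing_fraction=spacing_fraction,
        norm=norm,
    )


def mahalanobis(
    g: np.ndarray, mean: np.ndarray, inv_cov: np.ndarray
) -> float:
    """Quadratic profile distance D = (g-ḡ)^T S^{-1} (g-ḡ) (>= 0)."""
    g = np.asarray(g, float)
    if g.shape != mean.shape:
        raise ValueError("profile length mismatch")
    d = g - mean
    return float(d @ inv_cov @ d)
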