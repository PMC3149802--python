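"""Segmentation accuracy metrics.

Two complementary errors are reported: the point-to-point error (the
Euclidean distance between corresponding landmarks) and the
point-to-line error (the distance from each segmented landmark to the
closed piecewise-linear ground-truth contour of its vertebra), which
forgives sliding along the contour and is therefore never larger than
the point-to-point error.  The success rate is the percentage of
vertebrae whose mean point-to-line error falls under a threshold
(default 2 px on synthetic phantoms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Point

from .shapes import Shape

__all__ = [
    "EvalReport",
    "point_to_line_error",
    "point_to_point_error",
    "evaluate_segmentation",
    "success_rate",
]


@dataclass
class EvalReport:
    point_to_line: np.ndarray       # (n,) per-landmark distances
    point_to_point: np.ndarray      # (n,)
    per_vertebra_mean_p2l: np.ndarray  # (V,)
    per_vertebra_mean_p2p: np.ndarray  # (V,)
    pixel_spacing_mm: float | None = None

    @property
    def mean_point_to_line(self) -> float:
        return float(self.point_to_line.mean())

    @property
    def mean_point_to_point(self) -> float:
        return float(self.point_to_point.mean())

    def mm(self, px: float) -> float | None:
        return None if self.pixel_spacing_mm is None else px * self.pixel_spacing_mm


def _check(segmented: Shape, truth: Shape) -> None:
    if segmented.n_landmarks != truth.n_landmarks:
        raise ValueError("landmark counts differ")
    if (
        segmented.n_vertebrae != truth.n_vertebrae
        or segmented.n_per_vertebra != truth.n_per_vertebra
    ):
        raise ValueError("shape structures differ")


def point_to_line_error(segmented: Shape, truth: Shape) -> np.ndarray:
    """Distance from each segmented landmark to the closed ground-truth
    contour of its own vertebra."""
    _check(segmented, truth)
    L = truth.n_per_vertebra
    out = np.empty(segmented.n_landmarks)
    for v in range(truth.n_vertebrae):
        ring = LinearRing(truth.points[v * L : (v + 1) * L])
        for k in range(L):
            i = v * L + k
            out[i] = ring.distance(Point(segmented.points[i]))
    return out


def point_to_point_error(segmented: Shape, truth: Shape) -> np.ndarray:
    """Euclidean distance between corresponding landmarks."""
    _check(segmented, truth)
    return np.linalg.norm(segmented.points - truth.points, axis=1)


def evaluate_segmentation(
    segmented: Shape, truth: Shape, pixel_spacing_mm: float | None = None
) -> EvalReport:
    p2l = point_to_line_error(segmented, truth)
    p2p = point_to_point_error(segmented, truth)
    L = truth.n_per_vertebra
    v_p2l = p2l.reshape(truth.n_vertebrae, L).mean(axis=1)
    v_p2p = p2p.reshape(truth.n_vertebrae, L).mean(axis=1)
    return EvalReport(p2l, p2p, v_p2l, v_p2p, pixel_spacing_mm)


def success_rate(reports: list[EvalReport], threshold_px: float = 2.0) -> dict:
    """Percentage of vertebrae with mean point-to-line error under the
    threshold, overall and per vertebra position in the stack."""
    if not reports:
        raise ValueError("no reports to aggregate")
    if threshold_px <= 0:
        raise ValueError("threshold must be positive")
    per_v = np.stack([r.per_vertebra_mean_p2l for r in reports])  # (cases, V)
    ok = per_v <= threshold_px
    return {
        "overall_pct": float(100.0 * ok.mean()),
        "per_position_pct": (100.0 * ok.mean(axis=0)).tolist(),
        "mean_point_to_line_px": float(per_v.mean()),
    }
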