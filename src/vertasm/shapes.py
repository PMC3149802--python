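"""Landmark shapes, their file formats, and the standard vertebra marking.

Coordinate convention: image coordinates, origin at the top-left pixel
centre, x rightward, y downward, 0-based.  Landmark coordinates are
continuous (subpixel).  The anterior (front) side of a vertebra is taken
as the smaller-x side of the image, as on a standard lateral cervical
radiograph; mirrored images can be flipped before annotation.

A shape is an ordered list of 2-D landmarks with a block structure:
``n_vertebrae`` blocks of ``n_per_vertebra`` landmarks each.  Within a
block the landmarks run counter-clockwise (in the y-down image frame)
from the upper-anterior corner, so the four corners sit at indices
``0, L/4, L/2, 3L/4`` — the classic 16-point marking with corners at
points 1, 5, 9, 13, generalised to any L divisible by 4.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Shape",
    "TrainingSet",
    "to_vector",
    "from_vector",
    "read_landmarks",
    "write_landmarks",
    "default_marking",
]


class LandmarkFormatError(ValueError):
    """Raised when a points file is malformed or internally inconsistent."""


@dataclass
class Shape:
    """An ordered set of 2-D landmarks with vertebra block structure.

    Parameters
    ----------
    points : (n, 2) float array
        Landmark coordinates ``(x, y)`` in image pixels, subpixel allowed.
    n_vertebrae : int
        Number of vertebra blocks V.
    n_per_vertebra : int
        Landmarks per vertebra L; ``n = V * L``.
    """

    points: np.ndarray
    n_vertebrae: int = 1
    n_per_vertebra: int = field(default=0)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        n = len(self.points)
        if self.n_per_vertebra == 0:
            if n % self.n_vertebrae:
                raise ValueError("landmark count not divisible by n_vertebrae")
            self.n_per_vertebra = n // self.n_vertebrae
        if self.n_vertebrae * self.n_per_vertebra != n:
            raise ValueError(
                f"structure {self.n_vertebrae}x{self.n_per_vertebra} "
                f"does not match {n} landmarks"
            )

    @property
    def n_landmarks(self) -> int:
        return len(self.points)

    @property
    def corner_indices(self) -> np.ndarray:
        """Indices of the 4 corner landmarks within one vertebra block."""
        L = self.n_per_vertebra
        if L % 4:
            raise ValueError("corner indices undefined unless L divisible by 4")
        return np.array([0, L // 4, L // 2, 3 * L // 4])

    def vertebra(self, v: int) -> "Shape":
        """Extract vertebra block ``v`` as a single-vertebra Shape."""
        L = self.n_per_vertebra
        return Shape(self.points[v * L : (v + 1) * L].copy(), 1, L)

    def anterior_corners(self, v: int) -> tuple[np.ndarray, np.ndarray]:
        """(upper, lower) anterior corner coordinates of vertebra ``v``."""
        L = self.n_per_vertebra
        block = self.points[v * L : (v + 1) * L]
        return block[0], block[L // 4]

    def vertebra_size(self, v: int) -> float:
        """Anterior corner-to-corner distance, the vertebra size used for
        profile spacing."""
        up, lo = self.anterior_corners(v)
        return float(np.linalg.norm(up - lo))

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def copy(self) -> "Shape":
        return Shape(self.points.copy(), self.n_vertebrae, self.n_per_vertebra)

    def with_points(self, points: np.ndarray) -> "Shape":
        return Shape(np.asarray(points, float), self.n_vertebrae, self.n_per_vertebra)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Shape):
            return NotImplemented
        return (
            self.n_vertebrae == other.n_vertebrae
            and self.n_per_vertebra == other.n_per_vertebra
            and np.array_equal(self.points, other.points)
        )


@dataclass
class TrainingSet:
    """A collection of structurally identical shapes plus image ids."""

    shapes: list[Shape]
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.shapes) < 2:
            raise ValueError("a training set needs at least 2 shapes")
        s0 = self.shapes[0]
        for s in self.shapes[1:]:
            if (
                s.n_landmarks != s0.n_landmarks
                or s.n_vertebrae != s0.n_vertebrae
                or s.n_per_vertebra != s0.n_per_vertebra
            ):
                raise ValueError("all shapes in a training set must share structure")
        if not self.image_ids:
            self.image_ids = [f"shape_{i}" for i in range(len(self.shapes))]

    @property
    def n_shapes(self) -> int:
        return len(self.shapes)

    def as_matrix(self) -> np.ndarray:
        """(f, 2n) matrix of shape vectors."""
        return np.stack([to_vector(s) for s in self.shapes])


def to_vector(shape: Shape) -> np.ndarray:
    """Serialise a shape to the interleaved vector (x1, y1, x2, y2, ...)."""
    return shape.points.reshape(-1).copy()


def from_vector(
    vec: np.ndarray, n_vertebrae: int = 1, n_per_vertebra: int = 0
) -> Shape:
    """Inverse of :func:`to_vector`."""
    vec = np.asarray(vec, float)
    if vec.ndim != 1 or len(vec) % 2:
        raise ValueError("shape vector must be 1-D with even length")
    return Shape(vec.reshape(-1, 2), n_vertebrae, n_per_vertebra)


def write_landmarks(shape: Shape, path) -> None:
    """Write a points file::

        n_points: <n>
        {
        <x> <y>
        ...
        }

    Coordinates are written with 17 significant digits so the
    write-read round trip is exact at float64 resolution.
    """
    with open(path, "w") as fh:
        fh.write(f"n_points: {shape.n_landmarks}\n")
        fh.write(f"n_vertebrae: {shape.n_vertebrae}\n")
        fh.write("{\n")
        for x, y in shape.points:
            fh.write(f"{x:.17g} {y:.17g}\n")
        fh.write("}\n")


def read_landmarks(path) -> Shape:
    """Read a points file (or a ``vertebra,landmark,x,y`` CSV)."""
    with open(path) as fh:
        text = fh.read()
    head = text.lstrip().splitlines()[0] if text.strip() else ""
    if "," in head:  # CSV variant
        return _read_csv(text)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("n_points:"):
        raise LandmarkFormatError("missing 'n_points:' header")
    try:
        n = int(lines[0].split(":", 1)[1])
    except ValueError as exc:
        raise LandmarkFormatError("unparseable n_points header") from exc
    idx = 1
    n_vert = 1
    if lines[idx].startswith("n_vertebrae:"):
        n_vert = int(lines[idx].split(":", 1)[1])
        idx += 1
    if lines[idx] != "{":
        raise LandmarkFormatError("expected '{' after header")
    body = lines[idx + 1 :]
    if not body or body[-1] != "}":
        raise LandmarkFormatError("points block not closed with '}'")
    pts = []
    for ln in body[:-1]:
        parts = ln.split()
        if len(parts) != 2:
            raise LandmarkFormatError(f"bad coordinate line: {ln!r}")
        pts.append((float(parts[0]), float(parts[1])))
    if len(pts) != n:
        raise LandmarkFormatError(
            f"header declares {n} points but body has {len(pts)}"
        )
    return Shape(np.array(pts, float), n_vert)


def _read_csv(text: str) -> Shape:
    reader = csv.DictReader(io.StringIO(text))
    need = {"vertebra", "landmark", "x", "y"}
    if reader.fieldnames is None or not need.issubset(reader.fieldnames):
        raise LandmarkFormatError("CSV must have header vertebra,landmark,x,y")
    rows = [(int(r["vertebra"]), int(r["landmark"]), float(r["x"]), float(r["y"]))
            for r in reader]
    if not rows:
        raise LandmarkFormatError("empty CSV")
    rows.sort()
    n_vert = max(r[0] for r in rows) + 1
    pts = np.array([(x, y) for _, _, x, y in rows])
    if len(pts) % n_vert:
        raise LandmarkFormatError("unequal landmarks per vertebra in CSV")
    return Shape(pts, n_vert)


def write_landmarks_csv(shape: Shape, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertebra", "landmark", "x", "y"])
        L = shape.n_per_vertebra
        for i, (x, y) in enumerate(shape.points):
            w.writerow([i // L, i % L, f"{x:.17g}", f"{y:.17g}"])


def default_marking(corners: np.ndarray, n_per_vertebra: int) -> Shape:
    """Mark a vertebral body from its 4 corners.

    ``corners`` are ordered counter-clockwise in the y-down image frame
    starting at the upper-anterior corner: upper-anterior,
    lower-anterior, lower-posterior, upper-posterior.  Returns L
    landmarks: the corners plus (L-4)/4 equidistant points along each
    edge, so the corners land at indices 0, L/4, L/2, 3L/4.
    """
    corners = np.asarray(corners, float)
    if corners.shape != (4, 2):
        raise ValueError("need exactly 4 corner points")
    L = n_per_vertebra
    if L < 4 or L % 4:
        raise ValueError("landmarks per vertebra must be >= 4 and divisible by 4")
    per_edge = L // 4
    pts = np.empty((L, 2))
    for e in range(4):
        a, b = corners[e], corners[(e + 1) % 4]
        t = np.arange(per_edge) / per_edge
        pts[e * per_edge : (e + 1) * per_edge] = a + t[:, None] * (b - a)
    return Shape(pts, 1, L)
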