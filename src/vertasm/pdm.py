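"""Point distribution model: mean shape + principal deformation modes.

After alignment, each training shape is a vector x_i of interleaved
landmark coordinates.  The model is the sample mean x̄ together with the
leading eigenvectors P = (p_1 ... p_t) of the sample covariance matrix;
any plausible shape is x = x̄ + P b with the mode weights b_i confined
to ±3 standard deviations, |b_i| <= 3 sqrt(lambda_i).

Two flavours exist: a *column* model treating the whole spine as one
shape, and a *vertebra* model with one single-vertebra shape per
training example; the flavour only changes the structure metadata, the
mathematics is identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .shapes import Shape, TrainingSet, from_vector

__all__ = ["PointDistributionModel", "build_model", "project", "reconstruct", "clamp_b"]


@dataclass
class PointDistributionModel:
    """Fitted PDM.

    Attributes
    ----------
    mean : (2n,) array
        Mean shape vector x̄ in the aligned frame.
    modes : (2n, t) array
        Orthonormal eigenvector columns p_i, sorted by eigenvalue.
    eigenvalues : (t,) array
        Variances lambda_i along each mode, non-increasing, positive.
    model_kind : {"column", "vertebra"}
    n_vertebrae, n_per_vertebra : int
        Structure metadata (V=1 for a vertebra model).
    variance_fraction : float
        Fraction of total variance the retained modes explain.
    bound : {"sqrt", "raw"}
        Mode-weight constraint: ``sqrt`` clips b_i to ±3·sqrt(lambda_i)
        (the standard ±3 s.d. constraint), ``raw`` to ±3·lambda_i.
    """

    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    model_kind: str = "vertebra"
    n_vertebrae: int = 1
    n_per_vertebra: int = 0
    variance_fraction: float = 0.98
    bound: str = "sqrt"
    total_variance: float = 0.0

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def mean_shape(self) -> Shape:
        return from_vector(self.mean, self.n_vertebrae, self.n_per_vertebra)

    def bounds(self) -> np.ndarray:
        """Half-width of the allowed interval for each b_i."""
        if self.bound == "sqrt":
            return 3.0 * np.sqrt(self.eigenvalues)
        if self.bound == "raw":
            return 3.0 * self.eigenvalues
        raise ValueError(f"unknown bound mode {self.bound!r}")

    # estimator-style aliases
    def transform(self, x: np.ndarray) -> np.ndarray:
        return project(self, x)

    def inverse_transform(self, b: np.ndarray) -> np.ndarray:
        return reconstruct(self, b)


def build_model(
    aligned: TrainingSet,
    variance_fraction: float = 0.98,
    model_kind: str = "vertebra",
    bound: str = "sqrt",
) -> PointDistributionModel:
    """Fit the PDM to an aligned training set.

    Retains the smallest t such that the first t eigenvalues explain at
    least ``variance_fraction`` of the total variance.  Eigenvector sign
    is fixed so the first nonzero component is positive.
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    X = aligned.as_matrix()
    f = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (f - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    total = float(evals[evals > 0].sum())
    tol = max(total, 1.0) * 1e-12
    if total <= tol:
        warnings.warn("zero shape variance: mean-only model (t=0)", RuntimeWarning)
        t = 0
    else:
        ratio = np.cumsum(evals) / total
        t = int(np.searchsorted(ratio, variance_fraction - 1e-12) + 1)
        t = min(t, int(np.sum(evals > tol)), f - 1)
    evals, evecs = evals[:t], evecs[:, :t]

    for j in range(t):  # deterministic sign: first nonzero component positive
        col = evecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            evecs[:, j] = -col

    s0 = aligned.shapes[0]
    return PointDistributionModel(
        mean=mean,
        modes=evecs,
        eigenvalues=evals,
        model_kind=model_kind,
        n_vertebrae=s0.n_vertebrae,
        n_per_vertebra=s0.n_per_vertebra,
        variance_fraction=variance_fraction,
        bound=bound,
        total_variance=total,
    )


def project(model: PointDistributionModel, x: np.ndarray) -> np.ndarray:
    """Mode weights b = P^T (x - x̄)."""
    x = np.asarray(x, float)
    if x.shape != model.mean.shape:
        raise ValueError("shape vector length does not match model")
    return model.modes.T @ (x - model.mean)


def reconstruct(model: PointDistributionModel, b: np.ndarray) -> np.ndarray:
    """Shape vector x = x̄ + P b."""
    b = np.asarray(b, float)
    if b.shape != (model.n_modes,):
        raise ValueError("mode weight length does not match model")
    return model.mean + model.modes @ b


def clamp_b(model: PointDistributionModel, b: np.ndarray) -> np.ndarray:
    """Clip each mode weight into its allowed interval; idempotent."""
    b = np.asarray(b, float)
    if b.shape != (model.n_modes,):
        raise ValueError("mode weight length does not match model")
    half = model.bounds()
    return np.clip(b, -half, half)
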