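"""The ActiveShapeModel estimator and model-file persistence.

``ActiveShapeModel`` follows the scikit-learn estimator protocol:
hyperparameters are constructor arguments, ``fit(images, shapes)``
learns the point-distribution model (Procrustes alignment + PCA) and
the per-landmark grey-profile statistics, and ``predict`` /
``segment`` run the iterative profile-driven search on new images.
Fitted state lives in trailing-underscore attributes and round-trips
through a versioned JSON model file.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .align import generalized_procrustes
from .corners import CornerSequence, detect_corners
from .pdm import PointDistributionModel, build_model
from .profiles import ProfileModel, build_profile_model
from .search import SearchDiagnostics, place_mean_shape, segment
from .shapes import Shape, TrainingSet

__all__ = ["ActiveShapeModel", "save_model", "load_model"]

FORMAT_VERSION = 1


class ActiveShapeModel(BaseEstimator):
    """Active Shape Model for vertebral bodies in grey radiographs.

    Parameters
    ----------
    model_kind : {"vertebra", "column"}
        "vertebra" trains one single-vertebra model (every vertebra
        instance in every training image is an example and each
        instance evolves independently at search time); "column"
        models the whole spine as one shape.
    variance_fraction : float
        Fraction of shape variance the retained PCA modes must explain.
    bound : {"sqrt", "raw"}
        Mode-weight constraint, ±3·sqrt(lambda) (standard) or ±3·lambda.
    n_profile_points : int
        Gradient samples per profile (odd; 7 is the working default).
    profile_spacing_fraction : float
        Profile sample spacing as a fraction of the vertebra size
        (anterior corner-to-corner distance); default 5%.
    profile_norm : {"grey_sum", "abs_grad_sum", "none"}
        Profile normalizer; grey_sum divides the gradient by the sum of
        sampled grey levels.
    search_extent : int
        Candidate offsets tested on each side of a landmark.
    max_iter : int
        Iteration cap of the search (convergence is typically reached
        between 50 and 250 iterations).
    move_threshold_px : float
        Displacement under which a landmark counts as unmoved by the
        10% stopping rule.
    pose_update : bool
        Re-fit the similarity pose every iteration (else only the mode
        weights evolve after initial placement).
    """

    def __init__(
        self,
        model_kind: str = "vertebra",
        variance_fraction: float = 0.98,
        bound: str = "sqrt",
        n_profile_points: int = 7,
        profile_spacing_fraction: float = 0.05,
        profile_norm: str = "grey_sum",
        search_extent: int = 5,
        max_iter: int = 250,
        move_threshold_px: float = 0.5,
        pose_update: bool = True,
        gpa_tol: float = 1e-6,
        gpa_max_iter: int = 100,
    ):
        self.model_kind = model_kind
        self.variance_fraction = variance_fraction
        self.bound = bound
        self.n_profile_points = n_profile_points
        self.profile_spacing_fraction = profile_spacing_fraction
        self.profile_norm = profile_norm
        self.search_extent = search_extent
        self.max_iter = max_iter
        self.move_threshold_px = move_threshold_px
        self.pose_update = pose_update
        self.gpa_tol = gpa_tol
        self.gpa_max_iter = gpa_max_iter

    # ------------------------------------------------------------------
    def fit(self, X: list[np.ndarray], y: list[Shape]) -> "ActiveShapeModel":
        """Learn shape statistics and grey profiles.

        X is a list of grey images, y the matching annotated shapes
        (full spines; for a vertebra model each vertebra block becomes
        one training example).
        """
        if len(X) != len(y):
            raise ValueError("images and shapes must pair up")
        if self.model_kind == "vertebra":
            shapes, images = [], []
            for im, sh in zip(X, y):
                for v in range(sh.n_vertebrae):
                    shapes.append(sh.vertebra(v))
                    images.append(im)
        elif self.model_kind == "column":
            shapes, images = list(y), list(X)
        else:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")

        ts = TrainingSet(shapes)
        aligned, mean, gpa_diag = generalized_procrustes(
            ts, tol=self.gpa_tol, max_iter=self.gpa_max_iter
        )
        self.shape_model_ = build_model(
            aligned,
            variance_fraction=self.variance_fraction,
            model_kind=self.model_kind,
            bound=self.bound,
        )
        self.profile_model_ = build_profile_model(
            images,
            shapes,
            k_p=self.n_profile_points,
            spacing_fraction=self.profile_spacing_fraction,
            norm=self.profile_norm,
        )
        self.mean_shape_ = mean
        self.gpa_diagnostics_ = gpa_diag
        self.n_training_shapes_ = len(shapes)
        return self

    # ------------------------------------------------------------------
    def place(self, corner_pairs) -> Shape:
        """Pose the mean shape from per-vertebra (upper, lower) anterior
        corner pairs."""
        check_is_fitted(self, "shape_model_")
        return place_mean_shape(self.shape_model_, list(corner_pairs))

    def segment(
        self, image: np.ndarray, corner_pairs
    ) -> tuple[Shape, SearchDiagnostics]:
        """Initialize from corner pairs and run the iterative search."""
        check_is_fitted(self, "shape_model_")
        initial = self.place(corner_pairs)
        return segment(
            image,
            self.shape_model_,
            self.profile_model_,
            initial,
            max_iter=self.max_iter,
            search_extent=self.search_extent,
            move_threshold_px=self.move_threshold_px,
            pose_update=self.pose_update,
        )

    def segment_semiautomatic(
        self,
        image: np.ndarray,
        anchor_top,
        anchor_bottom,
        n_vertebrae: int,
        **detect_kwargs,
    ) -> tuple[Shape, CornerSequence, SearchDiagnostics]:
        """Two-click pipeline: detect the 2N corners, then segment."""
        seq, _ = detect_corners(
            image, anchor_top, anchor_bottom, n_vertebrae, **detect_kwargs
        )
        final, diag = self.segment(image, seq.corner_pairs())
        return final, seq, diag

    def predict(
        self, X: list[np.ndarray], corner_pairs_list
    ) -> list[Shape]:
        """Segment each image from its corner pairs; returns final shapes."""
        return [
            self.segment(im, pairs)[0] for im, pairs in zip(X, corner_pairs_list)
        ]

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        save_model(self, path)


def save_model(est: ActiveShapeModel, path) -> None:
    """Serialise a fitted estimator to a versioned JSON model file."""
    check_is_fitted(est, "shape_model_")
    sm, pm = est.shape_model_, est.profile_model_
    doc = {
        "format_version": FORMAT_VERSION,
        "params": est.get_params(),
        "shape_model": {
            "mean": sm.mean.tolist(),
            "modes": sm.modes.tolist(),
            "eigenvalues": sm.eigenvalues.tolist(),
            "model_kind": sm.model_kind,
            "n_vertebrae": sm.n_vertebrae,
            "n_per_vertebra": sm.n_per_vertebra,
            "variance_fraction": sm.variance_fraction,
            "bound": sm.bound,
            "total_variance": sm.total_variance,
        },
        "profile_model": {
            "mean": pm.mean.tolist(),
            "covariance": pm.covariance.tolist(),
            "epsilons": pm.epsilons.tolist(),
            "k_p": pm.k_p,
            "spacing_fraction": pm.spacing_fraction,
            "norm": pm.norm,
        },
        "n_training_shapes": est.n_training_shapes_,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ActiveShapeModel:
    """Load a model file produced by :func:`save_model`."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file version {doc.get('format_version')!r}"
        )
    est = ActiveShapeModel(**doc["params"])
    s = doc["shape_model"]
    est.shape_model_ = PointDistributionModel(
        mean=np.array(s["mean"]),
        modes=np.array(s["modes"]).reshape(len(s["mean"]), -1),
        eigenvalues=np.array(s["eigenvalues"]),
        model_kind=s["model_kind"],
        n_vertebrae=s["n_vertebrae"],
        n_per_vertebra=s["n_per_vertebra"],
        variance_fraction=s["variance_fraction"],
        bound=s["bound"],
        total_variance=s["total_variance"],
    )
    p = doc["profile_model"]
    cov = np.array(p["covariance"])
    k_p = p["k_p"]
    cov = cov.reshape(-1, k_p, k_p)
    from .profiles import _regularized_inverse

    inv = np.empty_like(cov)
    for i in range(cov.shape[0]):
        inv[i], _ = _regularized_inverse(cov[i])
    est.profile_model_ = ProfileModel(
        mean=np.array(p["mean"]).reshape(-1, k_p),
        covariance=cov,
        inv_covariance=inv,
        epsilons=np.array(p["epsilons"]),
        k_p=k_p,
        spacing_fraction=p["spacing_fraction"],
        norm=p["norm"],
    )
    est.mean_shape_ = est.shape_model_.mean_shape
    est.n_training_shapes_ = doc["n_training_shapes"]
    return est
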