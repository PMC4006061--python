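"""Procrustes superimposition: centroid size, optimal rotation, GPA,
Procrustes distances, and tangent-space coordinates.

All configurations are treated as k x 3 matrices of 3D landmarks. The
superimposition removes translation (centering), scale (unit centroid
size) and rotation (least-squares fitting, proper rotations only), so a
sample of k-landmark configurations retains 3k - 7 shape degrees of
freedom: 3 for translation, 3 for rotation and 1 for scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError
from .landmark_io import LandmarkConfiguration, StudyDataset

#: shape degrees of freedom lost to similarity alignment in 3D
SIMILARITY_DOF_3D = 7


def _as_coords(config) -> np.ndarray:
    if isinstance(config, LandmarkConfiguration):
        return config.coords
    return np.asarray(config, dtype=float)


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark-to-centroid distances.

    Translation- and rotation-invariant; scales linearly with the
    configuration. Units follow the coordinates (mm in this package).
    """
    coords = _as_coords(config)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs <= 0 or not np.isfinite(cs):
        raise DegenerateConfigurationError("all landmarks coincident: centroid size is zero")
    return cs


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (3x3) minimizing ||A - B @ R||_F.

    Both configurations must be centered. Reflections are forbidden: the
    determinant is forced to +1 by flipping the sign of the smallest
    singular direction, which is also the deterministic tie-break when
    the cross-covariance is rank deficient.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    H = B.T @ A
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    if d == 0:  # fully degenerate cross-covariance; fall back to +1
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def align_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale both configurations to unit CS, rotate b onto a.

    Returns the two aligned k x 3 matrices (a first).
    """
    A = _as_coords(a)
    B = _as_coords(b)
    A = (A - A.mean(axis=0)) / centroid_size(A)
    B = (B - B.mean(axis=0)) / centroid_size(B)
    R = optimal_rotation(A, B)
    return A, B @ R


def procrustes_distance(a, b) -> float:
    """Partial Procrustes distance between two configurations.

    The root summed squared difference between the two unit-centroid-size
    configurations after optimal translation and rotation. Zero iff the
    shapes are identical up to a similarity transform; symmetric.
    """
    A, B = align_pair(a, b)
    return float(np.sqrt(np.sum((A - B) ** 2)))


@dataclass
class ProcrustesFit:
    """Result of a Generalized Procrustes Analysis.

    ``aligned`` holds the n x k x 3 superimposed configurations, each
    centered and at unit centroid size; ``consensus`` is the unit-CS mean
    shape; ``centroid_sizes`` retains the original sizes in mm;
    ``tangent_coords`` are the n x 3k orthogonal tangent-space projections.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    tangent_coords: np.ndarray
    iterations: int
    converged: bool
    specimen_ids: list[str] | None = None
    residual_history: list[float] | None = None

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    @property
    def shape_dim(self) -> int:
        """Number of shape variables: 3k - 7."""
        return 3 * self.n_landmarks - SIMILARITY_DOF_3D


def gpa(
    dataset,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Generalized Procrustes Analysis of a sample of configurations.

    Each configuration is centered and scaled to unit centroid size, then
    iteratively rotated to the running consensus (the mean of the aligned
    configurations, re-centered and rescaled to unit CS) until the
    root-mean-square change in the consensus drops below ``tol`` or
    ``max_iter`` iterations are reached. The first specimen seeds the
    reference; the converged result does not depend on that choice beyond
    a global rotation, and aligned coordinates are invariant (to ~1e-8)
    under arbitrary similarity transforms applied to the inputs.
    """
    if isinstance(dataset, StudyDataset):
        coords = dataset.coords_array()
        ids = dataset.specimen_ids
    else:
        coords = np.asarray(dataset, dtype=float)
        ids = None
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ValueError("gpa requires at least 2 configurations of shape k x 3")

    n = coords.shape[0]
    sizes = np.array([centroid_size(coords[i]) for i in range(n)])
    X = coords - coords.mean(axis=1, keepdims=True)
    X /= sizes[:, None, None]

    consensus = X[0].copy()
    iterations = 0
    converged = False
    residual_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(consensus, X[i])
        new_consensus = X.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= centroid_size(new_consensus)
        residual_history.append(float(np.sum((X - new_consensus) ** 2)))
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"GPA did not converge in {max_iter} iterations; returning partial result",
            RuntimeWarning,
            stacklevel=2,
        )

    # canonical orientation: principal axes of the consensus with a
    # deterministic sign convention, so the result does not depend on the
    # original orientation of the first specimen
    R = _principal_axes(consensus)
    X = X @ R
    consensus = consensus @ R

    fit = ProcrustesFit(
        aligned=X,
        consensus=consensus,
        centroid_sizes=sizes,
        tangent_coords=np.empty((n, 0)),
        iterations=iterations,
        converged=converged,
        specimen_ids=ids,
        residual_history=residual_history,
    )
    fit.tangent_coords = tangent_coordinates(fit)
    return fit


def _principal_axes(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation onto the consensus principal axes (deterministic signs).

    Axis directions are disambiguated by the third moments of the shape
    along its own principal axes (a frame-independent criterion): the two
    axes with the largest |skewness| point toward positive skewness and
    the third sign is set by det = +1.
    """
    cov = consensus.T @ consensus
    _, vecs = np.linalg.eigh(cov)
    V = vecs[:, ::-1]  # descending variance
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    rotated = consensus @ V
    m = np.sum(rotated**3, axis=0)
    signs = np.ones(3)
    order = np.argsort(-np.abs(m))
    for j in order[:2]:
        signs[j] = 1.0 if m[j] >= 0 else -1.0
    signs[order[2]] = signs[order[0]] * signs[order[1]]  # keep det = +1
    return V * signs


def tangent_coordinates(fit: ProcrustesFit) -> np.ndarray:
    """Orthogonal projection of aligned shapes onto the tangent space.

    The tangent space is taken at the consensus: each flattened aligned
    configuration x is mapped to x - (x . c) c where c is the flattened
    unit-norm consensus, so the consensus itself maps to the origin and
    every tangent vector is orthogonal to c. Euclidean distances between
    rows closely approximate Procrustes distances for small shape
    variation, and the row space has rank at most 3k - 7.
    """
    n, k, _ = fit.aligned.shape
    c = fit.consensus.ravel()
    c = c / np.linalg.norm(c)
    X = fit.aligned.reshape(n, 3 * k)
    return X - np.outer(X @ c, c)
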