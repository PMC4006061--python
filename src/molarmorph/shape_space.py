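"""Shape space construction: tangent-space PCA, dimensionality selection
by the distance-correlation criterion, group mean shapes, and 3D
thin-plate-spline warps between mean shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateConfigurationError
from .procrustes import ProcrustesFit, procrustes_distance

_EIG_RTOL = 1e-8  # eigenvalues below this fraction of the largest count as zero


@dataclass
class ShapeSpace:
    """Principal components of tangent-space shape coordinates.

    ``eigenvectors`` has one unit row per component (d x 3k),
    ``eigenvalues`` are the component variances in descending order,
    ``scores`` the centered n x d specimen projections, and
    ``percent_variance`` each component's share of total variance.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    scores: np.ndarray
    percent_variance: np.ndarray
    mean: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nonzero(self) -> int:
        """Components with eigenvalue above the relative tolerance."""
        if self.eigenvalues[0] <= 0:
            return 0
        return int(np.sum(self.eigenvalues > _EIG_RTOL * self.eigenvalues[0]))


def shape_pca(fit_or_coords) -> ShapeSpace:
    """Covariance-based PCA of tangent coordinates.

    Accepts a :class:`~molarmorph.procrustes.ProcrustesFit` (its tangent
    coordinates are used) or an n x q coordinate matrix. Reconstruction
    from all components reproduces the input to numerical precision.
    """
    if isinstance(fit_or_coords, ProcrustesFit):
        X = fit_or_coords.tangent_coords
    else:
        X = np.asarray(fit_or_coords, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA requires at least 3 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign convention: largest-magnitude loading positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    percent = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapeSpace(
        eigenvectors=Vt,
        eigenvalues=eigenvalues,
        scores=U * s,
        percent_variance=percent,
        mean=mean,
    )


@dataclass
class DistanceCorrelationProfile:
    """Correlation r(m) between m-PC Euclidean distances and full
    Procrustes distances, for m = 1..d."""

    r_values: np.ndarray

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values, dtype=float)

    def __len__(self) -> int:
        return len(self.r_values)

    def r(self, m: int) -> float:
        return float(self.r_values[m - 1])


def distance_correlation_profile(
    fit: ProcrustesFit, space: ShapeSpace
) -> DistanceCorrelationProfile:
    """Pearson correlation between reduced-space and full shape distances.

    The reference distances are full pairwise Procrustes distances between
    the aligned configurations (each pair re-superimposed); the reduced
    distances are Euclidean distances on the first m PC scores. r at the
    full dimension equals 1 because tangent-space distances are Euclidean.
    """
    n = fit.n_specimens
    if n < 3:
        raise ValueError("need at least 3 specimens for a distance correlation")
    ref = np.array(
        [
            procrustes_distance(fit.aligned[i], fit.aligned[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    d = space.n_components
    sq = np.zeros(len(ref))
    r_values = np.empty(d)
    for m in range(d):
        sq = sq + pdist(space.scores[:, m : m + 1]) ** 2
        r_values[m] = np.corrcoef(np.sqrt(sq), ref)[0, 1]
    return DistanceCorrelationProfile(r_values)


def select_dimensionality(
    profile: DistanceCorrelationProfile,
    threshold: float = 0.98,
    plateau_window: int = 5,
    plateau_increase: float = 0.005,
) -> tuple[int, int]:
    """Smallest m with r(m) >= threshold, plus a plateau diagnostic.

    Returns ``(m_star, m_plateau)`` where ``m_plateau`` is the first m
    after which the largest r increase over the next ``plateau_window``
    components falls below ``plateau_increase``.
    """
    r = profile.r_values
    hits = np.nonzero(r >= threshold)[0]
    if len(hits) == 0:
        raise ValueError(
            f"threshold {threshold} exceeds max r = {r.max():.6f}; "
            f"use the full dimension ({len(r)})"
        )
    m_star = int(hits[0]) + 1
    d = len(r)
    m_plateau = d
    for m in range(1, d + 1):
        upcoming = r[m : min(m + plateau_window, d)]
        base = np.concatenate(([r[m - 1]], upcoming[:-1])) if len(upcoming) else np.array([])
        if len(upcoming) == 0 or np.max(upcoming - base) < plateau_increase:
            m_plateau = m
            break
    return m_star, m_plateau


def group_mean_shapes(fit: ProcrustesFit, labels, groups=None) -> dict[str, np.ndarray]:
    """Per-group arithmetic mean of the aligned configurations (k x 3)."""
    labels = np.asarray(labels)
    if groups is None:
        groups = list(dict.fromkeys(labels.tolist()))
    means: dict[str, np.ndarray] = {}
    for g in groups:
        rows = labels == g
        if not np.any(rows):
            raise ValueError(f"group {g!r} has no specimens")
        means[g] = fit.aligned[rows].mean(axis=0)
    return means


def mean_shape_pca(mean_shapes: dict[str, np.ndarray]) -> ShapeSpace:
    """PCA of the (small) matrix of group mean shapes.

    With g groups at most g - 1 components are nonzero. Scores order
    follows the dict insertion order of ``mean_shapes``.
    """
    if len(mean_shapes) < 3:
        raise ValueError("mean-shape PCA needs at least 3 group means")
    M = np.stack([m.ravel() for m in mean_shapes.values()])
    return shape_pca(M)


# ---------------------------------------------------------------------------
# thin-plate splines


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # 3D biharmonic fundamental solution: U(r) = r
    return r


@dataclass
class TpsWarpField:
    """3D thin-plate-spline interpolant mapping reference onto target.

    The warp f(x) = A [1, x] + sum_i w_i U(|x - p_i|) interpolates every
    reference landmark p_i exactly onto its target. ``bending_energy`` is
    the (non-negative) quadratic form of the kernel weights; it is zero
    exactly when the target is an affine image of the reference.
    """

    reference: np.ndarray
    target: np.ndarray
    affine: np.ndarray  # 3 x 4, row-form: f_affine(x) = affine @ [1, x, y, z]
    weights: np.ndarray  # k x 3 kernel weights
    bending_energy: float
    grid: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the warp at m x 3 query points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts[:, None, :] - self.reference[None, :, :], axis=2)
        ones = np.column_stack([np.ones(len(pts)), pts])
        return ones @ self.affine.T + _tps_kernel(r) @ self.weights


def _section_grid(reference: np.ndarray, n_cells: int, margin: float) -> dict[str, np.ndarray]:
    """Three axis-aligned planes through the reference centroid."""
    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    pad = margin * (hi - lo)
    lo, hi = lo - pad, hi + pad
    center = reference.mean(axis=0)
    axes = {"xy": (0, 1, 2), "xz": (0, 2, 1), "yz": (1, 2, 0)}
    planes = {}
    for name, (a, b, fixed) in axes.items():
        u = np.linspace(lo[a], hi[a], n_cells + 1)
        v = np.linspace(lo[b], hi[b], n_cells + 1)
        uu, vv = np.meshgrid(u, v)
        pts = np.zeros((uu.size, 3))
        pts[:, a] = uu.ravel()
        pts[:, b] = vv.ravel()
        pts[:, fixed] = center[fixed]
        planes[name] = pts
    return planes


def tps_warp(
    reference: np.ndarray,
    target: np.ndarray,
    grid_spec: dict | None = None,
) -> TpsWarpField:
    """Thin-plate-spline warp from ``reference`` onto ``target`` landmarks.

    Solves the bordered interpolation system with the 3D kernel U(r) = r
    and evaluates the warp on three orthogonal planes through the
    reference centroid (``grid_spec`` keys: ``n_cells`` per side, default
    20, and ``margin`` as a fraction of the bounding box, default 0.1).
    """
    P = np.asarray(reference, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("reference and target must be matching k x 3 arrays")
    k = P.shape[0]
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-10) < 3:
        raise DegenerateConfigurationError("reference landmarks are coplanar or degenerate")

    r = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=2)
    K = _tps_kernel(r)
    Pmat = np.column_stack([np.ones(k), P])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = Pmat
    L[k:, :k] = Pmat.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = Q
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateConfigurationError(
            "singular TPS system (coincident reference landmarks?)"
        ) from exc
    W = sol[:k]
    A = sol[k:].T  # 3 x 4
    # U(r) = r is conditionally negative definite under sum-to-zero
    # constraints, so -tr(W' K W) >= 0 and vanishes iff W = 0 (affine map)
    energy = float(max(-np.trace(W.T @ K @ W), 0.0))

    spec = {"n_cells": 20, "margin": 0.1}
    if grid_spec:
        spec.update(grid_spec)
    field_obj = TpsWarpField(
        reference=P, target=Q, affine=A, weights=W, bending_energy=energy
    )
    residual = np.max(np.abs(field_obj.transform(P) - Q))
    if residual > 1e-8 * max(1.0, np.max(np.abs(Q))):
        raise DegenerateConfigurationError(
            f"TPS system nearly singular: landmark residual {residual:.2e}"
        )
    for name, pts in _section_grid(P, spec["n_cells"], spec["margin"]).items():
        field_obj.grid[name] = {"points": pts, "warped": field_obj.transform(pts)}
    return field_obj
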