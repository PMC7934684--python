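"""Ordination of combined shape matrices and shape modelling.

PCA is computed on column-mean-centered data via singular value
decomposition, without column scaling (all coordinates share units, as is
standard for Procrustes shape data).  The sign of each component is fixed
deterministically (largest-magnitude loading made positive) so ordinations
reproduce bit-for-bit.  ``reverse_pca`` reconstructs shape coordinates from
score values — e.g. the modelled extreme shapes at the observed score range
— and :func:`tps_grid` renders the thin-plate-spline deformation between a
reference and a target configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .staging import CombinedMatrix

__all__ = ["pca", "reverse_pca", "mean_shape", "tps_grid", "Morphospace", "DeformationGrid"]


@dataclass
class Morphospace:
    """A PCA basis over a combined shape matrix."""

    mean_vector: np.ndarray
    eigenvectors: np.ndarray  # (p, k) orthonormal columns
    eigenvalues: np.ndarray  # non-increasing
    variance_proportions: np.ndarray
    scores: np.ndarray  # (n, k)
    kind: str = "developmental"
    rows: object = None  # row descriptors (DataFrame) when built from a CombinedMatrix

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def score_range(self, component: int) -> tuple[float, float]:
        col = self.scores[:, component]
        return float(col.min()), float(col.max())


def pca(matrix: CombinedMatrix | np.ndarray, kind: str | None = None) -> Morphospace:
    """Column-mean-centered PCA via SVD with a deterministic sign convention.

    All min(n-1, p) components are retained, so reconstruction from the full
    score vector is exact and the variance proportions sum to one.
    """
    if isinstance(matrix, CombinedMatrix):
        X = matrix.values
        rows = matrix.rows
        kind = kind or matrix.layout
    else:
        X = np.asarray(matrix, float)
        rows = None
        kind = kind or "generic"
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2D matrix with at least two rows")
    mean = X.mean(axis=0)
    centered = X - mean
    total_var = float((centered**2).sum()) / (X.shape[0] - 1)
    if total_var == 0.0:
        raise ValueError("no variance: all rows identical")
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest-magnitude loading of each PC positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    eigenvalues = S**2 / (X.shape[0] - 1)
    return Morphospace(
        mean_vector=mean,
        eigenvectors=Vt.T,
        eigenvalues=eigenvalues,
        variance_proportions=eigenvalues / eigenvalues.sum(),
        scores=U * S,
        kind=kind,
        rows=rows,
    )


def reverse_pca(
    morphospace: Morphospace,
    pc_scores: dict[int, float] | np.ndarray,
    as_points: bool = True,
) -> np.ndarray:
    """Reconstruct (artificial) shape coordinates from PC scores.

    ``pc_scores`` maps 0-based component indices to score values (missing
    components are treated as zero), or gives a full score vector.  With
    ``as_points`` the flat vector is reshaped to (k, 2) landmark geometry.
    """
    v = np.zeros(morphospace.n_components)
    if isinstance(pc_scores, dict):
        for comp, score in pc_scores.items():
            if not 0 <= comp < morphospace.n_components:
                raise IndexError(f"unknown PC index {comp}")
            v[comp] = score
    else:
        arr = np.asarray(pc_scores, float)
        v[: arr.size] = arr
    flat = morphospace.mean_vector + morphospace.eigenvectors @ v
    if as_points and flat.size % 2 == 0:
        return flat.reshape(-1, 2)
    return flat


def mean_shape(shapes: np.ndarray) -> np.ndarray:
    """Coordinate-wise average of aligned shapes, renormalized to unit CS."""
    stack = np.asarray(shapes, float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] == 0:
        raise ValueError("empty selection")
    avg = stack.mean(axis=0)
    avg = avg - avg.mean(axis=0)
    norm = np.sqrt((avg**2).sum())
    if norm == 0:
        raise ValueError("degenerate mean shape")
    return avg / norm


@dataclass
class DeformationGrid:
    """A thin-plate-spline warp of a rectangular grid, reference -> target."""

    reference: np.ndarray
    target: np.ndarray
    grid: np.ndarray  # (rows, cols, 2) unwarped grid points
    warped: np.ndarray  # (rows, cols, 2) warped grid points
    bending_energy: float


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 * np.log(r2)
    return np.where(r2 > 0, out, 0.0)


def _tps_solve(reference: np.ndarray, target: np.ndarray, regularized: bool = False):
    k = reference.shape[0]
    d2 = ((reference[:, None] - reference[None]) ** 2).sum(-1)
    K = _tps_kernel(d2)
    P = np.hstack([np.ones((k, 1)), reference])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    if regularized:
        # minimum-norm solve tolerates a collinear (rank-deficient) reference
        coeffs, *_ = np.linalg.lstsq(L, rhs, rcond=None)
    else:
        coeffs = np.linalg.solve(L, rhs)
    W, A = coeffs[:k], coeffs[k:]
    bending = float(np.trace(W.T @ K @ W))
    return W, A, max(bending, 0.0)


def _tps_apply(points: np.ndarray, reference: np.ndarray, W: np.ndarray, A: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None] - reference[None]) ** 2).sum(-1)
    U = _tps_kernel(d2)
    return A[0] + points @ A[1:] + U @ W


def tps_grid(
    reference: np.ndarray,
    target: np.ndarray,
    resolution: int = 24,
    margin: float = 0.1,
) -> DeformationGrid:
    """Thin-plate-spline deformation grid interpolating reference -> target.

    Solves the 2D TPS with kernel U(r) = r^2 log r^2 so that every
    reference landmark maps exactly onto its target, then warps a
    ``resolution`` x ``resolution`` grid covering the reference bounding box
    with a fractional ``margin``.  Affine reference->target maps have zero
    bending energy.  A singular system (collinear reference) falls back to a
    slightly regularized solve with a warning.
    """
    import warnings

    reference = np.asarray(reference, float)
    target = np.asarray(target, float)
    if reference.shape != target.shape:
        raise ValueError("reference and target must have equal landmark counts")
    try:
        W, A, bending = _tps_solve(reference, target)
        if not np.all(np.isfinite(W)):
            raise np.linalg.LinAlgError("non-finite TPS weights")
    except np.linalg.LinAlgError:
        warnings.warn("singular TPS system; using regularized solve", RuntimeWarning)
        W, A, bending = _tps_solve(reference, target, regularized=True)

    lo = reference.min(axis=0)
    hi = reference.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - margin * span
    hi = hi + margin * span
    xs = np.linspace(lo[0], hi[0], resolution)
    ys = np.linspace(lo[1], hi[1], resolution)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.stack([gx, gy], axis=-1)
    warped = _tps_apply(grid.reshape(-1, 2), reference, W, A).reshape(grid.shape)
    return DeformationGrid(reference, target, grid, warped, bending)
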