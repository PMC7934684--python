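"""Procrustes superimposition for half-whorl landmark configurations.

Each whorl stage is treated as its own structure, so generalized Procrustes
analysis (GPA) runs separately per stage.  The alignment removes position,
scale and orientation; semilandmarks are additionally slid along their flank
curves to the positions minimizing Procrustes distance to the consensus, and
object symmetry can be enforced by averaging every configuration with its
reflected-and-relabelled copy.

Reflections are never applied during alignment: left/right homology of the
mirrored even whorls is handled explicitly upstream
(:func:`conchmorph.landmark_io.mirror_even_whorls`), and allowing reflection
here would silently mask labelling errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import DEFAULT_SCHEME, LandmarkConfiguration, LandmarkScheme

__all__ = [
    "centroid_size",
    "opa_align",
    "gpa",
    "slide_semilandmarks",
    "symmetrize",
    "AlignedStageSet",
    "SlidingSpec",
]


def centroid_size(points: np.ndarray | LandmarkConfiguration) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the centroid.

    Computed on the raw configuration, in its original units; this is the
    standard geometric-morphometric size proxy.
    """
    pts = points.points if isinstance(points, LandmarkConfiguration) else np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return cs


def _center_unit(pts: np.ndarray) -> np.ndarray:
    centered = pts - pts.mean(axis=0)
    return centered / centroid_size(pts)


def _optimal_rotation(target: np.ndarray, reference: np.ndarray,
                      allow_reflection: bool = False) -> np.ndarray:
    """2x2 orthogonal matrix R minimizing ||target @ R.T - reference||_F."""
    M = reference.T @ target  # 2x2 cross-product matrix
    if allow_reflection:
        U, _, Vt = np.linalg.svd(M)
        return U @ Vt
    # closed form for the proper rotation in 2D
    a = M[0, 0] + M[1, 1]
    b = M[0, 1] - M[1, 0]
    h = np.hypot(a, b)
    if h == 0.0:
        return np.eye(2)
    c, s = a / h, -b / h
    return np.array([[c, -s], [s, c]])


def opa_align(
    target: np.ndarray,
    reference: np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes alignment of *target* onto *reference*.

    Both configurations are centered and scaled to unit centroid size; the
    target is then rotated (reflected too, only if allowed) to minimize the
    summed squared distance to the reference.  Returns the aligned target
    and the minimized root-sum-of-squares (partial Procrustes) distance.
    """
    target = np.asarray(target, float)
    reference = np.asarray(reference, float)
    if target.shape != reference.shape:
        raise ValueError(
            f"dimension mismatch: target {target.shape} vs reference {reference.shape}"
        )
    t = _center_unit(target)
    r = _center_unit(reference)
    R = _optimal_rotation(t, r, allow_reflection)
    aligned = t @ R.T
    return aligned, float(np.sqrt(((aligned - r) ** 2).sum()))


@dataclass(frozen=True)
class SlidingSpec:
    """Semilandmark sliding specification (Procrustes-distance criterion)."""

    curves: tuple[tuple[int, ...], ...]
    sliding_ids: tuple[int, ...]
    mode: str = "procrustes_distance"

    def __post_init__(self) -> None:
        for sid in self.sliding_ids:
            hosts = [c for c in self.curves if sid in c]
            if len(hosts) != 1:
                raise ValueError(f"sliding id {sid} must be on exactly one curve")
            k = hosts[0].index(sid)
            if k == 0 or k == len(hosts[0]) - 1:
                raise ValueError(f"sliding id {sid} lacks a curve neighbour")

    @classmethod
    def from_scheme(cls, scheme: LandmarkScheme) -> "SlidingSpec":
        return cls(curves=scheme.curves, sliding_ids=scheme.sliding_ids)

    def neighbours(self, sliding_id: int) -> tuple[int, int]:
        for c in self.curves:
            if sliding_id in c:
                k = c.index(sliding_id)
                return c[k - 1], c[k + 1]
        raise KeyError(sliding_id)


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closest point to p on segment [a, b] (vectorized over leading axes)."""
    ab = b - a
    denom = (ab**2).sum(axis=-1, keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    t = ((p - a) * ab).sum(axis=-1, keepdims=True) / denom
    t = np.clip(t, 0.0, 1.0)
    return a + t * ab


def slide_semilandmarks(
    aligned: np.ndarray,
    consensus: np.ndarray,
    sliding_spec: SlidingSpec,
) -> np.ndarray:
    """Slide semilandmarks towards the consensus along their flank curves.

    For each sliding landmark, the candidate positions are the two polyline
    segments joining it to its curve neighbours (at their current, pre-slide
    positions); the landmark moves to the candidate closest to its consensus
    homologue.  Because the current position is itself a candidate, sliding
    can never increase the squared distance to the consensus.  Fixed
    landmarks never move.

    ``aligned`` may be a single configuration (k, 2) or a stack (n, k, 2).
    """
    single = aligned.ndim == 2
    X = aligned[None] if single else aligned
    out = X.copy()
    for sid in sliding_spec.sliding_ids:
        prev_id, next_id = sliding_spec.neighbours(sid)
        p = X[:, sid - 1]
        a = X[:, prev_id - 1]
        b = X[:, next_id - 1]
        c = consensus[sid - 1]
        cand1 = _project_to_segment(c, a, p)
        cand2 = _project_to_segment(c, p, b)
        d1 = ((cand1 - c) ** 2).sum(axis=-1)
        d2 = ((cand2 - c) ** 2).sum(axis=-1)
        out[:, sid - 1] = np.where((d1 <= d2)[:, None], cand1, cand2)
    return out[0] if single else out


def _reflection_about_axis(a: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Householder map for reflection across the line through a along unit d."""
    H = 2.0 * np.outer(d, d) - np.eye(2)
    return H, a - a @ H.T


def symmetrize(
    points: np.ndarray,
    pairs: tuple[tuple[int, int], ...] = DEFAULT_SCHEME.pairs,
    midline_ids: tuple[int, int] = DEFAULT_SCHEME.midline_ids,
    axis_tol: float = 1e-12,
) -> np.ndarray:
    """Object-symmetry average of a configuration and its mirrored copy.

    The configuration is reflected about the axial line through the two
    midline landmarks, paired landmarks are relabelled, and the original and
    mirrored copies are averaged.  The output is exactly bilaterally
    symmetric about that line, and the operation is idempotent.
    """
    pts = np.asarray(points, float)
    m1, m2 = midline_ids
    a, b = pts[m1 - 1], pts[m2 - 1]
    d = b - a
    norm = np.hypot(*d)
    scale = max(np.ptp(pts[:, 0]), np.ptp(pts[:, 1]), 1.0)
    if norm < axis_tol * scale:
        raise ValueError("axis undefined: midline landmarks coincide")
    H, _ = _reflection_about_axis(a, d / norm)
    reflected = (pts - a) @ H.T + a
    perm = np.arange(pts.shape[0])
    for i, j in pairs:
        perm[i - 1], perm[j - 1] = j - 1, i - 1
    return 0.5 * (pts + reflected[perm])


@dataclass
class AlignedStageSet:
    """GPA output for one whorl stage."""

    stage: float
    mean_shape: np.ndarray
    aligned: np.ndarray  # (n, k, 2) Procrustes shape coordinates
    centroid_sizes: np.ndarray  # pre-alignment CS, original units
    specimen_ids: list[str] = field(default_factory=list)
    iterations: int = 0
    converged: bool = True
    ssq_history: list[float] = field(default_factory=list)


def _canonical_rotation(consensus: np.ndarray, midline_ids: tuple[int, int]) -> np.ndarray:
    """Rotation sending the consensus axial direction to +y (deterministic frame)."""
    m1, m2 = midline_ids
    d = consensus[m2 - 1] - consensus[m1 - 1]
    norm = np.hypot(*d)
    if norm == 0:
        return np.eye(2)
    c, s = d / norm  # rotate (c, s) onto (0, 1)
    return np.array([[s, -c], [c, s]])


def gpa(
    configurations: list[LandmarkConfiguration] | np.ndarray,
    sliding_spec: SlidingSpec | None = None,
    symmetry: bool = False,
    scheme: LandmarkScheme = DEFAULT_SCHEME,
    stage: float | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedStageSet:
    """Generalized Procrustes analysis of one whorl stage.

    Iterates: align every configuration to the consensus, slide
    semilandmarks (optional), symmetrize (optional), recompute the
    consensus, until the consensus root-mean-square change falls below
    ``tol``.  The final frame is canonical: the consensus axial line points
    +y, making results independent of input order and orientation.
    """
    if isinstance(configurations, np.ndarray):
        stack = np.asarray(configurations, float)
        specimen_ids = [str(i) for i in range(stack.shape[0])]
        the_stage = stage if stage is not None else 0.5
    else:
        if len(configurations) < 2:
            raise ValueError("GPA needs at least two configurations")
        stack = np.stack([c.points for c in configurations])
        specimen_ids = [c.specimen_id for c in configurations]
        stages = {round(c.stage, 6) for c in configurations}
        if len(stages) > 1:
            raise ValueError(f"mixed stages in one GPA: {sorted(stages)}")
        the_stage = configurations[0].stage

    n = stack.shape[0]
    centered = stack - stack.mean(axis=1, keepdims=True)
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    if not (sizes > 0).all():
        raise ValueError("degenerate configuration: all landmarks coincide")
    X = centered / sizes[:, None, None]

    perm = scheme.pair_permutation if symmetry else None
    m1, m2 = scheme.midline_ids
    # order- and orientation-independent start: orient every configuration
    # by its own axial line, then average
    for i in range(n):
        Q = _canonical_rotation(X[i], scheme.midline_ids)
        X[i] = X[i] @ Q.T
    # the original (unslid) geometry defines each specimen's sliding curves;
    # it rotates rigidly with the configuration but never deforms, so the
    # sliding problem has a fixed domain and the iteration can converge
    curves = X.copy()
    consensus = _center_unit(X.mean(axis=0))
    converged = False
    iterations = 0
    ssq_history: list[float] = []
    for iterations in range(1, max_iter + 1):
        # batch 2D rotations onto the consensus (closed form)
        M = np.einsum("ka,nkb->nab", consensus, X)
        a = M[:, 0, 0] + M[:, 1, 1]
        b = M[:, 1, 0] - M[:, 0, 1]
        h = np.hypot(a, b)
        h = np.where(h == 0, 1.0, h)
        c, s = a / h, b / h
        R = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)
        X = np.einsum("nkb,nab->nka", X, R)
        curves = np.einsum("nkb,nab->nka", curves, R)
        if sliding_spec is not None:
            X = slide_semilandmarks(curves, consensus, sliding_spec)
        if symmetry:
            origin = X[:, m1 - 1][:, None]
            d = X[:, m2 - 1] - X[:, m1 - 1]
            norm = np.sqrt((d**2).sum(-1, keepdims=True))
            if (norm == 0).any():
                raise ValueError("axis undefined: midline landmarks coincide")
            d = d / norm
            H = 2.0 * d[:, :, None] * d[:, None, :] - np.eye(2)
            reflected = np.einsum("nkb,nab->nka", X - origin, H) + origin
            X = 0.5 * (X + reflected[:, perm])
        if sliding_spec is not None or symmetry:
            # renormalize after sliding/symmetrizing
            X -= X.mean(axis=1, keepdims=True)
            X /= np.sqrt((X**2).sum(axis=(1, 2), keepdims=True))
        new_consensus = _center_unit(X.mean(axis=0))
        Q = _canonical_rotation(new_consensus, scheme.midline_ids)
        new_consensus = new_consensus @ Q.T
        X = X @ Q.T
        curves = curves @ Q.T
        ssq_history.append(procrustes_sum_of_squares(X, new_consensus))
        change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
        consensus = new_consensus
        if change < tol:
            converged = True
            break

    return AlignedStageSet(
        stage=the_stage,
        mean_shape=consensus,
        aligned=X,
        centroid_sizes=sizes,
        specimen_ids=specimen_ids,
        iterations=iterations,
        converged=converged,
        ssq_history=ssq_history,
    )


def procrustes_sum_of_squares(aligned: np.ndarray, consensus: np.ndarray) -> float:
    """Summed squared deviations of aligned shapes from the consensus."""
    return float(((aligned - consensus[None]) ** 2).sum())
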