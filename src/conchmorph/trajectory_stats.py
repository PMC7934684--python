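"""Phenotypic trajectory analysis with residual-randomization inference.

The developmental shape matrix (non-weighted Procrustes coordinates only —
weighting would inject an artificial size-shape signal into the test) is
modelled as ``Shape ~ Species * Stage``.  The least-squares means of the
full factorial model define one ontogenetic trajectory per species: an
ordered sequence of stage means in shape space.  Three pairwise statistics
compare trajectories:

* **path distance** difference — |length(t1) - length(t2)|, the magnitude
  of ontogenetic shape change;
* **trajectory shape** distance — Procrustes distance between the two
  trajectories treated as point configurations (size and orientation
  removed);
* **trajectory angle** — angle in degrees between the first principal
  directions of the two trajectories, folded to [0, 90] (direction of
  change, irrespective of stage order).

Significance comes from residual randomization in a permutation procedure
(RRPP): rows of the reduced-model (``Species + Stage``) residuals are
permuted, added back to the reduced-model fitted values, the full model is
refit, and the statistics recomputed; p = (#{null >= observed} + 1) /
(iterations + 1), one-sided (large statistic = more different).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .staging import CombinedMatrix

__all__ = [
    "fit_trajectory_model",
    "path_distance",
    "trajectory_shape_distance",
    "trajectory_angle",
    "trajectory_analysis",
    "manova_pillai",
    "TrajectoryModel",
    "TrajectoryTestResult",
]


@dataclass
class TrajectoryModel:
    """OLS fits of the full (Species * Stage) and reduced (Species + Stage) models."""

    response: np.ndarray  # (n, p)
    species: np.ndarray  # (n,) labels
    stage: np.ndarray  # (n,) ordered numeric levels
    species_levels: list
    stage_levels: list
    cell_index: np.ndarray  # (n,) row -> species*stage cell
    cell_counts: np.ndarray  # (g*k,)
    reduced_fitted: np.ndarray
    reduced_residuals: np.ndarray
    full_fitted: np.ndarray
    full_residuals: np.ndarray
    full_design: np.ndarray
    reduced_design: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_levels)

    @property
    def n_stages(self) -> int:
        return len(self.stage_levels)

    def ls_means(self, response: np.ndarray | None = None) -> np.ndarray:
        """Least-squares (cell) means, shaped (g, k, p)."""
        Y = self.response if response is None else response
        g, k = self.n_species, self.n_stages
        sums = np.zeros((g * k, Y.shape[1]))
        np.add.at(sums, self.cell_index, Y)
        means = sums / self.cell_counts[:, None]
        return means.reshape(g, k, -1)

    def trajectories(self) -> dict:
        means = self.ls_means()
        return {sp: means[i] for i, sp in enumerate(self.species_levels)}


def fit_trajectory_model(
    dev_matrix: CombinedMatrix | np.ndarray,
    species=None,
    stage=None,
) -> TrajectoryModel:
    """Fit ``Shape ~ Species * Stage`` by ordinary least squares.

    The full model uses cell-mean coding, so its least-squares means are the
    species-by-stage cell means and fitted + residual reproduces the
    response exactly.  Every cell must be non-empty.
    """
    if isinstance(dev_matrix, CombinedMatrix):
        Y = dev_matrix.values
        species = dev_matrix.rows["species"].to_numpy()
        stage = dev_matrix.rows["stage"].to_numpy()
    else:
        Y = np.asarray(dev_matrix, float)
        species = np.asarray(species)
        stage = np.asarray(stage)
    if Y.ndim == 1:
        Y = Y[:, None]
    species_levels = sorted(pd.unique(species).tolist())
    stage_levels = sorted(pd.unique(stage).tolist())
    g, k = len(species_levels), len(stage_levels)
    sp_idx = np.array([species_levels.index(s) for s in species])
    st_idx = np.array([stage_levels.index(s) for s in stage])
    cell_index = sp_idx * k + st_idx
    cell_counts = np.bincount(cell_index, minlength=g * k)
    if (cell_counts == 0).any():
        empty = int(np.argmin(cell_counts))
        raise ValueError(
            f"empty design cell: species {species_levels[empty // k]!r} "
            f"at stage {stage_levels[empty % k]!r}"
        )
    n = Y.shape[0]
    full_design = np.zeros((n, g * k))
    full_design[np.arange(n), cell_index] = 1.0

    # full-model fit: cell-mean coding makes LS means the cell means
    sums = np.zeros((g * k, Y.shape[1]))
    np.add.at(sums, cell_index, Y)
    cell_means = sums / cell_counts[:, None]
    full_fitted = cell_means[cell_index]
    full_residuals = Y - full_fitted

    # reduced model: intercept + species + stage main effects (drop-first coding)
    reduced_design = np.ones((n, 1 + (g - 1) + (k - 1)))
    for j in range(1, g):
        reduced_design[:, j] = (sp_idx == j).astype(float)
    for j in range(1, k):
        reduced_design[:, g - 1 + j] = (st_idx == j).astype(float)
    coef, *_ = np.linalg.lstsq(reduced_design, Y, rcond=None)
    reduced_fitted = reduced_design @ coef
    reduced_residuals = Y - reduced_fitted

    return TrajectoryModel(
        response=Y,
        species=np.asarray(species),
        stage=np.asarray(stage),
        species_levels=species_levels,
        stage_levels=stage_levels,
        cell_index=cell_index,
        cell_counts=cell_counts,
        reduced_fitted=reduced_fitted,
        reduced_residuals=reduced_residuals,
        full_fitted=full_fitted,
        full_residuals=full_residuals,
        full_design=full_design,
        reduced_design=reduced_design,
    )


def path_distance(trajectory: np.ndarray) -> float:
    """Summed Euclidean lengths of consecutive steps along a trajectory."""
    t = np.asarray(trajectory, float)
    if t.shape[0] < 2:
        raise ValueError("a trajectory needs at least two points")
    return float(np.sqrt(((np.diff(t, axis=0)) ** 2).sum(axis=1)).sum())


def _centered_unit(trajectory: np.ndarray) -> np.ndarray:
    t = np.asarray(trajectory, float)
    t = t - t.mean(axis=0)
    norm = np.sqrt((t**2).sum())
    if norm == 0:
        raise ValueError("degenerate trajectory: all points equal")
    return t / norm


def trajectory_shape_distance(t1: np.ndarray, t2: np.ndarray) -> float:
    """Procrustes distance between two trajectories as point configurations.

    Each trajectory's k points are centered and scaled to unit size, then
    optimally rotated (full orthogonal group of the ambient shape space);
    the root summed squared difference of the superimposed point sets is
    returned.  Symmetric in its arguments.
    """
    a = _centered_unit(t1)
    b = _centered_unit(t2)
    if a.shape != b.shape:
        raise ValueError("trajectories must have the same number of points")
    s = np.linalg.svd(b.T @ a, compute_uv=False)
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * s.sum())))


def _principal_direction(trajectory: np.ndarray) -> np.ndarray:
    t = np.asarray(trajectory, float)
    t = t - t.mean(axis=0)
    if not (t**2).sum() > 0:
        raise ValueError("zero-extent trajectory")
    _, _, Vt = np.linalg.svd(t, full_matrices=False)
    return Vt[0]


def trajectory_angle(t1: np.ndarray, t2: np.ndarray) -> float:
    """Angle (degrees, folded to [0, 90]) between first principal directions.

    Principal directions are axes, not vectors, so the statistic is
    invariant to reversing a trajectory's stage order.
    """
    u = _principal_direction(t1)
    v = _principal_direction(t2)
    c = min(1.0, abs(float(u @ v)))
    return float(np.degrees(np.arccos(c)))


@dataclass
class TrajectoryTestResult:
    """Pairwise trajectory statistics with RRPP permutation p-values."""

    species: list
    path_distances: pd.Series
    magnitude_diff: pd.DataFrame
    magnitude_p: pd.DataFrame
    shape_dist: pd.DataFrame
    shape_p: pd.DataFrame
    angle_deg: pd.DataFrame
    angle_p: pd.DataFrame
    iterations: int
    seed: int | None

    def significant_pairs(self, which: str = "magnitude", alpha: float = 0.05) -> int:
        p = {"magnitude": self.magnitude_p, "shape": self.shape_p, "angle": self.angle_p}[which]
        vals = p.values[np.triu_indices(len(self.species), k=1)]
        return int((vals <= alpha).sum())


def _pair_statistics(
    trajs: np.ndarray, do_shape: bool = True, do_angle: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """(path, |dPD|, shape distance, angle) for all species pairs.

    ``trajs``: (g, k, p) stage means.  Returns the per-species path vector
    and three condensed upper-triangle pair vectors (None when skipped).
    """
    g = trajs.shape[0]
    steps = np.diff(trajs, axis=1)
    paths = np.sqrt((steps**2).sum(axis=2)).sum(axis=1)

    iu, ju = np.triu_indices(g, k=1)
    mag = np.abs(paths[iu] - paths[ju])

    shape_d = angles = None
    if do_shape or do_angle:
        centered = trajs - trajs.mean(axis=1, keepdims=True)
        if do_shape:
            norms = np.sqrt((centered**2).sum(axis=(1, 2), keepdims=True))
            norms = np.where(norms == 0, 1.0, norms)
            unit = centered / norms
            cross = np.einsum("akp,akq->apq", unit[ju], unit[iu])  # b^T a per pair
            sv = np.linalg.svd(cross, compute_uv=False)
            shape_d = np.sqrt(np.maximum(0.0, 2.0 - 2.0 * sv.sum(axis=1)))
        if do_angle:
            Vt = np.linalg.svd(centered, full_matrices=False)[2]
            pdirs = Vt[:, 0, :]
            cosang = np.clip(np.abs((pdirs[iu] * pdirs[ju]).sum(axis=1)), 0.0, 1.0)
            angles = np.degrees(np.arccos(cosang))
    return paths, mag, shape_d, angles


def trajectory_analysis(
    model: TrajectoryModel,
    iterations: int = 999,
    seed: int | None = None,
    statistics: tuple[str, ...] = ("magnitude", "shape", "angle"),
) -> TrajectoryTestResult:
    """Pairwise trajectory comparison with RRPP permutation p-values.

    Null datasets are built by permuting reduced-model residual rows and
    adding them to the reduced-model fitted values, which preserves the
    species and stage main effects exactly while destroying the interaction
    that trajectories measure.  ``statistics`` selects which of the three
    statistics to test (skipped ones get p = 1 tables).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    g = model.n_species
    do_shape = "shape" in statistics
    do_angle = "angle" in statistics
    obs_paths, obs_mag, obs_shape, obs_angle = _pair_statistics(model.ls_means())
    if obs_shape is None:
        obs_shape = np.zeros_like(obs_mag)
    if obs_angle is None:
        obs_angle = np.zeros_like(obs_mag)

    n = model.response.shape[0]
    # dense cell-mean operator: means = D @ Y
    D = (model.full_design / model.cell_counts[None, :]).T
    k = model.n_stages
    ge_mag = np.zeros_like(obs_mag)
    ge_shape = np.zeros_like(obs_mag)
    ge_angle = np.zeros_like(obs_mag)
    for _ in range(iterations):
        perm = rng.permutation(n)
        y_null = model.reduced_fitted + model.reduced_residuals[perm]
        trajs = (D @ y_null).reshape(g, k, -1)
        _, mag, shp, ang = _pair_statistics(trajs, do_shape, do_angle)
        ge_mag += mag >= obs_mag
        if do_shape:
            ge_shape += shp >= obs_shape
        if do_angle:
            ge_angle += ang >= obs_angle
    if not do_shape:
        ge_shape[:] = iterations
    if not do_angle:
        ge_angle[:] = iterations

    def pvals(ge: np.ndarray) -> np.ndarray:
        return (ge + 1.0) / (iterations + 1.0)

    def square(vec: np.ndarray) -> pd.DataFrame:
        M = np.zeros((g, g))
        iu, ju = np.triu_indices(g, k=1)
        M[iu, ju] = vec
        M[ju, iu] = vec
        return pd.DataFrame(M, index=model.species_levels, columns=model.species_levels)

    def square_p(vec: np.ndarray) -> pd.DataFrame:
        M = np.ones((g, g))
        iu, ju = np.triu_indices(g, k=1)
        M[iu, ju] = vec
        M[ju, iu] = vec
        np.fill_diagonal(M, 1.0)
        return pd.DataFrame(M, index=model.species_levels, columns=model.species_levels)

    return TrajectoryTestResult(
        species=model.species_levels,
        path_distances=pd.Series(obs_paths, index=model.species_levels, name="path_distance"),
        magnitude_diff=square(obs_mag),
        magnitude_p=square_p(pvals(ge_mag)),
        shape_dist=square(obs_shape),
        shape_p=square_p(pvals(ge_shape)),
        angle_deg=square(obs_angle),
        angle_p=square_p(pvals(ge_angle)),
        iterations=iterations,
        seed=seed,
    )


def manova_pillai(scores: np.ndarray, groups) -> dict:
    """One-way MANOVA with Pillai's trace on (PC-reduced) scores.

    V = tr[(H + E)^-1 H] from the between-group (H) and within-group (E)
    sums-of-squares-and-cross-products matrices, with the standard F
    approximation.  The response dimensionality must leave E invertible;
    callers with wide data should pass PCA scores truncated to at most
    n - g components.
    """
    X = np.asarray(scores, float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    gnum = len(levels)
    n, p = X.shape
    if n < gnum:
        raise ValueError("need at least as many rows as groups")
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lv in levels:
        sub = X[groups == lv]
        m = sub.mean(axis=0)
        d = (m - grand)[:, None]
        H += sub.shape[0] * (d @ d.T)
        resid = sub - m
        E += resid.T @ resid
    T = H + E
    try:
        V = float(np.trace(np.linalg.solve(T, H)))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular H+E: reduce dimensionality (e.g. PCA scores with at "
            "most n - g components) before the MANOVA"
        ) from exc
    s = min(p, gnum - 1)
    m_par = (abs(p - gnum + 1) - 1) / 2.0
    n_par = (n - gnum - p - 1) / 2.0
    df1 = s * (2 * m_par + s + 1)
    df2 = s * (2 * n_par + s + 1)
    if df2 <= 0 or V >= s:
        F = np.inf if V >= s else np.nan
        pval = np.nan
    else:
        F = (df2 / df1) * (V / (s - V))
        pval = float(sps.f.sf(F, df1, df2))
    return {
        "pillai": V,
        "F": float(F),
        "df1": float(df1),
        "df2": float(df2),
        "p": pval,
        "n_groups": int(gnum),
        "n_obs": int(n),
        "n_vars": int(p),
    }
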