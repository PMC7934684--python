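"""End-to-end workflow: read -> mirror -> per-whorl GPA -> morphospaces -> tests.

The pipeline is a fixed sequence; every step is also available on its own
through the library modules.  All stochastic steps (only the permutation
test) take the configured seed, so a rerun with the same config produces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .landmark_io import mirror_even_whorls, read_tps
from .morphospace import Morphospace, pca
from .scheme import STAGES, LandmarkDataset
from .staging import (
    CombinedMatrix,
    assemble_developmental_space,
    assemble_trajectory_space,
    centroid_size_table,
    stage_weights,
)
from .superimposition import AlignedStageSet, SlidingSpec, gpa
from .trajectory_stats import (
    TrajectoryTestResult,
    fit_trajectory_model,
    manova_pillai,
    trajectory_analysis,
)

__all__ = ["RunConfig", "run_pipeline", "align_all_stages", "PipelineResult"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    tps_path: str | None = None
    metadata_path: str | None = None
    sliding: bool = True
    symmetry: bool = True
    mirror_even: bool = True
    permutation_iterations: int = 999
    seed: int = 0
    output_dir: str | None = None
    manova_max_components: int | None = None  # default: n - g
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    aligned_sets: dict[float, AlignedStageSet]
    trajectory_space: Morphospace
    developmental_space: Morphospace
    weighted_developmental_space: Morphospace
    trajectory_matrix: CombinedMatrix
    developmental_matrix: CombinedMatrix
    weighted_developmental_matrix: CombinedMatrix
    trajectory_test: TrajectoryTestResult
    manova: dict
    config: RunConfig
    manifest: dict = field(default_factory=dict)


def align_all_stages(
    dataset: LandmarkDataset,
    sliding: bool = True,
    symmetry: bool = True,
) -> dict[float, AlignedStageSet]:
    """Run GPA separately for every whorl stage (whorls are distinct structures)."""
    spec = SlidingSpec.from_scheme(dataset.scheme) if sliding else None
    return {
        stage: gpa(
            dataset.configurations_at(stage),
            sliding_spec=spec,
            symmetry=symmetry,
            scheme=dataset.scheme,
        )
        for stage in STAGES
    }


def run_pipeline(
    config: RunConfig,
    dataset: LandmarkDataset | None = None,
) -> PipelineResult:
    """Execute the full workflow and (optionally) write its artifacts.

    Pass either a pre-built ``dataset`` (e.g. from the synthetic generator)
    or TPS + metadata paths in the config.
    """
    if dataset is None:
        if config.tps_path is None:
            raise ValueError("run_pipeline needs a dataset or a tps_path")
        dataset = read_tps(config.tps_path, config.metadata_path)

    if config.mirror_even:
        dataset = mirror_even_whorls(dataset)

    aligned = align_all_stages(dataset, sliding=config.sliding, symmetry=config.symmetry)

    species_of = dict(zip(dataset.specimen_ids, dataset.species_labels))
    cs_table = centroid_size_table(aligned)
    w_flat = stage_weights(cs_table, "non_weighted")
    w_log = stage_weights(cs_table, "weighted")

    traj_matrix = assemble_trajectory_space(aligned, w_flat, species_of)
    dev_matrix = assemble_developmental_space(aligned, w_flat, species_of)
    wdev_matrix = assemble_developmental_space(aligned, w_log, species_of)

    traj_space = pca(traj_matrix, kind="trajectory_space")
    dev_space = pca(dev_matrix, kind="developmental")
    wdev_space = pca(wdev_matrix, kind="weighted_developmental")

    # trajectory analysis on the non-weighted developmental matrix only
    model = fit_trajectory_model(dev_matrix)
    test = trajectory_analysis(
        model, iterations=config.permutation_iterations, seed=config.seed
    )

    # MANOVA on trajectory-space PC scores, truncated so E stays invertible
    n, g = traj_matrix.n_rows, len(set(species_of.values()))
    limit = config.manova_max_components or max(1, n - g)
    k = min(limit, traj_space.n_components)
    manova = manova_pillai(traj_space.scores[:, :k], traj_matrix.rows["species"].to_numpy())

    result = PipelineResult(
        aligned_sets=aligned,
        trajectory_space=traj_space,
        developmental_space=dev_space,
        weighted_developmental_space=wdev_space,
        trajectory_matrix=traj_matrix,
        developmental_matrix=dev_matrix,
        weighted_developmental_matrix=wdev_matrix,
        trajectory_test=test,
        manova=manova,
        config=config,
    )
    if config.output_dir:
        _write_artifacts(result, Path(config.output_dir))
    return result


def _variance_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for name, space in [
        ("trajectory_space", result.trajectory_space),
        ("developmental", result.developmental_space),
        ("weighted_developmental", result.weighted_developmental_space),
    ]:
        props = space.variance_proportions
        rows.append(
            {
                "morphospace": name,
                "pc1": props[0],
                "pc2": props[1] if props.size > 1 else 0.0,
                "pc3": props[2] if props.size > 2 else 0.0,
                "total": props.sum(),
            }
        )
    return pd.DataFrame(rows)


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def save_csv(frame: pd.DataFrame, name: str, index: bool = False) -> None:
        path = outdir / name
        frame.to_csv(path, index=index, float_format="%.10g")
        written[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    for name, space in [
        ("scores_trajectory_space.csv", result.trajectory_space),
        ("scores_developmental.csv", result.developmental_space),
        ("scores_weighted_developmental.csv", result.weighted_developmental_space),
    ]:
        scores = pd.DataFrame(
            space.scores, columns=[f"PC{i + 1}" for i in range(space.n_components)]
        )
        if space.rows is not None:
            scores = pd.concat([space.rows.reset_index(drop=True), scores], axis=1)
        save_csv(scores, name)

    save_csv(_variance_table(result), "variance_proportions.csv")

    test = result.trajectory_test
    save_csv(test.path_distances.to_frame(), "path_distances.csv", index=True)
    save_csv(test.magnitude_diff, "pairwise_magnitude.csv", index=True)
    save_csv(test.magnitude_p, "pairwise_magnitude_p.csv", index=True)
    save_csv(test.shape_dist, "pairwise_shape.csv", index=True)
    save_csv(test.shape_p, "pairwise_shape_p.csv", index=True)
    save_csv(test.angle_deg, "pairwise_angle.csv", index=True)
    save_csv(test.angle_p, "pairwise_angle_p.csv", index=True)

    (outdir / "manova.json").write_text(json.dumps(result.manova, indent=2) + "\n")
    written["manova.json"] = hashlib.sha256((outdir / "manova.json").read_bytes()).hexdigest()

    if result.config.make_plots:
        _write_plots(result, outdir, written)

    cfg = {k: v for k, v in vars(result.config).items()}
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": result.config.seed,
        "files": written,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    result.manifest = manifest


def _write_plots(result: PipelineResult, outdir: Path, written: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, space in [
        ("trajectory_space", result.trajectory_space),
        ("developmental", result.developmental_space),
        ("weighted_developmental", result.weighted_developmental_space),
    ]:
        fig, ax = plt.subplots(figsize=(7, 6))
        rows = space.rows
        species = rows["species"].to_numpy() if rows is not None else None
        sizes = (
            10 + 8 * rows["stage"].to_numpy()
            if rows is not None and "stage" in rows
            else 25
        )
        if species is not None:
            for sp in sorted(set(species)):
                mask = species == sp
                pts = space.scores[mask][:, :2]
                ax.scatter(pts[:, 0], pts[:, 1], s=np.atleast_1d(sizes)[mask] if np.ndim(sizes) else sizes, label=sp, alpha=0.7)
                if mask.sum() >= 3:
                    try:
                        from scipy.spatial import ConvexHull

                        hull = ConvexHull(pts)
                        cycle = np.append(hull.vertices, hull.vertices[0])
                        ax.plot(pts[cycle, 0], pts[cycle, 1], lw=0.7, alpha=0.4)
                    except Exception:
                        pass
            ax.legend(fontsize=6, ncol=2)
        else:
            ax.scatter(space.scores[:, 0], space.scores[:, 1], s=20)
        v = space.variance_proportions
        ax.set_xlabel(f"PC1 ({100 * v[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * v[1]:.1f}%)")
        ax.set_title(name.replace("_", " "))
        fname = f"morphospace_{name}.svg"
        fig.savefig(outdir / fname)
        plt.close(fig)
        written[fname] = hashlib.sha256((outdir / fname).read_bytes()).hexdigest()
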