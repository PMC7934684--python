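"""Combine per-stage Procrustes shapes into analysis matrices.

After the per-whorl GPA every stage lives in its own unit-centroid-size
shape space.  Three combination schemes are supported:

``non_weighted``
    every stage kept at unit centroid size (equal weight);
``weighted``
    each stage block scaled by the specimen's proportional log10 centroid
    size, w_s = log10(CS_s) / sum_t log10(CS_t), re-introducing the
    allometric size signal without altering the shapes themselves;
``size_shape``
    the non-weighted matrix augmented by a log10(CS) column (relative-warp
    style size-shape space).

Two matrix layouts exist: the *trajectory space* (one row per specimen, all
11 stage blocks concatenated: 352 columns for 16 2D landmarks) and the
*developmental space* (one row per specimen-stage, 32 columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .scheme import N_LANDMARKS, STAGES
from .superimposition import AlignedStageSet

__all__ = [
    "stage_weights",
    "assemble_trajectory_space",
    "assemble_developmental_space",
    "size_shape_augment",
    "StageWeights",
    "CombinedMatrix",
]

Scheme = Literal["non_weighted", "weighted", "size_shape"]


class UnitDependenceError(ValueError):
    """Centroid sizes <= 1 make log10 weights non-positive; rescale the units."""


@dataclass
class StageWeights:
    """Per specimen-stage scale factors under one combination scheme."""

    scheme: Scheme
    weights: pd.DataFrame  # specimens x stages
    centroid_sizes: pd.DataFrame  # specimens x stages, original units

    def weight(self, specimen_id: str, stage: float) -> float:
        return float(self.weights.loc[specimen_id, stage])


@dataclass
class CombinedMatrix:
    """A combined shape matrix plus its row descriptors and weighting."""

    values: np.ndarray
    rows: pd.DataFrame  # specimen_id, species (+ stage for developmental layout)
    weighting: StageWeights
    layout: Literal["trajectory", "developmental"]
    column_labels: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.column_labels or None)
        return pd.concat([self.rows.reset_index(drop=True), frame], axis=1)


def centroid_size_table(aligned_sets: dict[float, AlignedStageSet]) -> pd.DataFrame:
    """Specimens x stages table of pre-alignment centroid sizes."""
    stages = sorted(aligned_sets)
    first = aligned_sets[stages[0]]
    table = pd.DataFrame(
        index=pd.Index(first.specimen_ids, name="specimen_id"),
        columns=stages,
        dtype=float,
    )
    for stage in stages:
        aset = aligned_sets[stage]
        table.loc[aset.specimen_ids, stage] = aset.centroid_sizes
    return table


def stage_weights(cs_table: pd.DataFrame, scheme: Scheme = "non_weighted") -> StageWeights:
    """Per-specimen-stage scale factors for combining aligned stages.

    The weighted scheme uses each specimen's own centroid-size profile:
    w_s = log10(CS_s) / sum over the specimen's stages of log10(CS_t), so
    weights sum to one within every specimen.  It requires all CS > 1 in
    the working unit (mm here) — otherwise log10 would be non-positive and
    the weights meaningless, which is reported as an error rather than
    silently fixed.
    """
    cs = cs_table.astype(float)
    if (cs.values <= 0).any():
        raise ValueError("centroid sizes must be positive")
    if scheme == "non_weighted":
        w = pd.DataFrame(1.0, index=cs.index, columns=cs.columns)
    elif scheme == "weighted":
        if (cs.values <= 1.0).any():
            raise UnitDependenceError(
                "weighted scheme needs all centroid sizes > 1 in the working "
                "unit; rescale the coordinates (e.g. to mm) before weighting"
            )
        logs = np.log10(cs.values)
        w = pd.DataFrame(
            logs / logs.sum(axis=1, keepdims=True), index=cs.index, columns=cs.columns
        )
    elif scheme == "size_shape":
        # shapes stay at unit CS; size enters via the augmentation column
        w = pd.DataFrame(1.0, index=cs.index, columns=cs.columns)
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    return StageWeights(scheme=scheme, weights=w, centroid_sizes=cs)


def _ordered_specimens(aligned_sets: dict[float, AlignedStageSet]) -> list[str]:
    stages = sorted(aligned_sets)
    reference = aligned_sets[stages[0]].specimen_ids
    for stage in stages[1:]:
        if set(aligned_sets[stage].specimen_ids) != set(reference):
            missing = set(reference) ^ set(aligned_sets[stage].specimen_ids)
            raise ValueError(
                f"specimens {sorted(missing)} are not present in every stage"
            )
    return list(reference)


def _stage_columns(stage: float) -> list[str]:
    return [
        f"s{stage:.1f}_{axis}{lm}" for lm in range(1, N_LANDMARKS + 1) for axis in ("x", "y")
    ]


def assemble_trajectory_space(
    aligned_sets: dict[float, AlignedStageSet],
    weights: StageWeights,
    species_of: dict[str, str] | None = None,
) -> CombinedMatrix:
    """One row per specimen: all stage blocks concatenated (2*16*11 = 352 cols).

    Each specimen's whole ontogeny becomes a single point, so ordination of
    this matrix places complete ontogenetic trajectories in one space.
    """
    stages = sorted(aligned_sets)
    specimens = _ordered_specimens(aligned_sets)
    blocks = []
    columns: list[str] = []
    for stage in stages:
        aset = aligned_sets[stage]
        order = [aset.specimen_ids.index(s) for s in specimens]
        flat = aset.aligned[order].reshape(len(specimens), -1)
        w = weights.weights.loc[specimens, stage].to_numpy()[:, None]
        blocks.append(flat * w)
        columns.extend(_stage_columns(stage))
    values = np.hstack(blocks)
    rows = pd.DataFrame(
        {
            "specimen_id": specimens,
            "species": [species_of.get(s, "unknown") if species_of else "unknown" for s in specimens],
        }
    )
    return CombinedMatrix(values, rows, weights, "trajectory", columns)


def assemble_developmental_space(
    aligned_sets: dict[float, AlignedStageSet],
    weights: StageWeights,
    species_of: dict[str, str] | None = None,
) -> CombinedMatrix:
    """One row per specimen-stage (n*11 rows, 32 columns).

    Rows carry specimen, species and stage descriptors so each specimen's
    stage points can be reconnected into its ontogenetic trajectory.
    """
    stages = sorted(aligned_sets)
    specimens = _ordered_specimens(aligned_sets)
    rows = []
    values = []
    for specimen in specimens:
        for stage in stages:
            aset = aligned_sets[stage]
            i = aset.specimen_ids.index(specimen)
            w = weights.weight(specimen, stage)
            values.append(aset.aligned[i].ravel() * w)
            rows.append(
                {
                    "specimen_id": specimen,
                    "species": species_of.get(specimen, "unknown") if species_of else "unknown",
                    "stage": stage,
                }
            )
    columns = [f"{axis}{lm}" for lm in range(1, N_LANDMARKS + 1) for axis in ("x", "y")]
    return CombinedMatrix(
        np.asarray(values), pd.DataFrame(rows), weights, "developmental", columns
    )


def size_shape_augment(
    matrix: CombinedMatrix,
    proportional: bool = False,
) -> CombinedMatrix:
    """Append a log10 centroid-size column (relative-warp size-shape space).

    For the developmental layout the row's own stage CS is used; for the
    trajectory layout the specimen's summed CS over stages.  With
    ``proportional`` the column is normalized to sum to one.
    """
    cs = matrix.weighting.centroid_sizes
    if (cs.values <= 0).any():
        raise ValueError("centroid sizes must be positive")
    if matrix.layout == "developmental":
        logcs = np.array(
            [
                np.log10(cs.loc[r.specimen_id, r.stage])
                for r in matrix.rows.itertuples()
            ]
        )
    else:
        logcs = np.array(
            [np.log10(cs.loc[r.specimen_id].sum()) for r in matrix.rows.itertuples()]
        )
    if proportional:
        logcs = logcs / logcs.sum()
    values = np.hstack([matrix.values, logcs[:, None]])
    return CombinedMatrix(
        values,
        matrix.rows.copy(),
        matrix.weighting,
        matrix.layout,
        list(matrix.column_labels) + ["log10_cs"],
    )
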