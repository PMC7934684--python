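"""Landmark scheme and core containers for half-whorl cross-section data.

A planispiral conch cut through the protoconch exposes a sequence of
half-whorl cross sections.  Each half whorl is digitized with 16 landmarks:
two on the symmetry (axial) plane, seven bilateral pairs on the flanks, of
which eight points are sliding semilandmarks constrained to flank curves.
Stages run from 0.5 to 5.5 in half-whorl steps; "odd" half whorls lie on one
side of the protoconch, "even" ones (integer stages) on the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Half-whorl stage grid: 0.5, 1.0, ..., 5.5 (11 stages).
STAGES: tuple[float, ...] = tuple(0.5 * k for k in range(1, 12))

#: Integer stages lie on the far side of the protoconch and appear mirrored.
EVEN_STAGES: tuple[float, ...] = tuple(float(k) for k in range(1, 6))

N_LANDMARKS = 16
N_STAGES = len(STAGES)


def is_valid_stage(stage: float) -> bool:
    """True when *stage* sits on the 0.5-step grid in [0.5, 5.5]."""
    return any(abs(stage - s) < 1e-9 for s in STAGES)


def is_even_stage(stage: float) -> bool:
    return any(abs(stage - s) < 1e-9 for s in EVEN_STAGES)


@dataclass(frozen=True)
class LandmarkScheme:
    """Which landmarks are fixed, sliding, paired and on the midline.

    All landmark indices are 1-based, matching digitizing practice.
    ``curves`` are ordered landmark sequences along which the interior
    semilandmarks slide; every sliding landmark is interior to exactly one
    curve (it has a neighbour on each side).
    """

    n_landmarks: int = N_LANDMARKS
    fixed_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    sliding_ids: tuple[int, ...] = (9, 10, 11, 12, 13, 14, 15, 16)
    pairs: tuple[tuple[int, int], ...] = (
        (3, 4), (5, 6), (7, 8), (9, 10), (11, 12), (13, 14), (15, 16)
    )
    midline_ids: tuple[int, int] = (1, 2)
    curves: tuple[tuple[int, ...], ...] = (
        (3, 9, 11, 5),    # left flank, ventral shoulder -> maximum width
        (5, 13, 15, 7),   # left flank, maximum width -> umbilical seam
        (4, 10, 12, 6),   # right flank, ventral shoulder -> maximum width
        (6, 14, 16, 8),   # right flank, maximum width -> umbilical seam
    )

    def __post_init__(self) -> None:
        ids = set(self.fixed_ids) | set(self.sliding_ids)
        if ids != set(range(1, self.n_landmarks + 1)):
            raise ValueError("fixed and sliding ids must partition 1..n")
        if set(self.fixed_ids) & set(self.sliding_ids):
            raise ValueError("fixed and sliding ids overlap")
        paired = [i for pair in self.pairs for i in pair]
        if len(paired) != len(set(paired)):
            raise ValueError("a landmark appears in more than one pair")
        if set(self.midline_ids) & set(paired):
            raise ValueError("midline landmarks cannot be paired")
        for sid in self.sliding_ids:
            hosts = [c for c in self.curves if sid in c]
            if len(hosts) != 1:
                raise ValueError(f"sliding landmark {sid} must lie on exactly one curve")
            c = hosts[0]
            k = c.index(sid)
            if k == 0 or k == len(c) - 1:
                raise ValueError(f"sliding landmark {sid} has no neighbour on one side")

    @property
    def pair_permutation(self) -> np.ndarray:
        """0-based index permutation that swaps left/right homologues."""
        perm = np.arange(self.n_landmarks)
        for a, b in self.pairs:
            perm[a - 1], perm[b - 1] = b - 1, a - 1
        return perm

    def curve_neighbours(self, sliding_id: int) -> tuple[int, int]:
        """1-based (previous, next) landmark ids along the sliding curve."""
        for c in self.curves:
            if sliding_id in c:
                k = c.index(sliding_id)
                return c[k - 1], c[k + 1]
        raise KeyError(f"landmark {sliding_id} is not on any curve")


DEFAULT_SCHEME = LandmarkScheme()


@dataclass
class LandmarkConfiguration:
    """One half-whorl: 16 labelled 2D points in physical units (mm), y-up."""

    points: np.ndarray
    stage: float
    specimen_id: str

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} 2D points, got array of shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if not is_valid_stage(self.stage):
            raise ValueError(
                f"stage {self.stage} is not on the half-whorl grid 0.5..5.5"
            )

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(self.points.copy(), self.stage, self.specimen_id)


@dataclass
class SpecimenSeries:
    """The full ontogenetic record of one specimen: all 11 half-whorl stages."""

    specimen_id: str
    species: str
    configurations: dict[float, LandmarkConfiguration]

    def __post_init__(self) -> None:
        missing = [s for s in STAGES if s not in self.configurations]
        if missing:
            raise IncompleteSeriesError(self.specimen_id, missing)

    @property
    def n_points(self) -> int:
        return sum(c.points.shape[0] for c in self.configurations.values())

    def stage(self, stage: float) -> LandmarkConfiguration:
        return self.configurations[stage]


class IncompleteSeriesError(ValueError):
    """A specimen is missing one or more half-whorl stages."""

    def __init__(self, specimen_id: str, missing: list[float]):
        self.specimen_id = specimen_id
        self.missing = missing
        super().__init__(
            f"specimen {specimen_id!r} is missing stages {sorted(missing)}"
        )


@dataclass
class LandmarkDataset:
    """A collection of complete specimen series sharing one landmark scheme."""

    scheme: LandmarkScheme
    specimens: list[SpecimenSeries]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    def __len__(self) -> int:
        return len(self.specimens)

    @property
    def specimen_ids(self) -> list[str]:
        return [s.specimen_id for s in self.specimens]

    @property
    def species_labels(self) -> list[str]:
        return [s.species for s in self.specimens]

    def configurations_at(self, stage: float) -> list[LandmarkConfiguration]:
        return [s.stage(stage) for s in self.specimens]
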