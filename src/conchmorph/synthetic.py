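"""Simulated ammonoid whorl-profile ontogenies for end-to-end testing.

The generator emulates the study design the pipeline targets: 12 species
with a handful of specimens each, 16-landmark half-whorl cross sections at
the 11 half-whorl stages 0.5-5.5, shapes progressing from broad, flat and
depressed early whorls to compressed, triangular-ventered adult whorls, and
two heterochronic ontogeny types:

* type **A** (paedomorphic / truncated): the shape-parameter progression
  stops at a truncation stage, so adults retain depressed, juvenile-like
  whorls and the ontogenetic trajectory is short;
* type **B** (peramorphic / accelerated): the progression runs to its
  compressed end state, giving a long trajectory.

Species within a type share the same parameter curves and differ by a
small, stage-constant, bilaterally symmetric shape offset.  A constant
offset translates the whole trajectory in shape space without changing its
length, shape or direction, so within-type pairs are true nulls for the
trajectory statistics while A-vs-B pairs carry a real path-distance signal.

Because the half-outline is built analytically, every downstream quantity
has a closed-form oracle (:func:`reference_statistics`) computed directly
from the parameter curves without running the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import (
    DEFAULT_SCHEME,
    EVEN_STAGES,
    N_LANDMARKS,
    STAGES,
    LandmarkConfiguration,
    LandmarkDataset,
    LandmarkScheme,
    SpecimenSeries,
    is_even_stage,
)
from .superimposition import centroid_size, symmetrize

__all__ = [
    "SpeciesModel",
    "SimulationSpec",
    "whorl_template",
    "simulate_dataset",
    "reference_statistics",
    "default_study_spec",
]


def _logistic(s: float, lo: float, hi: float, mid: float = 3.0, rate: float = 1.2) -> float:
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (s - mid)))


@dataclass(frozen=True)
class SpeciesModel:
    """Parameter curves of one simulated species.

    Shape parameters are evaluated at an effective stage: type A models
    clamp it at ``s_trunc`` (development truncated; size keeps growing),
    type B scale it by the acceleration ``rate`` (> 1 reaches the adult
    end-state earlier).  ``offset_seed`` selects the species' fixed
    symmetric shape offset; magnitude ``offset_scale`` in unit-CS shape
    space.
    """

    label: str
    ontogeny_type: str = "B"  # "A" (truncated) or "B" (accelerated)
    s_trunc: float = 3.0
    rate: float = 1.0
    cs0: float = 1.8  # mm, centroid size at stage 0
    cs_growth: float = 2.0  # CS multiplies by this per whole whorl
    offset_seed: int = 0
    offset_scale: float = 0.015

    def __post_init__(self) -> None:
        if self.ontogeny_type not in ("A", "B"):
            raise ValueError("ontogeny_type must be 'A' or 'B'")
        if self.cs_growth <= 1.0:
            raise ValueError("centroid size must grow strictly with stage")

    def effective_stage(self, s: float) -> float:
        if self.ontogeny_type == "A":
            return min(s, self.s_trunc)
        return 0.5 + (s - 0.5) * self.rate

    def shape_params(self, s: float) -> dict[str, float]:
        """Width, height, venter angularity, umbilical position, overlap at stage s."""
        e = self.effective_stage(s)
        return {
            "w": _logistic(e, 1.80, 0.65),   # whorl width: broad -> narrow
            "h": _logistic(e, 0.45, 1.90),   # whorl height: flat -> high
            "v": _logistic(e, 0.02, 0.95),   # venter angularity: flat -> triangular
            "u": _logistic(e, 0.82, 0.42),   # umbilical seam half-width fraction
            "o": _logistic(e, 0.03, 0.35),   # overlap with preceding whorl
        }

    def cs(self, s: float) -> float:
        """Centroid size (mm) at stage s; strictly increasing."""
        return self.cs0 * self.cs_growth**s

    def shape_offset(self, scheme: LandmarkScheme = DEFAULT_SCHEME) -> np.ndarray:
        """Stage-constant symmetric offset distinguishing this species."""
        rng = np.random.default_rng(self.offset_seed)
        delta = np.zeros((scheme.n_landmarks, 2))
        for mid in scheme.midline_ids:
            delta[mid - 1, 1] = rng.normal()
        for left, right in scheme.pairs:
            dx, dy = rng.normal(size=2)
            delta[left - 1] = (dx, dy)
            delta[right - 1] = (-dx, dy)
        delta -= delta.mean(axis=0)
        norm = np.sqrt((delta**2).sum())
        return delta / norm * self.offset_scale if norm > 0 else delta


def _bezier(a: np.ndarray, c: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    return (1 - t) ** 2 * a + 2 * t * (1 - t) * c + t**2 * b


def _half_outline(params: dict[str, float]) -> np.ndarray:
    """Place the 16 scheme landmarks on a parametric half-whorl outline.

    y-up, midline at x = 0, venter apex on top, umbilical seam near the
    base; the left flank is built and mirrored exactly onto the right.
    """
    w, h, v, u, o = (params[k] for k in "whvuo")
    venter = np.array([0.0, h])                                   # lm 2
    preceding = np.array([0.0, o * h])                            # lm 1
    shoulder = np.array([-(w / 2) * (0.95 - 0.50 * v), h * (0.95 - 0.35 * v)])  # lm 3
    maxwidth = np.array([-w / 2, h * (0.45 - 0.15 * v)])          # lm 5
    umbseam = np.array([-(w / 2) * u, 0.05 * h])                  # lm 7

    # flank control points bulge slightly outward of the chords
    c_upper = 0.5 * (shoulder + maxwidth) + np.array([-0.08 * w, 0.0])
    c_lower = 0.5 * (maxwidth + umbseam) + np.array([-0.06 * w, -0.02 * h])

    pts = np.zeros((N_LANDMARKS, 2))
    pts[0] = preceding
    pts[1] = venter
    pts[2] = shoulder
    pts[4] = maxwidth
    pts[6] = umbseam
    pts[8] = _bezier(shoulder, c_upper, maxwidth, 1 / 3)   # lm 9
    pts[10] = _bezier(shoulder, c_upper, maxwidth, 2 / 3)  # lm 11
    pts[12] = _bezier(maxwidth, c_lower, umbseam, 1 / 3)   # lm 13
    pts[14] = _bezier(maxwidth, c_lower, umbseam, 2 / 3)   # lm 15
    # mirror the left flank onto the right (pairs are (odd left, even right))
    for left, right in DEFAULT_SCHEME.pairs:
        pts[right - 1] = pts[left - 1] * np.array([-1.0, 1.0])
    return pts


def unit_shape(model: SpeciesModel, stage: float,
               scheme: LandmarkScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Centered, unit-centroid-size species shape at one stage."""
    geom = _half_outline(model.shape_params(stage))
    geom = geom - geom.mean(axis=0)
    geom = geom / centroid_size(geom)
    x = geom + model.shape_offset(scheme)
    x = x - x.mean(axis=0)
    return x / centroid_size(x)


def whorl_template(model: SpeciesModel, stage: float,
                   scheme: LandmarkScheme = DEFAULT_SCHEME) -> LandmarkConfiguration:
    """Noise-free template configuration at physical size CS(stage), in mm."""
    pts = unit_shape(model, stage, scheme) * model.cs(stage)
    width = np.ptp(pts[:, 0])
    height = np.ptp(pts[:, 1])
    if width <= 0 or height <= 0:
        raise ValueError("degenerate template geometry")
    return LandmarkConfiguration(pts, stage, f"{model.label}_template")


@dataclass
class SimulationSpec:
    """Study design of one simulated dataset."""

    species_models: list[SpeciesModel]
    n_specimens: int = 6
    noise_sd: float = 0.02  # per-coordinate Gaussian sd, as a fraction of CS(stage)
    seed: int = 0
    scheme: LandmarkScheme = field(default_factory=lambda: DEFAULT_SCHEME)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        labels = [m.label for m in self.species_models]
        if len(labels) != len(set(labels)):
            raise ValueError("species labels must be unique")


def default_study_spec(seed: int = 0, n_specimens: int = 6, noise_sd: float = 0.02) -> SimulationSpec:
    """The default study design: 12 species, 5 truncated (A) / 7 accelerated (B)."""
    models = []
    for i in range(5):
        models.append(
            SpeciesModel(
                label=f"sp_A{i + 1}", ontogeny_type="A", s_trunc=3.0, offset_seed=100 + i
            )
        )
    for i in range(7):
        models.append(
            SpeciesModel(
                label=f"sp_B{i + 1}", ontogeny_type="B", rate=1.15, offset_seed=200 + i
            )
        )
    return SimulationSpec(models, n_specimens=n_specimens, noise_sd=noise_sd, seed=seed)


def simulate_dataset(spec: SimulationSpec) -> LandmarkDataset:
    """Generate a landmark dataset: templates + Gaussian landmark noise.

    Even-stage (integer) configurations are emitted the way whorls on the
    far side of the protoconch appear in digitized cross sections: their
    coordinates are mirrored about the vertical midline and their pairs are
    labelled by image position (left point gets the left label), not by
    homology.  The pipeline's mirroring step — reflect about the axial line
    and swap pair labels — exactly undoes this.  Deterministic under the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    perm = spec.scheme.pair_permutation
    specimens = []
    for model in spec.species_models:
        for j in range(spec.n_specimens):
            specimen_id = f"{model.label}-{j + 1:02d}"
            configs = {}
            for stage in STAGES:
                template = whorl_template(model, stage, spec.scheme).points
                noise = rng.normal(
                    scale=spec.noise_sd * model.cs(stage), size=template.shape
                )
                pts = template + noise
                if is_even_stage(stage):
                    pts = (pts * np.array([-1.0, 1.0]))[perm]
                configs[stage] = LandmarkConfiguration(pts, stage, specimen_id)
            specimens.append(SpecimenSeries(specimen_id, model.label, configs))
    return LandmarkDataset(
        spec.scheme,
        specimens,
        provenance={"generator": "conchmorph.synthetic", "seed": spec.seed},
    )


def reference_statistics(spec: SimulationSpec) -> dict:
    """Closed-form oracles computed from the parameter curves alone.

    Returns per-species true path distances in unit-CS shape space, true
    pairwise path-distance differences, the true angle between the type
    archetype trajectories, per-stage centroid-size profiles, and the type
    labels — without running any part of the alignment pipeline.
    """
    shapes = {
        m.label: np.stack([unit_shape(m, s, spec.scheme) for s in STAGES])
        for m in spec.species_models
    }
    paths = {
        label: float(np.sqrt((np.diff(arr, axis=0) ** 2).sum(axis=(1, 2))).sum())
        for label, arr in shapes.items()
    }
    labels = list(shapes)
    pairwise = {
        (a, b): abs(paths[a] - paths[b])
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    }

    def principal_direction(arr: np.ndarray) -> np.ndarray:
        flat = arr.reshape(arr.shape[0], -1)
        flat = flat - flat.mean(axis=0)
        return np.linalg.svd(flat, full_matrices=False)[2][0]

    types = {m.label: m.ontogeny_type for m in spec.species_models}
    type_angle = None
    a_models = [m for m in spec.species_models if m.ontogeny_type == "A"]
    b_models = [m for m in spec.species_models if m.ontogeny_type == "B"]
    if a_models and b_models:
        ua = principal_direction(shapes[a_models[0].label])
        ub = principal_direction(shapes[b_models[0].label])
        type_angle = float(
            np.degrees(np.arccos(min(1.0, abs(float(ua @ ub)))))
        )
    cs_profiles = {
        m.label: [m.cs(s) for s in STAGES] for m in spec.species_models
    }
    return {
        "path_distances": paths,
        "pairwise_path_diff": pairwise,
        "type_archetype_angle_deg": type_angle,
        "cs_profiles": cs_profiles,
        "ontogeny_types": types,
    }
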