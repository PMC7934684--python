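# Methods

## Landmark scheme and data model

Each half whorl carries 16 landmarks: two on the axial (symmetry) plane —
the venter of the preceding whorl (1) and the venter of the whorl (2) —
and seven bilateral pairs: ventral shoulders (3, 4), maximum width (5, 6),
umbilical seam (7, 8), and eight sliding semilandmarks (9–16) on four flank
curves, two per curve: shoulder → 9, 11 → maximum width and maximum width
→ 13, 15 → umbilical seam on the left flank, mirrored on the right. The
curve assignment of the sliders is a package convention; any scheme with
the same invariants (fixed ∪ sliding = 1..16, every slider interior to
exactly one curve, midline unpaired) can be supplied.

Stages run 0.5–5.5 in half-whorl steps; a specimen is only usable when all
eleven stages are present (176 landmarks), which the loader enforces (an
`--allow-incomplete` escape drops incomplete specimens instead). Integer
("even") stages lie on the far side of the protoconch; their records are
assumed to be digitized in mirrored, position-labelled form and are
reflected about the axial line through landmarks 1–2 with pair labels
swapped before any alignment. TPS files are read in the tpsDig dialect
(`LM=`, coordinate pairs, `ID=<specimen>_<stage>`, optional `SCALE=`,
`IMAGE=`); image rows are flipped to y-up Cartesian mm on read. The ID
encoding is a package convention — digitizers do not standardize one.

## Superimposition

GPA runs separately per whorl stage, since successive whorls are distinct
structures whose sizes differ by orders of magnitude. The iteration:
rotate every configuration onto the consensus (closed-form 2D rotation;
reflections are never allowed — left/right homology is handled explicitly
by the mirroring step, and allowing reflection would mask labelling
errors), slide semilandmarks, symmetrize, renormalize, recompute the
consensus, until the consensus RMS change falls below 1e-10 or 100
iterations. The final frame is canonical (consensus axial line pointing
+y), and initialization orients every configuration by its own axial line
before averaging, so the result is independent of input order and input
orientation to machine precision.

Sliding minimizes each semilandmark's distance to its consensus homologue
*exactly* over the two adjacent segments of the specimen's curve polyline
(closed-form point-to-segment projection). Two consequences: sliding can
never increase the distance to the consensus (the current position is in
the candidate set), and the result matches an exhaustive search along the
polyline to the search grid's resolution. The polyline is taken from the
specimen's *original* geometry, rigidly rotated along with the
configuration but never deformed; re-sliding along an already-slid
polyline lets semilandmarks creep indefinitely and prevents convergence.
Tangent-based sliding (projection on the chord through the neighbours) is
a first-order approximation of this and is not used.

Object symmetry averages each configuration with its
reflected-and-relabelled copy about the axial line through the midline
landmarks; the output is exactly bilaterally symmetric and the operation
is idempotent. On the noisy 12-species study a few late stages
occasionally reach the 100-iteration cap (the sliding step switches
between polyline segments at the 1e-10 tolerance); the result is returned
with `converged=False` and is still deterministic.

## Stage combination and weighting

After per-stage GPA every stage lives at unit centroid size. Combination
schemes:

* `non_weighted` — all stages equal; the only scheme used for trajectory
  statistics (weighting would inject an artificial size–shape signal).
* `weighted` — stage blocks scaled by w_s = log10(CS_s) / Σ_t log10(CS_t),
  computed from each specimen's own centroid-size profile (the proportions
  could also be computed across the stage column; per-specimen keeps rows
  self-contained and is the default). Requires all CS > 1 in the working
  unit (mm for this material); violating that flips log signs and is
  reported as an error, never silently fixed.
* size–shape — the matrix augmented with a log10(CS) column (optionally
  proportional). With CS spanning ≥ 2 orders of magnitude the size column
  dominates PC1, which is the expected relative-warp behaviour.

De-weighting a weighted row (dividing each stage block by w_s) recovers
the unit-size coordinates exactly: weighting never alters shape.

Two layouts: trajectory space (one row per specimen, 2·16·11 = 352
columns) and developmental space (one row per specimen-stage, 32 columns);
a specimen's trajectory-space row is exactly the concatenation of its
developmental rows under the same weighting.

## Ordination and shape modelling

PCA is SVD-based on column-mean-centered data, no column scaling
(coordinates share units). All min(n−1, p) components are kept, so
variance proportions sum to 1 and reconstruction from full scores is
exact. Component signs follow a fixed convention (largest-magnitude
loading positive), making ordinations bit-for-bit reproducible. Reverse
PCA maps any score vector back to landmark coordinates; deformation grids
are classical thin-plate splines (kernel U(r) = r² log r²) interpolating
the reference landmarks exactly, with zero bending energy for affine maps;
a collinear reference falls back to a minimum-norm least-squares solve
with a warning. Default grid: 24 × 24 with a 10 % bounding-box margin.

## Trajectory statistics and inference

`Shape ~ Species * WhorlStage` is fit by OLS with cell-mean coding for the
full model (LS means are then exactly the cell means, and fitted +
residual reproduces the response), and intercept + main-effect dummies for
the reduced model. Statistics on the g trajectories of k = 11 stage means:

* path distance Σ_j ‖m_{j+1} − m_j‖ and pairwise |ΔPD|;
* trajectory shape distance: trajectories centered, scaled to unit size,
  optimally rotated over the full orthogonal group of the ambient space;
* trajectory angle: angle between first principal directions, folded to
  [0°, 90°] (an axis, not a vector: invariant to reversing stage order).
  Start-to-end vectors would be an alternative convention; the principal
  direction is more stable for curved trajectories.

All three are invariant to global rotation and translation of shape space.
RRPP permutes reduced-model residual rows (999 iterations by default,
seeded), one-sided p-values with the +1 convention, so the p floor is
1/(iterations+1). Under a true null the p-values are uniform (verified by
KS over 500 simulated datasets in the test suite).

The MANOVA uses Pillai's trace with the standard F approximation on
trajectory-space PC scores truncated to at most n − g components — with
352 variables and 72 specimens the raw-space error SSCP is singular, so
some reduction convention is unavoidable; the package reports its own
degrees of freedom alongside.

## The synthetic study design

The generator emulates a 12-species, 72-specimen cross-section study:
16-landmark half-whorl templates on a parametric outline (venter apex,
shoulders, maximum-width points, umbilical seam, Bezier-interpolated flank
sliders), exactly bilaterally symmetric, scaled to a strictly increasing
centroid-size curve CS(s) = 1.8 mm · 2^s (2.5 mm at stage 0.5 to 81 mm at
5.5, keeping log10 CS positive for the weighting scheme). Five parameter
curves (width, height, venter angularity, umbilical position, whorl
overlap) follow logistics in stage, from broad/flat/depressed early whorls
to high/compressed/triangular-ventered adults.

Heterochrony enters through an effective stage: type A (5 species) clamps
it at s_trunc = 3.0 (development truncated; size keeps growing), type B
(7 species) scales it by an acceleration rate 1.15. Species within a type
share identical parameter curves and differ only by a small (0.015 in
unit-shape units), stage-constant, symmetric shape offset. A constant
offset translates the whole trajectory without changing its length, shape
or direction, so within-type pairs are true nulls for all three trajectory
statistics while A-vs-B pairs carry a real path-distance signal. The
amplitude of the parameter curves was chosen so that this A/B contrast is
signal-dominated relative to the default landmark noise (isotropic
Gaussian, sd 0.02 × CS(s) per coordinate — a 2 % digitization error):
the pipeline then flags essentially all 35 A-vs-B pairs at α = 0.05 while
within-type pairs stay at or below the nominal rate. Weaker effect sizes
(e.g. the near-overlapping path-distance ranges typical of real ceratitid
material) give correspondingly weaker, more realistic power.

Even-stage templates are emitted mirrored and position-relabelled, exactly
the convention the mirroring step inverts. `reference_statistics` computes
per-species true path distances, pairwise differences, the A/B archetype
angle and CS profiles directly from the parameter curves — no alignment
code — and is the oracle for parameter-recovery tests: on noise-free data
(sliding disabled) the full pipeline reproduces the true path distances to
machine precision. With sliding enabled, semilandmarks legitimately move
toward cross-species consensus correspondence, so slid coordinates
estimate a slightly different (correspondence-optimized) quantity than the
raw templates.

What the generator does *not* emulate: ornamentation (ribs, tubercles,
keels as sculpture), correlated along-outline noise, digitization outliers,
missing or damaged whorls, and intraspecific allometric variation beyond
the isotropic noise. Passing tests therefore demonstrate correctness of
the machinery and recoverability of heterochronic signal under clean
conditions, not performance on degraded real material.

## Problem sizes and numerical conventions

The default test-suite study is 12 species × 6 specimens (72 series, 7,920
landmark configurations). The replicate power study uses 100 simulated
studies with 199 permutation iterations (p floor 0.005); the null
uniformity check uses 500 small two-group datasets at 99 iterations; the
full pipeline with 999 iterations runs in a few seconds. GPA tolerance
1e-10, max 100 iterations; PCA rank cut at min(n−1, p); permutation seeds
always explicit. Ties in the sliding step (equidistant segment candidates)
resolve to the first segment; degenerate inputs (coincident landmarks,
zero-extent trajectories, constant matrices) raise informative errors
rather than returning NaNs.

## Known limitations

* 2D cross sections only; no 3D landmark support.
* Procrustes-distance sliding only (no bending-energy criterion).
* No missing-landmark estimation: incomplete specimens are dropped.
* The MANOVA dimensionality convention (PC scores, n − g cap) is one of
  several defensible choices and affects Pillai's trace magnitude.
* Heterochrony parameters (rate, timing) are simulated, not estimated;
  the package quantifies trajectory differences, not their developmental
  mechanism.
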