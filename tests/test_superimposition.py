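"""Centroid size, ordinary/generalized Procrustes, sliding and symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import conchmorph as cm
from conchmorph.scheme import DEFAULT_SCHEME, LandmarkConfiguration
from conchmorph.superimposition import (
    SlidingSpec,
    centroid_size,
    gpa,
    opa_align,
    slide_semilandmarks,
    symmetrize,
)


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_square_of_unit_half_diagonal(self):
        pts = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        assert centroid_size(pts) == pytest.approx(np.sqrt(8.0))

    @given(scale=st.floats(0.01, 100.0), theta=st.floats(-np.pi, np.pi),
           tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_homogeneous_and_isometry_invariant(self, scale, theta, tx, ty):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(16, 2))
        cs = centroid_size(pts)
        moved = scale * pts @ _rot(theta).T + np.array([tx, ty])
        assert centroid_size(moved) == pytest.approx(scale * cs, rel=1e-9)

    def test_coincident_points_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.ones((16, 2)))


class TestOpaAlign:
    def test_similarity_copy_has_zero_distance(self, rng):
        ref = rng.normal(size=(16, 2))
        copy = 3.1 * ref @ _rot(1.2).T + np.array([5.0, -2.0])
        _, d = opa_align(copy, ref)
        assert d < 1e-12

    def test_chirality_needs_reflection(self, rng):
        ref = rng.normal(size=(16, 2))
        mirror = ref * np.array([-1.0, 1.0])
        _, d_no = opa_align(mirror, ref, allow_reflection=False)
        _, d_yes = opa_align(mirror, ref, allow_reflection=True)
        assert d_no > 1e-3
        assert d_yes < 1e-12

    def test_matches_rotation_grid_search(self, rng):
        x = rng.normal(size=(16, 2))
        y = rng.normal(size=(16, 2))
        _, d = opa_align(x, y)
        xc = x - x.mean(0)
        xc /= np.sqrt((xc**2).sum())
        yc = y - y.mean(0)
        yc /= np.sqrt((yc**2).sum())
        thetas = np.arange(0.0, 2 * np.pi, 1e-4)
        cos, sin = np.cos(thetas), np.sin(thetas)
        # rotate xc by every grid angle at once
        rx = xc[:, 0][:, None] * cos - xc[:, 1][:, None] * sin
        ry = xc[:, 0][:, None] * sin + xc[:, 1][:, None] * cos
        dist = np.sqrt(((rx - yc[:, 0][:, None]) ** 2 + (ry - yc[:, 1][:, None]) ** 2).sum(0))
        assert abs(d - dist.min()) < 1e-6

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            opa_align(np.zeros((15, 2)), np.zeros((16, 2)))


class TestGpa:
    def test_similarity_copies_align_exactly(self, rng):
        base = rng.normal(size=(16, 2))
        a = LandmarkConfiguration(base, 1.5, "a")
        b = LandmarkConfiguration(2.0 * base @ _rot(0.8).T + 3.0, 1.5, "b")
        res = gpa([a, b])
        assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-10
        assert np.abs(res.aligned[0] - res.mean_shape).max() < 1e-10

    def test_aligned_shapes_centered_at_unit_size(self, study_dataset):
        configs = study_dataset.configurations_at(3.5)
        res = gpa(configs, sliding_spec=SlidingSpec.from_scheme(DEFAULT_SCHEME),
                  symmetry=True)
        assert np.abs(res.aligned.mean(axis=1)).max() < 1e-9
        sizes = np.sqrt((res.aligned**2).sum(axis=(1, 2)))
        assert np.abs(sizes - 1.0).max() < 1e-9
        assert abs(np.sqrt((res.mean_shape**2).sum()) - 1.0) < 1e-9

    def test_invariant_to_input_order_and_rotation(self, study_dataset):
        configs = study_dataset.configurations_at(2.5)[:12]
        spec = SlidingSpec.from_scheme(DEFAULT_SCHEME)
        r1 = gpa(configs, sliding_spec=spec, symmetry=True)
        r2 = gpa(configs[::-1], sliding_spec=spec, symmetry=True)
        order = [r2.specimen_ids.index(s) for s in r1.specimen_ids]
        assert np.abs(r1.aligned - r2.aligned[order]).max() < 1e-8
        rotated = [
            LandmarkConfiguration(c.points @ _rot(0.9).T, c.stage, c.specimen_id)
            for c in configs
        ]
        r3 = gpa(rotated, sliding_spec=spec, symmetry=True)
        assert np.abs(r1.aligned - r3.aligned).max() < 1e-8

    def test_recovers_template_from_noisy_whorls(self):
        model = cm.default_study_spec(seed=0).species_models[0]
        stage = 3.0
        template = cm.whorl_template(model, stage).points
        cs = centroid_size(template)
        rng = np.random.default_rng(1)
        configs = [
            LandmarkConfiguration(
                template + rng.normal(scale=0.01 * cs, size=(16, 2)), stage, f"s{i}"
            )
            for i in range(50)
        ]
        res = gpa(configs)
        unit = template - template.mean(0)
        unit /= np.sqrt((unit**2).sum())
        # the consensus averages the noise away (~ sqrt(32)*0.01/sqrt(50))
        d_consensus = float(np.sqrt(((res.mean_shape - unit) ** 2).sum()))
        assert d_consensus < 0.02

    def test_two_config_gpa_reduces_to_opa(self, rng):
        a = rng.normal(size=(16, 2))
        b = rng.normal(size=(16, 2)) * 0.1 + a
        res = gpa(np.stack([a, b]))
        d_gpa = float(np.sqrt(((res.aligned[0] - res.aligned[1]) ** 2).sum()))
        _, d_opa = opa_align(b, a)
        assert d_gpa == pytest.approx(d_opa, abs=1e-6)

    def test_sum_of_squares_monotone_non_increasing(self, study_dataset):
        configs = study_dataset.configurations_at(5.5)
        res = gpa(configs)  # plain GPA: classic monotone convergence
        diffs = np.diff(res.ssq_history)
        assert (diffs <= 1e-12).all()

    def test_noise_free_recovery_is_exact(self):
        spec = cm.default_study_spec(seed=3, n_specimens=3, noise_sd=0.0)
        ds = cm.simulate_dataset(spec)
        ds = cm.mirror_even_whorls(ds)
        model = spec.species_models[0]
        configs = [
            s.stage(2.0) for s in ds.specimens if s.species == model.label
        ]
        res = gpa(configs, symmetry=True)
        unit = cm.whorl_template(model, 2.0).points
        unit = unit - unit.mean(0)
        unit /= np.sqrt((unit**2).sum())
        assert np.sqrt(((res.aligned - unit[None]) ** 2).sum(axis=(1, 2))).max() < 1e-10

    def test_mixed_stages_rejected(self, small_dataset):
        configs = [
            small_dataset.specimens[0].stage(0.5),
            small_dataset.specimens[0].stage(1.5),
        ]
        with pytest.raises(ValueError, match="mixed"):
            gpa(configs)


class TestSliding:
    def test_optimal_position_does_not_move(self):
        spec = SlidingSpec.from_scheme(DEFAULT_SCHEME)
        model = cm.default_study_spec(seed=0).species_models[0]
        pts = cm.whorl_template(model, 2.5).points
        pts = pts - pts.mean(0)
        pts /= np.sqrt((pts**2).sum())
        slid = slide_semilandmarks(pts, pts, spec)  # consensus == configuration
        assert np.abs(slid - pts).max() < 1e-12

    def test_never_increases_distance_to_consensus(self, study_dataset, rng):
        spec = SlidingSpec.from_scheme(DEFAULT_SCHEME)
        res = gpa(study_dataset.configurations_at(2.5), symmetry=False)
        consensus = res.mean_shape + rng.normal(scale=0.01, size=(16, 2))
        before = ((res.aligned - consensus[None]) ** 2).sum()
        slid = slide_semilandmarks(res.aligned, consensus, spec)
        after = ((slid - consensus[None]) ** 2).sum()
        assert after <= before + 1e-12

    def test_matches_exhaustive_polyline_search(self, study_dataset, rng):
        spec = SlidingSpec.from_scheme(DEFAULT_SCHEME)
        res = gpa(study_dataset.configurations_at(2.5))
        X = res.aligned[0]
        consensus = res.mean_shape + rng.normal(scale=0.02, size=(16, 2))
        slid = slide_semilandmarks(X, consensus, spec)
        for sid in spec.sliding_ids:
            prev_id, next_id = spec.neighbours(sid)
            a, p, b = X[prev_id - 1], X[sid - 1], X[next_id - 1]
            ts = np.linspace(0.0, 1.0, 10001)[:, None]
            candidates = np.vstack([a + ts * (p - a), p + ts * (b - p)])
            c = consensus[sid - 1]
            brute = candidates[((candidates - c) ** 2).sum(1).argmin()]
            resolution = max(np.linalg.norm(p - a), np.linalg.norm(b - p)) / 10000
            assert np.linalg.norm(slid[sid - 1] - brute) <= resolution

    def test_fixed_landmarks_never_move(self, study_dataset, rng):
        spec = SlidingSpec.from_scheme(DEFAULT_SCHEME)
        res = gpa(study_dataset.configurations_at(1.5))
        consensus = res.mean_shape + rng.normal(scale=0.05, size=(16, 2))
        slid = slide_semilandmarks(res.aligned, consensus, spec)
        fixed = [i - 1 for i in DEFAULT_SCHEME.fixed_ids]
        assert np.abs(slid[:, fixed] - res.aligned[:, fixed]).max() == 0.0

    def test_interior_requirement_enforced(self):
        with pytest.raises(ValueError, match="neighbour"):
            SlidingSpec(curves=((9, 3, 5),), sliding_ids=(9,))


class TestSymmetrize:
    def test_symmetric_input_unchanged(self):
        model = cm.default_study_spec(seed=0).species_models[0]
        pts = cm.whorl_template(model, 4.0).points
        assert np.allclose(symmetrize(pts), pts, atol=1e-9)

    def test_idempotent(self, study_dataset):
        pts = study_dataset.specimens[0].stage(2.5).points
        once = symmetrize(pts)
        twice = symmetrize(once)
        assert np.allclose(once, twice, atol=1e-10)

    def test_one_sided_perturbation_is_halved(self):
        model = cm.default_study_spec(seed=0).species_models[0]
        pts = cm.whorl_template(model, 3.0).points.copy()
        sym0 = symmetrize(pts)
        eps = np.array([0.003, -0.002])
        bumped = sym0.copy()
        bumped[4] += eps  # left max-width landmark (id 5)
        out = symmetrize(bumped)
        # the asymmetric component of the bump is averaged away by half
        assert np.allclose(out[4], sym0[4] + eps / 2, atol=1e-9)

    def test_output_exactly_bilaterally_symmetric(self, study_dataset):
        pts = symmetrize(study_dataset.specimens[3].stage(3.5).points)
        again = symmetrize(pts)
        assert np.allclose(pts, again, atol=1e-12)
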