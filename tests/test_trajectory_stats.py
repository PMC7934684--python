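"""Factorial shape model, trajectory statistics, RRPP and Pillai MANOVA."""

import numpy as np
import pytest
from scipy.stats import ortho_group

import conchmorph as cm
from conchmorph.trajectory_stats import (
    fit_trajectory_model,
    manova_pillai,
    path_distance,
    trajectory_analysis,
    trajectory_angle,
    trajectory_shape_distance,
)


def _toy_model(rng, g=3, k=4, n_per=3, p=5, effect=0.0):
    species = np.repeat([f"s{i}" for i in range(g)], k * n_per)
    stage = np.tile(np.repeat(np.arange(k, dtype=float), n_per), g)
    Y = rng.normal(size=(g * k * n_per, p))
    Y[:, 0] += stage  # shared ontogenetic drift
    if effect:
        Y[:, 1] += effect * stage * (species == "s0")
    return Y, species, stage


class TestModelFit:
    def test_balanced_ls_means_equal_cell_means(self, rng):
        Y, species, stage = _toy_model(rng)
        model = fit_trajectory_model(Y, species, stage)
        means = model.ls_means()
        for i, sp in enumerate(model.species_levels):
            for j, st in enumerate(model.stage_levels):
                cell = Y[(species == sp) & (stage == st)]
                assert np.allclose(means[i, j], cell.mean(axis=0), atol=1e-12)

    def test_constant_shift_moves_all_ls_means(self, rng):
        Y, species, stage = _toy_model(rng)
        shift = rng.normal(size=Y.shape[1])
        m1 = fit_trajectory_model(Y, species, stage).ls_means()
        m2 = fit_trajectory_model(Y + shift, species, stage).ls_means()
        assert np.allclose(m2 - m1, shift, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        Y, species, stage = _toy_model(rng)
        model = fit_trajectory_model(Y, species, stage)
        assert np.abs(model.full_design.T @ model.full_residuals).max() < 1e-8
        assert np.abs(model.reduced_design.T @ model.reduced_residuals).max() < 1e-8

    def test_fit_plus_residual_reproduces_response(self, rng):
        Y, species, stage = _toy_model(rng)
        model = fit_trajectory_model(Y, species, stage)
        assert np.allclose(model.full_fitted + model.full_residuals, Y, atol=1e-12)
        assert np.allclose(model.reduced_fitted + model.reduced_residuals, Y, atol=1e-10)

    def test_empty_cell_names_the_cell(self, rng):
        Y, species, stage = _toy_model(rng)
        keep = ~((species == "s1") & (stage == 2.0))
        with pytest.raises(ValueError, match="'s1'.*2.0"):
            fit_trajectory_model(Y[keep], species[keep], stage[keep])


class TestPathDistance:
    def test_three_four_five_legs(self):
        assert path_distance(np.array([[0, 0], [3, 0], [3, 4]])) == pytest.approx(7.0)

    def test_single_segment_is_endpoint_distance(self):
        assert path_distance(np.array([[1.0, 1.0], [4.0, 5.0]])) == pytest.approx(5.0)

    def test_rotation_invariant(self, rng):
        t = rng.normal(size=(6, 8))
        Q = ortho_group.rvs(8, random_state=0)
        assert path_distance(t @ Q) == pytest.approx(path_distance(t), rel=1e-12)


class TestTrajectoryShapeDistance:
    def test_similarity_copy_is_zero(self, rng):
        t = rng.normal(size=(5, 4))
        Q = ortho_group.rvs(4, random_state=1)
        copy = 2.5 * t @ Q + rng.normal(size=4)
        assert trajectory_shape_distance(t, copy) < 1e-10

    def test_symmetric(self, rng):
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert trajectory_shape_distance(a, b) == pytest.approx(
            trajectory_shape_distance(b, a), abs=1e-12
        )

    def test_matches_rotation_grid_oracle_in_2d(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        angle = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        d = trajectory_shape_distance(line, angle)

        def unit(t):
            t = t - t.mean(axis=0)
            return t / np.sqrt((t**2).sum())

        a, b = unit(line), unit(angle)
        thetas = np.arange(0.0, 2 * np.pi, 1e-4)
        best = np.inf
        for flip in (1.0, -1.0):  # the orthogonal group includes reflections
            bf = b * np.array([1.0, flip])
            for th in thetas:
                c, s = np.cos(th), np.sin(th)
                R = np.array([[c, -s], [s, c]])
                best = min(best, np.sqrt(((a - bf @ R.T) ** 2).sum()))
        assert d == pytest.approx(best, abs=1e-6)

    def test_degenerate_trajectory_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            trajectory_shape_distance(np.ones((4, 3)), np.random.rand(4, 3))


class TestTrajectoryAngle:
    def test_collinear_is_zero(self):
        t1 = np.outer(np.arange(4.0), [1.0, 2.0])
        t2 = np.outer(np.arange(4.0) * 3, [1.0, 2.0]) + 5.0
        assert trajectory_angle(t1, t2) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_axes_give_ninety_degrees(self):
        t1 = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        t2 = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0]])
        assert trajectory_angle(t1, t2) == pytest.approx(90.0)

    def test_invariant_to_stage_reversal(self, rng):
        a, b = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        assert trajectory_angle(a[::-1], b) == pytest.approx(
            trajectory_angle(a, b), abs=1e-9
        )


class TestStatisticsInvariance:
    def test_all_statistics_invariant_to_global_rotation(self, rng):
        """Rotating/translating the whole shape space changes none of the
        three trajectory statistics."""
        Y, species, stage = _toy_model(rng, effect=1.0)
        Q = ortho_group.rvs(Y.shape[1], random_state=3)
        shift = rng.normal(size=Y.shape[1])
        m1 = fit_trajectory_model(Y, species, stage)
        m2 = fit_trajectory_model(Y @ Q + shift, species, stage)
        t1, t2 = m1.trajectories(), m2.trajectories()
        for sp in t1:
            assert path_distance(t1[sp]) == pytest.approx(path_distance(t2[sp]), rel=1e-9)
        pairs = [("s0", "s1"), ("s0", "s2")]
        for a, b in pairs:
            assert trajectory_shape_distance(t1[a], t1[b]) == pytest.approx(
                trajectory_shape_distance(t2[a], t2[b]), abs=1e-9
            )
            assert trajectory_angle(t1[a], t1[b]) == pytest.approx(
                trajectory_angle(t2[a], t2[b]), abs=1e-6
            )


class TestTrajectoryAnalysis:
    def test_duplicated_species_show_no_differences(self, rng):
        """Two noise-free identical 'species' have zero pairwise statistics
        and p-values of 1 (every permutation ties the observed zero)."""
        k, n_per, p = 4, 2, 3
        base = np.outer(np.arange(k, dtype=float), np.ones(p))
        Y = np.vstack([np.repeat(base, n_per, axis=0)] * 2)
        species = np.repeat(["a", "b"], k * n_per)
        stage = np.tile(np.repeat(np.arange(k, dtype=float), n_per), 2)
        model = fit_trajectory_model(Y, species, stage)
        res = trajectory_analysis(model, iterations=49, seed=0)
        assert res.magnitude_diff.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert res.magnitude_p.loc["a", "b"] == pytest.approx(1.0)

    def test_p_value_floor_is_one_over_iterations_plus_one(self, rng):
        Y, species, stage = _toy_model(rng, effect=10.0)
        model = fit_trajectory_model(Y, species, stage)
        res = trajectory_analysis(model, iterations=99, seed=1)
        pvals = res.magnitude_p.values[np.triu_indices(3, k=1)]
        assert pvals.min() == pytest.approx(1.0 / 100.0)
        assert (pvals >= 1.0 / 100.0).all()

    def test_reproducible_under_seed(self, rng):
        Y, species, stage = _toy_model(rng, effect=2.0)
        model = fit_trajectory_model(Y, species, stage)
        r1 = trajectory_analysis(model, iterations=49, seed=7)
        r2 = trajectory_analysis(model, iterations=49, seed=7)
        assert r1.magnitude_p.equals(r2.magnitude_p)
        assert r1.shape_p.equals(r2.shape_p)

    def test_permutations_preserve_reduced_fit(self, rng):
        """Every null dataset is reduced-model fitted values plus a row
        permutation of the reduced-model residuals — the systematic
        (species + stage) component is carried unchanged into each
        permutation, and the null response is an exact rearrangement of
        the observed residual rows."""
        Y, species, stage = _toy_model(rng)
        model = fit_trajectory_model(Y, species, stage)
        perm = rng.permutation(Y.shape[0])
        y_null = model.reduced_fitted + model.reduced_residuals[perm]
        # the construction leaves the reduced fit untouched ...
        assert np.allclose(y_null - model.reduced_residuals[perm],
                           model.reduced_fitted, atol=1e-12)
        # ... and permutes residual rows without altering them
        assert np.allclose(
            np.sort(y_null - model.reduced_fitted, axis=0),
            np.sort(model.reduced_residuals, axis=0),
            atol=1e-12,
        )

    def test_zero_iterations_rejected(self, rng):
        Y, species, stage = _toy_model(rng)
        model = fit_trajectory_model(Y, species, stage)
        with pytest.raises(ValueError, match="iterations"):
            trajectory_analysis(model, iterations=0)


class TestManovaPillai:
    def test_hand_computed_two_group_toy(self):
        """Groups {(0,0),(1,0)} and {(0,1),(1,1)}: H = [[0,0],[0,1]],
        E = [[1,0],[0,0]], so V = tr[(H+E)^-1 H] = 1 exactly."""
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        groups = np.array(["a", "a", "b", "b"])
        out = manova_pillai(X, groups)
        assert out["pillai"] == pytest.approx(1.0, abs=1e-12)

    def test_identical_group_means_give_zero(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        groups = np.array(["a", "a", "b", "b"])
        assert manova_pillai(X, groups)["pillai"] == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_min_groups_minus_one_and_dims(self, rng):
        X = rng.normal(size=(30, 4))
        groups = np.repeat(["a", "b", "c"], 10)
        out = manova_pillai(X, groups)
        assert 0.0 <= out["pillai"] <= min(2, 4) + 1e-12

    def test_f_approximation_matches_univariate_anova(self, rng):
        """With one response variable Pillai reduces to eta-squared and the
        F approximation to the one-way ANOVA F."""
        from scipy.stats import f_oneway

        a, b, c = rng.normal(size=(3, 12))
        b = b + 1.0
        X = np.concatenate([a, b, c])[:, None]
        groups = np.repeat(["a", "b", "c"], 12)
        out = manova_pillai(X, groups)
        F, p = f_oneway(a, b, c)
        assert out["F"] == pytest.approx(F, rel=1e-9)
        assert out["p"] == pytest.approx(p, rel=1e-9)
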