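"""GGE engine: centering, SVD partitioning, AEC views, which-won-where, Ward."""

import numpy as np
import pandas as pd
import pytest

from metgge import (
    CrossoverSpec,
    DegenerateGeometryError,
    DomainError,
    ENVIRONMENT_FOCUSED,
    GENOTYPE_FOCUSED,
    GGEModel,
    SimulationConfig,
    TraitMatrix,
    aec_frame,
    center_environment,
    environment_metrics,
    fit_gge,
    mean_stability,
    plant_crossover_truth,
    rank_vs_ideal,
    simulate_met,
    to_two_way,
    ward_cluster,
    which_won_where,
)


def _matrix(values, trait="t"):
    values = np.asarray(values, float)
    g, e = values.shape
    return TraitMatrix(values, [f"G{i+1}" for i in range(g)],
                       [f"E{j+1}" for j in range(e)], trait)


def _model_2d(geno, env, labels=None):
    """Hand-built 2-D model for geometry tests."""
    geno, env = np.asarray(geno, float), np.asarray(env, float)
    return GGEModel(
        centered=geno @ env.T,
        singular_values=np.array([1.0, 1.0]),
        genotype_scores=geno,
        environment_scores=env,
        svp_mode=GENOTYPE_FOCUSED,
        variance_explained=np.array([0.5, 0.5]),
        n_axes=2,
        genotype_labels=labels or [f"G{i+1}" for i in range(len(geno))],
        environment_labels=[f"E{j+1}" for j in range(len(env))],
    )


class TestCentering:
    def test_column_constant_matrix_annihilated(self):
        assert np.all(center_environment(_matrix([[3, 5], [3, 5], [3, 5]])) == 0)

    def test_subtracts_column_means(self):
        np.testing.assert_array_equal(
            center_environment(_matrix([[1, 2], [3, 4]])), [[-1, -1], [1, 1]]
        )

    def test_idempotent(self, rng):
        m = rng.normal(size=(5, 4))
        once = center_environment(m)
        np.testing.assert_allclose(center_environment(once), once)


class TestFitGGE:
    def test_rank_one_matrix_explains_everything_on_axis_1(self):
        model = fit_gge(_matrix([[1, 2], [3, 6], [5, 10]]), n_axes=2)
        assert model.variance_explained[0] == pytest.approx(1.0)

    def test_singular_values_of_worked_matrix(self):
        model = fit_gge(_matrix([[1, 2], [3, 4]]))
        np.testing.assert_allclose(model.singular_values, [2.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("mode", [GENOTYPE_FOCUSED, ENVIRONMENT_FOCUSED])
    def test_full_rank_reconstruction(self, rng, mode):
        m = _matrix(rng.normal(size=(5, 4)))
        model = fit_gge(m, svp_mode=mode, n_axes=4)
        recon = model.genotype_scores @ model.environment_scores.T
        np.testing.assert_allclose(recon, model.centered, atol=1e-10)

    def test_variance_explained_invariant_to_svp_mode(self, rng):
        m = _matrix(rng.normal(size=(6, 4)))
        a = fit_gge(m, GENOTYPE_FOCUSED).variance_explained
        b = fit_gge(m, ENVIRONMENT_FOCUSED).variance_explained
        np.testing.assert_allclose(a, b)

    def test_sign_convention_environment_loadings_sum_nonnegative(self, rng):
        model = fit_gge(_matrix(rng.normal(size=(7, 4))), n_axes=4)
        v = model.environment_scores  # genotype-focused: environments get V
        assert np.all(v.sum(axis=0) >= -1e-12)

    def test_axes_out_of_range(self, rng):
        with pytest.raises(DomainError):
            fit_gge(_matrix(rng.normal(size=(5, 4))), n_axes=5)


class TestAECFrame:
    def test_all_environments_on_axis(self):
        model = _model_2d([[0, 0]], [[1, 0], [1, 0]])
        frame = aec_frame(model)
        np.testing.assert_allclose(frame.abscissa, [1, 0])
        np.testing.assert_allclose(frame.ordinate, [0, 1])

    def test_mean_then_normalize(self):
        frame = aec_frame(_model_2d([[0, 0]], [[1, 1], [1, -1]]))
        np.testing.assert_allclose(frame.abscissa, [1, 0], atol=1e-12)
        assert abs(frame.abscissa @ frame.ordinate) < 1e-12

    def test_duplicating_environments_leaves_frame_unchanged(self):
        env = [[2, 1], [1, 2]]
        a = aec_frame(_model_2d([[0, 0]], env))
        b = aec_frame(_model_2d([[0, 0]], env + env))
        np.testing.assert_allclose(a.abscissa, b.abscissa)

    def test_degenerate_average_environment(self):
        with pytest.raises(DegenerateGeometryError):
            aec_frame(_model_2d([[0, 0]], [[1, 0], [-1, 0]]))


class TestMeanStability:
    def test_axis_aligned_projection(self):
        model = _model_2d([[3, 4], [0, 0]], [[1, 0], [1, 0]])
        ms = mean_stability(model, aec_frame(model))
        assert ms.loc["G1", "mean_proxy"] == 3
        assert ms.loc["G1", "stability"] == 4
        assert (ms.loc["G2"] == 0).all()

    def test_no_interaction_means_zero_stability(self):
        cfg = SimulationConfig(g=8, e=4, r=1, var_ge=0, var_err=0, seed=21)
        model = fit_gge(to_two_way(simulate_met(cfg), "trait"), GENOTYPE_FOCUSED)
        ms = mean_stability(model, aec_frame(model))
        np.testing.assert_allclose(ms["stability"], 0, atol=1e-9)


class TestRankVsIdeal:
    def test_best_genotype_has_zero_distance(self):
        model = _model_2d([[4, 0], [1, 4]], [[1, 0], [2, 0]])
        ranked = rank_vs_ideal(mean_stability(model, aec_frame(model)))
        assert ranked.loc["G1", "distance_to_ideal"] == 0
        assert ranked.loc["G1", "rank"] == 1
        assert ranked.loc["G2", "distance_to_ideal"] == 5  # 3-4-5 triangle

    def test_ranking_invariant_under_rotation(self, rng):
        theta = np.pi / 6
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        geno = rng.normal(size=(8, 2))
        env = rng.normal(size=(4, 2)) + [2, 0]
        m1 = _model_2d(geno, env)
        m2 = _model_2d(geno @ R.T, env @ R.T)
        r1 = rank_vs_ideal(mean_stability(m1, aec_frame(m1)))
        r2 = rank_vs_ideal(mean_stability(m2, aec_frame(m2)))
        assert list(r1.index) == list(r2.index)
        np.testing.assert_allclose(
            r1["distance_to_ideal"], r2["distance_to_ideal"], atol=1e-9
        )


class TestEnvironmentMetrics:
    def test_environment_on_abscissa(self):
        model = _model_2d([[0, 0]], [[5, 0], [1, 0]])
        out = environment_metrics(model, aec_frame(model))
        row = out.loc["E1"]
        assert (row["discriminating_power"], row["representativeness"],
                row["desirability"]) == (5.0, 1.0, 5.0)

    def test_hand_trigonometry(self):
        model = _model_2d([[0, 0]], [[3, 4], [1, 0]])
        out = environment_metrics(model, aec_frame(model))
        # abscissa is the normalized mean of (3,4) and (1,0) = (4,4)/|.|
        # use an explicit frame instead for the worked numbers
        from metgge.gge import AECFrame

        frame = AECFrame(np.array([1.0, 0]), np.array([1.0, 0]),
                         np.array([0.0, 1.0]))
        out = environment_metrics(model, frame)
        row = out.loc["E1"]
        assert row["discriminating_power"] == 5.0
        assert row["representativeness"] == pytest.approx(0.6)
        assert row["desirability"] == pytest.approx(3.0)

    def test_desirability_monotone_in_representativeness(self):
        angles = np.linspace(0.1, 1.2, 5)
        env = 5 * np.column_stack([np.cos(angles), np.sin(angles)])
        model = _model_2d([[0, 0]], env)
        from metgge.gge import AECFrame

        frame = AECFrame(np.array([1.0, 0]), np.array([1.0, 0]),
                         np.array([0.0, 1.0]))
        des = environment_metrics(model, frame)["desirability"].to_numpy()
        assert np.all(np.diff(des) < 0)  # growing angle = less representative

    def test_zero_length_vector_flagged(self):
        model = _model_2d([[0, 0]], [[0, 0], [1, 0]])
        out = environment_metrics(model, aec_frame(model))
        assert bool(out.loc["E1", "degenerate"])
        assert np.isnan(out.loc["E1", "representativeness"])


class TestWhichWonWhere:
    def test_square_hull_two_mega_environments(self):
        model = _model_2d([[1, 1], [1, -1], [-1, 1], [-1, -1], [0.2, 0.1]],
                          [[1, 0.1], [-1, -0.1]])
        res = which_won_where(model)
        assert res.environment_assignment == {"E1": "G1", "E2": "G4"}
        assert len(res.mega_environments) == 2
        assert "G5" not in res.hull_vertices  # interior point

    def test_single_environment_single_mega_environment(self):
        model = _model_2d([[1, 1], [1, -1], [-1, 0]], [[1, 0]])
        res = which_won_where(model)
        assert len(res.mega_environments) == 1

    def test_winner_equals_inner_product_argmax(self, rng):
        # central correctness property on random instances
        for _ in range(30):
            m = _matrix(rng.normal(size=(10, 4)))
            model = fit_gge(m, GENOTYPE_FOCUSED, n_axes=2)
            res = which_won_where(model)
            geno, env = model.scores_2d()
            for j, label in enumerate(model.environment_labels):
                expected = model.genotype_labels[int(np.argmax(geno @ env[j]))]
                assert res.environment_assignment[label] == expected

    def test_boundary_environment_flagged_ccw(self):
        geno = [[1, 1], [1, -1], [-1, 1], [-1, -1]]
        # boundary ray between G1 (upper right) and G2 (lower right) is +x
        model = _model_2d(geno, [[1.0, 0.0]])
        res = which_won_where(model)
        assert res.boundary_flags == ["E1"]
        assert res.environment_assignment["E1"] == "G1"  # CCW sector

    def test_collinear_points_degenerate(self):
        model = _model_2d([[1, 0], [2, 0], [3, 0]], [[1, 0]])
        with pytest.raises(DegenerateGeometryError):
            which_won_where(model)

    def test_planted_crossover_recovered(self):
        cfg = SimulationConfig(g=10, e=4, r=1, mu=100, var_g=1e-8, var_e=1.0,
                               var_ge=25.0, var_err=0.0,
                               crossover=CrossoverSpec(n_groups=2), seed=3)
        tm = to_two_way(simulate_met(cfg), "trait")
        model = fit_gge(tm, GENOTYPE_FOCUSED)
        assert model.variance_explained[:2].sum() == pytest.approx(1.0)
        res = which_won_where(model)
        got = sorted(sorted(me) for me in res.mega_environments)
        truth = sorted(sorted(me) for me in plant_crossover_truth(cfg))
        assert got == truth


def _naive_ward_heights(points):
    """Greedy Ward from scratch: merge the pair with least ESS increase."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = points[clusters[a]], points[clusters[b]]
                na, nb = len(ca), len(cb)
                delta = na * nb / (na + nb) * np.sum(
                    (ca.mean(axis=0) - cb.mean(axis=0)) ** 2)
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        heights.append(np.sqrt(2 * delta))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestWardCluster:
    def test_two_separated_clouds_recovered(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        features = pd.DataFrame(pts, index=[f"I{i}" for i in range(10)])
        result = ward_cluster(features, k=2, standardize=False)
        labels = result.labels.to_numpy()
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_k_equals_n_gives_singletons(self, rng):
        features = pd.DataFrame(rng.normal(size=(6, 3)))
        result = ward_cluster(features, k=6)
        assert result.labels.nunique() == 6

    def test_merge_heights_match_from_scratch_ward(self, rng):
        pts = rng.normal(size=(6, 2))
        result = ward_cluster(pd.DataFrame(pts), k=2, standardize=False)
        np.testing.assert_allclose(
            result.merge_heights, _naive_ward_heights(pts), rtol=1e-10
        )
        assert np.all(np.diff(result.merge_heights) >= -1e-12)

    def test_invalid_k(self, rng):
        with pytest.raises(DomainError):
            ward_cluster(pd.DataFrame(rng.normal(size=(4, 2))), k=5)
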