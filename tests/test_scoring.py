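"""Higher-level scores, scoring-model algebra, reliabilities, alpha."""

import numpy as np
import pytest

import circumfit as cf
from circumfit.core import DataMatrix
from circumfit.scoring import SCORE_NAMES, WEIGHTED_SUM_B


def raw_octants(values):
    return DataMatrix(cf.OCTANTS, np.atleast_2d(np.asarray(values, float)),
                      standardized=True)


class TestWeightedSumScores:
    def test_all_ones_row(self):
        ss = cf.weighted_sum_scores(raw_octants(np.ones(8)), standardize_first=False)
        dom, love, distress = ss.scores.values[0]
        assert dom == pytest.approx(0.0)
        assert love == pytest.approx(0.0)
        assert distress == pytest.approx(1.0)

    def test_unit_pa_row(self):
        row = np.zeros(8)
        row[cf.OCTANTS.index("PA")] = 1.0
        ss = cf.weighted_sum_scores(raw_octants(row), standardize_first=False)
        assert np.allclose(ss.scores.values[0], [1.0, 0.0, 0.125])

    def test_random_row_matches_direct_substitution(self, rng):
        vals = rng.normal(size=8)
        ss = cf.weighted_sum_scores(raw_octants(vals), standardize_first=False)
        r = dict(zip(cf.OCTANTS, vals))
        dom = r["PA"] + 0.71 * r["NO"] + 0.71 * r["BC"] - 0.71 * r["FG"] \
            - 0.71 * r["JK"] - r["HI"]
        love = r["LM"] + 0.71 * r["NO"] + 0.71 * r["JK"] - 0.71 * r["BC"] \
            - 0.71 * r["FG"] - r["DE"]
        distress = np.mean(vals)
        assert np.allclose(ss.scores.values[0], [dom, love, distress])

    def test_weight_matrix_symmetries(self):
        B = WEIGHTED_SUM_B
        opposite = {"PA": "HI", "NO": "FG", "BC": "JK", "LM": "DE"}
        for a, b in opposite.items():
            ia, ib = cf.OCTANTS.index(a), cf.OCTANTS.index(b)
            assert np.allclose(B[ia, :2], -B[ib, :2])
        assert np.allclose(B[:, 2], 0.125)

    def test_missing_column_named(self, rng):
        dm = DataMatrix(cf.OCTANTS[:-1], rng.normal(size=(5, 7)))
        with pytest.raises(ValueError, match="JK"):
            cf.weighted_sum_scores(dm)


class TestRegressionScores:
    def test_selector_weights_reproduce_columns(self, octant_data):
        W = np.zeros((8, 3))
        W[0, 0] = W[1, 1] = W[2, 2] = 1.0
        ss = cf.regression_scores(octant_data, W)
        assert np.allclose(ss.scores.values, octant_data.values[:, :3])

    def test_deterministic(self, octant_data, mcfa_solution):
        W = cf.regression_score_weights(mcfa_solution)
        a = cf.regression_scores(octant_data, W)
        b = cf.regression_scores(octant_data, W)
        assert np.array_equal(a.scores.values, b.scores.values)

    def test_distress_score_validity(self, population):
        X, F = cf.simulate_scales(population, 822, seed=33, return_factors=True)
        Z = cf.standardize(X)
        sol = cf.fit_mcfa(Z, cf.ideal_circumplex_pattern())
        ss = cf.regression_scores(Z, cf.regression_score_weights(sol))
        r = np.corrcoef(ss.scores.values[:, 2], F[:, 2])[0, 1]
        assert r >= 0.9


class TestScoringModel:
    def test_orthonormal_scores_lambda_equals_lambda_star(self, octant_data, rng):
        raw = rng.normal(size=(octant_data.n_rows, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        scores = cf.ScoreSet(
            method="weighted_sum",
            scores=DataMatrix(SCORE_NAMES, q * np.sqrt(octant_data.n_rows)),
            weights=np.zeros((8, 3)),
        )
        model = cf.scoring_model(octant_data, scores)
        assert np.allclose(model.score_intercorrelations, np.eye(3), atol=1e-10)
        assert np.allclose(model.loadings, model.octant_score_correlations, atol=1e-8)

    def test_reproduced_matches_brute_force_triple_product(self, octant_data):
        ss = cf.weighted_sum_scores(octant_data)
        model = cf.scoring_model(octant_data, ss)
        brute = model.loadings @ model.score_intercorrelations @ model.loadings.T
        assert np.max(np.abs(model.reproduced - brute)) < 1e-12

    def test_true_factor_scores_recover_generating_loadings(self, population):
        X, F = cf.simulate_scales(population, 200_000, seed=34, return_factors=True)
        Z = cf.standardize(X)
        scores = cf.ScoreSet(
            method="mcfa_regression",
            scores=DataMatrix(SCORE_NAMES, F),
            weights=np.zeros((8, 3)),
        )
        model = cf.scoring_model(Z, scores)
        assert np.allclose(model.loadings, population.loading_table()[:8], atol=0.01)

    def test_linearity_r_squared_one(self, octant_data, mcfa_solution):
        ss = cf.regression_scores(
            octant_data, cf.regression_score_weights(mcfa_solution)
        )
        Y = ss.scores.values
        B, *_ = np.linalg.lstsq(octant_data.values, Y, rcond=None)
        resid = Y - octant_data.values @ B
        r2 = 1 - resid.var(axis=0) / Y.var(axis=0)
        assert np.allclose(r2, 1.0, atol=1e-12)
        assert np.allclose(B, ss.weights, atol=1e-8)


class TestScoreReliability:
    def test_parallel_forms_identity(self, octant_data):
        S = octant_data.correlations()
        B = WEIGHTED_SUM_B
        assert np.allclose(cf.score_reliability(B, S, S, S), 1.0)

    def test_diagonal_cross_block_with_selector(self):
        S = np.eye(8)
        sigma_12 = np.diag(np.linspace(0.5, 0.85, 8))
        B = np.zeros((8, 3))
        B[0, 0] = B[3, 1] = B[7, 2] = 1.0
        r = cf.score_reliability(B, S, sigma_12, S)
        assert np.allclose(r, [sigma_12[0, 0], sigma_12[3, 3], sigma_12[7, 7]])

    def test_weight_rescaling_invariance(self, octant_data, mcfa_solution):
        B = WEIGHTED_SUM_B.copy()
        r0 = cf.cfa_score_reliability(B, mcfa_solution)
        B2 = B * np.array([3.0, 0.2, 7.0])
        r1 = cf.cfa_score_reliability(B2, mcfa_solution)
        assert np.allclose(r0, r1)

    def test_cfa_reliability_matches_population_algebra(self, population):
        X = cf.simulate_scales(population, 100_000, seed=35)
        Z = cf.standardize(X)
        sol = cf.fit_mcfa(Z, cf.ideal_circumplex_pattern())
        sample = cf.cfa_score_reliability(WEIGHTED_SUM_B, sol)
        lam = population.loading_table()
        S_pop = cf.implied_correlations(population)
        pop = cf.score_reliability(WEIGHTED_SUM_B, S_pop, lam @ lam.T, S_pop)
        assert np.allclose(sample, pop, atol=0.02)
        assert np.all((pop > 0) & (pop <= 1))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cf.score_reliability(np.zeros((8, 3)), np.eye(8), np.eye(8), np.eye(8))


class TestCronbachAlpha:
    def test_limit_cases(self, rng):
        x = rng.normal(size=(200, 1))
        twins = DataMatrix(("a", "b"), np.hstack([x, x]))
        assert cf.cronbach_alpha(twins) == pytest.approx(1.0)
        indep = DataMatrix(("a", "b", "c"), rng.normal(size=(20_000, 3)))
        assert abs(cf.cronbach_alpha(indep)) < 0.05

    def test_matches_pingouin_oracle(self, population):
        pingouin = pytest.importorskip("pingouin")
        items = cf.simulate_items(population, 500, seed=12).items
        cols = [f"BC_{i + 1}" for i in range(8)]
        sub = items.select(cols)
        ours = cf.cronbach_alpha(sub)
        theirs = pingouin.cronbach_alpha(sub.to_dataframe())[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_single_item_rejected(self, rng):
        with pytest.raises(ValueError):
            cf.cronbach_alpha(DataMatrix(("a",), rng.normal(size=(10, 1))))


class TestExternalCorrelations:
    def test_self_correlation_is_one(self, octant_data):
        ss = cf.weighted_sum_scores(octant_data)
        ext = DataMatrix(("SelfDistress",), ss.scores.values[:, [2]])
        R, stars = cf.external_correlations(ss, ext)
        assert R.loc["Distress", "SelfDistress"] == pytest.approx(1.0)
        assert stars.loc["Distress", "SelfDistress"] == "***"

    def test_external_loading_recovery(self, population):
        model = population.with_externals([("Neuroticism", (-0.14, -0.16, 0.61))])
        X = cf.simulate_scales(model, 822, seed=36)
        Z = cf.standardize(X)
        ss = cf.weighted_sum_scores(Z.select(cf.OCTANTS))
        R, _ = cf.external_correlations(ss, Z.select(["Neuroticism"]))
        # population correlation of the Distress composite with the criterion
        S_pop = cf.implied_correlations(model)
        b = ss.weights[:, 2]
        k = model.labels.index("Neuroticism")
        pop_r = b @ S_pop[:8, k] / np.sqrt(b @ S_pop[:8, :8] @ b)
        assert R.loc["Distress", "Neuroticism"] > 0
        assert R.loc["Distress", "Neuroticism"] == pytest.approx(pop_r, abs=0.07)

    def test_independent_external_usually_null(self, population, rng):
        X = cf.simulate_scales(population, 822, seed=37)
        Z = cf.standardize(X)
        ss = cf.weighted_sum_scores(Z)
        hits = 0
        for rep in range(20):
            noise = DataMatrix(("Noise",), rng.normal(size=(822, 1)))
            R, _ = cf.external_correlations(ss, noise)
            hits += int(np.all(np.abs(R["Noise"]) < 0.07))
        assert hits >= 17  # ~95% of replications inside +/-0.07 at n = 822

    def test_constant_column_rejected(self, octant_data):
        ss = cf.weighted_sum_scores(octant_data)
        flat = DataMatrix(("Flat",), np.ones((octant_data.n_rows, 1)))
        with pytest.raises(ValueError, match="Flat"):
            cf.external_correlations(ss, flat)
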