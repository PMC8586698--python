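"""ML covariance-structure estimation: recovery, fit indices, MI, score weights."""

from dataclasses import replace

import numpy as np
import pytest

import circumfit as cf
from circumfit.core import FIXED, FREE, CircumplexPattern
from circumfit.mcfa import (
    drop_external,
    extend_with_external,
    fit_statistics,
    select_error_covariances,
)


def printed_pattern_population():
    """Population whose circumplex equals the printed pattern times 0.6,
    so the fixed-pattern model fits its implied matrix exactly."""
    pat = cf.ideal_circumplex_pattern()
    loads = pat.loading_matrix.copy()
    loads[:, :2] *= 0.6
    loads[:, 2] = cf.default_population().distress_loadings
    pat = replace(pat, loading_matrix=loads)
    d = loads[:, 2]
    uniq = 1.0 - np.sum(loads[:, :2] ** 2, axis=1) - d**2
    return cf.PopulationModel(pattern=pat, distress_loadings=d, uniquenesses=uniq)


def one_factor_toy_pattern(labels=("V1", "V2", "V3")):
    p = len(labels)
    loads = np.zeros((p, 3))
    loads[:, 2] = 0.5
    status = np.full((p, 3), FIXED, dtype=object)
    status[:, 2] = FREE
    return CircumplexPattern(
        scale_labels=tuple(labels),
        ideal_angles=np.zeros(p),
        loading_matrix=loads,
        cell_status=status,
        error_covariance_mask=np.zeros((p, p), bool),
    )


class TestFitMcfa:
    def test_just_identified_single_factor_closed_form(self):
        r12, r13, r23 = 0.35, 0.42, 0.30
        S = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
        sol = cf.fit_mcfa(S, one_factor_toy_pattern(), n=500)
        lam = sol.loadings[:, 2]
        assert lam[0] == pytest.approx(np.sqrt(r12 * r13 / r23), abs=1e-5)  # 0.70
        assert lam[1] == pytest.approx(np.sqrt(r12 * r23 / r13), abs=1e-5)  # 0.50
        assert lam[2] == pytest.approx(np.sqrt(r13 * r23 / r12), abs=1e-5)  # 0.60
        assert sol.discrepancy < 1e-9

    def test_perfect_fit_recovers_generating_values(self):
        model = printed_pattern_population()
        S = cf.implied_correlations(model)
        sol = cf.fit_mcfa(S, cf.ideal_circumplex_pattern(), n=822)
        assert sol.discrepancy < 1e-8
        assert np.allclose(sol.loadings[:, 2], model.distress_loadings, atol=1e-4)
        assert np.allclose(np.diag(sol.factor_covariance)[:2], 0.36, atol=1e-4)
        assert np.allclose(np.diag(sol.uniquenesses), model.uniquenesses, atol=1e-4)

    def test_solution_invariants(self, mcfa_solution):
        pat = mcfa_solution.pattern
        fixed = pat.cell_status == FIXED
        assert np.array_equal(
            mcfa_solution.loadings[fixed], pat.loading_matrix[fixed]
        )
        phi = mcfa_solution.factor_covariance
        assert np.allclose(phi - np.diag(np.diag(phi)), 0.0)
        assert phi[2, 2] == 1.0
        # ML stationarity zeroes diag(Sigma^-1 (S - Sigma) Sigma^-1), not
        # diag(S - Sigma); the implied diagonal matches the sample diagonal
        # exactly only at perfect fit, and to sampling accuracy otherwise
        assert np.allclose(np.diag(mcfa_solution.implied),
                           np.diag(mcfa_solution.sample_corr), atol=0.05)

    def test_distress_recovery_at_study_n(self, mcfa_solution, population):
        # per-loading ML sampling error at n = 822 is about 0.03, so the
        # dataset-level summary is the root-mean-square recovery error
        err = mcfa_solution.loadings[:, 2] - population.distress_loadings
        assert np.sqrt(np.mean(err**2)) < 0.05
        assert np.abs(err).max() < 0.10

    def test_octant_order_invariance(self, octant_data):
        pat = cf.ideal_circumplex_pattern()
        base = cf.fit_mcfa(octant_data, pat)
        perm = [3, 1, 0, 7, 5, 2, 6, 4]
        labels = tuple(cf.OCTANTS[i] for i in perm)
        pat_p = replace(
            pat,
            scale_labels=labels,
            ideal_angles=pat.ideal_angles[perm],
            loading_matrix=pat.loading_matrix[perm],
            cell_status=pat.cell_status[perm],
        )
        sol_p = cf.fit_mcfa(octant_data.select(labels), pat_p)
        assert sol_p.discrepancy == pytest.approx(base.discrepancy, abs=1e-8)

    def test_non_psd_input_rejected(self):
        S = np.full((8, 8), 0.99)
        np.fill_diagonal(S, 1.0)
        S[0, 1] = S[1, 0] = -0.99
        with pytest.raises(ValueError):
            cf.fit_mcfa(S, cf.ideal_circumplex_pattern(), n=100)


class TestFitIndices:
    def test_perfect_fit_limits(self):
        model = printed_pattern_population()
        S = cf.implied_correlations(model)
        sol = cf.fit_mcfa(S, cf.ideal_circumplex_pattern(), n=822)
        fs = cf.fit_indices(sol)
        assert fs.df == 18
        assert fs.chi_square == pytest.approx(0, abs=1e-4)
        assert fs.cfi == 1.0
        assert fs.srmr == pytest.approx(0, abs=1e-4)
        assert fs.rmsea == 0.0

    def test_baseline_model_has_cfi_zero(self, octant_data):
        # the independence model evaluated as a "solution" defines CFI = 0
        S = octant_data.correlations()
        implied = np.eye(8)
        disc = float(-np.linalg.slogdet(S)[1])
        fs = fit_statistics(disc, implied, S, octant_data.n_rows, n_free=8)
        assert fs.cfi == pytest.approx(0.0, abs=1e-9)

    def test_srmr_matches_brute_force(self, mcfa_solution):
        fs = cf.fit_indices(mcfa_solution)
        S, implied = mcfa_solution.sample_corr, mcfa_solution.implied
        acc = [
            ((S[i, j] - implied[i, j]) / np.sqrt(S[i, i] * S[j, j])) ** 2
            for i in range(8)
            for j in range(i, 8)
        ]
        assert fs.srmr == pytest.approx(np.sqrt(np.mean(acc)), abs=1e-12)

    def test_rmsea_interval_brackets_point(self, octant_data):
        # a deliberately misfitting model: independence with uniqueness free
        S = octant_data.correlations()
        fs = fit_statistics(0.5, np.eye(8), S, octant_data.n_rows, n_free=8)
        assert fs.rmsea_ci[0] <= fs.rmsea <= fs.rmsea_ci[1]
        assert fs.rmsea > 0


class TestModificationIndices:
    def test_perfect_fit_gives_null_indices(self):
        model = printed_pattern_population()
        S = cf.implied_correlations(model)
        sol = cf.fit_mcfa(S, cf.ideal_circumplex_pattern(), n=822)
        entries = cf.modification_indices(sol)
        assert max(e.index for e in entries) < 0.01
        names = {e.parameter for e in entries}
        # free and scaling cells never appear
        assert not any("Distress" in n for n in names)
        assert "loading:PA:Dominance" not in names

    def test_displaced_loading_detected_with_signed_epc(self):
        model = printed_pattern_population()
        loads = model.pattern.loading_matrix.copy()
        lm = cf.OCTANTS.index("LM")
        loads[lm, 0] = -0.25  # LM picks up a negative Dominance loading
        displaced = model.with_pattern(replace(model.pattern, loading_matrix=loads))
        S = cf.implied_correlations(displaced)
        sol = cf.fit_mcfa(S, cf.ideal_circumplex_pattern(), n=822)
        entries = cf.modification_indices(sol)
        loading_entries = [e for e in entries if e.parameter.startswith("loading:")]
        assert loading_entries[0].parameter == "loading:LM:Dominance"
        assert loading_entries[0].epc < 0

    def test_freed_covariance_lowers_chi_square(self, octant_data, mcfa_solution):
        entries = cf.modification_indices(mcfa_solution)
        top = next(e for e in entries if e.parameter.startswith("errcov:"))
        _, a, b = top.parameter.split(":")
        pat2 = cf.ideal_circumplex_pattern().with_error_covariances([(a, b)])
        sol2 = cf.fit_mcfa(octant_data, pat2)
        chi_before = cf.fit_indices(mcfa_solution).chi_square
        chi_after = cf.fit_indices(sol2).chi_square
        assert chi_after <= chi_before + 1e-6

    def test_threshold_selector(self, mcfa_solution):
        entries = cf.modification_indices(mcfa_solution)
        pairs = select_error_covariances(entries, threshold=0.0)
        assert all(len(p) == 2 for p in pairs)
        assert select_error_covariances(entries, threshold=1e9) == []


class TestRegressionScoreWeights:
    def test_matches_matrix_oracle(self, mcfa_solution):
        W = cf.regression_score_weights(mcfa_solution)
        sigma = mcfa_solution.implied
        oracle = np.linalg.inv(sigma) @ mcfa_solution.loadings @ \
            mcfa_solution.factor_covariance
        assert np.allclose(W, oracle, atol=1e-10)

    def test_single_factor_equal_loadings_equal_weights(self):
        S = np.full((3, 3), 0.49)
        np.fill_diagonal(S, 1.0)
        sol = cf.fit_mcfa(S, one_factor_toy_pattern(), n=500)
        W = cf.regression_score_weights(sol)[:, 2]
        assert np.allclose(W, W[0])

    def test_vanishing_uniqueness_limit_reproduces_factors(self):
        # with near-zero uniquenesses the weights invert the loading map
        pat = one_factor_toy_pattern()
        lam = np.array([0.99, 0.99, 0.99])
        S = np.outer(lam, lam) + np.diag(1 - lam**2)
        sol = cf.fit_mcfa(S, pat, n=2000)
        W = cf.regression_score_weights(sol)[:, 2]
        # score variance approaches factor variance 1 and validity 1
        assert W @ S @ W == pytest.approx(1.0, abs=0.01)

    def test_maximal_validity_among_random_weightings(self, population, rng):
        X, F = cf.simulate_scales(population, 10_000, seed=31, return_factors=True)
        Z = cf.standardize(X)
        sol = cf.fit_mcfa(Z, cf.ideal_circumplex_pattern())
        W = cf.regression_score_weights(sol)
        best = np.corrcoef(Z.values @ W[:, 2], F[:, 2])[0, 1]
        for _ in range(25):
            w = rng.normal(size=8)
            r = abs(np.corrcoef(Z.values @ w, F[:, 2])[0, 1])
            assert r <= best + 1e-3


class TestExternalExtension:
    def test_extend_and_drop_round_trip(self):
        pat = cf.ideal_circumplex_pattern()
        ext = extend_with_external(pat, ["Neuroticism"])
        assert ext.n_vars == 9
        assert np.all(ext.cell_status[8] == FREE)
        assert np.array_equal(ext.cell_status[:8], pat.cell_status)
        back = drop_external(ext, ["Neuroticism"])
        assert back.scale_labels == pat.scale_labels
        assert np.array_equal(back.loading_matrix, pat.loading_matrix)

    def test_duplicate_label_rejected(self):
        with pytest.raises(ValueError):
            extend_with_external(cf.ideal_circumplex_pattern(), ["PA"])

    def test_external_loading_recovery(self, population):
        model = population.with_externals(
            [("Neuroticism", (-0.14, -0.16, 0.61))]
        )
        X = cf.simulate_scales(model, 822, seed=13)
        Z = cf.standardize(X)
        pat = extend_with_external(cf.ideal_circumplex_pattern(), ["Neuroticism"])
        sol = cf.fit_mcfa(Z, pat)
        est = sol.standardized_loadings()[8]
        assert np.allclose(est, (-0.14, -0.16, 0.61), atol=0.07)
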