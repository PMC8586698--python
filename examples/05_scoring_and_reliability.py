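"""Higher-level scores, scoring-model algebra, reliability, external validity.

Computes weighted-sum and regression factor scores for Dominance, Love,
and Distress, the regression-component loadings and reproduced
correlations of each scoring model, parallel-forms reliabilities, and
correlations with a simulated external criterion.
"""

import numpy as np

import circumfit as cf

population = cf.default_population().with_externals(
    [("Neuroticism", (-0.14, -0.16, 0.61))]
)
full = cf.standardize(cf.simulate_scales(population, n=822, seed=7))
octants = full.select(cf.OCTANTS)

mcfa = cf.fit_mcfa(octants, cf.ideal_circumplex_pattern())
scores = {
    "weighted sums": cf.weighted_sum_scores(octants),
    "regression scores": cf.regression_scores(
        octants, cf.regression_score_weights(mcfa)
    ),
}

lam_gen = population.loading_table()[:8]
for name, ss in scores.items():
    model = cf.scoring_model(octants, ss)
    cong = [cf.tucker_congruence(model.loadings[:, k], lam_gen[:, k])
            for k in range(3)]
    rel = cf.cfa_score_reliability(ss.weights, mcfa)
    print(f"{name}:")
    print(f"  congruence of scoring-model loadings with generating factors: "
          f"Dom {cong[0]:.3f}, Love {cong[1]:.3f}, Distress {cong[2]:.3f}")
    print(f"  reliabilities (CFA parallel-forms): "
          f"Dom {rel[0]:.2f}, Love {rel[1]:.2f}, Distress {rel[2]:.2f}")
    R, stars = cf.external_correlations(ss, full.select(["Neuroticism"]))
    r = R.loc["Distress", "Neuroticism"]
    print(f"  r(Distress score, Neuroticism) = {r:.2f}"
          f"{stars.loc['Distress', 'Neuroticism']}"
          f"  (population loading of the criterion on Distress is 0.61)")
    print()

both = np.corrcoef(scores["weighted sums"].scores.values.T,
                   scores["regression scores"].scores.values.T)[:3, 3:]
print("between-method score correlations (diagonal):",
      np.round(np.diag(both), 3))
print("  (the two scoring methods measure nearly the same composites)")
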