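"""End-to-end circumplex analysis pipeline.

Runs the full study workflow on an octant-scale dataset: standardization,
ML bi-factor CFA (with misspecification analysis and a correlated-error
follow-up), Bayesian CFA under two loading-prior variances (the one whose
posterior circumplex is more congruent with the ideal pattern is carried
forward), target-rotated EFA, the SPMC under three constraint sets,
higher-level scoring by both methods with reliabilities, circumplexity
diagnostics (SPMC on reproduced correlations, angle tables, GDIFF), and
external-criterion correlations.  A split-half stability check compares
MCFA and BCFA fit across two random halves.

Every stage is seeded deterministically from one master seed, stage
failures are recorded without aborting independent stages, and the report
renders identically as JSON (machine-readable) and text (human-readable).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import __version__
from .bcfa import BcfaConfig, bayes_fit_indices, fit_bcfa, posterior_predictive_check
from .core import (
    OCTANTS,
    AngleSet,
    DataMatrix,
    gdiff,
    ideal_circumplex_pattern,
    loadings_to_angles,
    standardize,
    tucker_congruence,
)
from .efa import TargetSpec, congruence_report, fit_efa_ml, target_rotate_partial
from .mcfa import (
    fit_indices,
    fit_mcfa,
    fit_statistics,
    modification_indices,
    regression_score_weights,
    select_error_covariances,
)
from .scoring import (
    SCORE_NAMES,
    cfa_score_reliability,
    external_correlations,
    regression_scores,
    scoring_model,
    weighted_sum_scores,
)
from .spmc import fit_spmc, spmc_on_reproduced

ALL_STAGES = (
    "mcfa", "mcfa_correlated_errors", "bcfa", "tefa", "spmc",
    "scoring", "circumplexity", "external", "split_half",
)


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[str, ...] = ALL_STAGES
    prior_variances: tuple[float, ...] = (0.01, 0.1)
    spmc_grid: tuple[tuple[str, str], ...] = (
        ("equal", "equal"), ("free", "equal"), ("free", "free")
    )
    fourier_order: int = 3
    mi_threshold: float = 10.0
    seed: int = 0
    bcfa: BcfaConfig = field(default_factory=lambda: BcfaConfig(max_iterations=30_000))
    ppc_draws: int = 200

    def __post_init__(self):
        if not self.stages:
            raise ValueError("at least one stage must be enabled")
        if any(v <= 0 for v in self.prior_variances):
            raise ValueError("prior variances must be positive")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class AnalysisReport:
    blocks: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.blocks, indent=indent, sort_keys=True, default=_jsonify)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    def to_text(self) -> str:
        """Human-readable rendering; every number is read from the JSON blocks."""
        data = json.loads(self.to_json())
        lines = []

        def emit(obj, indent=0):
            pad = "  " * indent
            if isinstance(obj, dict):
                for k, v in obj.items():
                    if isinstance(v, (dict, list)):
                        lines.append(f"{pad}{k}:")
                        emit(v, indent + 1)
                    else:
                        lines.append(f"{pad}{k}: {v}")
            elif isinstance(obj, list):
                for v in obj:
                    emit(v, indent)
            else:
                lines.append(f"{pad}{obj}")

        for name, block in data.items():
            lines.append(f"== {name} ==")
            emit(block, 1)
            lines.append("")
        return "\n".join(lines)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"cannot serialize {type(obj)}")


def _round_floats(x, nd=10):
    if isinstance(x, dict):
        return {k: _round_floats(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_floats(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return _round_floats(x.tolist(), nd)
    return x


def run_full_analysis(data: DataMatrix, config: RunConfig | None = None) -> AnalysisReport:
    """Run all enabled stages in dependency order and collect a report."""
    config = config or RunConfig()
    blocks: dict = {
        "provenance": {
            "seed": config.seed,
            "version": __version__,
            "stages": list(config.stages),
            "prior_variances": list(config.prior_variances),
            "n": data.n_rows,
        }
    }
    octants = standardize(data.select(OCTANTS))
    external_labels = [l for l in data.column_labels if l not in OCTANTS]
    S = octants.correlations()
    n = octants.n_rows
    pattern = ideal_circumplex_pattern()

    mcfa_sol = None
    scores_by_method = {}
    models_by_method = {}

    def _run(stage, fn):
        if stage not in config.stages:
            return
        try:
            fn()
        except Exception as err:  # record and continue independent stages
            blocks[stage] = {"error": f"{type(err).__name__}: {err}"}

    def do_mcfa():
        nonlocal mcfa_sol
        mcfa_sol = fit_mcfa(S, pattern, n=n, seed=stage_seed(config.seed, "mcfa"))
        mis = modification_indices(mcfa_sol)
        blocks["mcfa"] = _round_floats(
            {
                "fit": fit_indices(mcfa_sol).as_dict(),
                "loadings": {
                    lbl: mcfa_sol.standardized_loadings()[i].tolist()
                    for i, lbl in enumerate(OCTANTS)
                },
                "modification_indices": [
                    {"parameter": e.parameter, "mi": e.index, "epc": e.epc}
                    for e in mis[:10]
                ],
                "warnings": list(mcfa_sol.warnings),
            }
        )

    _run("mcfa", do_mcfa)

    def do_corr_errors():
        if mcfa_sol is None:
            raise RuntimeError("mcfa stage did not run")
        pairs = select_error_covariances(
            modification_indices(mcfa_sol), config.mi_threshold
        )
        if pairs:
            pat2 = pattern.with_error_covariances(pairs)
            sol2 = fit_mcfa(S, pat2, n=n, seed=stage_seed(config.seed, "mcfa_ce"))
            blocks["mcfa_correlated_errors"] = _round_floats(
                {"freed_pairs": [list(p) for p in pairs],
                 "fit": fit_indices(sol2).as_dict()}
            )
        else:
            blocks["mcfa_correlated_errors"] = {"freed_pairs": [], "fit": None}

    _run("mcfa_correlated_errors", do_corr_errors)

    def do_bcfa():
        results = {}
        best_pv, best_c = None, -np.inf
        for pv in config.prior_variances:
            cfg = replace(
                config.bcfa,
                loading_prior_variance=pv,
                seed=stage_seed(config.seed, f"bcfa:{pv}"),
            )
            post = fit_bcfa(octants, pattern.with_priors(pv), cfg)
            lam = post.standardized_median_loadings()
            cong = {
                "Dominance": tucker_congruence(lam[:, 0], pattern.circumplex[:, 0]),
                "Love": tucker_congruence(lam[:, 1], pattern.circumplex[:, 1]),
            }
            ppc = posterior_predictive_check(
                post, octants, n_draws=config.ppc_draws,
                seed=stage_seed(config.seed, f"ppc:{pv}"),
            )
            bfi = bayes_fit_indices(post, octants, ppc=ppc)
            results[str(pv)] = {
                "max_psr": post.max_psr,
                "converged": post.converged,
                "iterations": post.draws.shape[1],
                "psr_trace": [list(t) for t in post.psr_trace[-5:]],
                "congruence": cong,
                "ppc_p": ppc.p_value,
                "chi2_diff_interval_95": list(ppc.difference_interval),
                "cfi": bfi.cfi,
                "rmsea": bfi.rmsea,
                "rmsea_interval_90": list(bfi.rmsea_interval),
                "median_loadings": {
                    lbl: lam[i].tolist() for i, lbl in enumerate(OCTANTS)
                },
            }
            mean_c = (cong["Dominance"] + cong["Love"]) / 2
            if mean_c > best_c:
                best_pv, best_c = pv, mean_c
        blocks["bcfa"] = _round_floats(
            {"by_prior_variance": results, "selected_prior_variance": best_pv}
        )

    _run("bcfa", do_bcfa)

    def do_tefa():
        efa = fit_efa_ml(S, 3, n)
        rotated, _ = target_rotate_partial(
            efa.loadings, TargetSpec.from_pattern(pattern),
            seed=stage_seed(config.seed, "tefa"),
        )
        blocks["tefa"] = _round_floats(
            {
                "fit": efa.fit.as_dict(),
                "congruence": congruence_report(rotated, pattern, kaiser=False),
                "congruence_kaiser": congruence_report(rotated, pattern, kaiser=True),
                "rotated_loadings": {
                    lbl: rotated[i].tolist() for i, lbl in enumerate(OCTANTS)
                },
            }
        )

    _run("tefa", do_tefa)

    def do_spmc():
        rows = {}
        for spacing, communalities in config.spmc_grid:
            sol = fit_spmc(
                S, n, spacing=spacing, communalities=communalities,
                fourier_order=config.fourier_order,
                seed=stage_seed(config.seed, f"spmc:{spacing}:{communalities}"),
            )
            rows[f"{spacing}-spacing/{communalities}-communalities"] = {
                "fit": sol.fit.as_dict(),
                "minimum_correlation": sol.minimum_correlation,
                "minimum_correlation_angle": sol.minimum_correlation_angle,
            }
        blocks["spmc"] = _round_floats(rows)

    _run("spmc", do_spmc)

    def do_scoring():
        if mcfa_sol is None:
            raise RuntimeError("scoring needs the mcfa stage")
        W = regression_score_weights(mcfa_sol)
        scores_by_method["mcfa_regression"] = regression_scores(octants, W)
        scores_by_method["weighted_sum"] = weighted_sum_scores(octants)
        out = {}
        mcfa_std = mcfa_sol.standardized_loadings()
        for method, ss in scores_by_method.items():
            model = scoring_model(octants, ss)
            models_by_method[method] = model
            out[method] = {
                "score_intercorrelations": model.score_intercorrelations.tolist(),
                "reliabilities_scoring_model": dict(zip(SCORE_NAMES, model.reliabilities)),
                "reliabilities_cfa": dict(
                    zip(SCORE_NAMES, cfa_score_reliability(ss.weights, mcfa_sol))
                ),
                "loading_congruence_with_mcfa": {
                    f: tucker_congruence(model.loadings[:, k], mcfa_std[:, k])
                    for k, f in enumerate(SCORE_NAMES)
                },
            }
        both = np.corrcoef(
            scores_by_method["mcfa_regression"].scores.values.T,
            scores_by_method["weighted_sum"].scores.values.T,
        )[:3, 3:]
        out["between_method_correlations"] = {
            f: both[k, k] for k, f in enumerate(SCORE_NAMES)
        }
        blocks["scoring"] = _round_floats(out)

    _run("scoring", do_scoring)

    def do_circumplexity():
        inputs = {"original_octants": S}
        for method, model in models_by_method.items():
            inputs[f"reproduced_{method}"] = model.reproduced
        angles_out, gdiff_out = {}, {}
        ideal = AngleSet.ideal()
        for name, mat in inputs.items():
            if name == "original_octants":
                sol = fit_spmc(
                    mat, n, spacing="free", communalities="equal",
                    fourier_order=config.fourier_order,
                    seed=stage_seed(config.seed, f"circ:{name}"),
                )
            else:
                sol = spmc_on_reproduced(
                    mat, n, spacing="free", communalities="equal",
                    fourier_order=config.fourier_order,
                    seed=stage_seed(config.seed, f"circ:{name}"),
                )
            angles_out[name] = {
                lbl: sol.angles.angle(lbl) for lbl in OCTANTS
            }
            gdiff_out[name] = gdiff(sol.angles, ideal)
        blocks["circumplexity"] = _round_floats(
            {"angles": angles_out, "gdiff": gdiff_out}
        )

    _run("circumplexity", do_circumplexity)

    def do_external():
        if not external_labels:
            blocks["external"] = {"note": "no external columns present"}
            return
        ext = standardize(data.select(external_labels))
        out = {}
        for method, ss in scores_by_method.items():
            R, stars = external_correlations(ss, ext)
            out[method] = {
                "correlations": R.round(10).to_dict(),
                "significance": stars.to_dict(),
            }
        blocks["external"] = _round_floats(out)

    _run("external", do_external)

    def do_split_half():
        blocks["split_half"] = _round_floats(
            split_half_stability(
                data.select(OCTANTS),
                seed=stage_seed(config.seed, "split_half"),
                bcfa_config=config.bcfa,
                ppc_draws=config.ppc_draws,
            )
        )

    _run("split_half", do_split_half)

    return AnalysisReport(blocks=blocks)


def split_half_stability(
    data: DataMatrix,
    seed: int,
    bcfa_config: BcfaConfig | None = None,
    ppc_draws: int = 200,
    halves: tuple | None = None,
) -> dict:
    """Fit MCFA and BCFA to two random halves; report between-half fit shifts.

    The split is an equal random partition (odd N puts the extra case in
    the first half); ``halves`` overrides it with explicit row-index
    pairs.  Both models use the plain bi-factor circumplex pattern
    without correlated errors.  Reported per method: CFI, RMSEA, and BIC
    per half and their absolute differences.
    """
    if data.n_rows < 100:
        raise ValueError("need N >= 100 for a meaningful split-half check")
    if halves is None:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(data.n_rows)
        cut = (data.n_rows + 1) // 2
        halves = [perm[:cut], perm[cut:]]
    pattern = ideal_circumplex_pattern()
    bcfa_config = bcfa_config or BcfaConfig(max_iterations=30_000)
    out: dict = {"n_halves": [len(h) for h in halves]}
    mcfa_stats, bcfa_stats = [], []
    for k, idx in enumerate(halves):
        half = standardize(DataMatrix(data.column_labels, data.values[idx]))
        sol = fit_mcfa(half, pattern, seed=seed + k)
        mcfa_stats.append(fit_indices(sol))
        cfg = replace(bcfa_config, seed=(seed + 7 * k + 1) % 2**31)
        post = fit_bcfa(half, pattern.with_priors(cfg.loading_prior_variance), cfg)
        bfi = bayes_fit_indices(
            post, half,
            ppc=posterior_predictive_check(post, half, n_draws=ppc_draws, seed=seed + k),
        )
        lam, phi, theta = post.median_parameters()
        sigma = lam @ phi @ lam.T + theta
        S_half = half.correlations()
        from .mcfa import _discrepancy

        chi2 = (half.n_rows - 1) * _discrepancy(
            S_half, sigma, np.linalg.slogdet(S_half)[1]
        )
        df = S_half.shape[0] * (S_half.shape[0] + 1) // 2 - len(post.param_names)
        bcfa_stats.append(
            {"cfi": bfi.cfi, "rmsea": bfi.rmsea,
             "bic": float(chi2 - df * np.log(half.n_rows))}
        )
    out["mcfa"] = {
        "halves": [s.as_dict() for s in mcfa_stats],
        "abs_differences": {
            "cfi": abs(mcfa_stats[0].cfi - mcfa_stats[1].cfi),
            "rmsea": abs(mcfa_stats[0].rmsea - mcfa_stats[1].rmsea),
            "bic": abs(mcfa_stats[0].bic - mcfa_stats[1].bic),
        },
    }
    out["bcfa"] = {
        "halves": bcfa_stats,
        "abs_differences": {
            k: abs(bcfa_stats[0][k] - bcfa_stats[1][k]) for k in ("cfi", "rmsea", "bic")
        },
    }
    return out
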