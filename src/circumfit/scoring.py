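"""Higher-level scores for Dominance, Love, and Distress, and their psychometrics.

Two scoring methods are supported: fixed-weight circumplex sum scores

    Dominance = PA + 0.71 NO + 0.71 BC - 0.71 FG - 0.71 JK - HI
    Love      = LM + 0.71 NO + 0.71 JK - 0.71 BC - 0.71 FG - DE
    Distress  = (PA + BC + DE + FG + HI + JK + LM + NO) / 8

applied to z-standardized octant scales, and regression factor scores
(standardized data times W = Sigma^-1 Lambda Phi from a fitted CFA).  Both
are linear combinations of the octants, so a multiple regression of the
scores on the octants recovers the weights with R^2 = 1.

From any score set the scoring-model algebra gives regression-component
loadings Lambda = Lambda* C^-1 (Lambda* the octant-score correlations, C
the score intercorrelations), the reproduced octant correlation matrix
Sigma_r = Lambda C Lambda', and parallel-forms reliabilities

    Rtts = diag( diag(B' S11 B)^-1/2  B' S12 B  diag(B' S22 B)^-1/2 )

with S11 = S22 the observed octant correlations and S12 = Sigma_r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import OCTANTS, DataMatrix, standardize

SCORE_NAMES = ("Dominance", "Love", "Distress")

#: Fixed circumplex weights, octants in circular order (LM, NO, PA, BC, DE, FG, HI, JK).
WEIGHTED_SUM_B = np.array(
    [
        #  Dom    Love   Distress
        [0.00, 1.00, 0.125],   # LM
        [0.71, 0.71, 0.125],   # NO
        [1.00, 0.00, 0.125],   # PA
        [0.71, -0.71, 0.125],  # BC
        [0.00, -1.00, 0.125],  # DE
        [-0.71, -0.71, 0.125],  # FG
        [-1.00, 0.00, 0.125],  # HI
        [-0.71, 0.71, 0.125],  # JK
    ]
)


@dataclass(frozen=True)
class ScoreSet:
    """Higher-level scores with the weight matrix that produced them."""

    method: str                       # "weighted_sum" | "mcfa_regression"
    scores: DataMatrix                # N x 3 (Dominance, Love, Distress)
    weights: np.ndarray               # 8 x 3 octant-to-score weights B
    octant_labels: tuple[str, ...] = OCTANTS


@dataclass(frozen=True)
class ScoringModel:
    """Scoring-model algebra: loadings, reproduced correlations, reliabilities."""

    method: str
    octant_score_correlations: np.ndarray   # Lambda*: 8 x 3
    score_intercorrelations: np.ndarray     # C: 3 x 3
    loadings: np.ndarray                    # Lambda = Lambda* C^-1
    reproduced: np.ndarray                  # Sigma_r = Lambda C Lambda'
    reliabilities: np.ndarray               # Rtts per score


def _require_octants(data: DataMatrix) -> DataMatrix:
    missing = [l for l in OCTANTS if l not in data.column_labels]
    if missing:
        raise ValueError(f"missing octant column {missing[0]!r}")
    return data.select(OCTANTS)


def weighted_sum_scores(scales: DataMatrix, standardize_first: bool = True) -> ScoreSet:
    """Fixed-weight circumplex sum scores from the eight octant scales.

    Applied to z-standardized scales by default (matching how the scales
    enter all structural models); ``standardize_first=False`` applies the
    weights to the raw columns.
    """
    octants = _require_octants(scales)
    if standardize_first and not octants.standardized:
        octants = standardize(octants)
    B = WEIGHTED_SUM_B.copy()
    S = octants.values @ B
    return ScoreSet(
        method="weighted_sum",
        scores=DataMatrix(SCORE_NAMES, S, standardized=False),
        weights=B,
    )


def regression_scores(scales: DataMatrix, weights: np.ndarray) -> ScoreSet:
    """Regression factor scores: standardized octant data times W."""
    octants = _require_octants(scales)
    if not octants.standardized:
        octants = standardize(octants)
    W = np.asarray(weights, float)
    if W.shape[0] != 8:
        # a CFA with external rows yields a (8+k) x 3 weight matrix; scores
        # for the octant-only composite need the octant rows
        raise ValueError(f"weight matrix must have 8 rows, got {W.shape[0]}")
    S = octants.values @ W
    return ScoreSet(
        method="mcfa_regression",
        scores=DataMatrix(SCORE_NAMES, S, standardized=False),
        weights=W,
    )


def scoring_model(octants: DataMatrix, scores: ScoreSet) -> ScoringModel:
    """Regression-component loadings, reproduced correlations, reliabilities.

    B is re-derived by multiple regression of the scores on the
    standardized octants (for linear-combination scores this reproduces
    the stored weights exactly, and it also covers externally supplied
    scores); reliabilities use the observed octant correlations for both
    parallel sets and the reproduced matrix for their cross-correlations.
    """
    oct_dm = _require_octants(octants)
    if not oct_dm.standardized:
        oct_dm = standardize(oct_dm)
    X, Y = oct_dm.values, scores.scores.values
    lam_star = _cross_correlations(X, Y)            # 8 x 3
    C = np.corrcoef(Y, rowvar=False)
    try:
        C_inv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("score intercorrelation matrix is singular") from err
    lam = lam_star @ C_inv
    sigma_r = lam @ C @ lam.T
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    S11 = np.corrcoef(X, rowvar=False)
    rtts = score_reliability(B, S11, sigma_r, S11)
    return ScoringModel(
        method=scores.method,
        octant_score_correlations=lam_star,
        score_intercorrelations=C,
        loadings=lam,
        reproduced=(sigma_r + sigma_r.T) / 2,
        reliabilities=rtts,
    )


def score_reliability(B, sigma_11, sigma_12, sigma_22) -> np.ndarray:
    """Parallel-forms composite reliabilities.

    Rtts_k = (B' S12 B)_kk / sqrt((B' S11 B)_kk (B' S22 B)_kk).
    """
    B = np.asarray(B, float)
    v11 = np.diag(B.T @ np.asarray(sigma_11, float) @ B)
    v22 = np.diag(B.T @ np.asarray(sigma_22, float) @ B)
    v12 = np.diag(B.T @ np.asarray(sigma_12, float) @ B)
    if np.any(v11 <= 0) or np.any(v22 <= 0):
        k = int(np.argmin(v11 if np.any(v11 <= 0) else v22))
        raise ValueError(f"zero variance for score {SCORE_NAMES[k] if k < 3 else k}")
    return v12 / np.sqrt(v11 * v22)


def cfa_score_reliability(B, solution) -> np.ndarray:
    """Parallel-forms reliabilities with the CFA common part as the cross-block.

    Uses Sigma_12 = Lambda Phi Lambda' from a fitted CFA solution: two
    parallel octant sets share the common factors but have independent
    uniquenesses, so the cross-correlation of the composites estimates
    their reliability.  Unlike the scoring-model reproduced matrix (whose
    projection algebra makes the same formula identically 1 for linear
    scores), this yields the conventional, nontrivial factor-score
    reliability.
    """
    common = solution.loadings @ solution.factor_covariance @ solution.loadings.T
    S = solution.sample_corr
    return score_reliability(B, S, common, S)


def cronbach_alpha(items: DataMatrix) -> float:
    """Cronbach's alpha: (k/(k-1)) (1 - sum item variances / variance of sum)."""
    X = items.values
    k = X.shape[1]
    if k < 2:
        raise ValueError("need at least two item columns")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def external_correlations(scores: ScoreSet, externals: DataMatrix):
    """Score-by-criterion Pearson correlations with two-tailed significance flags.

    Returns a DataFrame of correlations and a parallel DataFrame of
    significance markers ('', '*', '**', '***' at 0.05 / 0.01 / 0.001,
    normal-approximation two-tailed tests).
    """
    import pandas as pd

    Y = scores.scores.values
    X = externals.values
    if X.shape[0] != Y.shape[0]:
        raise ValueError("scores and externals differ in N")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise ValueError(
            f"constant external column {externals.column_labels[int(np.argmin(sd))]!r}"
        )
    n = Y.shape[0]
    R = _cross_correlations(Y, X)                 # 3 x k
    z = np.arctanh(np.clip(R, -0.999999, 0.999999)) * np.sqrt(max(n - 3, 1))
    pvals = 2 * stats.norm.sf(np.abs(z))
    stars = np.select(
        [pvals < 0.001, pvals < 0.01, pvals < 0.05], ["***", "**", "*"], default=""
    )
    idx, cols = list(SCORE_NAMES), list(externals.column_labels)
    return (
        pd.DataFrame(R, index=idx, columns=cols),
        pd.DataFrame(stars, index=idx, columns=cols),
    )


def _cross_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Yc = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
    return Xc.T @ Yc / (X.shape[0] - 1)
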