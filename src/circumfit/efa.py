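"""Exploratory ML factor analysis with orthogonal partial target rotation.

A three-factor exploratory solution is rotated orthogonally toward the
ideal 8x2 circumplex pattern: only the Dominance and Love columns enter
the rotation criterion, while the general (Distress) column rides along in
the orthogonal transform without being targeted.  Congruence with the
ideal circumplex can be evaluated raw or after Kaiser normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.multivariate.factor import Factor

from .core import CircumplexPattern, kaiser_normalize, tucker_congruence
from .mcfa import FitStats, _discrepancy, fit_statistics


@dataclass(frozen=True)
class TargetSpec:
    """Partial target for orthogonal rotation.

    ``target`` holds the ideal circumplex values for the two targeted
    columns; ``mask`` marks the cells that count in the criterion; the
    column at ``untargeted_factor`` (Distress) is blind to the criterion.
    """

    target: np.ndarray                       # 8 x 2 ideal circumplex values
    mask: np.ndarray = None                  # 8 x 2 bool; default: all cells
    untargeted_factor: int = 2

    def __post_init__(self):
        t = np.atleast_2d(np.asarray(self.target, float))
        object.__setattr__(self, "target", t)
        m = self.mask
        m = np.ones(t.shape, bool) if m is None else np.asarray(m, bool)
        if m.shape != t.shape:
            raise ValueError("mask must match the targeted columns in shape")
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_pattern(cls, pattern: CircumplexPattern) -> "TargetSpec":
        return cls(target=pattern.circumplex.copy())


@dataclass(frozen=True)
class EfaSolution:
    loadings: np.ndarray
    uniquenesses: np.ndarray
    discrepancy: float
    n: int
    n_factors: int
    fit: FitStats


def efa_degrees_of_freedom(p: int, m: int) -> int:
    """Standard ML-EFA residual degrees of freedom ((p-m)^2 - (p+m)) / 2."""
    df2 = (p - m) ** 2 - (p + m)
    if df2 % 2:
        raise ValueError("degrees of freedom not integral for this p, m")
    return df2 // 2


def fit_efa_ml(corr: np.ndarray, n_factors: int, n: int) -> EfaSolution:
    """Maximum-likelihood exploratory factor analysis of a correlation matrix.

    Returns the canonical (unrotated) ML solution with chi-square fit
    statistics at the standard EFA degrees of freedom.  Heywood cases are
    floored at a uniqueness of 1e-6 with a warning.
    """
    S = np.asarray(corr, float)
    p = S.shape[0]
    if n_factors >= p:
        raise ValueError("n_factors must be smaller than the number of variables")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("input correlation matrix is not positive definite")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = Factor(corr=S, n_factor=n_factors, method="ml", smc=True, nobs=n).fit()
    lam = np.asarray(res.loadings, float)
    uniq = np.asarray(res.uniqueness, float)
    if np.any(uniq < 1e-6):
        warnings.warn("Heywood case: uniqueness floored at 1e-6", stacklevel=2)
        uniq = np.clip(uniq, 1e-6, None)
    implied = lam @ lam.T + np.diag(uniq)
    _, logdet_s = np.linalg.slogdet(S)
    disc = max(float(_discrepancy(S, implied, logdet_s)), 0.0)
    df = efa_degrees_of_freedom(p, n_factors)
    n_free = p * (p + 1) // 2 - df
    return EfaSolution(
        loadings=lam, uniquenesses=uniq, discrepancy=disc, n=n,
        n_factors=n_factors, fit=fit_statistics(disc, implied, S, n, n_free),
    )


# --------------------------------------------------------------------------
# orthogonal partial target rotation (gradient projection on O(m))

def _criterion(L_rot: np.ndarray, spec: TargetSpec, cols: np.ndarray) -> float:
    diff = (L_rot[:, cols] - spec.target) * spec.mask
    return float(np.sum(diff * diff))


def _criterion_grad(L_rot: np.ndarray, spec: TargetSpec, cols: np.ndarray) -> np.ndarray:
    G = np.zeros_like(L_rot)
    G[:, cols] = 2.0 * ((L_rot[:, cols] - spec.target) * spec.mask)
    return G


def target_rotate_partial(
    loadings: np.ndarray,
    target: TargetSpec,
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 1000,
):
    """Orthogonal rotation minimizing the masked squared distance to the target.

    Returns ``(rotated_loadings, rotation_matrix)`` with
    rotated = loadings @ rotation.  The untargeted column participates in
    the orthogonal transform but contributes nothing to the criterion, so
    communalities (row norms of the full matrix) are invariant.
    """
    A = np.asarray(loadings, float)
    m = A.shape[1]
    if np.any(np.linalg.norm(A, axis=0) < 1e-12):
        raise ValueError("degenerate loadings: zero column")
    cols = np.array([f for f in range(m) if f != target.untargeted_factor])
    if target.target.shape != (A.shape[0], cols.size):
        raise ValueError("target shape does not match the targeted columns")
    rng = np.random.default_rng(seed)
    best_T, best_q = None, np.inf
    for attempt in range(max(1, n_starts)):
        if attempt == 0:
            T = np.eye(m)
        else:
            q_, _ = np.linalg.qr(rng.standard_normal((m, m)))
            T = q_
        T, q = _gpa(A, T, target, cols, max_iter=max_iter)
        if q < best_q - 1e-14:
            best_T, best_q = T, q
    return A @ best_T, best_T


def _gpa(A, T, spec, cols, max_iter=1000, tol=1e-12):
    """Gradient projection on the orthogonal group (step-halving line search)."""
    al = 1.0
    q = _criterion(A @ T, spec, cols)
    G = A.T @ _criterion_grad(A @ T, spec, cols)
    for _ in range(max_iter):
        M = T.T @ G
        Gp = G - T @ (M + M.T) / 2.0
        s = np.linalg.norm(Gp)
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            U, _, Vt = np.linalg.svd(T - al * Gp)
            T_new = U @ Vt
            q_new = _criterion(A @ T_new, spec, cols)
            if q_new < q - 0.5 * s**2 * al * 1e-4:
                break
            al /= 2.0
        else:
            break
        T, q = T_new, q_new
        G = A.T @ _criterion_grad(A @ T, spec, cols)
    return T, q


def congruence_report(
    rotated: np.ndarray, pattern: CircumplexPattern, kaiser: bool = False
) -> dict[str, float]:
    """Tucker congruence of the rotated circumplex columns with the ideal pattern.

    With ``kaiser=True`` both loading sets are row-normalized over the two
    circumplex columns first, removing communality differences.
    """
    obs = np.asarray(rotated, float)[:, :2]
    ideal = pattern.circumplex
    if kaiser:
        obs = kaiser_normalize(obs, pattern.scale_labels)
        ideal = kaiser_normalize(ideal, pattern.scale_labels)
    return {
        "Dominance": tucker_congruence(obs[:, 0], ideal[:, 0]),
        "Love": tucker_congruence(obs[:, 1], ideal[:, 1]),
    }
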