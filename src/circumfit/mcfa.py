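"""Maximum-likelihood estimation of bi-factor circumplex covariance structures.

Fits Sigma(theta) = Lambda Phi Lambda' + Theta to a sample correlation
matrix by minimizing the normal-theory ML discrepancy

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free cells of a :class:`~circumfit.core.CircumplexPattern`:
free/prior loadings (priors are ignored under ML), the Dominance and Love
factor variances (Distress variance fixed to 1; the PA-Dominance and
LM-Love loadings fixed to 1 set the circumplex factors' scales), the
uniquenesses, and any residual covariances freed by the pattern's mask.
Uniquenesses and factor variances are log-parameterized, so Heywood cases
cannot go negative; near-zero uniquenesses are reported as warnings.

Point estimates are plain ML.  Standard errors come from the inverse
observed information; no robustness correction is applied, which would
change standard errors and chi-square scaling but not the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .core import FIXED, FREE, PRIOR, CircumplexPattern, DataMatrix


# --------------------------------------------------------------------------
# parameterization

class _Parameterization:
    """Maps between the unconstrained optimizer vector and (Lambda, Phi, Theta)."""

    def __init__(self, pattern: CircumplexPattern):
        self.pattern = pattern
        p = pattern.n_vars
        self.p = p
        self.load_cells = [
            (i, f)
            for i in range(p)
            for f in range(3)
            if pattern.cell_status[i, f] in (FREE, PRIOR)
        ]
        self.cov_pairs = [
            (i, j) for i in range(p) for j in range(i + 1, p)
            if pattern.error_covariance_mask[i, j]
        ]
        # Dominance and Love variances free (scaled by the fixed unit
        # loadings); Distress variance fixed to 1.
        self.free_factor_vars = (0, 1)
        self.n_load = len(self.load_cells)
        self.n_phi = len(self.free_factor_vars)
        self.n_free = self.n_load + self.n_phi + p + len(self.cov_pairs)

    def start(self) -> np.ndarray:
        x = np.empty(self.n_free)
        for k, (i, f) in enumerate(self.load_cells):
            x[k] = self.pattern.loading_matrix[i, f]
        x[self.n_load : self.n_load + self.n_phi] = np.log(0.4)
        x[self.n_load + self.n_phi : self.n_load + self.n_phi + self.p] = np.log(0.4)
        x[self.n_load + self.n_phi + self.p :] = 0.0
        return x

    def unpack(self, x: np.ndarray):
        p = self.p
        lam = self.pattern.loading_matrix.copy()
        for k, (i, f) in enumerate(self.load_cells):
            lam[i, f] = x[k]
        # fixed cells keep the pattern's values exactly
        phi = np.eye(3)
        for k, f in enumerate(self.free_factor_vars):
            phi[f, f] = np.exp(x[self.n_load + k])
        theta = np.diag(np.exp(x[self.n_load + self.n_phi : self.n_load + self.n_phi + p]))
        off = x[self.n_load + self.n_phi + p :]
        for k, (i, j) in enumerate(self.cov_pairs):
            theta[i, j] = theta[j, i] = off[k]
        return lam, phi, theta

    def implied(self, x: np.ndarray) -> np.ndarray:
        lam, phi, theta = self.unpack(x)
        return lam @ phi @ lam.T + theta


def _discrepancy(S, sigma, logdet_s):
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    return logdet + np.trace(np.linalg.solve(sigma, S)) - logdet_s - S.shape[0]


def _grad(par: _Parameterization, x, S):
    """Analytic gradient of F in the optimizer parameterization."""
    lam, phi, theta = par.unpack(x)
    sigma = lam @ phi @ lam.T + theta
    sigma_inv = np.linalg.inv(sigma)
    G = sigma_inv - sigma_inv @ S @ sigma_inv  # dF = tr(G dSigma)
    g = np.empty(par.n_free)
    GLP = G @ lam @ phi
    for k, (i, f) in enumerate(par.load_cells):
        g[k] = 2.0 * GLP[i, f]
    for k, f in enumerate(par.free_factor_vars):
        g[par.n_load + k] = (lam[:, f] @ G @ lam[:, f]) * phi[f, f]  # chain d/dlog
    diag_theta = np.exp(x[par.n_load + par.n_phi : par.n_load + par.n_phi + par.p])
    g[par.n_load + par.n_phi : par.n_load + par.n_phi + par.p] = np.diag(G) * diag_theta
    for k, (i, j) in enumerate(par.cov_pairs):
        g[par.n_load + par.n_phi + par.p + k] = 2.0 * G[i, j]
    return g


# --------------------------------------------------------------------------
# results containers

@dataclass(frozen=True)
class FitStats:
    """Fit statistics of a covariance-structure solution."""

    chi_square: float
    df: int
    p_value: float
    cfi: float
    srmr: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    bic: float
    gfi: float

    def as_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "srmr": self.srmr,
            "rmsea": self.rmsea,
            "rmsea_ci_low": self.rmsea_ci[0],
            "rmsea_ci_high": self.rmsea_ci[1],
            "bic": self.bic,
            "gfi": self.gfi,
        }


@dataclass(frozen=True)
class CfaSolution:
    pattern: CircumplexPattern
    loadings: np.ndarray           # p x 3, fixed cells exact
    uniquenesses: np.ndarray       # p x p: diagonal plus freed covariances
    factor_covariance: np.ndarray  # 3 x 3 diagonal
    discrepancy: float
    sample_corr: np.ndarray
    n: int
    converged: bool
    grad_norm: float
    n_free: int
    warnings: tuple[str, ...] = ()
    _par: "_Parameterization" = None
    _x: np.ndarray = None

    @property
    def implied(self) -> np.ndarray:
        return self.loadings @ self.factor_covariance @ self.loadings.T + self.uniquenesses

    def standardized_loadings(self) -> np.ndarray:
        """Loadings rescaled so factors have unit variance (completely standardized)."""
        return self.loadings * np.sqrt(np.diag(self.factor_covariance))

    def standard_errors(self) -> np.ndarray:
        """Delta-method SEs for the free parameter vector (natural units)."""
        H = _numeric_hessian(lambda v: _grad(self._par, v, self.sample_corr), self._x)
        H = (H + H.T) / 2
        cov = 2.0 / (self.n - 1) * np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        # log-parameterized entries: var(exp x) ~ exp(x)^2 var(x)
        par = self._par
        sl = slice(par.n_load, par.n_load + par.n_phi + par.p)
        se[sl] = se[sl] * np.exp(self._x[sl])
        return se

    def loading_significance(self, alpha: float = 0.001) -> dict[tuple[int, int], bool]:
        """Two-tailed normal-test flags for free loading cells."""
        se = self.standard_errors()
        out = {}
        for k, (i, f) in enumerate(self._par.load_cells):
            z = self.loadings[i, f] / se[k] if se[k] > 0 else np.inf
            out[(i, f)] = 2 * stats.norm.sf(abs(z)) < alpha
        return out


@dataclass(frozen=True)
class ModificationEntry:
    parameter: str                 # "loading:LM:Dominance" or "errcov:PA:BC"
    index: float                   # univariate score-test statistic
    epc: float                     # expected parameter change
    flagged: bool = False          # singular-information flag


# --------------------------------------------------------------------------
# fitting

def _as_corr(data_or_corr, n):
    if isinstance(data_or_corr, DataMatrix):
        return data_or_corr.correlations(), data_or_corr.n_rows
    S = np.asarray(data_or_corr, float)
    if n is None:
        raise ValueError("n is required when passing a correlation matrix")
    return S, n


def fit_mcfa(
    data_or_corr,
    pattern: CircumplexPattern,
    n: int | None = None,
    n_starts: int = 3,
    gtol: float = 1e-7,
    seed: int = 0,
) -> CfaSolution:
    """Fit the bi-factor circumplex model by maximum likelihood.

    Accepts a (standardized) :class:`DataMatrix` or a correlation matrix
    with ``n``.  Retries from jittered starting points if the gradient
    norm at the first optimum exceeds ``gtol``.
    """
    S, n = _as_corr(data_or_corr, n)
    p = S.shape[0]
    if p != pattern.n_vars:
        raise ValueError("pattern and data disagree on the number of variables")
    if np.linalg.eigvalsh(S).min() <= 1e-10:
        raise ValueError("input matrix is not positive definite")
    sign, logdet_s = np.linalg.slogdet(S)

    par = _Parameterization(pattern)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max(1, n_starts)):
        x0 = par.start()
        if attempt:
            x0 = x0 + rng.normal(0, 0.1, size=x0.size)
        res = optimize.minimize(
            lambda v: _discrepancy(S, par.implied(v), logdet_s),
            x0,
            jac=lambda v: _grad(par, v, S),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        gn = float(np.max(np.abs(_grad(par, res.x, S))))
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gn)
        if gn < gtol:
            best = (res, gn)
            break
    res, gn = best
    lam, phi, theta = par.unpack(res.x)
    warns = []
    if gn >= gtol:
        warns.append(f"gradient norm {gn:.2e} above tolerance {gtol:g}")
    small = np.flatnonzero(np.diag(theta) < 1e-4)
    for i in small:
        warns.append(f"near-zero uniqueness for {pattern.scale_labels[i]} (boundary solution)")
    return CfaSolution(
        pattern=pattern,
        loadings=lam,
        uniquenesses=theta,
        factor_covariance=phi,
        discrepancy=max(float(res.fun), 0.0),
        sample_corr=S,
        n=n,
        converged=gn < gtol,
        grad_norm=gn,
        n_free=par.n_free,
        warnings=tuple(warns),
        _par=par,
        _x=res.x,
    )


# --------------------------------------------------------------------------
# fit indices

def _baseline_chi_square(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model baseline: Sigma_b = diag(S)."""
    p = S.shape[0]
    f_b = float(np.linalg.slogdet(np.diag(np.diag(S)))[1] - np.linalg.slogdet(S)[1])
    return (n - 1) * f_b, p * (p - 1) // 2


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    lo_p, hi_p = (1 + level) / 2, (1 - level) / 2

    def _solve(target):
        if stats.ncx2.cdf(chi2, df, 1e-10) < target:
            return 0.0
        hi = max(chi2 * 10, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2
        return optimize.brentq(lambda nc: stats.ncx2.cdf(chi2, df, nc) - target, 1e-10, hi)

    lam_lo, lam_hi = _solve(lo_p), _solve(hi_p)
    denom = df * (n - 1)
    return float(np.sqrt(lam_lo / denom)), float(np.sqrt(lam_hi / denom))


def fit_statistics(
    discrepancy: float, implied: np.ndarray, S: np.ndarray, n: int, n_free: int
) -> FitStats:
    """Chi-square and descriptive fit indices for any covariance-structure fit."""
    p = S.shape[0]
    df = p * (p + 1) // 2 - n_free
    chi2 = max((n - 1) * discrepancy, 0.0)
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    chi2_b, df_b = _baseline_chi_square(S, n)
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0 else float(np.clip(1.0 - num / den, 0.0, 1.0))
    d = np.sqrt(np.diag(S))
    resid = (S - implied) / np.outer(d, d)
    iu = np.triu_indices(p)
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    if df > 0:
        rmsea = float(np.sqrt(num / (df * (n - 1))))
        ci = _rmsea_ci(chi2, df, n)
    else:
        rmsea, ci = float("nan"), (float("nan"), float("nan"))
    bic = chi2 - df * np.log(n)
    sigma_inv_s = np.linalg.solve(implied, S)
    gfi = float(
        1.0
        - np.trace((sigma_inv_s - np.eye(p)) @ (sigma_inv_s - np.eye(p)))
        / np.trace(sigma_inv_s @ sigma_inv_s)
    )
    return FitStats(chi2, df, p_value, cfi, srmr, rmsea, ci, float(bic), gfi)


def fit_indices(solution: CfaSolution) -> FitStats:
    return fit_statistics(
        solution.discrepancy, solution.implied, solution.sample_corr, solution.n,
        solution.n_free,
    )


# --------------------------------------------------------------------------
# modification indices

def _numeric_hessian(grad_fn, x, eps=1e-5):
    n = x.size
    H = np.empty((n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = eps
        H[:, k] = (grad_fn(x + e) - grad_fn(x - e)) / (2 * eps)
    return (H + H.T) / 2


def modification_indices(
    solution: CfaSolution, threshold: float | None = None
) -> list[ModificationEntry]:
    """Univariate score tests (Lagrange multipliers) for constrained parameters.

    Candidates are every fixed loading cell except the two scaling cells
    and every error covariance not already freed.  The index estimates the
    chi-square drop from freeing the single parameter; the expected
    parameter change (EPC) is the signed value it would move to.  Entries
    are sorted by index, largest first; ``threshold`` keeps only entries
    above it.
    """
    pat, par = solution.pattern, solution._par
    S, n = solution.sample_corr, solution.n
    p = par.p
    cand: list[tuple[str, tuple]] = []
    for i in range(p):
        for f in range(2):
            if pat.cell_status[i, f] == FIXED and not pat._is_scaling_cell(i, f):
                cand.append((f"loading:{pat.scale_labels[i]}:{['Dominance', 'Love'][f]}",
                             ("load", i, f)))
    for i in range(p):
        for j in range(i + 1, p):
            if not pat.error_covariance_mask[i, j]:
                cand.append((f"errcov:{pat.scale_labels[i]}:{pat.scale_labels[j]}",
                             ("cov", i, j)))
    if not cand:
        return []

    # Extended gradient: optimizer vector plus every candidate (natural units).
    def ext_grad(v):
        x, extra = v[: par.n_free], v[par.n_free :]
        lam, phi, theta = par.unpack(x)
        for val, (_, spec) in zip(extra, cand):
            kind, i, jf = spec
            if kind == "load":
                lam = lam.copy()
                lam[i, jf] = lam[i, jf] + val
            else:
                theta = theta.copy()
                theta[i, jf] += val
                theta[jf, i] += val
        sigma = lam @ phi @ lam.T + theta
        sigma_inv = np.linalg.inv(sigma)
        G = sigma_inv - sigma_inv @ S @ sigma_inv
        g = np.empty(v.size)
        GLP = G @ lam @ phi
        for k, (i, f) in enumerate(par.load_cells):
            g[k] = 2.0 * GLP[i, f]
        for k, f in enumerate(par.free_factor_vars):
            g[par.n_load + k] = (lam[:, f] @ G @ lam[:, f]) * phi[f, f]
        dth = np.exp(x[par.n_load + par.n_phi : par.n_load + par.n_phi + p])
        g[par.n_load + par.n_phi : par.n_load + par.n_phi + p] = np.diag(G) * dth
        for k, (i, j) in enumerate(par.cov_pairs):
            g[par.n_load + par.n_phi + p + k] = 2.0 * G[i, j]
        for k, (_, spec) in enumerate(cand):
            kind, i, jf = spec
            g[par.n_free + k] = 2.0 * GLP[i, jf] if kind == "load" else 2.0 * G[i, jf]
        return g

    v0 = np.concatenate([solution._x, np.zeros(len(cand))])
    g0 = ext_grad(v0)
    H = _numeric_hessian(ext_grad, v0)
    Htt = H[: par.n_free, : par.n_free]
    try:
        Htt_inv = np.linalg.inv(Htt)
        singular_base = False
    except np.linalg.LinAlgError:
        Htt_inv = np.linalg.pinv(Htt)
        singular_base = True
    out = []
    for k, (name, _) in enumerate(cand):
        idx = par.n_free + k
        gc, hcc = g0[idx], H[idx, idx]
        hct = H[idx, : par.n_free]
        h_adj = hcc - hct @ Htt_inv @ hct
        if h_adj <= 1e-10:
            out.append(ModificationEntry(name, 0.0, 0.0, flagged=True))
            continue
        mi = (n - 1) / 2.0 * gc * gc / h_adj
        epc = -gc / h_adj
        out.append(ModificationEntry(name, float(max(mi, 0.0)), float(epc),
                                     flagged=singular_base))
    out.sort(key=lambda e: -e.index)
    if threshold is not None:
        out = [e for e in out if e.index > threshold]
    return out


def select_error_covariances(
    entries: list[ModificationEntry], threshold: float = 10.0
) -> list[tuple[str, str]]:
    """Error-covariance pairs whose modification index exceeds the threshold."""
    pairs = []
    for e in entries:
        if e.parameter.startswith("errcov:") and e.index > threshold:
            _, a, b = e.parameter.split(":")
            pairs.append((a, b))
    return pairs


# --------------------------------------------------------------------------
# factor scores and external criteria

def regression_score_weights(solution: CfaSolution) -> np.ndarray:
    """Regression (Thurstone) factor-score weights W = Sigma^-1 Lambda Phi.

    Scores obtained as standardized data times W have the maximal
    correlation of any linear combination of the observed variables with
    the corresponding factor.
    """
    sigma = solution.implied
    try:
        return np.linalg.solve(sigma, solution.loadings @ solution.factor_covariance)
    except np.linalg.LinAlgError as err:
        raise ValueError("implied covariance matrix is singular") from err


def extend_with_external(
    pattern: CircumplexPattern, external_labels, start: float = 0.3
) -> CircumplexPattern:
    """Append external-criterion rows with all three loadings free."""
    labels = list(external_labels)
    dup = set(labels) & set(pattern.scale_labels)
    if dup or len(set(labels)) != len(labels):
        raise ValueError(f"duplicate labels: {sorted(dup) or labels}")
    k = len(labels)
    p = pattern.n_vars
    loads = np.vstack([pattern.loading_matrix, np.full((k, 3), start)])
    status = np.vstack([pattern.cell_status, np.full((k, 3), FREE, dtype=object)])
    mask = np.zeros((p + k, p + k), bool)
    mask[:p, :p] = pattern.error_covariance_mask
    return replace(
        pattern,
        scale_labels=tuple(pattern.scale_labels) + tuple(labels),
        loading_matrix=loads,
        cell_status=status,
        error_covariance_mask=mask,
    )


def drop_external(pattern: CircumplexPattern, external_labels) -> CircumplexPattern:
    """Remove previously appended external rows, restoring the octant pattern."""
    keep = [i for i, l in enumerate(pattern.scale_labels) if l not in set(external_labels)]
    return replace(
        pattern,
        scale_labels=tuple(pattern.scale_labels[i] for i in keep),
        loading_matrix=pattern.loading_matrix[keep],
        cell_status=pattern.cell_status[keep],
        error_covariance_mask=pattern.error_covariance_mask[np.ix_(keep, keep)],
    )
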