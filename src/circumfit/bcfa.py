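"""Bayesian estimation of the bi-factor circumplex model by Gibbs sampling.

Circumplex loadings carry normal priors centered on the ideal circumplex
values with a small prior variance (default sigma^2 = 0.01), so the
posterior can move loadings away from perfect circumplexity exactly as far
as the data warrant.  Distress loadings are free (diffuse normal priors),
uniquenesses carry inverse-gamma priors, the Dominance and Love factor
variances are free (the PA-Dominance and LM-Love loadings are fixed to 1
for scaling), and the Distress variance is fixed to 1.

The sampler is a blocked Gibbs scheme:

1. factor scores given loadings, factor variances, and residual covariance
   (joint multivariate normal across the three factors);
2. all free/prior loading cells jointly given factor scores (conjugate
   normal; exact also when residual covariances are freed);
3. uniquenesses given residuals (conjugate inverse-gamma when the residual
   covariance is diagonal; random-walk Metropolis otherwise);
4. freed residual covariances given residuals (random-walk Metropolis with
   the normal prior, positive-definiteness enforced);
5. Dominance/Love factor variances given factor scores (conjugate
   inverse-gamma).

Chains run in parallel batches until the maximum Gelman-Rubin potential
scale reduction (PSR) over all sampled parameters, evaluated on the second
half of each chain, drops to the target (default 1.001) or an iteration
cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import FIXED, FREE, PRIOR, CircumplexPattern, DataMatrix
from .mcfa import FitStats, _baseline_chi_square, _discrepancy

FACTOR_NAMES = ("Dominance", "Love", "Distress")


@dataclass(frozen=True)
class BcfaConfig:
    """Sampler and prior settings for the Bayesian circumplex CFA."""

    loading_prior_variance: float = 0.01     # sigma^2 of circumplex-loading priors
    free_loading_prior_variance: float = 100.0
    uniqueness_prior: tuple[float, float] = (0.001, 0.001)  # inverse-gamma shape/scale
    error_cov_prior_variance: float = 0.01
    factor_var_prior: tuple[float, float] = (0.001, 0.001)
    chains: int = 2
    seed: int = 0
    psr_target: float = 1.001
    thin: int = 1
    burn_in_fraction: float = 0.5
    max_iterations: int = 100_000
    min_iterations: int = 2_000
    check_every: int = 1_000

    def __post_init__(self):
        if self.loading_prior_variance <= 0:
            raise ValueError("loading prior variance must be positive")
        if self.chains < 2:
            raise ValueError("need at least two chains for PSR monitoring")
        if not 0 < self.burn_in_fraction < 1:
            raise ValueError("burn-in fraction must be in (0, 1)")


def psr(draws: np.ndarray) -> np.ndarray:
    """Gelman-Rubin potential scale reduction per parameter.

    ``draws`` has shape (chains, iterations, parameters); the statistic is
    computed from the second half of each chain.  Parameters with zero
    within-chain variance get PSR = inf (flagged, not fatal).
    """
    draws = np.asarray(draws, float)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("need draws of shape (chains >= 2, iterations, parameters)")
    half = draws[:, draws.shape[1] // 2 :, :]
    if half.shape[1] < 10:
        raise ValueError("need at least 10 retained iterations per chain")
    L = half.shape[1]
    W = half.var(axis=1, ddof=1).mean(axis=0)
    B = L * half.mean(axis=1).var(axis=0, ddof=1)
    out = np.full(W.shape, np.inf)
    ok = W > 0
    # the pooled-variance estimator (L-1)/L W + B/L undershoots the true
    # variance when chains coincide; report the conventional floor of 1
    out[ok] = np.maximum(np.sqrt((L - 1) / L + B[ok] / (L * W[ok])), 1.0)
    return out


@dataclass(frozen=True)
class BcfaPosterior:
    """Joint posterior of the Bayesian circumplex CFA."""

    pattern: CircumplexPattern
    config: BcfaConfig
    param_names: tuple[str, ...]
    draws: np.ndarray            # (chains, iterations, parameters), burn-in included
    n: int
    sample_corr: np.ndarray
    psr_trace: tuple[tuple[int, float], ...]
    max_psr: float
    converged: bool

    def retained(self) -> np.ndarray:
        """Post-burn-in draws of all chains stacked, thinned per the config."""
        start = int(self.draws.shape[1] * self.config.burn_in_fraction)
        kept = self.draws[:, start :: self.config.thin, :]
        return kept.reshape(-1, kept.shape[-1])

    def summary(self):
        import pandas as pd

        kept = self.retained()
        med = np.median(kept, axis=0)
        lo, hi = np.percentile(kept, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {"median": med, "ci_low": lo, "ci_high": hi,
             "mean": kept.mean(axis=0), "sd": kept.std(axis=0, ddof=1)},
            index=list(self.param_names),
        )

    def median_loadings(self) -> np.ndarray:
        """Posterior-median p x 3 loading matrix (fixed cells at their values)."""
        lam = self.pattern.loading_matrix.copy()
        lam[self.pattern.cell_status == FIXED] = self.pattern.loading_matrix[
            self.pattern.cell_status == FIXED
        ]
        med = np.median(self.retained(), axis=0)
        for name, value in zip(self.param_names, med):
            if name.startswith("lambda:"):
                _, lbl, fac = name.split(":")
                lam[self.pattern.scale_labels.index(lbl), FACTOR_NAMES.index(fac)] = value
        return lam

    def median_parameters(self):
        """Posterior-median (Lambda, Phi, Theta)."""
        med = dict(zip(self.param_names, np.median(self.retained(), axis=0)))
        return _build_matrices(self.pattern, self.param_names, np.median(self.retained(), axis=0))

    def standardized_median_loadings(self) -> np.ndarray:
        lam, phi, _ = self.median_parameters()
        return lam * np.sqrt(np.diag(phi))


def _param_index(pattern: CircumplexPattern):
    """Names and index maps for all sampled parameters."""
    names, load_cells, cov_pairs = [], [], []
    p = pattern.n_vars
    for i in range(p):
        for f in range(3):
            if pattern.cell_status[i, f] in (FREE, PRIOR):
                load_cells.append((i, f))
                names.append(f"lambda:{pattern.scale_labels[i]}:{FACTOR_NAMES[f]}")
    names += [f"theta:{l}" for l in pattern.scale_labels]
    names += ["phi:Dominance", "phi:Love"]
    for i in range(p):
        for j in range(i + 1, p):
            if pattern.error_covariance_mask[i, j]:
                cov_pairs.append((i, j))
                names.append(f"errcov:{pattern.scale_labels[i]}:{pattern.scale_labels[j]}")
    return tuple(names), load_cells, cov_pairs


def _build_matrices(pattern: CircumplexPattern, names, values):
    lam = pattern.loading_matrix.copy()
    p = pattern.n_vars
    theta = np.zeros((p, p))
    phi = np.eye(3)
    for name, v in zip(names, values):
        kind, rest = name.split(":", 1)
        if kind == "lambda":
            lbl, fac = rest.split(":")
            lam[pattern.scale_labels.index(lbl), FACTOR_NAMES.index(fac)] = v
        elif kind == "theta":
            i = pattern.scale_labels.index(rest)
            theta[i, i] = v
        elif kind == "phi":
            phi[FACTOR_NAMES.index(rest), FACTOR_NAMES.index(rest)] = v
        elif kind == "errcov":
            a, b = rest.split(":")
            i, j = pattern.scale_labels.index(a), pattern.scale_labels.index(b)
            theta[i, j] = theta[j, i] = v
    return lam, phi, theta


class _GibbsChain:
    def __init__(self, X, pattern, config, load_cells, cov_pairs, rng, overdispersion,
                 warm_start=None):
        self.X = X
        self.n, self.p = X.shape
        self.pattern = pattern
        self.cfg = config
        self.load_cells = load_cells
        self.cov_pairs = cov_pairs
        self.rng = rng
        # prior means/variances per sampled loading cell
        self.prior_mean = np.array(
            [
                pattern.loading_matrix[i, f] if pattern.cell_status[i, f] == PRIOR else 0.0
                for (i, f) in load_cells
            ]
        )
        self.prior_var = np.array(
            [
                config.loading_prior_variance
                if pattern.cell_status[i, f] == PRIOR
                else config.free_loading_prior_variance
                for (i, f) in load_cells
            ]
        )
        # fixed part of Lambda
        self.lam_fix = pattern.loading_matrix.copy()
        for (i, f) in load_cells:
            self.lam_fix[i, f] = 0.0
        self.ji = np.array([i for (i, _) in load_cells])
        self.fi = np.array([f for (_, f) in load_cells])
        if warm_start is not None:
            # start at a fitted ML solution (tiny jitter keeps chains distinct)
            lam0, phi0, theta0 = warm_start
            self.lam_val = lam0[self.ji, self.fi] + rng.normal(0, 0.01, len(load_cells))
            self.theta_diag = np.clip(np.diag(theta0), 1e-3, None)
            self.theta_off = np.array([theta0[i, j] for (i, j) in cov_pairs])
            self.phi = np.clip(np.diag(phi0)[:2], 1e-3, None)
        else:
            # overdispersed starting values
            self.lam_val = self.prior_mean + rng.normal(
                0, 0.2 * overdispersion, len(load_cells)
            )
            self.theta_diag = np.exp(rng.normal(np.log(0.4), 0.3 * overdispersion, self.p))
            self.theta_off = np.zeros(len(cov_pairs))
            self.phi = np.exp(rng.normal(np.log(0.35), 0.3 * overdispersion, 2))
        self.mh_scale_diag = 0.1
        self.mh_scale_off = 0.05

    # -- matrix assembly ---------------------------------------------------
    def lam(self):
        L = self.lam_fix.copy()
        L[self.ji, self.fi] = self.lam_val
        return L

    def theta(self):
        T = np.diag(self.theta_diag)
        for k, (i, j) in enumerate(self.cov_pairs):
            T[i, j] = T[j, i] = self.theta_off[k]
        return T

    def phi_mat(self):
        return np.diag([self.phi[0], self.phi[1], 1.0])

    def state(self):
        return np.concatenate([self.lam_val, self.theta_diag, self.phi, self.theta_off])

    # -- Gibbs blocks ------------------------------------------------------
    def sample_factors(self) -> np.ndarray:
        """(i) factor scores | loadings, factor variances, residual covariance."""
        lam, theta, phi = self.lam(), self.theta(), self.phi_mat()
        theta_inv = np.linalg.inv(theta)
        M = lam.T @ theta_inv @ lam + np.linalg.inv(phi)
        cov = np.linalg.inv(M)
        mean = self.X @ (theta_inv @ lam) @ cov
        return mean + self.rng.standard_normal((self.n, 3)) @ np.linalg.cholesky(cov).T

    def loading_conditional(self, F: np.ndarray):
        """Mean and precision of the joint conditional of all sampled loading cells.

        The conditional is exact also for non-diagonal residual covariance:
        the precision of cells (j, f), (k, g) is (Theta^-1)_jk (F'F)_fg.
        """
        theta_inv = np.linalg.inv(self.theta())
        FtF = F.T @ F
        resid_fix = self.X - F @ self.lam_fix.T
        Bmat = theta_inv @ resid_fix.T @ F          # p x 3
        prec = theta_inv[np.ix_(self.ji, self.ji)] * FtF[np.ix_(self.fi, self.fi)]
        prec = prec + np.diag(1.0 / self.prior_var)
        b = Bmat[self.ji, self.fi] + self.prior_mean / self.prior_var
        return np.linalg.solve(prec, b), prec

    def sample_loadings(self, F: np.ndarray) -> None:
        """(ii) all free/prior loading cells jointly | factor scores."""
        mean_l, prec = self.loading_conditional(F)
        chol = np.linalg.cholesky(prec)
        z = self.rng.standard_normal(mean_l.size)
        self.lam_val = mean_l + np.linalg.solve(chol.T, z)
        # The Distress column (free loadings, variance fixed to 1) is
        # identified only up to a joint sign flip; relabel draws onto the
        # positive-sum mode.  Valid because the posterior is symmetric
        # under (Lambda_3, f_3) -> (-Lambda_3, -f_3).
        distress = self.fi == 2
        if np.any(distress) and self.lam_val[distress].sum() < 0:
            self.lam_val = np.where(distress, -self.lam_val, self.lam_val)

    def sample_residual_covariance(self, E: np.ndarray) -> None:
        """(iii)/(iv) uniquenesses and freed covariances | residuals."""
        a0, b0 = self.cfg.uniqueness_prior
        if not self.cov_pairs:
            ss = np.sum(E * E, axis=0)
            self.theta_diag = 1.0 / self.rng.gamma(a0 + self.n / 2, 1.0 / (b0 + ss / 2))
        else:
            self._metropolis_theta(E)

    def sample_factor_variances(self, F: np.ndarray) -> None:
        """(v) free Dominance/Love variances | factor scores."""
        av, bv = self.cfg.factor_var_prior
        ssf = np.sum(F[:, :2] ** 2, axis=0)
        self.phi = 1.0 / self.rng.gamma(av + self.n / 2, 1.0 / (bv + ssf / 2))

    def step(self):
        F = self.sample_factors()
        self.sample_loadings(F)
        E = self.X - F @ self.lam().T
        self.sample_residual_covariance(E)
        self.sample_factor_variances(F)

    def _metropolis_theta(self, E):
        """Random-walk Metropolis sweep over Theta when covariances are freed."""
        EtE = E.T @ E
        a0, b0 = self.cfg.uniqueness_prior
        v_c = self.cfg.error_cov_prior_variance

        def logpost(diag, off):
            T = np.diag(diag)
            for k, (i, j) in enumerate(self.cov_pairs):
                T[i, j] = T[j, i] = off[k]
            sign, logdet = np.linalg.slogdet(T)
            if sign <= 0:
                return -np.inf
            ll = -0.5 * self.n * logdet - 0.5 * np.trace(np.linalg.solve(T, EtE))
            lp = np.sum(-(a0 + 1) * np.log(diag) - b0 / diag)
            lp += np.sum(-0.5 * off**2 / v_c)
            return ll + lp

        cur = logpost(self.theta_diag, self.theta_off)
        for k in range(self.p):
            prop = self.theta_diag.copy()
            prop[k] *= np.exp(self.rng.normal(0, self.mh_scale_diag))
            new = logpost(prop, self.theta_off) + np.log(prop[k] / self.theta_diag[k])
            if np.log(self.rng.uniform()) < new - cur:
                self.theta_diag, cur = prop, logpost(prop, self.theta_off)
        for k in range(len(self.cov_pairs)):
            prop = self.theta_off.copy()
            prop[k] += self.rng.normal(0, self.mh_scale_off)
            new = logpost(self.theta_diag, prop)
            if np.log(self.rng.uniform()) < new - cur:
                self.theta_off, cur = prop, new


def fit_bcfa(
    data: DataMatrix,
    pattern: CircumplexPattern,
    config: BcfaConfig | None = None,
    warm_start=None,
) -> BcfaPosterior:
    """Run the blocked Gibbs sampler until PSR convergence or the iteration cap.

    ``pattern`` should carry prior cells (see
    :meth:`CircumplexPattern.with_priors`); a pattern whose circumplex
    cells are all fixed is converted automatically using the config's
    loading prior variance.

    ``warm_start`` optionally takes a fitted :class:`~circumfit.mcfa.CfaSolution`
    (or a ``(loadings, factor_covariance, residual_covariance)`` triple) and
    initializes every chain at those values with small jitter.  Useful for
    diffuse loading priors, where the posterior is well concentrated but
    Gibbs mixing along the soft factor-rotation ridge is extremely slow
    from overdispersed starts.
    """
    config = config or BcfaConfig()
    if not np.any(pattern.cell_status == PRIOR) and np.any(pattern.cell_status[:8, :2] == FIXED):
        pattern = pattern.with_priors(config.loading_prior_variance)
    elif np.any(pattern.cell_status == PRIOR):
        pattern = pattern.with_priors(config.loading_prior_variance)
    X = np.asarray(data.values, float)
    names, load_cells, cov_pairs = _param_index(pattern)
    if warm_start is not None and hasattr(warm_start, "loadings"):
        warm_start = (
            warm_start.loadings, warm_start.factor_covariance, warm_start.uniquenesses
        )
    master = np.random.default_rng(config.seed)
    chains = [
        _GibbsChain(
            X, pattern, config, load_cells, cov_pairs,
            np.random.default_rng(master.integers(2**31)), overdispersion=1.0 + c,
            warm_start=warm_start,
        )
        for c in range(config.chains)
    ]
    store = [[] for _ in chains]
    psr_trace: list[tuple[int, float]] = []
    total = 0
    converged = False
    max_psr = np.inf
    while total < config.max_iterations:
        batch = min(config.check_every, config.max_iterations - total)
        for c, chain in enumerate(chains):
            block = np.empty((batch, len(names)))
            for t in range(batch):
                chain.step()
                block[t] = chain.state()
            store[c].append(block)
        total += batch
        draws = np.stack([np.concatenate(s, axis=0) for s in store])
        if total >= max(config.min_iterations, 20):
            max_psr = float(np.max(psr(draws)))
            psr_trace.append((total, max_psr))
            if max_psr <= config.psr_target:
                converged = True
                break
    draws = np.stack([np.concatenate(s, axis=0) for s in store])
    return BcfaPosterior(
        pattern=pattern,
        config=config,
        param_names=names,
        draws=draws,
        n=X.shape[0],
        sample_corr=np.corrcoef(X, rowvar=False),
        psr_trace=tuple(psr_trace),
        max_psr=max_psr,
        converged=converged,
    )


# --------------------------------------------------------------------------
# posterior predictive checking and Bayesian fit indices

@dataclass(frozen=True)
class PosteriorPredictive:
    """Likelihood-ratio discrepancies of observed and replicated data per draw."""

    observed: np.ndarray
    replicated: np.ndarray
    p_value: float
    difference_interval: tuple[float, float]   # central 95% of observed - replicated

    @property
    def differences(self) -> np.ndarray:
        return self.observed - self.replicated


def posterior_predictive_check(
    posterior: BcfaPosterior,
    data: DataMatrix,
    n_draws: int = 200,
    seed: int = 0,
) -> PosteriorPredictive:
    """Chi-square-based posterior predictive check.

    For each retained draw, the likelihood-ratio discrepancy (n-1) * F of
    the observed correlation matrix under the drawn parameters is compared
    with that of a dataset of the same size replicated from the draw; the
    p-value is the proportion of draws whose replicated discrepancy is at
    least the observed one.  Near 0.5 indicates a well-calibrated model.
    """
    rng = np.random.default_rng(seed)
    kept = posterior.retained()
    idx = np.linspace(0, len(kept) - 1, min(n_draws, len(kept))).astype(int)
    X = np.asarray(data.values, float)
    n = X.shape[0]
    S_obs = np.cov(X, rowvar=False)
    _, logdet_obs = np.linalg.slogdet(S_obs)
    d_obs = np.empty(idx.size)
    d_rep = np.empty(idx.size)
    for k, t in enumerate(idx):
        lam, phi, theta = _build_matrices(posterior.pattern, posterior.param_names, kept[t])
        sigma = lam @ phi @ lam.T + theta
        d_obs[k] = (n - 1) * _discrepancy(S_obs, sigma, logdet_obs)
        chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(sigma.shape[0]))
        Xr = rng.standard_normal((n, sigma.shape[0])) @ chol.T
        S_rep = np.cov(Xr, rowvar=False)
        _, logdet_rep = np.linalg.slogdet(S_rep)
        d_rep[k] = (n - 1) * _discrepancy(S_rep, sigma, logdet_rep)
    diffs = d_obs - d_rep
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return PosteriorPredictive(
        observed=d_obs,
        replicated=d_rep,
        p_value=float(np.mean(d_rep >= d_obs)),
        difference_interval=(float(lo), float(hi)),
    )


@dataclass(frozen=True)
class BayesFitIndices:
    cfi: float
    cfi_interval: tuple[float, float]
    rmsea: float
    rmsea_interval: tuple[float, float]
    cfi_draws: np.ndarray
    rmsea_draws: np.ndarray


def bayes_fit_indices(
    posterior: BcfaPosterior,
    data: DataMatrix,
    ppc: PosteriorPredictive | None = None,
    seed: int = 0,
) -> BayesFitIndices:
    """Posterior CFI and RMSEA analogues.

    Per draw, the excess of observed over replicated discrepancy acts as a
    noncentrality estimate; RMSEA and CFI are built from it as in their
    frequentist counterparts and summarized by the median and a central
    90% interval.
    """
    if ppc is None:
        ppc = posterior_predictive_check(posterior, data, seed=seed)
    n, p = posterior.n, posterior.sample_corr.shape[0]
    df = p * (p + 1) // 2 - len(posterior.param_names)
    df = max(df, 1)
    chi2_b, df_b = _baseline_chi_square(np.corrcoef(data.values, rowvar=False), n)
    excess = np.clip(ppc.differences, 0.0, None)
    rmsea_d = np.sqrt(excess / (df * (n - 1)))
    cfi_d = np.clip(1.0 - excess / max(chi2_b - df_b, 1e-12), 0.0, 1.0)
    r_lo, r_hi = np.percentile(rmsea_d, [5, 95])
    c_lo, c_hi = np.percentile(cfi_d, [5, 95])
    return BayesFitIndices(
        cfi=float(np.median(cfi_d)),
        cfi_interval=(float(c_lo), float(c_hi)),
        rmsea=float(np.median(rmsea_d)),
        rmsea_interval=(float(r_lo), float(r_hi)),
        cfi_draws=cfi_d,
        rmsea_draws=rmsea_d,
    )


def credible_significance(
    posterior: BcfaPosterior, level: float = 0.95
) -> dict[str, bool]:
    """Flag loading and error-covariance parameters whose central credible
    interval excludes zero.  Fixed parameters are not sampled and never appear."""
    kept = posterior.retained()
    alpha = (1 - level) / 2 * 100
    lo, hi = np.percentile(kept, [alpha, 100 - alpha], axis=0)
    return {
        name: bool(l > 0 or h < 0)
        for name, l, h in zip(posterior.param_names, lo, hi)
        if name.startswith(("lambda:", "errcov:"))
    }
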