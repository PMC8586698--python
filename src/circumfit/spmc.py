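"""Circular stochastic process model (SPMC) for octant correlation matrices.

The SPMC represents the correlation between two scales i and j as

    r_ij = v_i * v_j * rho_c(theta_i - theta_j),

where v_i in (0, 1] is scale i's communality root (its radius in the
circle), theta_i its circular angle, and rho_c a Fourier-series
correlation function

    rho_c(d) = sum_{k=0..m} beta_k * cos(k d),   beta_k >= 0, sum beta_k = 1,

so that rho_c(0) = 1 and |rho_c| <= 1 everywhere.  Equality constraints can
be imposed separately on the spacing (equal = fixed 45-degree displacements)
and on the communalities (equal radius), giving the three model variants
conventionally compared: equal/equal, free spacing with equal communality,
and free/free.

Estimation minimizes the normal-theory ML discrepancy between the observed
and implied correlation structure; beta is parameterized by a softmax,
communality roots by a logistic transform, and angles as unconstrained
reals wrapped modulo 360 with LM pinned at zero.  The reflection
indeterminacy is resolved by orienting NO into (0, 180) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core import IDEAL_ANGLES, OCTANTS, AngleSet
from .mcfa import FitStats, _discrepancy, fit_statistics


@dataclass(frozen=True)
class SpmcSolution:
    angles: AngleSet
    communality_roots: np.ndarray      # v_i in (0, 1]
    betas: np.ndarray                  # beta_0..beta_m, >= 0, sum 1
    spacing: str                       # "equal" | "free"
    communalities: str                 # "equal" | "free"
    implied: np.ndarray
    discrepancy: float
    n: int
    fit: FitStats
    minimum_correlation: float         # min of rho_c over [0, 180] degrees
    minimum_correlation_angle: float
    provenance: str = "raw"
    converged: bool = True

    def correlation_function(self, angle_deg) -> np.ndarray:
        return correlation_function(self.betas, angle_deg)


def correlation_function(betas: np.ndarray, angle_deg) -> np.ndarray:
    """Evaluate rho_c(d) = sum_k beta_k cos(k d) at angles in degrees."""
    betas = np.asarray(betas, float)
    d = np.deg2rad(np.asarray(angle_deg, float))
    k = np.arange(betas.size)
    return np.cos(np.multiply.outer(d, k)) @ betas


def common_score_correlation(solution: SpmcSolution, angle_deg: float) -> float:
    """rho_c at one angular separation (degrees)."""
    return float(correlation_function(solution.betas, angle_deg))


def _minimum_correlation(betas, resolution=0.1):
    grid = np.arange(0.0, 180.0 + resolution, resolution)
    vals = correlation_function(betas, grid)
    k = int(np.argmin(vals))
    lo, hi = max(grid[k] - resolution, 0.0), min(grid[k] + resolution, 180.0)
    res = optimize.minimize_scalar(
        lambda a: float(correlation_function(betas, a)), bounds=(lo, hi), method="bounded"
    )
    if res.fun < vals[k]:
        return float(res.fun), float(res.x)
    return float(vals[k]), float(grid[k])


class _SpmcParam:
    """Unconstrained parameter vector <-> (angles, v, beta)."""

    def __init__(self, spacing: str, communalities: str, m: int, labels=OCTANTS):
        self.spacing, self.comm, self.m = spacing, communalities, m
        self.p = len(labels)
        self.labels = labels
        self.n_ang = self.p - 1 if spacing == "free" else 0
        self.n_v = self.p if communalities == "free" else 1
        self.n_free = self.n_ang + self.n_v + m

    def unpack(self, x):
        if self.spacing == "free":
            angles = np.concatenate([[0.0], np.mod(x[: self.n_ang], 360.0)])
        else:
            angles = np.asarray(IDEAL_ANGLES[: self.p], float)
        raw_v = x[self.n_ang : self.n_ang + self.n_v]
        v = 1.0 / (1.0 + np.exp(-raw_v))
        if self.comm == "equal":
            v = np.full(self.p, v[0])
        logits = np.concatenate([[0.0], x[self.n_ang + self.n_v :]])
        e = np.exp(logits - logits.max())
        betas = e / e.sum()
        return angles, v, betas

    def start(self, rng=None):
        x = np.empty(self.n_free)
        ang0 = np.asarray(IDEAL_ANGLES[1 : self.p], float)
        if self.spacing == "free":
            x[: self.n_ang] = ang0
        x[self.n_ang : self.n_ang + self.n_v] = np.log(0.8 / 0.2)  # v ~ 0.8
        x[self.n_ang + self.n_v :] = -np.arange(1, self.m + 1) * 0.8
        if rng is not None:
            x = x + rng.normal(0, [10.0] * self.n_ang + [0.5] * (self.n_v + self.m))
        return x


def implied_spmc(angles_deg, v, betas) -> np.ndarray:
    """Implied correlation matrix with unit diagonal (uniqueness 1 - v_i^2)."""
    delta = np.subtract.outer(angles_deg, angles_deg)
    P = correlation_function(betas, delta)
    sigma = np.outer(v, v) * P
    np.fill_diagonal(sigma, 1.0)
    return (sigma + sigma.T) / 2


def fit_spmc(
    corr: np.ndarray,
    n: int,
    spacing: str = "free",
    communalities: str = "free",
    fourier_order: int = 3,
    n_starts: int = 4,
    seed: int = 0,
    labels=OCTANTS,
    provenance: str = "raw",
) -> SpmcSolution:
    """Fit the SPMC to a correlation matrix under the given constraint set."""
    if spacing not in ("equal", "free") or communalities not in ("equal", "free"):
        raise ValueError("spacing and communalities must be 'equal' or 'free'")
    if fourier_order < 1:
        raise ValueError("fourier_order must be >= 1")
    S = np.asarray(corr, float)
    p = S.shape[0]
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("input correlation matrix is not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    par = _SpmcParam(spacing, communalities, fourier_order, labels=tuple(labels))
    rng = np.random.default_rng(seed)

    def objective(x):
        angles, v, betas = par.unpack(x)
        return _discrepancy(S, implied_spmc(angles, v, betas), logdet_s)

    best = None
    for attempt in range(max(1, n_starts)):
        x0 = par.start(rng if attempt else None)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if attempt >= 1 and best.fun < 1e-10:
            break
    angles, v, betas = par.unpack(best.x)

    # reflection rule: LM at 0, NO oriented into (0, 180)
    no_idx = labels.index("NO") if "NO" in labels else 1
    if angles[no_idx] > 180.0:
        angles = np.mod(-angles, 360.0)
    angle_set = AngleSet(labels=tuple(labels), angles=angles, reference=labels[0])

    implied = implied_spmc(angle_set.angles, v, betas)
    disc = max(float(best.fun), 0.0)
    # df bookkeeping: p(p-1)/2 non-redundant correlations minus free
    # parameters; fit_statistics subtracts n_free from p(p+1)/2, so the p
    # unit diagonal entries are passed as fixed "parameters".
    fit = fit_statistics(disc, implied, S, n, par.n_free + p)
    min_r, min_a = _minimum_correlation(betas)
    return SpmcSolution(
        angles=angle_set,
        communality_roots=v,
        betas=betas,
        spacing=spacing,
        communalities=communalities,
        implied=implied,
        discrepancy=disc,
        n=n,
        fit=fit,
        minimum_correlation=min_r,
        minimum_correlation_angle=min_a,
        provenance=provenance,
        converged=bool(best.success or disc < 1e-8),
    )


def spmc_on_reproduced(
    reproduced: np.ndarray, n: int, spacing="free", communalities="free",
    fourier_order: int = 3, seed: int = 0,
) -> SpmcSolution:
    """Fit the SPMC to a scoring-model reproduced correlation matrix.

    The reproduced matrix carries communalities on its diagonal; the
    diagonal is replaced by unities (the uniqueness complement), which
    keeps the matrix positive definite and leaves the reproduced
    correlations untouched.
    """
    R = np.asarray(reproduced, float).copy()
    np.fill_diagonal(R, 1.0)
    return fit_spmc(
        R, n, spacing=spacing, communalities=communalities,
        fourier_order=fourier_order, seed=seed, provenance="reproduced",
    )
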