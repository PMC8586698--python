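"""Synthetic octant-scale, item, and external-criterion data.

Generates data from a known three-factor circumplex population -- two
orthogonal circumplex factors (Dominance, Love) with 45-degree-spaced
loadings and a general Distress factor with positive loadings -- so that
every downstream estimator has a parameter-recovery oracle.  The default
population mirrors the loading structure reported for the inventory of
interpersonal problems in a large non-clinical sample (N = 822).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import (
    FACTORS,
    IDEAL_ANGLES,
    OCTANTS,
    CircumplexPattern,
    DataMatrix,
    ideal_circumplex_pattern,
)

#: Standardized Distress (general-factor) loadings, OCTANTS order
#: (LM, NO, PA, BC, DE, FG, HI, JK).
DEFAULT_DISTRESS = (0.64, 0.65, 0.66, 0.49, 0.47, 0.59, 0.64, 0.73)

#: Common circumplex radius of the default population: every octant's
#: (Dominance, Love) loading pair is radius * (sin theta, cos theta).
DEFAULT_RADIUS = 0.6

#: Default external criteria: (label, loadings on (Dominance, Love, Distress)).
DEFAULT_EXTERNALS = (
    ("Extraversion", (0.50, 0.40, -0.35)),
    ("Agreeableness", (-0.48, 0.30, -0.22)),
    ("Neuroticism", (-0.14, -0.16, 0.61)),
    ("Narcissism", (0.52, -0.02, 0.03)),
)


@dataclass(frozen=True)
class ExternalBlock:
    label: str
    loadings: tuple[float, float, float]
    uniqueness: float | None = None  # complement of communality when None

    def resolved_uniqueness(self) -> float:
        if self.uniqueness is not None:
            return self.uniqueness
        u = 1.0 - float(np.sum(np.square(self.loadings)))
        if u <= 0:
            raise ValueError(f"external block {self.label!r} has communality >= 1")
        return u


@dataclass(frozen=True)
class PopulationModel:
    """A fully specified three-factor circumplex population.

    The model is standardized: for every variable, communality plus
    uniqueness equals one, so the implied covariance matrix is a
    correlation matrix.
    """

    pattern: CircumplexPattern
    distress_loadings: np.ndarray
    uniquenesses: np.ndarray
    factor_covariance: np.ndarray = field(default_factory=lambda: np.eye(3))
    external_blocks: tuple[ExternalBlock, ...] = ()
    items_per_scale: int = 8
    likert_levels: int = 5
    item_loading: float = 0.58

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.pattern.scale_labels[:8]) + tuple(b.label for b in self.external_blocks)

    def loading_table(self) -> np.ndarray:
        """Full p x 3 population loading matrix (octants then externals)."""
        lam = np.zeros((8 + len(self.external_blocks), 3))
        lam[:8, :2] = self.pattern.circumplex
        lam[:8, 2] = self.distress_loadings
        for k, blk in enumerate(self.external_blocks):
            lam[8 + k] = blk.loadings
        return lam

    def all_uniquenesses(self) -> np.ndarray:
        return np.concatenate(
            [self.uniquenesses, [b.resolved_uniqueness() for b in self.external_blocks]]
        )

    def with_externals(self, blocks=DEFAULT_EXTERNALS) -> "PopulationModel":
        ext = tuple(
            b if isinstance(b, ExternalBlock) else ExternalBlock(b[0], tuple(b[1]))
            for b in blocks
        )
        return replace(self, external_blocks=ext)

    def with_pattern(self, pattern: CircumplexPattern) -> "PopulationModel":
        """Swap the circumplex pattern, recomputing uniquenesses to keep variances at 1."""
        comm = np.sum(pattern.circumplex**2, axis=1) + self.distress_loadings**2
        if np.any(comm >= 1):
            raise ValueError("pattern implies communality >= 1 for some octant")
        return replace(self, pattern=pattern, uniquenesses=1.0 - comm)


def default_population() -> PopulationModel:
    """The default study population.

    Circumplex loadings are radius * (sin theta, cos theta) at the ideal
    octant angles with a common radius of 0.6; Distress loadings are the
    values estimated for the eight octants in the reference sample; each
    uniqueness is the complement 1 - communality, so implied variances are
    exactly one.
    """
    pattern = ideal_circumplex_pattern(exact_diagonals=True)
    loads = pattern.loading_matrix.copy()
    loads[:, :2] *= DEFAULT_RADIUS
    loads[:, 2] = DEFAULT_DISTRESS
    pattern = replace(pattern, loading_matrix=loads)
    d = np.asarray(DEFAULT_DISTRESS)
    uniq = 1.0 - DEFAULT_RADIUS**2 - d**2
    return PopulationModel(pattern=pattern, distress_loadings=d, uniquenesses=uniq)


def implied_correlations(model: PopulationModel) -> np.ndarray:
    """Model-implied correlation matrix Sigma = Lambda Phi Lambda' + Theta."""
    lam = model.loading_table()
    sigma = lam @ model.factor_covariance @ lam.T + np.diag(model.all_uniquenesses())
    sigma = (sigma + sigma.T) / 2
    np.fill_diagonal(sigma, np.round(np.diag(sigma), 12))
    if np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise ValueError("model-implied correlation matrix is not positive semi-definite")
    return sigma


def simulate_scales(
    model: PopulationModel,
    n: int,
    seed: int,
    t_dof: float | None = None,
    return_factors: bool = False,
):
    """Draw n rows from the factor model (implied correlation matrix).

    Data are built as X = F Lambda' + E with orthogonal-by-default normal
    factors F and independent normal uniquenesses, so the rows follow a
    zero-mean multivariate normal with the implied correlation matrix.
    ``return_factors=True`` also returns the latent factor scores used,
    enabling score-validity oracles.  ``t_dof`` rescales rows to a
    multivariate t with the same correlation matrix for robustness
    experiments (not part of the default population).
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    implied_correlations(model)  # validates PSD
    lam = model.loading_table()
    F = rng.standard_normal((n, 3)) @ np.linalg.cholesky(model.factor_covariance).T
    E = rng.standard_normal((n, lam.shape[0])) * np.sqrt(model.all_uniquenesses())
    X = F @ lam.T + E
    if t_dof is not None:
        g = rng.chisquare(t_dof, size=n) / t_dof
        X *= np.sqrt((t_dof - 2) / t_dof) / np.sqrt(g)[:, None]
    dm = DataMatrix(model.labels, X)
    return (dm, F) if return_factors else dm


@dataclass(frozen=True)
class ItemData:
    """Ordinal item responses plus the unit-weighted scale sums derived from them."""

    items: DataMatrix
    scale_sums: DataMatrix


def simulate_items(model: PopulationModel, n: int, seed: int) -> ItemData:
    """Generate Likert items for the eight octant scales.

    Each scale's common (true-score) part is standardized; every item is
    item_loading * true score + noise, marginally standard normal, then cut
    into ``likert_levels`` ordered categories at equal-probability normal
    thresholds.  Scale scores are the per-scale item sums, as questionnaire
    scoring conventionally computes them.
    """
    if model.items_per_scale < 2:
        raise ValueError("need at least two items per scale")
    rng = np.random.default_rng(seed)
    lam = model.loading_table()[:8]
    comm = np.sum((lam @ model.factor_covariance) * lam, axis=1)
    F = rng.standard_normal((n, 3)) @ np.linalg.cholesky(model.factor_covariance).T
    true = (F @ lam.T) / np.sqrt(comm)  # unit-variance common part per scale

    k, L, ell = model.items_per_scale, model.likert_levels, model.item_loading
    cuts = stats.norm.ppf(np.arange(1, L) / L)
    item_cols, item_vals = [], []
    sums = np.zeros((n, 8))
    for j, scale in enumerate(OCTANTS):
        noise = rng.standard_normal((n, k))
        latent = ell * true[:, [j]] + np.sqrt(max(1 - ell**2, 0.0)) * noise
        ordinal = np.digitize(latent, cuts) + 1  # 1..L
        sums[:, j] = ordinal.sum(axis=1)
        item_cols += [f"{scale}_{i + 1}" for i in range(k)]
        item_vals.append(ordinal)
    items = DataMatrix(tuple(item_cols), np.hstack(item_vals))
    return ItemData(items=items, scale_sums=DataMatrix(OCTANTS, sums))


def perturb_circumplex(
    pattern: CircumplexPattern, angle_jitter_sd: float, seed: int
) -> CircumplexPattern:
    """Jitter the octant angles by independent normal noise (degrees).

    Circumplex loadings are recomputed as (sin theta, cos theta) scaled by
    each row's original norm, so communalities are preserved; supports
    misfit and recovery experiments against a known, non-ideal circumplex.
    """
    if angle_jitter_sd < 0:
        raise ValueError("angle_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    angles = np.asarray(pattern.ideal_angles, float).copy()
    if angle_jitter_sd > 0:
        angles = np.mod(angles + rng.normal(0.0, angle_jitter_sd, size=angles.size), 360.0)
    loads = pattern.loading_matrix.copy()
    norms = np.linalg.norm(loads[:8, :2], axis=1)
    rad = np.deg2rad(angles[:8])
    loads[:8, 0] = norms * np.sin(rad)
    loads[:8, 1] = norms * np.cos(rad)
    return replace(pattern, ideal_angles=angles, loading_matrix=loads)
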