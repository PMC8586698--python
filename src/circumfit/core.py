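"""Core circumplex data structures and descriptive statistics.

The interpersonal circumplex arranges eight octant scales (LM, NO, PA,
BC, DE, FG, HI, JK) at 45-degree spacings on a circle spanned by two
orthogonal axes, Dominance and Love.  A third, general factor (Distress)
captures the overall level of interpersonal problems shared by all
octants.  This module holds:

* :class:`CircumplexPattern` -- the ideal 8x2 circumplex loading pattern
  plus the general-factor column, with per-cell fixed/free/prior status;
* :class:`AngleSet` -- eight circular scale positions referenced to LM = 0;
* :class:`DataMatrix` -- a thin labelled matrix wrapper with CSV I/O;
* Tucker's congruence coefficient, Kaiser row normalization, the
  trigonometric loading-to-angle transform, the GDIFF circular
  root-mean-square angle deviation, and z-standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Octant labels in circular order, starting at the reference octant LM (0 deg).
OCTANTS: tuple[str, ...] = ("LM", "NO", "PA", "BC", "DE", "FG", "HI", "JK")

#: Ideal circumplex angles (degrees) of the octants, in OCTANTS order.
IDEAL_ANGLES: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)

#: Row order conventionally used in loading tables (PA first).
TABLE_ORDER: tuple[str, ...] = ("PA", "BC", "DE", "FG", "HI", "JK", "LM", "NO")

FACTORS: tuple[str, ...] = ("Dominance", "Love", "Distress")

FIXED = "fixed"
FREE = "free"
PRIOR = "prior"


class DegenerateRowError(ValueError):
    """A circumplex loading row is (numerically) all zero."""


class UndefinedCongruenceError(ValueError):
    """Tucker congruence is undefined for an all-zero vector."""


def _ideal_circumplex_loading(angle_deg: float, exact: bool = False) -> tuple[float, float]:
    """(Dominance, Love) = (sin theta, cos theta), diagonals rounded to 0.71.

    The conventional printed pattern uses 0.71 rather than 1/sqrt(2) for the
    diagonal octants; ``exact=True`` switches to 1/sqrt(2).
    """
    s, c = np.sin(np.deg2rad(angle_deg)), np.cos(np.deg2rad(angle_deg))
    if exact:
        return float(s), float(c)

    def _round(x: float) -> float:
        if abs(abs(x) - np.sqrt(0.5)) < 1e-9:
            return float(np.sign(x) * 0.71)
        return float(np.round(x))

    return _round(s), _round(c)


@dataclass(frozen=True)
class CircumplexPattern:
    """Loading pattern of the bi-factor circumplex model.

    Attributes
    ----------
    scale_labels : tuple of str
        Variable names; the first eight are the octants in circular order.
    ideal_angles : ndarray
        Ideal circular positions (degrees) of the octant scales.
    loading_matrix : ndarray, shape (p, 3)
        Loading values over (Dominance, Love, Distress).  Fixed cells hold
        the value the model fixes; prior cells hold the prior mean; free
        cells hold a starting value (ignored by estimators).
    cell_status : ndarray of str, shape (p, 3)
        Per-cell marker in {"fixed", "free", "prior"}.
    prior_variance : float
        Variance sigma^2 of the normal loading priors attached to "prior"
        cells (Bayesian estimation only).
    error_covariance_mask : ndarray of bool, shape (p, p)
        Symmetric mask of residual covariances allowed to be nonzero.
    """

    scale_labels: tuple[str, ...] = OCTANTS
    ideal_angles: np.ndarray = field(default_factory=lambda: np.asarray(IDEAL_ANGLES))
    loading_matrix: np.ndarray = field(default_factory=lambda: np.zeros((8, 3)))
    cell_status: np.ndarray = field(default_factory=lambda: np.full((8, 3), FREE, dtype=object))
    prior_variance: float = 0.01
    error_covariance_mask: np.ndarray = field(default_factory=lambda: np.zeros((8, 8), bool))

    @property
    def n_vars(self) -> int:
        return len(self.scale_labels)

    @property
    def circumplex(self) -> np.ndarray:
        """The 8x2 (Dominance, Love) block of the octant rows."""
        return self.loading_matrix[:8, :2]

    def octant_index(self, label: str) -> int:
        return self.scale_labels.index(label)

    def with_priors(self, prior_variance: float = 0.01) -> "CircumplexPattern":
        """Convert fixed circumplex cells (except the two scaling cells) to priors.

        The prior mean of each converted cell is its ideal loading.  The
        scaling cells (PA on Dominance, LM on Love) stay fixed at 1 to keep
        the model identified and the factor orientation pinned.
        """
        status = self.cell_status.copy()
        for i in range(8):
            for f in range(2):
                if status[i, f] == FIXED and not self._is_scaling_cell(i, f):
                    status[i, f] = PRIOR
        return replace(self, cell_status=status, prior_variance=prior_variance)

    def with_free_circumplex(self) -> "CircumplexPattern":
        """Free every circumplex cell except the two scaling cells."""
        status = self.cell_status.copy()
        for i in range(8):
            for f in range(2):
                if not self._is_scaling_cell(i, f):
                    status[i, f] = FREE
        return replace(self, cell_status=status)

    def with_error_covariances(self, pairs: Sequence[tuple[str, str]]) -> "CircumplexPattern":
        """Allow the residual covariances of the named variable pairs to be nonzero."""
        mask = self.error_covariance_mask.copy()
        if mask.shape[0] != self.n_vars:
            mask = np.zeros((self.n_vars, self.n_vars), bool)
            mask[: self.error_covariance_mask.shape[0], : self.error_covariance_mask.shape[1]] = (
                self.error_covariance_mask
            )
        for a, b in pairs:
            i, j = self.octant_index(a), self.octant_index(b)
            if i == j:
                raise ValueError(f"error covariance requires two distinct variables, got {a!r}")
            mask[i, j] = mask[j, i] = True
        return replace(self, error_covariance_mask=mask)

    def _is_scaling_cell(self, i: int, f: int) -> bool:
        lbl = self.scale_labels[i]
        return (lbl == "PA" and f == 0) or (lbl == "LM" and f == 1)


def ideal_circumplex_pattern(exact_diagonals: bool = False) -> CircumplexPattern:
    """The canonical bi-factor circumplex pattern.

    Octant (Dominance, Love) loadings equal (sin theta, cos theta) of the
    ideal angles, with diagonal entries printed as +/-0.71 unless
    ``exact_diagonals`` asks for 1/sqrt(2).  All circumplex cells are marked
    fixed (the scaling cells PA-Dominance and LM-Love are fixed at 1 in any
    estimable configuration); the Distress column is free with a neutral
    0.5 starting value; the error-covariance mask is empty.
    """
    loads = np.zeros((8, 3))
    status = np.full((8, 3), FIXED, dtype=object)
    for i, ang in enumerate(IDEAL_ANGLES):
        loads[i, 0], loads[i, 1] = _ideal_circumplex_loading(ang, exact=exact_diagonals)
    loads[:, 2] = 0.5
    status[:, 2] = FREE
    return CircumplexPattern(
        scale_labels=OCTANTS,
        ideal_angles=np.asarray(IDEAL_ANGLES, float),
        loading_matrix=loads,
        cell_status=status,
    )


@dataclass(frozen=True)
class AngleSet:
    """Circular positions (degrees in [0, 360)) of labelled scales.

    The angle of ``reference`` (default LM) is pinned to zero; construction
    re-references and wraps automatically.
    """

    labels: tuple[str, ...]
    angles: np.ndarray
    reference: str = "LM"

    def __post_init__(self):
        angles = np.asarray(self.angles, float)
        if len(self.labels) != angles.size:
            raise ValueError("labels and angles differ in length")
        if self.reference not in self.labels:
            raise ValueError(f"reference {self.reference!r} not among labels")
        ref = angles[self.labels.index(self.reference)]
        angles = np.mod(angles - ref, 360.0)
        object.__setattr__(self, "angles", angles)

    def angle(self, label: str) -> float:
        return float(self.angles[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "degrees": self.angles})

    @classmethod
    def ideal(cls) -> "AngleSet":
        return cls(labels=OCTANTS, angles=np.asarray(IDEAL_ANGLES))


@dataclass(frozen=True)
class DataMatrix:
    """A labelled N x p real matrix, optionally z-standardized."""

    column_labels: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        vals = np.atleast_2d(np.asarray(self.values, float))
        if vals.shape[1] != len(self.column_labels):
            raise ValueError("values and column_labels disagree on column count")
        object.__setattr__(self, "values", vals)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.column_labels.index(label)]

    def select(self, labels: Sequence[str]) -> "DataMatrix":
        idx = [self.column_labels.index(l) for l in labels]
        return DataMatrix(tuple(labels), self.values[:, idx], self.standardized)

    def correlations(self) -> np.ndarray:
        return np.corrcoef(self.values, rowvar=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.column_labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, standardized: bool = False) -> "DataMatrix":
        return cls(tuple(map(str, df.columns)), df.to_numpy(float), standardized)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, standardized: bool = False) -> "DataMatrix":
        return cls.from_dataframe(pd.read_csv(path), standardized=standardized)


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient c = sum(a*b)/sqrt(sum(a^2) sum(b^2)).

    A cosine similarity between loading vectors; |c| near 1 indicates that
    the two vectors describe the same factor up to scale.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size or a.size == 0:
        raise ValueError("vectors must have equal, positive length")
    na, nb = np.sum(a * a), np.sum(b * b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCongruenceError("congruence undefined for an all-zero vector")
    return float(np.sum(a * b) / np.sqrt(na * nb))


def kaiser_normalize(loadings: np.ndarray, labels: Sequence[str] | None = None) -> np.ndarray:
    """Divide each row of an n x 2 circumplex loading block by its Euclidean norm.

    Removes communality differences so that every scale sits at radius 1;
    used before comparing patterns or transforming loadings to angles.
    """
    L = np.atleast_2d(np.asarray(loadings, float))
    norms = np.linalg.norm(L, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        name = labels[bad[0]] if labels is not None else f"row {bad[0]}"
        raise DegenerateRowError(f"zero circumplex loading row for {name}")
    return L / norms[:, None]


def loadings_to_angles(
    loadings: np.ndarray,
    labels: Sequence[str] = OCTANTS,
    reference: str = "LM",
) -> AngleSet:
    """Trigonometric transform of (Dominance, Love) loadings to circular angles.

    theta_i = atan2(Dominance_i, Love_i) in degrees wrapped to [0, 360),
    then rotated so the reference octant sits at 0.  With the ideal pattern
    this reproduces the conventional octant angles (LM 0, NO 45, ..., JK 315).
    """
    L = kaiser_normalize(loadings, labels)
    theta = np.mod(np.rad2deg(np.arctan2(L[:, 0], L[:, 1])), 360.0)
    return AngleSet(labels=tuple(labels), angles=theta, reference=reference)


def circular_difference(a, b):
    """Signed circular difference a - b wrapped to (-180, 180] degrees."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def gdiff(observed: AngleSet, ideal: AngleSet | None = None) -> float:
    """Root mean squared circular deviation (degrees) from the ideal angles.

    GDIFF = sqrt((1/8) sum_i d(theta_i, theta_id)^2) with d the signed
    circular difference wrapped to (-180, 180].  Zero iff the observed
    angles match the ideal circumplex exactly; smaller is more circumplex.
    """
    if ideal is None:
        ideal = AngleSet.ideal()
    if set(observed.labels) != set(ideal.labels):
        raise ValueError("observed and ideal angle sets cover different labels")
    obs = np.array([observed.angle(l) for l in ideal.labels])
    d = circular_difference(obs, ideal.angles)
    return float(np.sqrt(np.mean(d**2)))


def standardize(data: DataMatrix) -> DataMatrix:
    """z-standardize every column (mean 0, unit variance with the N-1 estimator)."""
    X = data.values
    sd = X.std(axis=0, ddof=1)
    const = np.flatnonzero(sd < 1e-12)
    if const.size:
        raise ValueError(f"column {data.column_labels[const[0]]!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    return DataMatrix(data.column_labels, Z, standardized=True)
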