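"""Latent-Gaussian copula layer for mixed-type data.

Continuous columns are Gaussianized once, before the MCMC chain starts, with
the rank-based semiparametric (nonparanormal) transform z_i = Phi^-1(r_i/(n+1))
— a map invariant under any strictly increasing transform of the input, so
the latent partial-correlation structure reflects the observed data's ranks,
not its margins.

Discrete columns (sex, education, APOE4, amyloid stage) have no well-defined
margin-free transform; following the extended-rank-likelihood construction,
their latent values are constrained only by the ordering of observed values
and are resampled at every MCMC iteration from truncated normal conditionals.
Tied observations impose no mutual constraint. Age, although recorded in
whole years, is treated as continuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .data_model import CohortTable
from .errors import ConfigError, NumericalError, ValidationError
from .graphs import is_spd

_U_EPS = 1e-12


@dataclass
class LatentMatrix:
    """Real-valued n x p Gaussianized data carried through the chain."""

    values: np.ndarray
    discrete_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.discrete_mask = np.asarray(self.discrete_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != self.discrete_mask.size:
            raise ValidationError("latent matrix / discrete mask shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "LatentMatrix":
        return LatentMatrix(self.values.copy(), self.discrete_mask.copy())


def winsorized_delta(n: int) -> float:
    """Truncation level delta_n = 1 / (4 n^(1/4) sqrt(pi log n))."""
    return 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))


def nonparanormal_transform(column: np.ndarray, winsorize: bool = False) -> np.ndarray:
    """Rank-based Gaussianization of one continuous column.

    Uses average ranks for ties and the r/(n+1) empirical CDF, which bounds
    the transform away from +-infinity; ``winsorize`` instead truncates the
    ECDF at delta_n (the shrunken-estimator variant).
    """
    y = np.asarray(column, dtype=float)
    n = y.size
    if n < 3:
        raise ValidationError("nonparanormal transform needs at least 3 observations")
    if np.all(y == y[0]):
        raise ValidationError("nonparanormal transform is undefined for a constant column")
    r = rankdata(y, method="average")
    if winsorize:
        delta = winsorized_delta(n)
        u = np.clip(r / n, delta, 1.0 - delta)
    else:
        u = r / (n + 1.0)
    return ndtri(u)


def initial_latent(table: CohortTable, winsorize: bool = False) -> LatentMatrix:
    """One-shot Gaussianization of a cohort table.

    Continuous columns get the semiparametric transform and are standardized
    to mean 0 / variance 1 (partial correlations are scale-invariant; this
    only stabilizes the sampler) and then frozen. Discrete columns get a
    rank-based starting point consistent with their ordering constraints and
    are resampled during MCMC.
    """
    mask = table.dictionary.discrete_mask
    Z = np.empty((table.n, table.p))
    raw = table.to_numpy()
    for j in range(table.p):
        z = nonparanormal_transform(raw[:, j], winsorize=winsorize) if not _constant(raw[:, j]) \
            else np.zeros(table.n)
        if not mask[j]:
            sd = z.std(ddof=0)
            if sd <= 0:
                raise ValidationError(
                    f"continuous column {table.dictionary.names[j]!r} is constant"
                )
            z = (z - z.mean()) / sd
        Z[:, j] = z
    return LatentMatrix(values=Z, discrete_mask=mask)


def _constant(col: np.ndarray) -> bool:
    return bool(np.all(col == col[0]))


def rank_bounds(
    observed_column: np.ndarray, latent_column: np.ndarray, row: int
) -> Tuple[float, float]:
    """Extended-rank-likelihood bounds for one latent value.

    lower = max latent over rows observed strictly below this row's value
    (-inf if none); upper = min latent over rows strictly above (+inf if
    none). Ties impose no mutual constraint.
    """
    y = np.asarray(observed_column)
    z = np.asarray(latent_column, dtype=float)
    below = y < y[row]
    above = y > y[row]
    lower = z[below].max() if below.any() else -np.inf
    upper = z[above].min() if above.any() else np.inf
    return float(lower), float(upper)


def conditional_params(K: np.ndarray, j: int, z_row: np.ndarray) -> Tuple[float, float]:
    """Mean and variance of latent column j given the rest under N(0, K^-1).

    mean = -(1/k_jj) sum_{l != j} k_jl z_l, var = 1/k_jj — the standard
    precision-matrix form of the Schur-complement conditional.
    """
    kjj = K[j, j]
    mean = -(K[j] @ z_row - kjj * z_row[j]) / kjj
    return float(mean), float(1.0 / kjj)


def _truncnorm_draw(mean, sd, lower, upper, rng) -> np.ndarray:
    """Inverse-CDF truncated normal draws, vectorized over rows."""
    a = ndtr((lower - mean) / sd)
    b = ndtr((upper - mean) / sd)
    u = a + (b - a) * rng.uniform(size=np.shape(mean))
    u = np.clip(u, _U_EPS, 1.0 - _U_EPS)
    return mean + sd * ndtri(u)


def resample_discrete_latents(
    latent: LatentMatrix, observed: CohortTable, K: np.ndarray, rng
) -> LatentMatrix:
    """One Gibbs sweep over discrete columns under precision matrix K.

    Columns are scanned in dictionary order; within a column the observed
    levels are processed in ascending order and all rows sharing a level are
    drawn jointly (they are conditionally independent and mutually
    unconstrained — ties carry no ordering information — so this equals the
    row-wise scan in distribution). Each draw is a univariate normal with
    mean -(1/k_jj) sum_{l!=j} k_jl z_il and variance 1/k_jj truncated to the
    rank bounds. Continuous columns are untouched.
    """
    K = np.asarray(K, dtype=float)
    if K.shape != (latent.p, latent.p):
        raise ValidationError("precision matrix does not match latent dimension")
    if not is_spd(K):
        raise NumericalError("precision matrix must be SPD for latent resampling")
    Z = latent.values
    raw = observed.to_numpy()
    for j in np.flatnonzero(latent.discrete_mask):
        y = raw[:, j]
        sd = float(1.0 / np.sqrt(K[j, j]))
        mean = -(Z @ K[:, j] - K[j, j] * Z[:, j]) / K[j, j]
        levels = np.unique(y)
        # suffix minima over higher levels are valid throughout the ascending
        # scan because those rows have not been updated yet this sweep
        level_rows = [np.flatnonzero(y == v) for v in levels]
        suffix_min = np.full(len(levels) + 1, np.inf)
        for t in range(len(levels) - 1, -1, -1):
            suffix_min[t] = min(suffix_min[t + 1], Z[level_rows[t], j].min())
        running_lo = -np.inf
        for t, rows in enumerate(level_rows):
            hi = suffix_min[t + 1]
            Z[rows, j] = _truncnorm_draw(mean[rows], sd, running_lo, hi, rng)
            running_lo = max(running_lo, Z[rows, j].max())
    return latent
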