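"""Derived site variables and ordination.

Rarefied species richness (Hurlbert's expectation for a fixed subsample
of individuals), per-site structure variables derived from the abundance
and trait tables, and PCA of standardized environment or trait matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.decomposition import PCA

from .matrices import (
    AbundanceMatrix,
    EnvMatrix,
    TraitMatrix,
    ValidationError,
    standardize_columns,
)

__all__ = [
    "OrdinationResult",
    "rarefied_richness",
    "structure_variables",
    "pca",
]


@dataclass(frozen=True)
class OrdinationResult:
    """PCA scores, loadings and explained-variance fractions.

    Axes are ordered by decreasing explained variance; loadings columns
    are orthonormal; for full-rank decompositions
    ``scores @ loadings.T`` reconstructs the centered (standardized)
    input.  Axis signs follow the convention that each axis' largest
    |loading| is positive.
    """

    scores: pd.DataFrame        # entities x axes
    loadings: pd.DataFrame      # variables x axes
    explained_variance: np.ndarray  # fraction per axis


def _log_binom(n: np.ndarray | float, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(counts, n: int = 100) -> float:
    """Hurlbert's expected species count in a subsample of ``n`` individuals.

    ``E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)]`` over species with
    count ``N_i > 0`` and census total ``N``.  Binomials are evaluated
    through log-gamma, so large censuses do not overflow.  If the census
    holds fewer than ``n`` individuals the observed richness is returned
    with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValidationError("counts must be non-negative integers")
    if n < 1:
        raise ValidationError("subsample size must be >= 1")
    counts = counts[counts > 0]
    N = counts.sum()
    if N == 0:
        raise ValidationError("all-zero count vector: no individuals to rarefy")
    if N < n:
        warnings.warn(
            f"census total {int(N)} < subsample size {n}; returning observed richness",
            stacklevel=2,
        )
        return float(counts.size)
    terms = np.zeros(counts.size)
    feasible = (N - counts) >= n  # species that can be absent from the subsample
    if feasible.any():
        terms[feasible] = np.exp(_log_binom(N - counts[feasible], n) - _log_binom(N, n))
    return float(np.sum(1.0 - terms))


def structure_variables(
    L: AbundanceMatrix,
    Q: TraitMatrix | None = None,
    deciduous_trait: str | None = None,
    rarefy_n: int = 100,
) -> pd.DataFrame:
    """Per-site structure table: individuals, richness, rarefied richness,
    and (if a deciduous indicator trait is named) the proportion of
    individuals belonging to deciduous species.

    ``deciduous_trait`` must be a 0/1-coded column of Q with 1 marking
    deciduous species.  Species with a missing indicator stay in the
    denominator but cannot contribute to the numerator.
    """
    arr = L.values
    out = pd.DataFrame(index=L.data.index)
    out["n_individuals"] = arr.sum(axis=1).astype(int)
    out["richness"] = (arr > 0).sum(axis=1)
    out["rarefied_richness"] = [
        rarefied_richness(row, rarefy_n) if row.sum() > 0 else np.nan for row in arr
    ]
    if deciduous_trait is not None:
        if Q is None:
            raise ValidationError("a trait matrix is required for the deciduous proportion")
        if deciduous_trait not in Q.data.columns:
            raise ValidationError(f"trait {deciduous_trait!r} not found in the trait table")
        flag = Q.data[deciduous_trait]
        bad = flag.dropna()[~flag.dropna().isin([0.0, 1.0])]
        if len(bad):
            raise ValidationError(
                f"trait {deciduous_trait!r} must be coded 0/1; found {bad.iloc[0]!r}"
            )
        indicator = flag.reindex(L.species_ids).fillna(0.0).to_numpy()
        with np.errstate(invalid="ignore"):
            out["prop_deciduous"] = (arr @ indicator) / arr.sum(axis=1)
    return out


def pca(matrix: EnvMatrix | TraitMatrix) -> OrdinationResult:
    """PCA of a standardized environment or trait matrix.

    The input is standardized first if it is not already (so the
    decomposition is of the correlation structure).  Missing values are
    not supported here: ordination needs complete rows.
    """
    if not matrix.standardized:
        matrix = standardize_columns(matrix)
    df = matrix.data
    if df.isna().any().any():
        raise ValidationError("PCA requires a complete matrix (no missing values)")
    n_ent, n_var = df.shape
    if n_var < 2 or n_ent < 3:
        raise ValidationError("PCA needs at least 2 variables and 3 entities")
    k = min(n_ent - 1, n_var)
    fit = PCA(n_components=k)
    scores = fit.fit_transform(df.to_numpy())
    loadings = fit.components_.T  # variables x axes, orthonormal columns
    # deterministic axis orientation: largest-|loading| element positive
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    axes = [f"PC{j + 1}" for j in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=df.index, columns=axes),
        loadings=pd.DataFrame(loadings, index=df.columns, columns=axes),
        explained_variance=fit.explained_variance_ratio_.copy(),
    )
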