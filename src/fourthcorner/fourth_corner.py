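"""Fourth-corner trait-environment statistic and its permutation null models.

The fourth-corner problem asks whether species traits (Q, species x
traits) are linked to the environment (R, sites x environmental
variables) through community composition (L, sites x species
abundances).  The statistic for one (trait, variable) pair is the
Pearson correlation computed on the *inflated* table: every nonzero
(site, species) cell of L becomes one row pairing that site's
environment vector with that species' trait vector, weighted by the
cell's fraction of total abundance.  Equivalently, on column-standardized
R and Q (under the abundance weights) the whole traits x variables
correlation matrix is the matrix product Q' W' R' and can be evaluated
in either association order.

Because an observed correlation can arise through two distinct links --
species sorting along the environment (L-R) and community selection of
trait values (L-Q) -- significance is assessed against three permutation
null models that destroy different links in L:

* model I  : permute abundances within each species (column) independently;
  destroys both the L-R and the L-Q link.
* model II : permute whole rows (sites) of L; destroys the L-R link only.
* model IV : permute whole columns (species) of L; destroys the L-Q link only.

Two-sided p-values use the add-one convention
``p = (1 + #{|r*| >= |r_obs|}) / (n_perm + 1)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrices import AbundanceMatrix, EnvMatrix, TraitMatrix, ValidationError

__all__ = [
    "MODELS",
    "InflatedTable",
    "FourthCornerResult",
    "SignificanceCounts",
    "inflate",
    "fourth_corner_stat",
    "full_stat_matrix",
    "permute_L",
    "fourth_corner_test",
    "count_significances",
]

#: The permutation null models implemented, keyed by their customary labels.
MODELS = ("I", "II", "IV")

_ABS_TIE_TOL = 1e-12  # |r*| vs |r_obs| comparisons are float-tolerant


@dataclass(frozen=True)
class InflatedTable:
    """Occurrence-level expansion of an aligned (R, L, Q) triple.

    One row per nonzero cell of L, carrying that site's environment
    vector, that species' trait vector and the cell's share of total
    abundance.  Weights are positive and sum to one.
    """

    env: np.ndarray          # n_occurrences x n_env
    traits: np.ndarray       # n_occurrences x n_traits
    weights: np.ndarray      # n_occurrences
    site_index: np.ndarray   # row of L for each occurrence
    species_index: np.ndarray
    env_names: tuple
    trait_names: tuple

    @property
    def n_rows(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class FourthCornerResult:
    """Correlations, permutation p-values and signs for one null model.

    ``r`` and ``p`` are traits x environment-variables DataFrames;
    ``sign`` holds +1 / -1 for significant positive / negative cells at
    ``alpha`` and 0 otherwise.  Cells whose correlation is undefined
    (zero weighted variance after pairwise deletion) carry NaN in ``r``
    and ``p`` and 0 in ``sign``; they are excluded from significance
    counts.
    """

    model: str
    r: pd.DataFrame
    p: pd.DataFrame
    sign: pd.DataFrame
    n_perm: int
    alpha: float
    seed: int


@dataclass(frozen=True)
class SignificanceCounts:
    """Per-environment-variable counts of significant traits, plus total."""

    per_variable: pd.Series
    total: int


def inflate(R: EnvMatrix, L: AbundanceMatrix, Q: TraitMatrix) -> InflatedTable:
    """Build the occurrence-level (inflated) table from an aligned triple."""
    W = L.values
    total = W.sum()
    if total <= 0:
        raise ValidationError("abundance table has no nonzero entry; cannot inflate")
    rows, cols = np.nonzero(W)
    return InflatedTable(
        env=R.values[rows],
        traits=Q.values[cols],
        weights=W[rows, cols] / total,
        site_index=rows,
        species_index=cols,
        env_names=tuple(R.var_names),
        trait_names=tuple(Q.trait_names),
    )


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx = w @ x
    my = w @ y
    vx = w @ (x - mx) ** 2
    vy = w @ (y - my) ** 2
    if vx <= 0 or vy <= 0:
        raise ValidationError("zero weighted variance: correlation undefined")
    r = (w @ ((x - mx) * (y - my))) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def fourth_corner_stat(infl: InflatedTable, env_index, trait_index) -> float:
    """Weighted Pearson correlation for one (environment, trait) pair.

    Indices may be integer positions or column names.  When a species is
    missing the selected trait, its occurrences are dropped and the
    weights renormalized (pairwise deletion).
    """
    if not isinstance(env_index, (int, np.integer)):
        env_index = infl.env_names.index(env_index)
    if not isinstance(trait_index, (int, np.integer)):
        trait_index = infl.trait_names.index(trait_index)
    x = infl.env[:, env_index]
    y = infl.traits[:, trait_index]
    keep = np.isfinite(y) & np.isfinite(x)
    if not keep.any():
        raise ValidationError("no occurrences with both values present")
    return _weighted_pearson(x[keep], y[keep], infl.weights[keep])


def _corr_core(E: np.ndarray, W: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """All pairwise weighted correlations, as a traits x variables array.

    ``E``: sites x n_env, ``W``: sites x species non-negative weights
    (normalized internally), ``Q``: species x n_traits with no NaN.
    Cells with vanishing weighted variance come back NaN.
    """
    total = W.sum()
    Wn = W / total
    a = Wn.sum(axis=1)  # site masses
    b = Wn.sum(axis=0)  # species masses
    me = a @ E
    mq = b @ Q
    ve = a @ (E * E) - me * me
    vq = b @ (Q * Q) - mq * mq
    np.clip(ve, 0.0, None, out=ve)
    np.clip(vq, 0.0, None, out=vq)
    cov = (E.T @ Wn) @ Q - np.outer(me, mq)
    bad_e = ve <= 1e-13 * np.maximum(1.0, a @ (E * E))
    bad_q = vq <= 1e-13 * np.maximum(1.0, b @ (Q * Q))
    denom = np.sqrt(np.outer(ve, vq))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / denom
    r[bad_e, :] = np.nan
    r[:, bad_q] = np.nan
    return np.clip(r, -1.0, 1.0).T


def _nan_groups(Qv: np.ndarray) -> dict[tuple, list[int]]:
    """Group trait columns by their pattern of missing species.

    Each group can be analysed with one complete-case species subset, so
    pairwise deletion costs one pass per distinct missingness pattern
    instead of one per trait.
    """
    groups: dict[tuple, list[int]] = {}
    mask = ~np.isfinite(Qv)
    for t in range(Qv.shape[1]):
        key = tuple(np.nonzero(mask[:, t])[0].tolist())
        groups.setdefault(key, []).append(t)
    return groups


def full_stat_matrix(R: EnvMatrix, L: AbundanceMatrix, Q: TraitMatrix) -> pd.DataFrame:
    """Fourth-corner correlations for every (trait, variable) pair.

    Returns a traits x environment-variables DataFrame.  Traits with
    missing species are handled by pairwise deletion: the affected
    species' L columns are dropped and weights renormalized for those
    traits only.  Undefined cells are NaN.
    """
    E = R.values
    W = L.values
    Qv = Q.values
    out = np.full((Qv.shape[1], E.shape[1]), np.nan)
    for missing, t_idx in _nan_groups(Qv).items():
        keep = np.setdiff1d(np.arange(Qv.shape[0]), np.asarray(missing, dtype=int))
        if keep.size == 0 or W[:, keep].sum() <= 0:
            continue
        out[t_idx, :] = _corr_core(E, W[:, keep], Qv[np.ix_(keep, t_idx)])
    return pd.DataFrame(out, index=Q.trait_names, columns=R.var_names)


def permute_L(L: AbundanceMatrix, model: str, rng: np.random.Generator) -> AbundanceMatrix:
    """Reshuffle L under one null model, preserving the entry multiset.

    Model I permutes each species' abundances across sites independently;
    model II reorders whole site rows; model IV reorders whole species
    columns.  Row and column labels keep their positions: the null
    reassigns abundance patterns to sites/species.
    """
    arr = L.values
    if model == "I":
        perm = rng.permuted(arr, axis=0)
    elif model == "II":
        perm = arr[rng.permutation(arr.shape[0]), :]
    elif model == "IV":
        perm = arr[:, rng.permutation(arr.shape[1])]
    else:
        raise ValueError(f"unknown permutation model {model!r}; expected one of {MODELS}")
    return AbundanceMatrix(
        pd.DataFrame(perm, index=L.data.index, columns=L.data.columns),
        relative=L.relative,
    )


def _permute_values(arr: np.ndarray, model: str, rng: np.random.Generator) -> np.ndarray:
    if model == "I":
        return rng.permuted(arr, axis=0)
    if model == "II":
        return arr[rng.permutation(arr.shape[0]), :]
    return arr[:, rng.permutation(arr.shape[1])]


def _group_rng(seed: int, model: str, keep_labels: Sequence[str]) -> np.random.Generator:
    # one deterministic stream per (seed, model, retained-species subset):
    # results do not depend on evaluation order, on which other traits are
    # present, or on whether dropped species were removed before the call
    key = zlib.crc32("\x00".join(str(s) for s in sorted(keep_labels)).encode())
    return np.random.default_rng([int(seed), MODELS.index(model), int(key)])


def fourth_corner_test(
    R: EnvMatrix,
    L: AbundanceMatrix,
    Q: TraitMatrix,
    model: str = "I",
    n_perm: int = 9999,
    alpha: float = 0.05,
    seed: int = 0,
) -> FourthCornerResult:
    """Permutation test of every trait-environment cell under one null model.

    For each cell the two-sided p-value is
    ``(1 + #{|r*| >= |r_obs|}) / (n_perm + 1)``, where r* are the
    correlations recomputed on reshuffled L matrices.  All cells share
    the same permutation sequence of L (the null acts on L alone), so
    p-values do not depend on how many traits or variables are analysed.

    Reproducible: the permutation stream is derived from ``seed``, the
    model label and the complete-case species subset.
    """
    if model not in MODELS:
        raise ValueError(f"unknown permutation model {model!r}; expected one of {MODELS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    E = R.values
    W = L.values
    Qv = Q.values
    n_traits, n_env = Qv.shape[1], E.shape[1]
    r_obs = np.full((n_traits, n_env), np.nan)
    hits = np.zeros((n_traits, n_env))

    for missing, t_idx in _nan_groups(Qv).items():
        keep = np.setdiff1d(np.arange(Qv.shape[0]), np.asarray(missing, dtype=int))
        if keep.size == 0 or W[:, keep].sum() <= 0:
            continue
        Wk = W[:, keep]
        Qk = Qv[np.ix_(keep, t_idx)]
        robs = _corr_core(E, Wk, Qk)
        r_obs[t_idx, :] = robs
        thresh = np.abs(robs) - _ABS_TIE_TOL
        species = L.species_ids
        rng = _group_rng(seed, model, [species[i] for i in keep])
        acc = np.zeros_like(robs)
        for _ in range(n_perm):
            rp = _corr_core(E, _permute_values(Wk, model, rng), Qk)
            acc += np.abs(rp) >= thresh  # NaN r* compares False: not a hit
        hits[t_idx, :] = acc

    p = (1.0 + hits) / (n_perm + 1.0)
    p[~np.isfinite(r_obs)] = np.nan
    sign = np.zeros((n_traits, n_env), dtype=int)
    sig = np.isfinite(p) & (p <= alpha)
    sign[sig & (r_obs > 0)] = 1
    sign[sig & (r_obs < 0)] = -1
    idx, cols = Q.trait_names, R.var_names
    return FourthCornerResult(
        model=model,
        r=pd.DataFrame(r_obs, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        sign=pd.DataFrame(sign, index=idx, columns=cols),
        n_perm=n_perm,
        alpha=alpha,
        seed=seed,
    )


def count_significances(res: FourthCornerResult) -> SignificanceCounts:
    """Count significant traits per environment variable, plus the grand total.

    Undefined cells (NaN p) are excluded rather than counted as zero so
    the totals reconcile with the number of testable cells.
    """
    sig = res.p.le(res.alpha) & res.p.notna()
    per_var = sig.sum(axis=0).astype(int)
    per_var.name = f"model_{res.model}"
    return SignificanceCounts(per_variable=per_var, total=int(per_var.sum()))


def holm_adjust(p: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjustment over all defined cells (optional, off by
    default in the pipeline; the primary analysis reports per-cell
    significance at alpha with no multiplicity correction)."""
    flat = p.to_numpy().ravel()
    ok = np.isfinite(flat)
    m = ok.sum()
    order = np.argsort(flat[ok])
    adj = np.empty(m)
    running = 0.0
    for rank, j in enumerate(order):
        running = max(running, (m - rank) * flat[ok][j])
        adj[j] = min(1.0, running)
    out = np.full(flat.shape, np.nan)
    out[ok] = adj
    return pd.DataFrame(out.reshape(p.shape), index=p.index, columns=p.columns)
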