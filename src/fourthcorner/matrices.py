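"""Data model, I/O, alignment and preprocessing for the R, L, Q matrix triple.

A trait-environment analysis links three rectangular tables:

* ``R`` -- sites x environmental variables (quantitative),
* ``L`` -- sites x species abundances (non-negative individual counts),
* ``Q`` -- species x traits (species means; binary traits coded 0/1).

This module provides thin typed wrappers around :class:`pandas.DataFrame`
that validate the invariants each matrix must satisfy, plus the standard
preprocessing steps: column standardization (z-scores), conversion of
counts to fractions of total abundance, per-column natural-log transforms
for heavy-tailed traits, and alignment of the triple on shared sites and
species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "AlignmentError",
    "EnvMatrix",
    "AbundanceMatrix",
    "TraitMatrix",
    "read_table",
    "write_table",
    "align_triple",
    "standardize_columns",
    "to_relative_abundance",
    "log_transform_columns",
    "trait_coverage",
]


class ParseError(ValueError):
    """A cell of an input table could not be interpreted as a number."""


class ValidationError(ValueError):
    """A matrix violates one of its structural invariants."""


class AlignmentError(ValueError):
    """The R/L/Q triple shares no sites or no species."""


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dupes = labels[labels.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dupes}")


def _check_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Coerce to float, naming the first offending cell on failure."""
    out = df.copy()
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric value {df.loc[row, col]!r} in {what} "
                f"at row {row!r}, column {col!r}"
            )
        out[col] = coerced.astype(float)
    return out


@dataclass(frozen=True)
class EnvMatrix:
    """Sites x environmental-variables table (the R matrix)."""

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "site identifiers")
        _check_unique(self.data.columns, "environment variable names")
        object.__setattr__(self, "data", _check_numeric(self.data, "environment table"))
        if self.data.isna().any().any():
            raise ValidationError("environment table contains missing values")

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def var_names(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class AbundanceMatrix:
    """Sites x species table of individual counts (the L matrix).

    ``relative=True`` marks the fractions-of-total-abundance form produced
    by :func:`to_relative_abundance`; the integer-count invariant is then
    replaced by "entries sum to one".
    """

    data: pd.DataFrame
    relative: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "site identifiers")
        _check_unique(self.data.columns, "species identifiers")
        object.__setattr__(self, "data", _check_numeric(self.data, "abundance table"))
        arr = self.values
        if np.isnan(arr).any():
            raise ValidationError("abundance table contains missing values")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative abundance at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )
        if not self.relative and not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer abundance at row {self.data.index[r]!r}, "
                f"column {self.data.columns[c]!r}"
            )

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class TraitMatrix:
    """Species x traits table of species-mean trait values (the Q matrix).

    Missing values are permitted: not every trait is measured for every
    species.  Downstream tests apply per-trait pairwise deletion.
    """

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "species identifiers")
        _check_unique(self.data.columns, "trait names")
        object.__setattr__(self, "data", _check_numeric(self.data, "trait table"))

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def trait_names(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


_KINDS = {"env": EnvMatrix, "abundance": AbundanceMatrix, "trait": TraitMatrix}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, kind: str):
    """Read a delimited table as a typed matrix.

    The first row holds variable/species names, the first column the
    site/species identifiers.  The delimiter is chosen from the file
    extension (``.csv`` -> comma, anything else -> tab).

    Parameters
    ----------
    path : str or Path
    kind : {"env", "abundance", "trait"}

    Returns
    -------
    EnvMatrix, AbundanceMatrix or TraitMatrix
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_KINDS)}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return _KINDS[kind](df)


def write_table(matrix, path: str | Path) -> None:
    """Write a typed matrix back to CSV/TSV (delimiter from extension)."""
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path))


def standardize_columns(matrix):
    """Z-score every column to mean 0 and sample standard deviation 1.

    Uses the n-1 denominator.  Missing values (trait tables only) are
    ignored in the column moments and preserved in the output.  Raises
    :class:`ValidationError` naming the first constant column found.
    """
    df = matrix.data
    sd = df.std(ddof=1)
    bad = sd.index[(sd == 0) | sd.isna()]
    if len(bad):
        raise ValidationError(f"cannot standardize zero-variance column {bad[0]!r}")
    out = (df - df.mean()) / sd
    return replace(matrix, data=out, standardized=True)


def to_relative_abundance(L: AbundanceMatrix) -> AbundanceMatrix:
    """Divide every entry of L by the grand total so the table sums to 1."""
    total = L.values.sum()
    if total <= 0:
        raise ValidationError("abundance table is all zero; cannot normalize")
    return AbundanceMatrix(L.data / total, relative=True)


def log_transform_columns(matrix, columns: Iterable[str]):
    """Natural-log transform the named columns in place of their raw values.

    Intended for heavy-tailed trait variables (e.g. leaf aluminium
    content).  All values in a transformed column must be strictly
    positive.  Applied before standardization.
    """
    df = matrix.data.copy()
    for col in columns:
        if col not in df.columns:
            raise ValidationError(f"cannot log-transform unknown column {col!r}")
        vals = df[col]
        if (vals <= 0).any():
            raise ValidationError(
                f"log transform of column {col!r} requires strictly positive values"
            )
        df[col] = np.log(vals)
    return replace(matrix, data=df)


def align_triple(
    R: EnvMatrix, L: AbundanceMatrix, Q: TraitMatrix
) -> tuple[EnvMatrix, AbundanceMatrix, TraitMatrix]:
    """Align the triple on shared sites (R, L) and shared species (L, Q).

    Site order follows R restricted to the intersection; species order
    follows L.  Sites or species absent from a partner table are dropped
    with a logged warning, and all-zero rows/columns of L (and their R/Q
    counterparts) are removed until none remain.

    Raises
    ------
    AlignmentError
        If the site or species intersection is empty, or L becomes empty.
    """
    l_sites = set(L.site_ids)
    q_species = set(Q.species_ids)
    sites = [s for s in R.site_ids if s in l_sites]
    species = [sp for sp in L.species_ids if sp in q_species]
    if not sites:
        raise AlignmentError("no sites shared between R and L")
    if not species:
        raise AlignmentError("no species shared between L and Q")

    dropped_sites = sorted((set(R.site_ids) | l_sites) - set(sites))
    dropped_species = sorted((set(L.species_ids) | q_species) - set(species))

    r_df = R.data.loc[sites]
    l_df = L.data.loc[sites, species]
    q_df = Q.data.loc[species]

    # empty rows/columns of L are mutually entangled: iterate to a fixed point
    while True:
        col_ok = l_df.sum(axis=0) > 0
        row_ok = l_df.sum(axis=1) > 0
        if col_ok.all() and row_ok.all():
            break
        dropped_species += list(l_df.columns[~col_ok])
        dropped_sites += list(l_df.index[~row_ok])
        l_df = l_df.loc[row_ok, col_ok]
        r_df = r_df.loc[row_ok]
        q_df = q_df.loc[col_ok]
        if l_df.empty:
            raise AlignmentError("alignment removed every site or species")

    if dropped_sites:
        logger.warning("alignment dropped %d site(s): %s", len(dropped_sites), dropped_sites)
    if dropped_species:
        logger.warning(
            "alignment dropped %d species: %s", len(dropped_species), dropped_species
        )
    return (
        EnvMatrix(r_df, standardized=R.standardized),
        AbundanceMatrix(l_df, relative=L.relative),
        TraitMatrix(q_df, standardized=Q.standardized),
    )


def trait_coverage(L: AbundanceMatrix, Q: TraitMatrix) -> dict:
    """Report what share of the community the trait table covers.

    A species counts as covered when it appears in Q with at least one
    non-missing trait value.  Returns both species-level coverage
    (covered species / all species in L) and individual-level coverage
    (individuals of covered species / all individuals), as percentages.
    """
    covered_ids = set(Q.data.index[Q.data.notna().any(axis=1)])
    species = L.species_ids
    covered = [sp for sp in species if sp in covered_ids]
    total_ind = L.values.sum()
    if total_ind <= 0:
        raise ValidationError("abundance table is all zero")
    covered_ind = L.data[covered].to_numpy().sum()
    return {
        "n_species": len(species),
        "n_species_covered": len(covered),
        "species_pct": 100.0 * len(covered) / len(species),
        "n_individuals": int(total_ind),
        "n_individuals_covered": int(covered_ind),
        "individual_pct": 100.0 * covered_ind / total_ind,
    }
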