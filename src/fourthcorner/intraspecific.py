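"""Within-species trait-variation pipeline.

The interspecific (fourth-corner) analysis works on species-mean traits;
this module isolates the *intraspecific* component instead.  Replicate
trait measurements (one individual per plot, identified by the plot in
which it was sampled) are z-normalized within each species, which removes
all between-species differences.  The normalized values of the species
present in a plot are then averaged with abundance weights, and the
resulting plot scores are regressed against each environmental variable.
If within-species trait variation does not track the environment, the
number of significant regressions should be near the chance expectation
``alpha * n_tests``.

Replicate tables are long-format DataFrames with columns
``species_id, individual_id, trait, value`` where ``individual_id``
names the plot (site) in which the individual was sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import AbundanceMatrix, EnvMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "REPLICATE_COLUMNS",
    "NormalizationReport",
    "IntraspecificResult",
    "read_replicates",
    "normalize_within_species",
    "plot_weighted_score",
    "regress_against_environment",
]

REPLICATE_COLUMNS = ("species_id", "individual_id", "trait", "value")


@dataclass(frozen=True)
class NormalizationReport:
    """What the within-species normalization kept and dropped."""

    species_retained: tuple
    species_dropped: tuple        # fewer than two individuals
    traits_retained: tuple
    traits_dropped: tuple         # constant within every species
    pairs_dropped: int            # (species, trait) groups with n < 2 or sd = 0


@dataclass(frozen=True)
class IntraspecificResult:
    """Per-(trait, variable) regression results and significance counts.

    ``n_tests`` is the full retained-traits x variables grid; pairs
    skipped for insufficient data are listed in ``skipped`` but still
    counted in the grid, mirroring how the chance expectation
    ``alpha * n_tests`` is framed.
    """

    slope: pd.DataFrame
    pvalue: pd.DataFrame
    sign: pd.DataFrame
    alpha: float
    n_tests: int
    n_significant: int
    expected_false_positives: float
    skipped: tuple = field(default_factory=tuple)


def read_replicates(path: str | Path) -> pd.DataFrame:
    """Read a long-format replicate trait table (TSV/CSV by extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(REPLICATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"replicate table lacks columns: {sorted(missing)}")
    df = df.loc[:, list(REPLICATE_COLUMNS)].copy()
    df["species_id"] = df["species_id"].astype(str)
    df["individual_id"] = df["individual_id"].astype(str)
    df["trait"] = df["trait"].astype(str)
    df["value"] = pd.to_numeric(df["value"])
    return df


def normalize_within_species(
    replicates: pd.DataFrame,
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Z-score trait values within each species (sample sd, n-1).

    Species with fewer than two measured individuals are dropped, as are
    traits that do not vary within any species; individual (species,
    trait) groups with fewer than two values or zero spread are dropped
    too.  Drops are warnings, not errors.
    """
    df = replicates.dropna(subset=["value"]).copy()
    n_ind = df.groupby("species_id")["individual_id"].nunique()
    few = set(n_ind.index[n_ind < 2])
    if few:
        logger.warning("dropping %d species with <2 individuals", len(few))
    df = df[~df["species_id"].isin(few)]

    grp = df.groupby(["species_id", "trait"])["value"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    size = grp.transform("size")
    ok = (size >= 2) & (sd > 0)
    pairs_dropped = int(
        df.loc[~ok, ["species_id", "trait"]].drop_duplicates().shape[0]
    )
    out = df[ok].copy()
    out["value"] = (df.loc[ok, "value"] - mean[ok]) / sd[ok]

    traits_all = sorted(replicates["trait"].unique())
    traits_kept = sorted(out["trait"].unique())
    traits_dropped = tuple(t for t in traits_all if t not in traits_kept)
    if traits_dropped:
        logger.warning(
            "dropping %d trait(s) with no within-species variation: %s",
            len(traits_dropped),
            traits_dropped,
        )
    species_all = sorted(replicates["species_id"].unique())
    species_kept = sorted(out["species_id"].unique())
    report = NormalizationReport(
        species_retained=tuple(species_kept),
        species_dropped=tuple(s for s in species_all if s not in species_kept),
        traits_retained=tuple(traits_kept),
        traits_dropped=traits_dropped,
        pairs_dropped=pairs_dropped,
    )
    return out, report


def plot_weighted_score(normalized: pd.DataFrame, L: AbundanceMatrix) -> pd.DataFrame:
    """Abundance-weighted mean normalized trait value per plot.

    For each plot and trait the normalized values of species measured in
    that plot are averaged, weighted by the species' abundance in the
    plot.  When a species was sampled more than once in a plot its
    replicates are averaged first.  Plots with no measured species for a
    trait are NaN.
    """
    df = (
        normalized.groupby(["species_id", "individual_id", "trait"], as_index=False)[
            "value"
        ].mean()
    )
    df = df.rename(columns={"individual_id": "plot"})
    known_sites = set(L.site_ids)
    unknown = set(df["plot"]) - known_sites
    if unknown:
        logger.warning("ignoring replicates from %d plot(s) absent from L", len(unknown))
        df = df[df["plot"].isin(known_sites)]
    known_species = set(L.species_ids)
    df = df[df["species_id"].isin(known_species)]

    ab = L.data.stack()
    ab.index.names = ["plot", "species_id"]
    df = df.join(ab.rename("weight"), on=["plot", "species_id"])
    df = df[df["weight"] > 0]

    def _wmean(sub: pd.DataFrame) -> float:
        return float(np.average(sub["value"], weights=sub["weight"]))

    scores = (
        df.groupby(["plot", "trait"])[["value", "weight"]]
        .apply(_wmean)
        .unstack("trait")
    )
    traits = sorted(normalized["trait"].unique())
    return scores.reindex(index=L.site_ids, columns=traits)


def regress_against_environment(
    scores: pd.DataFrame, R: EnvMatrix, alpha: float = 0.05
) -> IntraspecificResult:
    """Simple OLS of each trait's plot scores on each environmental variable.

    Each (trait, variable) pair is fit on the plots where the score is
    defined; pairs with fewer than three usable plots are skipped and
    logged.  Two-sided p-values for the slope; significance at ``alpha``.
    The chance expectation ``alpha * n_tests`` over the full grid is
    reported alongside the observed count.
    """
    scores = scores.loc[[s for s in R.site_ids if s in scores.index]]
    traits = list(scores.columns)
    variables = R.var_names
    slope = pd.DataFrame(np.nan, index=traits, columns=variables)
    pval = pd.DataFrame(np.nan, index=traits, columns=variables)
    skipped = []
    for t in traits:
        y_all = scores[t]
        mask = y_all.notna()
        for v in variables:
            if mask.sum() < 3:
                skipped.append((t, v))
                continue
            x = R.data.loc[mask[mask].index, v].to_numpy()
            y = y_all[mask].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped.append((t, v))
                continue
            fit = stats.linregress(x, y)
            slope.loc[t, v] = fit.slope
            pval.loc[t, v] = fit.pvalue
    if skipped:
        logger.warning("skipped %d (trait, variable) pair(s) with insufficient data", len(skipped))
    sig = pval.le(alpha) & pval.notna()
    sign = pd.DataFrame(0, index=traits, columns=variables, dtype=int)
    sign[sig & slope.gt(0)] = 1
    sign[sig & slope.lt(0)] = -1
    n_tests = len(traits) * len(variables)
    return IntraspecificResult(
        slope=slope,
        pvalue=pval,
        sign=sign,
        alpha=alpha,
        n_tests=n_tests,
        n_significant=int(sig.to_numpy().sum()),
        expected_false_positives=alpha * n_tests,
        skipped=tuple(skipped),
    )
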