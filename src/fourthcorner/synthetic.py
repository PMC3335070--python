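"""Synthetic community generator with known environmental-filtering structure.

Communities are assembled along a one-dimensional latent gradient (think
of successional time rescaled to [0, 1]).  Each species has a Gaussian
niche on the gradient: its expected abundance at a site is

    lambda_sj = A * exp(-(g_s - mu_j)^2 / (2 sigma^2))

with site gradient position ``g_s``, species optimum ``mu_j`` drawn
uniformly on the gradient, niche breadth ``sigma`` and abundance scale
``A``; observed counts are Poisson.  Environmental variables are either
coupled to the gradient (slope ``env_coupling`` plus Gaussian noise) or
pure noise; species-mean traits are either coupled to the species'
optimum (slope ``trait_coupling`` plus noise) or pure noise.  A (trait,
variable) pair is truly linked exactly when both slopes are nonzero, and
the generator records this ground truth so detection and calibration can
be scored against it.

Replicate-level trait tables for the intraspecific pipeline assign each
sampled individual to a plot where its species occurs; an optional
environment-dependent shift creates genuine within-species structure for
power tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .matrices import AbundanceMatrix, EnvMatrix, TraitMatrix, ValidationError

__all__ = ["SyntheticConfig", "GroundTruth", "SyntheticDataset", "generate", "generate_replicates"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the filtering simulation.

    Defaults match the motivating study design: 27 sites on the
    gradient, 122 species, 16 environmental variables (half coupled to
    the gradient), 26 traits (half coupled to the niche optima).
    """

    n_sites: int = 27
    n_species: int = 122
    n_env: int = 16
    n_traits: int = 26
    gradient: Sequence[float] | None = None  # default: equally spaced on [0, 1]
    niche_breadth: float = 0.15              # sigma, in gradient units
    trait_coupling: Sequence[float] | float | None = None  # beta per trait
    env_coupling: Sequence[float] | float | None = None    # slope per variable
    abundance_scale: float = 15.0            # expected individuals at the optimum
    env_noise_sd: float = 0.3
    trait_noise_sd: float = 0.3
    intraspecific_sd: Sequence[float] | float = 0.25
    overdispersion: float | None = None      # negative-binomial shape; None = Poisson
    drop_empty: bool = True
    max_retries: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.niche_breadth <= 0:
            raise ValidationError("niche breadth must be > 0")
        if self.abundance_scale <= 0:
            raise ValidationError("abundance scale must be > 0")
        if self.env_noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")

    def gradient_values(self) -> np.ndarray:
        if self.gradient is not None:
            g = np.asarray(self.gradient, dtype=float)
            if g.shape != (self.n_sites,):
                raise ValidationError("gradient must have one value per site")
            return g
        if self.n_sites == 1:
            return np.array([0.5])
        return np.linspace(0.0, 1.0, self.n_sites)

    def trait_slopes(self) -> np.ndarray:
        return _expand(self.trait_coupling, self.n_traits, default_head=2.0)

    def env_slopes(self) -> np.ndarray:
        return _expand(self.env_coupling, self.n_env, default_head=1.0)


def _expand(slopes, n: int, default_head: float) -> np.ndarray:
    """Per-item slopes: scalar broadcasts; None couples the first half."""
    if slopes is None:
        out = np.zeros(n)
        out[: n // 2] = default_head
        return out
    arr = np.asarray(slopes, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValidationError(f"expected {n} slopes, got shape {arr.shape}")
    return arr.copy()


@dataclass(frozen=True)
class GroundTruth:
    """The latent structure behind one generated dataset."""

    gradient: pd.Series       # site -> gradient position
    optima: pd.Series         # species -> niche optimum
    env_coupling: pd.Series   # variable -> slope on the gradient
    trait_coupling: pd.Series  # trait -> slope on the optimum

    @property
    def coupled_pairs(self) -> list[tuple[str, str]]:
        """(trait, variable) pairs linked through the gradient."""
        return [
            (t, v)
            for t in self.trait_coupling.index[self.trait_coupling != 0]
            for v in self.env_coupling.index[self.env_coupling != 0]
        ]

    def pair_effect(self, trait: str, variable: str) -> float:
        return float(self.trait_coupling[trait] * self.env_coupling[variable])


@dataclass(frozen=True)
class SyntheticDataset:
    R: EnvMatrix
    L: AbundanceMatrix
    Q: TraitMatrix
    truth: GroundTruth
    config: SyntheticConfig


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, k: float | None) -> np.ndarray:
    if k is None:
        return rng.poisson(lam)
    # negative binomial with mean lam and shape k (variance lam + lam^2 / k)
    return rng.poisson(rng.gamma(k, lam / k))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one (R, L, Q) triple plus its ground truth.

    Species that never occur and sites with no individuals are dropped
    (when ``drop_empty``); if every entry of L is zero the draw is
    retried up to ``max_retries`` times before failing.
    """
    rng = np.random.default_rng(config.seed)
    g = config.gradient_values()
    beta = config.trait_slopes()
    gamma = config.env_slopes()

    for _ in range(max(1, config.max_retries)):
        mu = rng.uniform(0.0, 1.0, config.n_species)
        lam = config.abundance_scale * np.exp(
            -((g[:, None] - mu[None, :]) ** 2) / (2.0 * config.niche_breadth**2)
        )
        counts = _draw_counts(rng, lam, config.overdispersion)
        if counts.sum() > 0:
            break
    else:
        raise ValidationError("generated an all-zero abundance matrix in every retry")

    env = g[:, None] * gamma[None, :] + rng.normal(
        0.0, config.env_noise_sd, (config.n_sites, config.n_env)
    )
    traits = mu[:, None] * beta[None, :] + rng.normal(
        0.0, config.trait_noise_sd, (config.n_species, config.n_traits)
    )

    sites = [f"site{i + 1:03d}" for i in range(config.n_sites)]
    species = [f"sp{j + 1:03d}" for j in range(config.n_species)]
    env_names = [f"env{k + 1:02d}" for k in range(config.n_env)]
    trait_names = [f"trait{m + 1:02d}" for m in range(config.n_traits)]

    l_df = pd.DataFrame(counts, index=sites, columns=species)
    r_df = pd.DataFrame(env, index=sites, columns=env_names)
    q_df = pd.DataFrame(traits, index=species, columns=trait_names)
    g_series = pd.Series(g, index=sites, name="gradient")
    mu_series = pd.Series(mu, index=species, name="optimum")

    if config.drop_empty:
        keep_sp = l_df.columns[l_df.sum(axis=0) > 0]
        l_df = l_df[keep_sp]
        q_df = q_df.loc[keep_sp]
        mu_series = mu_series[keep_sp]
        keep_site = l_df.index[l_df.sum(axis=1) > 0]
        l_df = l_df.loc[keep_site]
        r_df = r_df.loc[keep_site]
        g_series = g_series[keep_site]

    truth = GroundTruth(
        gradient=g_series,
        optima=mu_series,
        env_coupling=pd.Series(gamma, index=env_names),
        trait_coupling=pd.Series(beta, index=trait_names),
    )
    return SyntheticDataset(
        R=EnvMatrix(r_df),
        L=AbundanceMatrix(l_df),
        Q=TraitMatrix(q_df),
        truth=truth,
        config=config,
    )


def generate_replicates(
    dataset: SyntheticDataset,
    k_per_species: int = 5,
    env_slope: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate-level trait values for the intraspecific pipeline.

    Each species is sampled in up to ``k_per_species`` distinct plots
    chosen among the plots where it occurs (species occupying fewer
    plots get one individual per occupied plot; with a single occupied
    plot the species will later be dropped by the >=2-individuals rule).
    A replicate's value is the species mean plus Gaussian intraspecific
    noise, plus ``env_slope * gradient(plot)`` when an environment-
    dependent within-species shift is requested (zero slope gives a null
    dataset for calibration).

    Returns the long-format table consumed by
    :func:`fourthcorner.intraspecific.normalize_within_species`.
    """
    if k_per_species < 1:
        raise ValidationError("k_per_species must be >= 1")
    cfg = dataset.config
    rng = np.random.default_rng(
        [cfg.seed if seed is None else seed, 104729]  # distinct stream from generate()
    )
    sd_series = pd.Series(
        _expand(cfg.intraspecific_sd, cfg.n_traits, default_head=0.0),
        index=dataset.Q.trait_names,
    )
    g = dataset.truth.gradient
    records = []
    for sp in dataset.L.species_ids:
        occupied = dataset.L.data.index[dataset.L.data[sp] > 0]
        k = min(k_per_species, len(occupied))
        plots = rng.choice(occupied, size=k, replace=False)
        for plot in plots:
            shift = env_slope * g[plot]
            for trait in dataset.Q.trait_names:
                mean = dataset.Q.data.loc[sp, trait]
                noise = rng.normal(0.0, sd_series[trait]) if sd_series[trait] > 0 else 0.0
                records.append((sp, plot, trait, mean + shift + noise))
    return pd.DataFrame(records, columns=["species_id", "individual_id", "trait", "value"])
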