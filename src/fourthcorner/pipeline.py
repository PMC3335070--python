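"""End-to-end analysis pipeline and report bundle.

Runs, in order: table reading and alignment, optional log transforms,
derived site variables, PCA of R and Q, the fourth-corner permutation
test under the requested null models, the model-comparison count table,
and (when a replicate table is supplied) the intraspecific pipeline.
Every stage appends to a MANIFEST file so partial output is
interpretable, and a machine-readable JSON summary ties the numbers
together.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import community_metrics, fourth_corner, intraspecific, matrices

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    env_path: str
    abund_path: str
    traits_path: str
    out_dir: str
    replicates_path: str | None = None
    models: tuple[str, ...] = ("I", "II", "IV")
    n_perm: int = 9999
    alpha: float = 0.05
    seed: int = 0
    rarefy_n: int = 100
    deciduous_trait: str | None = None
    log_traits: tuple[str, ...] = ()
    log_env: tuple[str, ...] = ()
    holm: bool = False

    def __post_init__(self) -> None:
        if not self.models:
            raise matrices.ValidationError("at least one permutation model is required")
        bad = [m for m in self.models if m not in fourth_corner.MODELS]
        if bad:
            raise matrices.ValidationError(f"unknown permutation model(s): {bad}")
        if self.n_perm < 1:
            raise matrices.ValidationError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise matrices.ValidationError("alpha must lie in (0, 1)")
        if self.rarefy_n < 1:
            raise matrices.ValidationError("rarefy_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("models", "log_traits", "log_env"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("models", "log_traits", "log_env"):
            d[key] = list(d[key])
        return d


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the JSON-style summary dict.

    Outputs under ``cfg.out_dir``: the echoed config, per-site structure
    table, PCA scores/loadings/variance for R and Q, the fourth-corner r
    matrix, per-model p and sign matrices, the model-comparison count
    table (variables x models with a Sum row), the intraspecific sign
    matrix and summary, ``summary.json`` and a MANIFEST of completed
    stages.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "MANIFEST"
    manifest.write_text("")

    def done(stage: str) -> None:
        with manifest.open("a") as fh:
            fh.write(stage + "\n")
        logger.info("stage complete: %s", stage)

    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    done("config")

    summary: dict = {"schema_version": SCHEMA_VERSION, "config": cfg.to_dict()}

    R = matrices.read_table(cfg.env_path, "env")
    L = matrices.read_table(cfg.abund_path, "abundance")
    Q = matrices.read_table(cfg.traits_path, "trait")
    if cfg.log_env:
        R = matrices.log_transform_columns(R, cfg.log_env)
    if cfg.log_traits:
        Q = matrices.log_transform_columns(Q, cfg.log_traits)
    R, L, Q = matrices.align_triple(R, L, Q)
    summary["dimensions"] = {
        "n_sites": L.shape[0],
        "n_species": L.shape[1],
        "n_env": R.shape[1],
        "n_traits": Q.shape[1],
    }
    done("read_align")

    structure = community_metrics.structure_variables(
        L, Q, deciduous_trait=cfg.deciduous_trait, rarefy_n=cfg.rarefy_n
    )
    _write(structure, out / "structure.tsv")
    done("structure")

    for label, M in (("env", R), ("traits", Q)):
        if M.data.isna().any().any():
            logger.warning("skipping %s PCA: matrix has missing values", label)
            continue
        ord_res = community_metrics.pca(M)
        _write(ord_res.scores, out / f"pca_{label}_scores.tsv")
        _write(ord_res.loadings, out / f"pca_{label}_loadings.tsv")
        pd.Series(
            ord_res.explained_variance,
            index=ord_res.scores.columns,
            name="explained_fraction",
        ).to_csv(out / f"pca_{label}_variance.tsv", sep="\t")
        summary.setdefault("pca", {})[label] = [
            float(v) for v in ord_res.explained_variance
        ]
    done("pca")

    counts_cols = {}
    summary["fourth_corner"] = {}
    for model in cfg.models:
        res = fourth_corner.fourth_corner_test(
            R, L, Q, model=model, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed
        )
        if model == cfg.models[0]:
            _write(res.r.round(10), out / "fc_r.tsv")
        _write(res.p, out / f"fc_p_{model}.tsv")
        _write(res.sign, out / f"fc_sign_{model}.tsv")
        if cfg.holm:
            _write(fourth_corner.holm_adjust(res.p), out / f"fc_p_holm_{model}.tsv")
        counts = fourth_corner.count_significances(res)
        counts_cols[f"model_{model}"] = counts.per_variable
        summary["fourth_corner"][model] = {
            "total_significant": counts.total,
            "per_variable": {k: int(v) for k, v in counts.per_variable.items()},
            "n_undefined_cells": int(res.r.isna().to_numpy().sum()),
        }
        done(f"fourth_corner_{model}")

    count_table = pd.DataFrame(counts_cols)
    count_table.loc["Sum"] = count_table.sum()
    _write(count_table, out / "significance_counts.tsv")
    done("count_table")

    if cfg.replicates_path is not None:
        reps = intraspecific.read_replicates(cfg.replicates_path)
        normalized, report = intraspecific.normalize_within_species(reps)
        scores = intraspecific.plot_weighted_score(normalized, L)
        intra = intraspecific.regress_against_environment(scores, R, alpha=cfg.alpha)
        _write(intra.sign, out / "intraspecific_sign.tsv")
        _write(intra.pvalue, out / "intraspecific_p.tsv")
        summary["intraspecific"] = {
            "n_tests": intra.n_tests,
            "n_significant": intra.n_significant,
            "expected_false_positives": intra.expected_false_positives,
            "n_traits_retained": len(report.traits_retained),
            "n_species_retained": len(report.species_retained),
            "n_pairs_skipped": len(intra.skipped),
        }
        done("intraspecific")

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    done("summary")
    return summary
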