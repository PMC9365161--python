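"""End-to-end applied-analysis workflow.

Mirrors the usual one-sample interaction-MR analysis plan: split off a
discovery subset, scan it for gene-by-covariate interactions, then estimate
on the held-out data with MR-GxE per selected covariate alongside the
instrument-covariate correlation and sub-instrument Sargan sensitivity
checks, plus MR-GENIUS, conventional TSLS, and OLS comparators. Diagnostic
flags are reported, never auto-excluded: deciding whether a covariate is
downstream of the exposure is subject-matter judgement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset
from .diagnostics import (
    build_prs,
    gz_correlation,
    interaction_scan,
    sargan_gxe,
)
from .estimators import fit_mr_genius, fit_mr_gxe, fit_ols, fit_tsls
from .exceptions import InputError
from .io import RunManifest, read_table, write_json, write_table

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("mrgxe")


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters (all paths and column bindings)."""

    data: str
    outcome: str
    exposure: str
    instrument: str | None = None
    instruments: list[str] | None = None
    weights: list[float] | None = None
    covariates: list[str] | None = None
    discovery_fraction: float = 0.5
    standardize: tuple[str, ...] = ()  # subset of {outcome, exposure, score}
    alpha: float = 0.05
    top_k: int = 20
    m_groups: int = 9
    seed: int | None = None
    out_dir: str = "."
    delimiter: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.discovery_fraction < 1.0:
            raise InputError("discovery_fraction must lie in [0, 1)")
        bad = set(self.standardize) - {"outcome", "exposure", "score"}
        if bad:
            raise InputError(f"unknown standardize roles: {sorted(bad)}")


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise InputError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def _subset(data: Dataset, idx: np.ndarray) -> Dataset:
    return Dataset(
        y=data.y[idx],
        x=data.x[idx],
        g=None if data.g is None else data.g[idx],
        g_matrix=None if data.g_matrix is None else data.g_matrix[idx],
        z=None if data.z is None else data.z.iloc[idx].reset_index(drop=True),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the result bundle.

    Writes, under ``config.out_dir``: ``scan.tsv`` (discovery-sample
    interaction scan), ``results.tsv`` (one row per selected covariate with
    the MR-GxE estimate and sensitivity checks, then OLS / TSLS / MR-GENIUS
    comparator rows), ``forest.tsv`` (plot-ready estimates and intervals),
    ``results.json`` (full coefficient sets) and ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    data = read_table(
        config.data,
        outcome=config.outcome,
        exposure=config.exposure,
        instrument=config.instrument,
        instruments=config.instruments,
        covariates=config.covariates,
        delimiter=config.delimiter,
    )
    if data.g_matrix is not None:
        score = build_prs(
            data.g_matrix,
            weights=config.weights,
            standardize="score" in config.standardize,
        )
        data = Dataset(
            y=data.y, x=data.x, g=score, g_matrix=data.g_matrix, z=data.z
        )
    elif "score" in config.standardize:
        data = Dataset(
            y=data.y, x=data.x, g=_zscore(data.g), g_matrix=None, z=data.z
        )
    if "outcome" in config.standardize:
        data = Dataset(y=_zscore(data.y), x=data.x, g=data.g,
                       g_matrix=data.g_matrix, z=data.z)
    if "exposure" in config.standardize:
        data = Dataset(y=data.y, x=_zscore(data.x), g=data.g,
                       g_matrix=data.g_matrix, z=data.z)

    rng = np.random.default_rng(config.seed)
    n = data.n
    if config.discovery_fraction > 0:
        perm = rng.permutation(n)
        n_disc = int(round(config.discovery_fraction * n))
        disc_idx, est_idx = np.sort(perm[:n_disc]), np.sort(perm[n_disc:])
        if est_idx.size == 0:
            raise InputError("empty estimation set after discovery split")
        discovery, estimation = _subset(data, disc_idx), _subset(data, est_idx)
    else:
        logger.warning(
            "discovery_fraction = 0: interactions are selected and estimated "
            "on the same sample; estimates are exposed to winner's curse"
        )
        discovery = estimation = data

    scan = interaction_scan(discovery, alpha=config.alpha)
    selected = scan.table.loc[scan.table["passes"], "covariate"].head(config.top_k)

    rows, fits = [], {}
    for name in selected:
        fit = fit_mr_gxe(estimation, name)
        corr = gz_correlation(estimation, name)
        row = {
            "covariate": name,
            "f_stat": fit.f_interaction,
            "beta1": fit.beta1,
            "beta1_se": fit.beta1_se,
            "beta1_pvalue": _wald_p(fit.beta1, fit.beta1_se),
            "beta2": fit.beta2,
            "gz_correlation": corr.correlation,
            "gz_pvalue": corr.pvalue,
            "sargan_stat": np.nan,
            "sargan_pvalue": np.nan,
            "mean_sub_f": np.nan,
        }
        if estimation.g_matrix is not None and estimation.g_matrix.shape[1] >= config.m_groups:
            over = sargan_gxe(
                estimation,
                name,
                m_groups=config.m_groups,
                seed=config.seed,
                per_group=False,
            )
            from .diagnostics import partition_sub_instruments

            part = partition_sub_instruments(
                estimation.g_matrix, estimation.x, config.m_groups, seed=config.seed
            )
            row["sargan_stat"] = over.statistic
            row["sargan_pvalue"] = over.pvalue
            row["mean_sub_f"] = float(part.sub_f.mean())
        rows.append(row)
        fits[name] = fit

    ols = fit_ols(estimation)
    tsls = fit_tsls(
        estimation.y, estimation.x, estimation.score,
        endog_names=["x"],
    )
    genius = fit_mr_genius(estimation)
    comparators = [
        {"covariate": "OLS", "beta1": ols.beta, "beta1_se": ols.se,
         "beta1_pvalue": _wald_p(ols.beta, ols.se)},
        {"covariate": "TSLS", "f_stat": tsls.first_stage_f,
         "beta1": float(tsls.params["x"]), "beta1_se": float(tsls.se["x"]),
         "beta1_pvalue": _wald_p(float(tsls.params["x"]), float(tsls.se["x"]))},
        {"covariate": "MR-GENIUS", "f_stat": genius.bp_stat,
         "beta1": genius.beta1, "beta1_se": genius.beta1_se,
         "beta1_pvalue": _wald_p(genius.beta1, genius.beta1_se)},
    ]
    results = pd.DataFrame(rows + comparators)

    from .estimators import Z95

    forest = results[["covariate", "beta1", "beta1_se"]].copy()
    forest["ci_low"] = forest["beta1"] - Z95 * forest["beta1_se"]
    forest["ci_high"] = forest["beta1"] + Z95 * forest["beta1_se"]

    write_table(scan.table, out_dir / "scan.tsv")
    write_table(results, out_dir / "results.tsv")
    write_table(forest, out_dir / "forest.tsv")
    write_json({"fits": fits, "genius": genius}, out_dir / "results.json")
    manifest = RunManifest.create(
        "pipeline", vars(config).copy(), inputs=[config.data], seed=config.seed
    )
    manifest.save(out_dir / "manifest.json")
    return {
        "scan": scan,
        "results": results,
        "forest": forest,
        "fits": fits,
        "ols": ols,
        "tsls": tsls,
        "genius": genius,
        "manifest": manifest,
    }


def _wald_p(beta: float, se: float) -> float:
    from scipy import stats

    if se <= 0:
        return float("nan")
    return float(2 * stats.norm.sf(abs(beta) / se))
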