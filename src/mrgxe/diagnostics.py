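"""Assumption diagnostics for interaction-based MR.

The three identifying assumptions each get a testing tool:

* GxE1 (interaction strength): :func:`interaction_scan` fits the first-stage
  interaction model for every candidate covariate and reports the partial
  F-statistic of the interaction term with Bonferroni-corrected significance
  flags -- the Manhattan-plot analogue of a GWAS scan.
* GxE2 (interaction exogeneity): :func:`gz_correlation` checks the
  instrument-covariate correlation. Independence of G and Z does **not**
  prove GxE2 (a three-way interaction with a confounder can hide behind a
  zero correlation); a non-zero correlation flags a configuration where
  conditioning on Z can induce collider bias.
* GxE3 (constant pleiotropy): when the instrument is composite (e.g. a
  polygenic score), :func:`partition_sub_instruments` splits its components
  into groups of approximately equal strength and :func:`sargan_gxe` /
  :func:`cochran_q` test agreement of the per-group MR-GxE estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .exceptions import IdentificationError, InputError

__all__ = [
    "ScanResult",
    "CorrelationResult",
    "SubInstrumentPartition",
    "OverIdResult",
    "interaction_scan",
    "gz_correlation",
    "partition_sub_instruments",
    "sargan_gxe",
    "cochran_q",
    "build_prs",
]

_LN10 = np.log(10.0)


def _interaction_coefs(
    g: np.ndarray, Z: np.ndarray, targets: np.ndarray, robust: bool = True
):
    """Per-covariate interaction-term statistics.

    For each column z_k of Z, regresses every column t of ``targets`` on
    {1, g, z_k, g z_k} and extracts the interaction coefficient. Returns
    ``(coef, f_stat, log_pvalue)`` where ``coef`` is (K, T), and ``f_stat``
    / ``log_pvalue`` (natural-log survival value, K,) refer to the first
    target column (the partial F of the interaction, equal to its squared
    t-statistic). Singular designs yield NaN rows.

    ``robust=True`` (default) uses the HC0 sandwich variance for the
    interaction coefficient. This matters: when other covariates carry
    strong interactions, the residual variance of any single-covariate
    first-stage model grows with G**2, and the classical F for a *null*
    covariate is badly anti-conservative -- a Bonferroni scan would then
    admit spurious interactions at a large multiple of its nominal rate.

    Implemented through per-covariate 4x4 normal equations so a full
    K-covariate scan costs a handful of matrix-vector products.
    """
    n = g.shape[0]
    T = targets.shape[1]
    K = Z.shape[1]
    g2 = g * g
    ones = np.ones(n)
    s_g, s_g2 = g.sum(), g2.sum()
    s_g3, s_g4 = (g2 * g).sum(), (g2 * g2).sum()
    Z2 = Z * Z
    s_z = Z.sum(axis=0)
    s_gz = g @ Z
    s_g2z = g2 @ Z
    s_g3z = (g2 * g) @ Z
    s_z2 = Z2.sum(axis=0)
    s_gz2 = g @ Z2
    s_g2z2 = g2 @ Z2
    s_t = targets.sum(axis=0)
    s_gt = g[:, None] * targets
    s_gt_sum = s_gt.sum(axis=0)
    s_zt = Z.T @ targets  # (K, T)
    s_qt = Z.T @ s_gt  # (K, T): sum z_k g t
    s_tt = (targets * targets).sum(axis=0)

    coef = np.full((K, T), np.nan)
    f_stat = np.full(K, np.nan)
    log_p = np.full(K, np.nan)
    df = n - 4
    for k in range(K):
        gram = np.array(
            [
                [n, s_g, s_z[k], s_gz[k]],
                [s_g, s_g2, s_gz[k], s_g2z[k]],
                [s_z[k], s_gz[k], s_z2[k], s_gz2[k]],
                [s_gz[k], s_g2z[k], s_gz2[k], s_g2z2[k]],
            ]
        )
        rhs = np.vstack([s_t, s_gt_sum, s_zt[k], s_qt[k]])
        try:
            ginv = np.linalg.inv(gram)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.cond(gram) > 1e12:
            continue
        b = ginv @ rhs  # (4, T)
        coef[k] = b[3]
        rss = s_tt[0] - rhs[:, 0] @ b[:, 0]
        if rss <= 0 or df <= 0:
            continue
        if robust:
            D = np.column_stack([ones, g, Z[:, k], g * Z[:, k]])
            e = targets[:, 0] - D @ b[:, 0]
            meat = D.T @ (D * (e * e)[:, None])
            var_q = (ginv @ meat @ ginv)[3, 3]
        else:
            var_q = rss / df * ginv[3, 3]
        if var_q <= 0:
            continue
        f_stat[k] = b[3, 0] ** 2 / var_q
        log_p[k] = stats.f.logsf(f_stat[k], 1, df)
    return coef, f_stat, log_p


@dataclass
class ScanResult:
    """Interaction-strength scan over candidate covariates.

    ``table`` has one row per covariate, sorted by descending interaction F
    (invalid covariates last), with Bonferroni pass flags computed at
    ``alpha / n_tested``. The (covariate, neg_log10_p, threshold) triple is
    the plot-ready Manhattan data.
    """

    table: pd.DataFrame
    alpha: float
    bonferroni_threshold: float
    n_tested: int

    def passing(self) -> list[str]:
        return list(self.table.loc[self.table["passes"], "covariate"])


def interaction_scan(
    data: Dataset, alpha: float = 0.05, robust: bool = True
) -> ScanResult:
    """First-stage interaction F-statistic for every candidate covariate.

    Fits X ~ 1 + G + Z_k + G*Z_k per covariate and reports the partial F of
    the interaction term (the squared t-statistic) with its p-value against
    the F distribution with (1, n-4) degrees of freedom. The variance is
    heteroskedasticity-robust by default because interactions elsewhere
    make each single-covariate model's residual variance depend on G,
    inflating the classical statistic for null covariates; ``robust=False``
    restores the classical partial F. Constant or collinear covariates are
    flagged invalid with a reason and excluded from the Bonferroni
    denominator.
    """
    if data.z is None or data.z.shape[1] == 0:
        raise InputError("no candidate interaction covariates in dataset")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    g = data.score
    mask = data.complete_cases([data.x, g])
    x, g = data.x[mask], g[mask]
    Z = data.z.to_numpy(dtype=float)[mask]
    names = list(data.z.columns)
    K = Z.shape[1]

    _, f_stat, log_p = _interaction_coefs(g, Z, x[:, None], robust=robust)
    valid = np.isfinite(f_stat)
    n_tested = int(valid.sum())
    if n_tested == 0:
        raise InputError("no valid (non-degenerate) covariates to scan")
    threshold = alpha / n_tested
    pvalue = np.where(valid, np.exp(log_p), np.nan)
    neg_log10_p = np.where(valid, -log_p / _LN10, np.nan)
    table = pd.DataFrame(
        {
            "covariate": names,
            "f_stat": f_stat,
            "pvalue": pvalue,
            "neg_log10_p": neg_log10_p,
            "passes": valid & (pvalue < threshold),
            "valid": valid,
            "reason": [
                "" if v else "constant or collinear covariate" for v in valid
            ],
        }
    )
    table = table.sort_values(
        ["valid", "f_stat"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)
    return ScanResult(
        table=table,
        alpha=alpha,
        bonferroni_threshold=threshold,
        n_tested=n_tested,
    )


@dataclass
class CorrelationResult:
    """Pearson correlation between instrument and covariate with its
    two-sided p-value. A small correlation is necessary but not sufficient
    for interaction exogeneity (GxE2)."""

    correlation: float
    pvalue: float
    n_used: int


def gz_correlation(data: Dataset, covariate) -> CorrelationResult:
    """Instrument-covariate Pearson correlation (GxE2 screen)."""
    name, z = data.covariate(covariate)
    g = data.score
    mask = data.complete_cases([g, z])
    g, z = g[mask], z[mask]
    if np.var(g) == 0:
        raise InputError("instrument g is constant")
    if np.var(z) == 0:
        raise InputError(f"covariate {name!r} is constant")
    r = stats.pearsonr(g, z)
    return CorrelationResult(
        correlation=float(r.statistic),
        pvalue=float(r.pvalue),
        n_used=int(mask.sum()),
    )


@dataclass
class SubInstrumentPartition:
    """Assignment of sub-instruments to composite groups.

    ``assignment[j]`` is the group (0..M-1) of sub-instrument j;
    ``group_scores`` holds the per-group composite scores, ``group_f`` their
    first-stage F against the exposure, ``sub_f`` the individual
    sub-instrument F-statistics, and ``group_strength`` the summed member F
    the balancing greedy heuristic equalises.
    """

    assignment: np.ndarray
    M: int
    group_scores: np.ndarray = field(repr=False)
    group_f: np.ndarray
    sub_f: np.ndarray
    group_strength: np.ndarray


def _marginal_f(cols: np.ndarray, x: np.ndarray) -> np.ndarray:
    """F-statistic of x ~ 1 + col for each column (vectorised via the
    squared correlation identity F = r^2 (n-2) / (1 - r^2))."""
    n = x.shape[0]
    xc = x - x.mean()
    cc = cols - cols.mean(axis=0)
    sx = float(xc @ xc)
    sc = (cc * cc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (xc @ cc) ** 2 / (sx * sc)
        f = r2 * (n - 2) / (1.0 - r2)
    return f


def partition_sub_instruments(
    g_matrix,
    x,
    M: int,
    seed: int | None = None,
    weights=None,
) -> SubInstrumentPartition:
    """Randomly assort sub-instruments into M groups of approximately equal
    strength.

    Strength is the first-stage F of each sub-instrument against the
    exposure. Assignment is a randomised greedy bin-packing: sub-instruments
    are taken in descending F order (ties broken randomly under ``seed``)
    and each is placed in the weakest group among those currently smallest,
    so group sizes never differ by more than one while summed strengths are
    equalised. Group composite scores are unweighted sums of member columns
    (weighted when ``weights`` is given). Reproducible under ``seed``.
    """
    gm = np.asarray(g_matrix, dtype=float)
    if gm.ndim != 2:
        raise InputError("g_matrix must be 2-dimensional")
    n, m = gm.shape
    if not 2 <= M <= m:
        raise InputError(
            f"group count M={M} must satisfy 2 <= M <= {m} (sub-instrument count)"
        )
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != n:
        raise InputError("x length does not match g_matrix rows")
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()
        if weights.shape[0] != m:
            raise InputError("weights length must equal sub-instrument count")
        gm = gm * weights

    rng = np.random.default_rng(seed)
    sub_f = _marginal_f(gm, x)
    order = np.lexsort((rng.random(m), -sub_f))
    assignment = np.empty(m, dtype=int)
    totals = np.zeros(M)
    counts = np.zeros(M, dtype=int)
    for j in order:
        cand = np.flatnonzero(counts == counts.min())
        lo = totals[cand].min()
        cand = cand[totals[cand] == lo]
        pick = int(rng.choice(cand))
        assignment[j] = pick
        totals[pick] += sub_f[j]
        counts[pick] += 1
    group_scores = np.zeros((n, M))
    for grp in range(M):
        group_scores[:, grp] = gm[:, assignment == grp].sum(axis=1)
    group_f = _marginal_f(group_scores, x)
    return SubInstrumentPartition(
        assignment=assignment,
        M=M,
        group_scores=group_scores,
        group_f=group_f,
        sub_f=sub_f,
        group_strength=totals,
    )


@dataclass
class OverIdResult:
    """Over-identification test over sub-instrument groups."""

    statistic: float
    df: int
    pvalue: float
    method: str
    per_group_estimates: pd.DataFrame | None = None
    ivw_estimate: float | None = None


def sargan_gxe(
    data: Dataset,
    covariate,
    partition: SubInstrumentPartition | None = None,
    m_groups: int = 9,
    seed: int | None = None,
    per_group: bool = True,
) -> OverIdResult:
    """Sargan over-identification test of constant pleiotropy (GxE3).

    Fits one TSLS with the M group-score interactions {S_m * Z} as excluded
    instruments, the group scores {S_m} and Z included exogenous, and X
    endogenous -- the multi-sub-instrument analogue of the MR-GxE model.
    The statistic is n R-squared from regressing the TSLS residuals on all
    instruments and exogenous regressors, chi-square with M - 1 degrees of
    freedom under the null that every group identifies the same causal
    effect. Identical violation across all groups is *not* detectable.
    """
    from .estimators import Z95, fit_tsls

    if partition is None:
        if data.g_matrix is None:
            raise InputError("sargan_gxe needs a sub-instrument matrix or partition")
        partition = partition_sub_instruments(
            data.g_matrix, data.x, m_groups, seed=seed
        )
    if partition.M < 2:
        raise InputError("just-identified: over-identification untestable with M = 1")
    name, z = data.covariate(covariate)
    S = partition.group_scores
    mask = data.complete_cases([data.y, data.x, z] + [S[:, i] for i in range(S.shape[1])])
    y, x, z, S = data.y[mask], data.x[mask], z[mask], S[mask]
    instruments = S * z[:, None]
    exog = np.hstack([S, z[:, None]])
    fit = fit_tsls(
        y,
        x,
        instruments,
        exog=exog,
        endog_names=["x"],
        exog_names=[f"S{i + 1}" for i in range(S.shape[1])] + [name],
    )
    groups = None
    if per_group:
        rows = []
        for mgr in range(S.shape[1]):
            sub = fit_tsls(
                y,
                x,
                S[:, mgr] * z,
                exog=np.column_stack([S[:, mgr], z]),
                endog_names=["x"],
                exog_names=["g", "z"],
            )
            b, s = float(sub.params["x"]), float(sub.se["x"])
            rows.append(
                {
                    "group": mgr,
                    "beta1": b,
                    "se": s,
                    "ci_low": b - Z95 * s,
                    "ci_high": b + Z95 * s,
                }
            )
        groups = pd.DataFrame(rows)
    return OverIdResult(
        statistic=float(fit.sargan_stat),
        df=int(fit.sargan_df),
        pvalue=float(fit.sargan_pvalue),
        method="sargan",
        per_group_estimates=groups,
    )


def cochran_q(estimates, ses) -> OverIdResult:
    """Cochran's Q heterogeneity test across per-group MR-GxE estimates.

    Q = sum w_m (b_m - b_IVW)^2 with inverse-variance weights w_m = 1/se_m^2,
    chi-square with M - 1 degrees of freedom under homogeneity.
    """
    b = np.asarray(estimates, dtype=float).ravel()
    s = np.asarray(ses, dtype=float).ravel()
    if b.shape != s.shape or b.size < 2:
        raise InputError("need >= 2 estimates with matching standard errors")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise InputError("all standard errors must be positive and finite")
    w = 1.0 / s**2
    ivw = float((w * b).sum() / w.sum())
    q = float((w * (b - ivw) ** 2).sum())
    df = b.size - 1
    table = pd.DataFrame({"group": np.arange(b.size), "beta1": b, "se": s})
    return OverIdResult(
        statistic=q,
        df=df,
        pvalue=float(stats.chi2.sf(q, df)),
        method="cochran_q",
        per_group_estimates=table,
        ivw_estimate=ivw,
    )


def build_prs(
    g_matrix,
    weights=None,
    standardize: bool = False,
    mean_impute: bool = False,
) -> np.ndarray:
    """Weighted polygenic score: per-individual sum of weight * dosage.

    ``standardize`` z-scores the result (mean 0, sd 1), which also makes it
    invariant to a common rescaling of the weights. Missing dosages are an
    error unless ``mean_impute`` replaces them by the column mean.
    """
    gm = np.asarray(g_matrix, dtype=float)
    if gm.ndim != 2:
        raise InputError("g_matrix must be 2-dimensional")
    if weights is None:
        weights = np.ones(gm.shape[1])
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.shape[0] != gm.shape[1]:
        raise InputError(
            f"weights length {weights.shape[0]} != column count {gm.shape[1]}"
        )
    if np.isnan(gm).any():
        if not mean_impute:
            raise InputError("missing dosages present; set mean_impute=True")
        col_means = np.nanmean(gm, axis=0)
        gm = np.where(np.isnan(gm), col_means, gm)
    score = gm @ weights
    if standardize:
        sd = score.std(ddof=0)
        if sd == 0:
            raise InputError("score is constant; cannot standardize")
        score = (score - score.mean()) / sd
    return score
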