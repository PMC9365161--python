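"""Point estimation for interaction-based Mendelian randomization.

Two estimators are provided, both targeting the causal effect ``beta1`` of a
continuous exposure X on a continuous outcome Y when the genetic instrument G
may act on Y through a horizontal pleiotropic pathway:

``fit_mr_gxe``
    MR-GxE: two-stage least squares using an explicitly observed
    gene-by-covariate interaction G*Z as the single excluded instrument,
    with G and Z included in the second stage. The coefficient of G in the
    second stage is an estimate of the pleiotropic effect ``beta2``.

``fit_mr_genius``
    MR-GENIUS: Robins-style G-estimation, implemented as TSLS with the
    residual-product constructed instrument (G - mean(G)) * resid(X | G).
    It needs no observed interaction covariate, but is identified only if
    var(X | G) varies with G (heteroskedastic first-stage residuals),
    which the bundled Breusch-Pagan test reports.

A shared TSLS engine (``fit_tsls``), an OLS comparator (``fit_ols``), the
closed-form MR-GxE estimand (``mr_gxe_estimand``), and the population bias
predictor under constant-pleiotropy violation (``gxe3_bias``) round out the
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .data import Dataset
from .exceptions import IdentificationError, InputError

__all__ = [
    "Z95",
    "TSLSFit",
    "OLSFit",
    "GxEFit",
    "GeniusFit",
    "ReducedForm",
    "fit_tsls",
    "fit_ols",
    "fit_mr_gxe",
    "mr_gxe_estimand",
    "reduced_form",
    "fit_mr_genius",
    "gxe3_bias",
]

#: two-sided 95% normal quantile, fixed by convention
Z95 = 1.959964

_MIN_EXTRA_N = 10  # observations required beyond the parameter count


def _column_stack(name: str, a, n: int) -> np.ndarray:
    m = np.asarray(a, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    if m.ndim != 2 or m.shape[0] != n:
        raise InputError(f"{name} must have {n} rows, got shape {m.shape}")
    return m


def _check_full_rank(mat: np.ndarray, names: list[str], what: str) -> None:
    """Raise IdentificationError naming (nearly) linearly dependent columns."""
    if mat.shape[1] == 0:
        return
    from scipy.linalg import qr

    _, r, piv = qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(mat.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise IdentificationError(
            f"{what} design is rank deficient; dependent columns: {bad}"
        )


@dataclass
class TSLSFit:
    """Two-stage least squares result.

    ``params`` are ordered [intercept, exogenous..., endogenous...]. When the
    system is over-identified, ``sargan_stat``/``sargan_df``/``sargan_pvalue``
    carry the over-identification test (n R-squared of the structural
    residuals regressed on all instruments and exogenous regressors).
    """

    params: pd.Series
    se: pd.Series
    cov: pd.DataFrame
    resid: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    n: int
    df_resid: int
    endog_names: list[str]
    first_stage_f: float | None = None
    first_stage_f_pvalue: float | None = None
    sargan_stat: float | None = None
    sargan_df: int | None = None
    sargan_pvalue: float | None = None

    def conf_int(self, name: str) -> tuple[float, float]:
        b, s = self.params[name], self.se[name]
        return (b - Z95 * s, b + Z95 * s)


def fit_tsls(
    y,
    endog,
    instruments,
    exog=None,
    *,
    add_intercept: bool = True,
    robust: bool = False,
    endog_names: list[str] | None = None,
    exog_names: list[str] | None = None,
) -> TSLSFit:
    """Two-stage least squares with ``endog`` instrumented by ``instruments``.

    Parameters
    ----------
    y : (n,) outcome.
    endog : (n,) or (n, p) endogenous regressor(s).
    instruments : (n,) or (n, q) excluded instruments, q >= p.
    exog : (n, r), optional
        Included exogenous regressors (instrument themselves).
    add_intercept : bool
        Prepend a constant column (default True).
    robust : bool
        Heteroskedasticity-robust (HC0 sandwich) covariance instead of the
        classical asymptotic one.

    Handles just- and over-identified systems; over-identified fits also
    report the Sargan statistic. Raises :class:`IdentificationError` on
    under-identification or rank-deficient designs.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    endog = _column_stack("endog", endog, n)
    instruments = _column_stack("instruments", instruments, n)
    p, q = endog.shape[1], instruments.shape[1]
    if q < p:
        raise IdentificationError(
            f"under-identified: {q} instrument(s) for {p} endogenous regressor(s)"
        )

    if endog_names is None:
        endog_names = [f"endog{i + 1}" for i in range(p)] if p > 1 else ["endog"]
    blocks, names = [], []
    if add_intercept:
        blocks.append(np.ones((n, 1)))
        names.append("const")
    if exog is not None:
        exog = _column_stack("exog", exog, n)
        if exog_names is None:
            exog_names = [f"exog{i + 1}" for i in range(exog.shape[1])]
        blocks.append(exog)
        names.extend(exog_names)
    w_exog = np.hstack(blocks) if blocks else np.empty((n, 0))
    W = np.hstack([w_exog, endog])
    Z = np.hstack([w_exog, instruments])
    wnames = names + list(endog_names)
    znames = names + [f"iv{i + 1}" for i in range(q)]

    k = W.shape[1]
    if n < k + 1:
        raise InputError(f"n = {n} too small for {k} parameters")
    _check_full_rank(Z, znames, "instrument")

    # first stage: project W on the instrument set
    fs_coef, *_ = np.linalg.lstsq(Z, W, rcond=None)
    W_hat = Z @ fs_coef
    _check_full_rank(W_hat, wnames, "projected second-stage")

    beta, *_ = np.linalg.lstsq(W_hat, y, rcond=None)
    fitted = W @ beta
    resid = y - fitted
    df_resid = n - k
    bread = np.linalg.inv(W_hat.T @ W_hat)
    if robust:
        cov = bread @ (W_hat.T * (resid**2)) @ W_hat @ bread
    else:
        sigma2 = float(resid @ resid) / df_resid
        cov = sigma2 * bread

    params = pd.Series(beta, index=wnames)
    se = pd.Series(np.sqrt(np.diag(cov)), index=wnames)
    fit = TSLSFit(
        params=params,
        se=se,
        cov=pd.DataFrame(cov, index=wnames, columns=wnames),
        resid=resid,
        fitted=fitted,
        n=n,
        df_resid=df_resid,
        endog_names=list(endog_names),
    )

    if p == 1:
        # partial F for the excluded instruments in the first stage
        xcol = endog[:, 0]
        full_res = xcol - Z @ fs_coef[:, -1]
        if w_exog.shape[1]:
            r_coef, *_ = np.linalg.lstsq(w_exog, xcol, rcond=None)
            restr_res = xcol - w_exog @ r_coef
        else:
            restr_res = xcol
        rss_f = float(full_res @ full_res)
        rss_r = float(restr_res @ restr_res)
        df_f = n - Z.shape[1]
        if rss_f > 0 and df_f > 0:
            f_stat = (rss_r - rss_f) / q / (rss_f / df_f)
            fit.first_stage_f = float(f_stat)
            fit.first_stage_f_pvalue = float(stats.f.sf(f_stat, q, df_f))

    if q > p:
        u = resid
        g_coef, *_ = np.linalg.lstsq(Z, u, rcond=None)
        ssr = u - Z @ g_coef
        denom = float(u @ u)
        r2 = 1.0 - float(ssr @ ssr) / denom if denom > 0 else 0.0
        fit.sargan_stat = float(n * r2)
        fit.sargan_df = q - p
        fit.sargan_pvalue = float(stats.chi2.sf(fit.sargan_stat, q - p))
    return fit


@dataclass
class OLSFit:
    """Observational comparator: OLS slope of y on x with intercept."""

    beta: float
    se: float
    ci: tuple[float, float]
    n_used: int


def fit_ols(data: Dataset) -> OLSFit:
    """Least-squares regression of the outcome on the exposure (the
    conventional observational estimate, confounded in general)."""
    mask = data.complete_cases([data.y, data.x])
    y, x = data.y[mask], data.x[mask]
    n = y.shape[0]
    if n < _MIN_EXTRA_N + 2:
        raise InputError(f"n_used = {n} insufficient for OLS fit")
    if np.var(x) == 0:
        raise InputError("exposure x is constant; OLS slope undefined")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[1, 1]))
    b = float(beta[1])
    return OLSFit(beta=b, se=se, ci=(b - Z95 * se, b + Z95 * se), n_used=n)


@dataclass
class GxEFit:
    """MR-GxE result: causal effect (beta1), pleiotropy (beta2), covariate
    main effect (beta3), first-stage interaction strength, and the full
    first-stage coefficient set (gamma0..gamma3)."""

    covariate: str
    beta1: float
    beta1_se: float
    beta1_ci: tuple[float, float]
    beta2: float
    beta2_se: float
    beta2_ci: tuple[float, float]
    beta3: float
    beta3_se: float
    f_interaction: float
    f_pvalue: float
    first_stage: dict[str, float]
    n_used: int
    tsls: TSLSFit = field(repr=False, default=None)


def _gxe_arrays(data: Dataset, covariate) -> tuple[str, np.ndarray, ...]:
    name, z = data.covariate(covariate)
    g = data.score
    mask = data.complete_cases([data.y, data.x, g, z])
    y, x, g, z = data.y[mask], data.x[mask], g[mask], z[mask]
    n = y.shape[0]
    if n < _MIN_EXTRA_N + 4:
        raise InputError(f"n_used = {n} insufficient for MR-GxE fit")
    gz = g * z
    if np.var(gz) <= 0:
        raise IdentificationError(
            f"degenerate instrument: var(g*z) = 0 for covariate {name!r}"
        )
    _check_full_rank(
        np.column_stack([np.ones(n), g, z, gz]),
        ["const", "g", name, f"g*{name}"],
        "first-stage",
    )
    return name, y, x, g, z, gz


def fit_mr_gxe(data: Dataset, covariate, *, robust: bool = False) -> GxEFit:
    """MR-GxE for one named interaction covariate.

    TSLS with the interaction g*z as the single excluded instrument and
    {1, g, z} included exogenous; beta1 is the coefficient of the fitted
    exposure, beta2 the coefficient of g (pleiotropy), beta3 of z. The
    first-stage partial F for the interaction term (equal to the squared
    t-statistic of the interaction coefficient) quantifies GxE1 strength.
    """
    name, y, x, g, z, gz = _gxe_arrays(data, covariate)
    n = y.shape[0]
    tsls = fit_tsls(
        y,
        x,
        gz,
        exog=np.column_stack([g, z]),
        robust=robust,
        endog_names=["x"],
        exog_names=["g", "z"],
    )
    # first-stage coefficients (gamma0..gamma3) from the explicit OLS
    D = np.column_stack([np.ones(n), g, z, gz])
    gamma, *_ = np.linalg.lstsq(D, x, rcond=None)
    first_stage = {
        "gamma0": float(gamma[0]),
        "gamma1": float(gamma[1]),
        "gamma2": float(gamma[2]),
        "gamma3": float(gamma[3]),
    }
    b1, s1 = float(tsls.params["x"]), float(tsls.se["x"])
    b2, s2 = float(tsls.params["g"]), float(tsls.se["g"])
    return GxEFit(
        covariate=name,
        beta1=b1,
        beta1_se=s1,
        beta1_ci=(b1 - Z95 * s1, b1 + Z95 * s1),
        beta2=b2,
        beta2_se=s2,
        beta2_ci=(b2 - Z95 * s2, b2 + Z95 * s2),
        beta3=float(tsls.params["z"]),
        beta3_se=float(tsls.se["z"]),
        f_interaction=float(tsls.first_stage_f),
        f_pvalue=float(tsls.first_stage_f_pvalue),
        first_stage=first_stage,
        n_used=n,
        tsls=tsls,
    )


@dataclass
class ReducedForm:
    """Coefficients of the outcome reduced form Y ~ 1 + G + Z + G*Z."""

    alpha0: float
    alpha1: float
    alpha2: float
    alpha3: float


def reduced_form(data: Dataset, covariate) -> ReducedForm:
    """OLS reduced-form regression of the outcome on {1, g, z, g*z}."""
    _, y, _, g, z, gz = _gxe_arrays(data, covariate)
    D = np.column_stack([np.ones(y.shape[0]), g, z, gz])
    a, *_ = np.linalg.lstsq(D, y, rcond=None)
    return ReducedForm(*map(float, a))


def mr_gxe_estimand(data: Dataset, covariate) -> float:
    """Closed-form MR-GxE estimand from sample covariances.

    Computes
    ``[cov(Y,GZ) - a1 cov(G,GZ) - a2 cov(Z,GZ)] /
    [cov(X,GZ) - g1 cov(G,GZ) - g2 cov(Z,GZ)]``
    where (a1, a2) are the G and Z coefficients of the outcome reduced form
    and (g1, g2) those of the first stage, both fitted including the
    interaction term. Algebraically identical to the TSLS ``beta1`` of
    :func:`fit_mr_gxe` (indirect least squares in the just-identified case).
    """
    name, y, x, g, z, gz = _gxe_arrays(data, covariate)
    n = y.shape[0]
    D = np.column_stack([np.ones(n), g, z, gz])
    coef, *_ = np.linalg.lstsq(D, np.column_stack([y, x]), rcond=None)
    a1, a2 = coef[1, 0], coef[2, 0]
    g1, g2 = coef[1, 1], coef[2, 1]

    def cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1])

    num = cov(y, gz) - a1 * cov(g, gz) - a2 * cov(z, gz)
    den = cov(x, gz) - g1 * cov(g, gz) - g2 * cov(z, gz)
    if abs(den) < 1e-12:
        raise IdentificationError(
            f"MR-GxE estimand denominator vanishes for covariate {name!r}"
        )
    return num / den


@dataclass
class GeniusFit:
    """MR-GENIUS result with the Breusch-Pagan identification diagnostic."""

    beta1: float
    beta1_se: float
    beta1_ci: tuple[float, float]
    bp_stat: float
    bp_pvalue: float
    n_used: int
    tsls: TSLSFit = field(repr=False, default=None)


def fit_mr_genius(
    data: Dataset,
    *,
    adjust: list | None = None,
    robust: bool = True,
    studentized_bp: bool = True,
    n_boot: int | None = None,
    seed: int | None = None,
) -> GeniusFit:
    """MR-GENIUS via the residual-product constructed instrument.

    X is regressed on G (with intercept); the residuals e are combined with
    the centred instrument into (G - mean(G)) * e, which is the single
    excluded instrument in a TSLS of Y on X. No interaction covariate needs
    to be specified: the estimator targets the *total* effect of X on Y.
    Passing ``adjust`` (covariate names) conditions the first stage and
    second stage on those covariates, targeting the direct effect instead.

    Standard errors are heteroskedasticity-robust by default (the
    constructed instrument is itself residual-based); ``n_boot`` replaces
    them with a seeded nonparametric bootstrap.

    The Breusch-Pagan test of e against G reports identification strength:
    MR-GENIUS is identified only when var(X | G) varies with G. The default
    statistic is the LM form n R-squared from regressing e**2 on G (one
    slope degree of freedom, chi-square reference -- the studentised
    variant, valid without normality); ``studentized_bp=False`` selects the
    original normality-based statistic.
    """
    g = data.score
    cols = [data.y, data.x, g]
    adj_arrays, adj_names = [], []
    if adjust:
        for c in adjust:
            nm, v = data.covariate(c)
            adj_arrays.append(v)
            adj_names.append(nm)
        cols += adj_arrays
    mask = data.complete_cases(cols)
    y, x, g = data.y[mask], data.x[mask], g[mask]
    adj = (
        np.column_stack([a[mask] for a in adj_arrays]) if adj_arrays else None
    )
    n = y.shape[0]
    if n < _MIN_EXTRA_N + 3:
        raise InputError(f"n_used = {n} insufficient for MR-GENIUS fit")
    if np.var(g) <= 0:
        raise InputError("instrument g is constant")

    fs = np.column_stack([np.ones(n), g] + ([adj] if adj is not None else []))
    coef, *_ = np.linalg.lstsq(fs, x, rcond=None)
    e = x - fs @ coef
    instrument = (g - g.mean()) * e

    bp_stat, bp_pvalue, _, _ = het_breuschpagan(
        e, np.column_stack([np.ones(n), g]), robust=studentized_bp
    )

    if abs(np.cov(instrument, x, ddof=1)[0, 1]) < 1e-12:
        raise IdentificationError(
            "constructed instrument uncorrelated with exposure; MR-GENIUS is "
            "not identified -- inspect the Breusch-Pagan test "
            f"(stat = {bp_stat:.3f}, p = {bp_pvalue:.3g})"
        )

    tsls = fit_tsls(
        y,
        x,
        instrument,
        exog=adj,
        robust=robust,
        endog_names=["x"],
        exog_names=adj_names or None,
    )
    b1 = float(tsls.params["x"])
    if n_boot:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            yb, xb, gb = y[idx], x[idx], g[idx]
            fsb = np.column_stack(
                [np.ones(n), gb] + ([adj[idx]] if adj is not None else [])
            )
            cb, *_ = np.linalg.lstsq(fsb, xb, rcond=None)
            eb = xb - fsb @ cb
            vb = (gb - gb.mean()) * eb
            fb = fit_tsls(
                yb, xb, vb, exog=adj[idx] if adj is not None else None,
                robust=False, endog_names=["x"],
            )
            draws[b] = fb.params["x"]
        s1 = float(np.std(draws, ddof=1))
    else:
        s1 = float(tsls.se["x"])
    return GeniusFit(
        beta1=b1,
        beta1_se=s1,
        beta1_ci=(b1 - Z95 * s1, b1 + Z95 * s1),
        bp_stat=float(bp_stat),
        bp_pvalue=float(bp_pvalue),
        n_used=n,
        tsls=tsls,
    )


def genius_moment_ratio(y, x, g) -> float:
    """Direct moment form of the MR-GENIUS estimator for a discrete
    instrument: ``Pn[(G-mean G)(X - E[X|G]) Y] / Pn[(G-mean G)(X - E[X|G]) X]``
    with E[X|G=g] the within-level sample mean. Used as an independent
    cross-check of the residual-product TSLS route."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    g = np.asarray(g, float)
    levels, inverse = np.unique(g, return_inverse=True)
    means = np.bincount(inverse, weights=x) / np.bincount(inverse)
    d = (g - g.mean()) * (x - means[inverse])
    den = float(np.mean(d * x))
    if abs(den) < 1e-12:
        raise IdentificationError("MR-GENIUS moment denominator vanishes")
    return float(np.mean(d * y)) / den


def gxe3_bias(dgp, covariate_index: int = 0) -> float:
    """Population bias of MR-GxE under constant-pleiotropy (GxE3) violation.

    For interaction covariate k with a non-zero second-stage interaction
    coefficient beta4k, the MR-GxE estimate converges to beta1 + bias with

    ``bias = beta4k var(GZ_k) /
    [cov(X,GZ_k) - bXG cov(G,GZ_k) - bXZk cov(Z_k,GZ_k)]``

    where bXG, bXZk are the population multivariable coefficients of the
    first-stage regression. The denominator equals gamma3k var(GZ_k), so in
    the simple independent-source case the bias is the ratio of the second-
    to the first-stage interaction coefficient. All moments are evaluated
    analytically from the generating-model parameters (standard-normal
    independent exogenous sources; requires pi_k1 = 0 and a single
    instrument).
    """
    from .simulate import population_moments

    mom = population_moments(dgp, covariate_index)
    den = (
        mom["cov_x_q"]
        - mom["b_xg"] * mom["cov_g_q"]
        - mom["b_xz"] * mom["cov_z_q"]
    )
    if abs(den) < 1e-12:
        raise IdentificationError(
            "bias predictor denominator vanishes (no first-stage interaction)"
        )
    beta4 = float(np.asarray(dgp.beta_4).reshape(dgp.M, dgp.K)[0, covariate_index])
    return beta4 * mom["var_q"] / den
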