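"""Synthetic data under the interaction-MR structural model.

The generating model has four layers, each with independent mean-zero
normal errors (unit scale by default):

    Z_k = pi_k0 + pi_k1 G + e_Zk                    (covariates)
    U   = theta_0 + theta_1 G
          + sum_k (theta_2k Z_k + theta_3k G Z_k) + e_U   (confounder)
    X   = gamma_0 + sum_m gamma_1m G_m
          + sum_k (gamma_2k Z_k) + sum_mk gamma_3mk G_m Z_k
          + gamma_4 U + e_X                          (exposure)
    Y   = beta_0 + beta_1 X + sum_m beta_2m G_m
          + sum_k beta_3k Z_k + sum_mk beta_4mk G_m Z_k
          + beta_5 U + e_Y                           (outcome)

G is a standard-normal instrument; with M > 1 sub-instruments the composite
score sum_m G_m plays the role of G in the covariate and confounder layers.
``beta_1`` is the causal effect every estimator targets; ``beta_2`` is
horizontal pleiotropy; ``theta_3k`` != 0 violates interaction exogeneity
(GxE2) and ``beta_4mk`` != 0 violates constant pleiotropy (GxE3).

``run_scenario`` reproduces the six simulation study designs (interaction
selection/strength, weak-interaction sweep, proportion of non-zero
interactions, GxE2 violation, GxE3 violation, and sub-instrument Sargan
testing) at a configurable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import Dataset
from .exceptions import IdentificationError, InputError

__all__ = [
    "DGPParams",
    "ScenarioConfig",
    "ScenarioResult",
    "MCSummary",
    "simulate_dataset",
    "population_moments",
    "oracle_estimand_gxe2",
    "mc_summary",
    "default_config",
    "run_scenario",
]


def _arr(v, shape, name: str) -> np.ndarray:
    try:
        a = np.broadcast_to(np.asarray(v, dtype=float), shape).copy()
    except ValueError as exc:
        raise InputError(f"{name} not broadcastable to {shape}") from exc
    if not np.all(np.isfinite(a)):
        raise InputError(f"{name} contains non-finite values")
    return a


@dataclass
class DGPParams:
    """All structural coefficients of the generating model.

    Scalar coefficients broadcast across covariates (K) and sub-instruments
    (M); array inputs must be broadcastable to (K,), (M,) or (M, K) as
    appropriate. Error scales default to 1 (standard-normal sources).
    """

    n: int
    K: int = 1
    M: int = 1
    seed: int | None = None
    beta_1: float = 1.0
    # covariate layer
    pi_0: np.ndarray | float = 0.0
    pi_1: np.ndarray | float = 0.0
    # confounder layer
    theta_0: float = 0.0
    theta_1: float = 0.0
    theta_2: np.ndarray | float = 0.0
    theta_3: np.ndarray | float = 0.0
    # exposure layer
    gamma_0: float = 0.0
    gamma_1: np.ndarray | float = 1.0
    gamma_2: np.ndarray | float = 0.0
    gamma_3: np.ndarray | float = 0.0
    gamma_4: float = 1.0
    # outcome layer
    beta_0: float = 0.0
    beta_2: np.ndarray | float = 0.0
    beta_3: np.ndarray | float = 0.0
    beta_4: np.ndarray | float = 0.0
    beta_5: float = 1.0
    # error scales
    sigma_z: float = 1.0
    sigma_u: float = 1.0
    sigma_x: float = 1.0
    sigma_y: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.K < 1 or self.M < 1:
            raise InputError("n, K and M must all be >= 1")
        K, M = self.K, self.M
        self.pi_0 = _arr(self.pi_0, (K,), "pi_0")
        self.pi_1 = _arr(self.pi_1, (K,), "pi_1")
        self.theta_2 = _arr(self.theta_2, (K,), "theta_2")
        self.theta_3 = _arr(self.theta_3, (K,), "theta_3")
        self.gamma_1 = _arr(self.gamma_1, (M,), "gamma_1")
        self.gamma_2 = _arr(self.gamma_2, (K,), "gamma_2")
        self.gamma_3 = _arr(self.gamma_3, (M, K), "gamma_3")
        self.beta_2 = _arr(self.beta_2, (M,), "beta_2")
        self.beta_3 = _arr(self.beta_3, (K,), "beta_3")
        self.beta_4 = _arr(self.beta_4, (M, K), "beta_4")
        for nm in (
            "beta_1", "theta_0", "theta_1", "gamma_0", "gamma_4",
            "beta_0", "beta_5", "sigma_z", "sigma_u", "sigma_x", "sigma_y",
        ):
            v = float(getattr(self, nm))
            if not np.isfinite(v):
                raise InputError(f"{nm} is not finite")
            setattr(self, nm, v)


def simulate_dataset(dgp: DGPParams, rng=None) -> Dataset:
    """Draw one dataset from the generating model.

    Variables are built in structural order (G, then Z, U, X, Y), so the
    draw is fully reproducible from the seed. The latent confounder is
    attached as ``Dataset.u`` for oracle-only use.
    """
    if rng is None:
        rng = np.random.default_rng(dgp.seed)
    n, K, M = dgp.n, dgp.K, dgp.M
    G = rng.standard_normal((n, M))
    score = G.sum(axis=1)
    Z = (
        dgp.pi_0
        + score[:, None] * dgp.pi_1
        + dgp.sigma_z * rng.standard_normal((n, K))
    )
    U = (
        dgp.theta_0
        + dgp.theta_1 * score
        + Z @ dgp.theta_2
        + (score[:, None] * Z) @ dgp.theta_3
        + dgp.sigma_u * rng.standard_normal(n)
    )
    X = (
        dgp.gamma_0
        + G @ dgp.gamma_1
        + Z @ dgp.gamma_2
        + ((G @ dgp.gamma_3) * Z).sum(axis=1)
        + dgp.gamma_4 * U
        + dgp.sigma_x * rng.standard_normal(n)
    )
    Y = (
        dgp.beta_0
        + dgp.beta_1 * X
        + G @ dgp.beta_2
        + Z @ dgp.beta_3
        + ((G @ dgp.beta_4) * Z).sum(axis=1)
        + dgp.beta_5 * U
        + dgp.sigma_y * rng.standard_normal(n)
    )
    zf = pd.DataFrame(Z, columns=[f"z{k + 1}" for k in range(K)])
    if M == 1:
        return Dataset(y=Y, x=X, g=G[:, 0], z=zf, u=U)
    return Dataset(y=Y, x=X, g_matrix=G, z=zf, u=U)


def population_moments(dgp: DGPParams, k: int) -> dict[str, float]:
    """Analytic population moments for interaction covariate ``k``.

    Valid for a single instrument (M = 1) with covariates independent of G
    (pi_k1 = 0), the setting of all simulation designs. Returns the
    covariances of (G, Z_k, GZ_k) with X, Y and U, plus the population
    multivariable regression coefficients of X and Y on {1, G, Z_k, GZ_k}.
    """
    if dgp.M != 1:
        raise InputError("population moments require a single instrument (M=1)")
    if np.any(dgp.pi_1 != 0):
        raise InputError("population moments require pi_1 = 0 (Z independent of G)")
    if not 0 <= k < dgp.K:
        raise InputError(f"covariate index {k} out of range")
    pi0 = dgp.pi_0
    sz2 = dgp.sigma_z**2
    a_g = dgp.gamma_1[0] + dgp.gamma_4 * dgp.theta_1
    a_z = dgp.gamma_2 + dgp.gamma_4 * dgp.theta_2
    a_q = dgp.gamma_3[0] + dgp.gamma_4 * dgp.theta_3
    b_g = dgp.beta_1 * a_g + dgp.beta_2[0] + dgp.beta_5 * dgp.theta_1
    b_z = dgp.beta_1 * a_z + dgp.beta_3 + dgp.beta_5 * dgp.theta_2
    b_q = dgp.beta_1 * a_q + dgp.beta_4[0] + dgp.beta_5 * dgp.theta_3

    var_q = pi0[k] ** 2 + sz2
    cov_g_q = pi0[k]
    cov_z_q = 0.0
    wsum_a = float(a_q @ pi0)
    wsum_b = float(b_q @ pi0)
    cov_x_q = a_g * pi0[k] + a_q[k] * sz2 + pi0[k] * wsum_a
    cov_y_q = b_g * pi0[k] + b_q[k] * sz2 + pi0[k] * wsum_b
    cov_u_q = (
        dgp.theta_1 * pi0[k]
        + dgp.theta_3[k] * sz2
        + pi0[k] * float(dgp.theta_3 @ pi0)
    )
    cov_x_g = a_g + wsum_a
    cov_y_g = b_g + wsum_b
    cov_x_z = a_z[k] * sz2
    cov_y_z = b_z[k] * sz2

    C = np.array(
        [
            [1.0, 0.0, cov_g_q],
            [0.0, sz2, cov_z_q],
            [cov_g_q, cov_z_q, var_q],
        ]
    )
    bx = np.linalg.solve(C, [cov_x_g, cov_x_z, cov_x_q])
    by = np.linalg.solve(C, [cov_y_g, cov_y_z, cov_y_q])
    return {
        "var_q": float(var_q),
        "cov_g_q": float(cov_g_q),
        "cov_z_q": float(cov_z_q),
        "cov_x_q": float(cov_x_q),
        "cov_y_q": float(cov_y_q),
        "cov_u_q": float(cov_u_q),
        "b_xg": float(bx[0]),
        "b_xz": float(bx[1]),
        "b_xq": float(bx[2]),
        "b_yg": float(by[0]),
        "b_yz": float(by[1]),
        "b_yq": float(by[2]),
    }


def oracle_estimand_gxe2(dgp: DGPParams, k: int = 0) -> float:
    """Population value of the MR-GxE estimator for covariate ``k``, with
    the confounder treated as known.

    Evaluates the estimand ratio from analytic moments, including the
    cov(U, GZ_k) pathways that open when interaction exogeneity (GxE2)
    fails: with theta_3k = 0 (and independent sources) the value is exactly
    beta_1; with theta_3k != 0 the excess over beta_1 is the asymptotic
    GxE2 bias that simulation reproduces. Simulation-only: requires the
    generating parameters, not data.
    """
    mom = population_moments(dgp, k)
    if abs(mom["b_xq"]) < 1e-12:
        raise IdentificationError(
            "no first-stage interaction at the population level (gamma3 "
            "+ gamma4*theta3 = 0); estimand undefined"
        )
    return mom["b_yq"] / mom["b_xq"]


@dataclass
class MCSummary:
    """Monte-Carlo aggregate of replicate estimates."""

    mean: float
    se: float
    ci: tuple[float, float]
    sd: float
    n_reps: int
    bias: float | None = None
    coverage: float | None = None


def mc_summary(
    estimates,
    true_value: float | None = None,
    ci_lows=None,
    ci_highs=None,
) -> MCSummary:
    """Mean, Monte-Carlo 95% interval of the mean, bias and (optionally)
    empirical CI coverage for a vector of replicate estimates."""
    from .estimators import Z95

    e = np.asarray(estimates, dtype=float)
    if e.size < 2:
        raise InputError("mc_summary needs at least 2 estimates")
    mean = float(e.mean())
    sd = float(e.std(ddof=1))
    se = sd / np.sqrt(e.size)
    out = MCSummary(
        mean=mean,
        se=se,
        ci=(mean - Z95 * se, mean + Z95 * se),
        sd=sd,
        n_reps=int(e.size),
    )
    if true_value is not None:
        out.bias = mean - float(true_value)
        if ci_lows is not None and ci_highs is not None:
            lo = np.asarray(ci_lows, dtype=float)
            hi = np.asarray(ci_highs, dtype=float)
            out.coverage = float(
                np.mean((lo <= true_value) & (true_value <= hi))
            )
    return out


def truncated_normal_above(
    rng, size: int, mean: float = 2.0, sd: float = 2.0, lower: float = 1.0
) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) conditioned on being > lower.

    Used for non-zero first-stage interaction coefficients, which are drawn
    strictly positive so the interactions cannot average out to zero."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        keep = draw[draw > lower]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# scenario suite
# ---------------------------------------------------------------------------

_DEFAULT_PROPORTIONS = {
    3: (0.01, 0.05, 0.10, 0.50, 1.00),
    4: (0.0, 0.01, 0.05, 0.10, 0.50, 0.99),
    5: (0.0, 0.01, 0.05, 0.10, 0.50, 0.99),
    6: (0.0, 0.01, 0.05, 0.10, 0.50, 1.00),
}


@dataclass
class ScenarioConfig:
    """One simulation-study configuration.

    ``scenario`` selects the design: 1 = interaction selection/strength,
    2 = weak-interaction sweep over target F, 3 = proportion of non-zero
    interactions, 4 = GxE2 violation (theta_3k = 1), 5 = GxE3 violation
    (beta_4k = 1, gamma_3k = 1), 6 = composite-score sub-instruments with
    Sargan testing (beta_2 = 0.05, gamma_3m = 0.2, beta_4m = 0.2 when
    violating).
    """

    scenario: int
    n: int = 20_000
    reps: int = 200
    seed: int | None = None
    K: int = 100
    n_valid: int = 10  # scenario 1: covariates with non-zero interactions
    proportions: tuple[float, ...] = ()
    f_targets: tuple[float, ...] = (1, 5, 10, 25, 50, 100)
    M: int = 100  # scenario 6: sub-instrument count
    m_groups: int = 9  # scenario 6: Sargan groups
    beta_1: float = 1.0

    def __post_init__(self) -> None:
        if self.scenario not in range(1, 7):
            raise InputError(f"unknown scenario id {self.scenario}")
        if self.reps < 1:
            raise InputError("replicate count must be >= 1")
        if not self.proportions:
            self.proportions = _DEFAULT_PROPORTIONS.get(self.scenario, (1.0,))
        if any(not 0.0 <= p <= 1.0 for p in self.proportions):
            raise InputError("proportions must lie in [0, 1]")


def default_config(scenario: int, *, full: bool = False, seed=None, **kw) -> ScenarioConfig:
    """Desk-scale defaults (n = 20,000, 200 replicates); ``full=True``
    selects the large profile (n = 100,000, 1,000 replicates, 1,000
    sub-instruments for scenario 6)."""
    base = dict(n=100_000, reps=1000) if full else dict(n=20_000, reps=200)
    if scenario == 6:
        base["M"] = 1000 if full else 100
    base.update(kw)
    return ScenarioConfig(scenario=scenario, seed=seed, **base)


@dataclass
class ScenarioResult:
    """Aggregated scenario output: one summary row per design cell, the
    replicate-level frame behind it, and (scenario 1) per-covariate mean
    scan statistics for Manhattan-style plotting."""

    config: ScenarioConfig
    summary: pd.DataFrame
    replicates: pd.DataFrame
    scan_means: pd.DataFrame | None = None


def _mc_cols(values) -> dict[str, float]:
    s = mc_summary(values)
    return {"mean": s.mean, "ci_low": s.ci[0], "ci_high": s.ci[1], "mc_se": s.se}


def _base_dgp(cfg: ScenarioConfig, **kw) -> DGPParams:
    """Shared nuisance parameterisation: strong instrument (gamma_1 = 1),
    additive confounding (gamma_4 = beta_5 = 1), covariates independent of
    the instrument (pi_1 = 0), unit-variance normal sources.

    Covariates carry a main effect on the exposure (gamma_2k = 1). This is
    load-bearing for MR-GENIUS: with a symmetric continuous instrument and
    mean-zero covariates, a pure interaction makes var(X | G) an even
    function of G, so cov(G, var(X | G)) -- and with it MR-GENIUS
    identification and the Breusch-Pagan statistic -- vanishes unless the
    gamma_2k * gamma_3k cross term is non-zero."""
    base = dict(
        n=cfg.n, K=cfg.K, beta_1=cfg.beta_1,
        gamma_1=1.0, gamma_2=1.0, gamma_4=1.0, beta_5=1.0,
    )
    base.update(kw)
    return DGPParams(**base)


def _rep_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Execute one simulation study and aggregate the replicate estimates.

    Uses one root seed with independent child streams per design cell and
    replicate, so identical configurations reproduce bitwise-identical
    summaries.
    """
    runner = {
        1: _run_scenario_1,
        2: _run_scenario_2,
        3: _run_scenario_3,
        4: _run_scenario_45,
        5: _run_scenario_45,
        6: _run_scenario_6,
    }[config.scenario]
    return runner(config)


def _spawn(config: ScenarioConfig, n_cells: int):
    root = np.random.SeedSequence(config.seed)
    return [cell.spawn(config.reps) for cell in root.spawn(n_cells)]


def _run_scenario_1(cfg: ScenarioConfig) -> ScenarioResult:
    from .diagnostics import interaction_scan
    from .estimators import fit_mr_genius

    streams = _spawn(cfg, 1)[0]
    rows = []
    neglog_sum = np.zeros(cfg.K)
    valid = np.arange(cfg.n_valid)
    for r, seq in enumerate(streams):
        rng = np.random.default_rng(seq)
        gamma3 = np.zeros(cfg.K)
        gamma3[valid] = truncated_normal_above(rng, cfg.n_valid)
        ds = simulate_dataset(_base_dgp(cfg, gamma_3=gamma3), rng)
        scan = interaction_scan(ds)
        tab = scan.table.set_index("covariate")
        names = [f"z{k + 1}" for k in valid]
        neglog_sum += (
            tab["neg_log10_p"]
            .reindex([f"z{k + 1}" for k in range(cfg.K)])
            .to_numpy()
        )
        passed = set(tab.index[tab["passes"]])
        beta1 = _covariate_beta1(ds, valid)
        genius = fit_mr_genius(ds)
        rows.append(
            {
                "rep": r,
                "gxe_beta1": float(beta1.mean()),
                "genius_beta1": genius.beta1,
                "mean_f": float(tab.loc[names, "f_stat"].mean()),
                "bp_stat": genius.bp_stat,
                "bp_pvalue": genius.bp_pvalue,
                "n_passed": len(passed),
                "exact_recovery": passed == set(names),
            }
        )
    reps = _rep_frame(rows)
    summary = pd.DataFrame(
        [
            {
                "cell": "simulation_1",
                **{f"gxe_{k}": v for k, v in _mc_cols(reps["gxe_beta1"]).items()},
                **{f"genius_{k}": v for k, v in _mc_cols(reps["genius_beta1"]).items()},
                "mean_f": reps["mean_f"].mean(),
                "mean_bp_stat": reps["bp_stat"].mean(),
                "mean_bp_pvalue": reps["bp_pvalue"].mean(),
                "exact_recovery_rate": reps["exact_recovery"].mean(),
            }
        ]
    )
    scan_means = pd.DataFrame(
        {
            "covariate": [f"z{k + 1}" for k in range(cfg.K)],
            "mean_neg_log10_p": neglog_sum / cfg.reps,
            "true_interaction": [k in set(valid) for k in range(cfg.K)],
        }
    )
    return ScenarioResult(cfg, summary, reps, scan_means)


def _covariate_beta1(ds: Dataset, indices) -> np.ndarray:
    """Fast MR-GxE point estimates for a set of covariates on one dataset
    (indirect-least-squares ratio; identical to the TSLS coefficient)."""
    from .diagnostics import _interaction_coefs

    g = ds.score
    Z = ds.z.to_numpy(dtype=float)[:, np.asarray(indices, dtype=int)]
    coef, _, _ = _interaction_coefs(
        g, Z, np.column_stack([ds.x, ds.y]), robust=False
    )
    return coef[:, 1] / coef[:, 0]


def _run_scenario_2(cfg: ScenarioConfig) -> ScenarioResult:
    from .estimators import fit_mr_gxe

    cells = _spawn(cfg, len(cfg.f_targets))
    resid_var = 1.0 + 1.0  # gamma_4^2 var(U) + var(e_X)
    rows = []
    for f_target, streams in zip(cfg.f_targets, cells):
        gamma3 = float(np.sqrt(max(f_target - 1.0, 0.0) * resid_var / cfg.n))
        for r, seq in enumerate(streams):
            rng = np.random.default_rng(seq)
            ds = simulate_dataset(
                _base_dgp(cfg, K=1, gamma_3=gamma3), rng
            )
            fit = fit_mr_gxe(ds, 0)
            rows.append(
                {
                    "f_target": f_target,
                    "rep": r,
                    "beta1": fit.beta1,
                    "ci_width": fit.beta1_ci[1] - fit.beta1_ci[0],
                    "f_stat": fit.f_interaction,
                    "ci_low": fit.beta1_ci[0],
                    "ci_high": fit.beta1_ci[1],
                }
            )
    reps = _rep_frame(rows)
    summary = pd.DataFrame(
        [
            {
                "f_target": f,
                **{f"gxe_{k}": v for k, v in _mc_cols(grp["beta1"]).items()},
                "mean_f": grp["f_stat"].mean(),
                "mean_ci_width": grp["ci_width"].mean(),
                "coverage": float(
                    np.mean((grp["ci_low"] <= cfg.beta_1) & (cfg.beta_1 <= grp["ci_high"]))
                ),
            }
            for f, grp in reps.groupby("f_target", sort=True)
        ]
    )
    return ScenarioResult(cfg, summary, reps)


def _run_scenario_3(cfg: ScenarioConfig) -> ScenarioResult:
    from .diagnostics import _interaction_coefs
    from .estimators import fit_mr_genius

    cells = _spawn(cfg, len(cfg.proportions))
    rows = []
    for prop, streams in zip(cfg.proportions, cells):
        n_nz = max(1, int(round(prop * cfg.K)))
        for r, seq in enumerate(streams):
            rng = np.random.default_rng(seq)
            gamma3 = np.zeros(cfg.K)
            gamma3[:n_nz] = truncated_normal_above(rng, n_nz)
            ds = simulate_dataset(_base_dgp(cfg, gamma_3=gamma3), rng)
            pick = int(rng.integers(n_nz))
            beta1 = float(_covariate_beta1(ds, [pick])[0])
            genius = fit_mr_genius(ds)
            g = ds.score
            Znz = ds.z.to_numpy(dtype=float)[:, :n_nz]
            _, fstat, _ = _interaction_coefs(g, Znz, ds.x[:, None])
            rows.append(
                {
                    "proportion": prop,
                    "rep": r,
                    "gxe_beta1": beta1,
                    "genius_beta1": genius.beta1,
                    "mean_f": float(fstat.mean()),
                    "bp_pvalue": genius.bp_pvalue,
                }
            )
    reps = _rep_frame(rows)
    summary = _summarise_cells(
        reps, ["gxe_beta1", "genius_beta1"], extra=["mean_f", "bp_pvalue"]
    )
    return ScenarioResult(cfg, summary, reps)


def _summarise_cells(
    reps: pd.DataFrame, mc_fields: list[str], extra: list[str] = ()
) -> pd.DataFrame:
    out = []
    for prop, grp in reps.groupby("proportion", sort=True):
        row = {"proportion": prop}
        for f in mc_fields:
            vals = grp[f].dropna()
            if len(vals) >= 2:
                prefix = f.replace("_beta1", "")
                row.update(
                    {f"{prefix}_{k}": v for k, v in _mc_cols(vals).items()}
                )
        for f in extra:
            row[f"mean_{f.removeprefix('mean_')}"] = grp[f].mean()
        out.append(row)
    return pd.DataFrame(out)


def _run_scenario_45(cfg: ScenarioConfig) -> ScenarioResult:
    from .diagnostics import _interaction_coefs
    from .estimators import fit_mr_genius

    cells = _spawn(cfg, len(cfg.proportions))
    rows = []
    for prop, streams in zip(cfg.proportions, cells):
        n_viol = int(round(prop * cfg.K))
        for r, seq in enumerate(streams):
            rng = np.random.default_rng(seq)
            if cfg.scenario == 4:
                gamma3 = truncated_normal_above(rng, cfg.K)
                theta3 = np.zeros(cfg.K)
                theta3[:n_viol] = 1.0
                dgp = _base_dgp(cfg, gamma_3=gamma3, theta_3=theta3)
            else:  # scenario 5: gamma_3k = 1 everywhere, beta_4k = 1 on violators
                beta4 = np.zeros(cfg.K)
                beta4[:n_viol] = 1.0
                dgp = _base_dgp(cfg, gamma_3=1.0, beta_4=beta4)
            ds = simulate_dataset(dgp, rng)
            all_beta1 = _covariate_beta1(ds, np.arange(cfg.K))
            if n_viol < cfg.K:
                pick = int(rng.integers(n_viol, cfg.K))
                valid_beta1 = float(all_beta1[pick])
            else:
                valid_beta1 = np.nan
            genius = fit_mr_genius(ds)
            g = ds.score
            _, fstat, _ = _interaction_coefs(
                g, ds.z.to_numpy(dtype=float), ds.x[:, None]
            )
            rows.append(
                {
                    "proportion": prop,
                    "rep": r,
                    "valid_gxe_beta1": valid_beta1,
                    "mean_gxe_beta1": float(all_beta1.mean()),
                    "genius_beta1": genius.beta1,
                    "mean_f": float(fstat.mean()),
                }
            )
    reps = _rep_frame(rows)
    summary = _summarise_cells(
        reps,
        ["valid_gxe_beta1", "mean_gxe_beta1", "genius_beta1"],
        extra=["mean_f"],
    )
    return ScenarioResult(cfg, summary, reps)


def _run_scenario_6(cfg: ScenarioConfig) -> ScenarioResult:
    from .diagnostics import partition_sub_instruments, sargan_gxe
    from .estimators import fit_mr_genius, fit_mr_gxe

    cells = _spawn(cfg, len(cfg.proportions))
    rows = []
    for prop, streams in zip(cfg.proportions, cells):
        n_viol = int(round(prop * cfg.M))
        beta4 = np.zeros((cfg.M, 1))
        beta4[:n_viol, 0] = 0.2
        for r, seq in enumerate(streams):
            rng = np.random.default_rng(seq)
            dgp = DGPParams(
                n=cfg.n, K=1, M=cfg.M, beta_1=cfg.beta_1,
                gamma_1=0.1, gamma_2=1.0, gamma_3=0.2, gamma_4=1.0,
                beta_2=0.05, beta_4=beta4, beta_5=1.0,
            )
            ds = simulate_dataset(dgp, rng)
            gxe = fit_mr_gxe(ds, 0)
            genius = fit_mr_genius(ds)
            part = partition_sub_instruments(
                ds.g_matrix, ds.x, cfg.m_groups, seed=int(rng.integers(2**31)),
            )
            over = sargan_gxe(ds, 0, partition=part, per_group=False)
            rows.append(
                {
                    "proportion": prop,
                    "rep": r,
                    "gxe_beta1": gxe.beta1,
                    "genius_beta1": genius.beta1,
                    "gxe_f": gxe.f_interaction,
                    "mean_sub_f": float(part.sub_f.mean()),
                    "sargan_stat": over.statistic,
                    "sargan_pvalue": over.pvalue,
                    "bp_stat": genius.bp_stat,
                }
            )
    reps = _rep_frame(rows)
    summary = []
    for prop, grp in reps.groupby("proportion", sort=True):
        row = {"proportion": prop}
        row.update({f"gxe_{k}": v for k, v in _mc_cols(grp["gxe_beta1"]).items()})
        row.update(
            {f"genius_{k}": v for k, v in _mc_cols(grp["genius_beta1"]).items()}
        )
        row["mean_sub_f"] = grp["mean_sub_f"].mean()
        row["mean_sargan_pvalue"] = grp["sargan_pvalue"].mean()
        row["sargan_rejection_rate"] = float((grp["sargan_pvalue"] < 0.05).mean())
        summary.append(row)
    return ScenarioResult(cfg, pd.DataFrame(summary), reps)
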