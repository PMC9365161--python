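"""Interaction scan, exogeneity screen, partitioning and over-identification
tests."""

import numpy as np
import pandas as pd
import pytest

from mrgxe import (
    Dataset,
    DGPParams,
    InputError,
    build_prs,
    cochran_q,
    gz_correlation,
    interaction_scan,
    partition_sub_instruments,
    sargan_gxe,
    simulate_dataset,
)
from mrgxe.diagnostics import SubInstrumentPartition

from conftest import SEED


class TestInteractionScan:
    def test_single_covariate_equals_robust_squared_t(self, iv_dataset):
        """Scan F for one covariate equals the HC0 squared t-statistic of
        the interaction term from the explicit first-stage OLS."""
        import statsmodels.api as sm

        g = iv_dataset.g
        z = iv_dataset.z["z1"].to_numpy()
        D = np.column_stack([np.ones(len(g)), g, z, g * z])
        ols = sm.OLS(iv_dataset.x, D).fit(cov_type="HC0")
        scan = interaction_scan(iv_dataset)
        assert scan.table["f_stat"].iloc[0] == pytest.approx(
            ols.tvalues[3] ** 2, rel=1e-6
        )

    def test_classical_variant_equals_classical_squared_t(self, iv_dataset):
        import statsmodels.api as sm

        g = iv_dataset.g
        z = iv_dataset.z["z1"].to_numpy()
        D = np.column_stack([np.ones(len(g)), g, z, g * z])
        ols = sm.OLS(iv_dataset.x, D).fit()
        scan = interaction_scan(iv_dataset, robust=False)
        assert scan.table["f_stat"].iloc[0] == pytest.approx(
            ols.tvalues[3] ** 2, rel=1e-8
        )

    def test_scan_result_invariants(self, rng):
        n, K = 1500, 12
        g = rng.standard_normal(n)
        Z = rng.standard_normal((n, K))
        x = g + Z[:, 0] + 0.6 * g * Z[:, 0] + rng.standard_normal(n)
        ds = Dataset(y=x + rng.standard_normal(n), x=x, g=g, z=Z)
        scan = interaction_scan(ds, alpha=0.05)
        tab = scan.table
        assert scan.bonferroni_threshold == pytest.approx(0.05 / K)
        pos = tab["pvalue"] > 0
        np.testing.assert_allclose(
            tab.loc[pos, "neg_log10_p"],
            -np.log10(tab.loc[pos, "pvalue"]),
            atol=1e-10,
        )
        assert (
            tab["passes"] == (tab["pvalue"] < scan.bonferroni_threshold)
        ).all()
        # sorted by descending strength
        assert tab["f_stat"].is_monotonic_decreasing

    def test_constant_covariate_flagged_and_scan_continues(self, rng):
        n = 800
        g = rng.standard_normal(n)
        z = rng.standard_normal(n)
        x = g + z + g * z + rng.standard_normal(n)
        zf = pd.DataFrame({"good": z, "flat": np.ones(n)})
        ds = Dataset(y=x.copy(), x=x, g=g, z=zf)
        scan = interaction_scan(ds)
        tab = scan.table.set_index("covariate")
        assert not tab.loc["flat", "valid"]
        assert "constant" in tab.loc["flat", "reason"]
        assert tab.loc["good", "valid"]
        assert scan.n_tested == 1

    def test_family_wise_error_controlled_under_global_null(self):
        """With no true interactions the Bonferroni scan's family-wise
        error stays at or below its nominal level."""
        n, K, reps = 800, 25, 1000
        root = np.random.SeedSequence(SEED)
        hits = 0
        for s in root.spawn(reps):
            rng = np.random.default_rng(s)
            g = rng.standard_normal(n)
            Z = rng.standard_normal((n, K))
            x = g + Z.sum(axis=1) * 0.2 + rng.standard_normal(n)
            ds = Dataset(y=x.copy(), x=x, g=g, z=Z)
            hits += interaction_scan(ds).table["passes"].any()
        fwer = hits / reps
        mc_se = np.sqrt(max(fwer, 1 / reps) * (1 - fwer) / reps)
        assert fwer <= 0.05 + 2 * mc_se


class TestGZCorrelation:
    def test_self_correlation_is_one(self, rng):
        n = 200
        v = rng.standard_normal(n)
        ds = Dataset(y=v, x=v, g=v, z=pd.DataFrame({"z1": v}))
        assert gz_correlation(ds, "z1").correlation == pytest.approx(1.0)

    def test_independent_covariate_small_correlation(self):
        dgp = DGPParams(n=50_000, K=1, pi_1=0.0, gamma_3=0.5, seed=SEED)
        res = gz_correlation(simulate_dataset(dgp), 0)
        assert abs(res.correlation) < 0.02

    def test_dependent_covariate_detected(self):
        """pi_1 = 0.1 gives correlation ~0.1: decisively detected at
        moderate n."""
        dgp = DGPParams(n=20_000, K=1, pi_1=0.1, gamma_3=0.5, seed=SEED)
        res = gz_correlation(simulate_dataset(dgp), 0)
        assert res.pvalue < 1e-3
        assert res.correlation == pytest.approx(0.1 / np.sqrt(1.01), abs=0.03)

    def test_constant_input_raises(self, rng):
        n = 100
        ds = Dataset(y=rng.standard_normal(n), x=rng.standard_normal(n),
                     g=rng.standard_normal(n), z=np.ones(n)[:, None])
        with pytest.raises(InputError):
            gz_correlation(ds, 0)


class TestPartition:
    @pytest.fixture
    def equal_strength(self, rng):
        n, m = 400, 1000
        G = rng.standard_normal((n, m))
        x = G.sum(axis=1) * 0.05 + rng.standard_normal(n)
        return G, x

    def test_equal_strengths_give_balanced_group_sizes(self, equal_strength):
        G, x = equal_strength
        part = partition_sub_instruments(G, x, 9, seed=SEED)
        sizes = np.bincount(part.assignment, minlength=9)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == G.shape[1]

    def test_same_seed_reproduces_assignment(self, equal_strength):
        G, x = equal_strength
        a = partition_sub_instruments(G, x, 9, seed=7).assignment
        b = partition_sub_instruments(G, x, 9, seed=7).assignment
        np.testing.assert_array_equal(a, b)

    def test_every_sub_instrument_assigned_once(self, equal_strength):
        G, x = equal_strength
        part = partition_sub_instruments(G, x, 5, seed=SEED)
        assert part.assignment.shape == (G.shape[1],)
        assert set(part.assignment) == set(range(5))

    def test_greedy_balances_better_than_random(self, rng):
        """With heterogeneous strengths the greedy assignment's
        strongest/weakest group ratio beats uniform random assignment on
        average over 100 seeds."""
        n, m, M = 500, 40, 4
        scale = np.linspace(0.05, 1.0, m)
        G = rng.standard_normal((n, m))
        x = G @ scale + rng.standard_normal(n)

        def ratio(strengths):
            return strengths.max() / strengths.min()

        greedy, random_ = [], []
        for seed in range(100):
            part = partition_sub_instruments(G, x, M, seed=seed)
            greedy.append(ratio(part.group_strength))
            r = np.random.default_rng(seed)
            assign = np.repeat(np.arange(M), m // M)
            r.shuffle(assign)
            totals = np.bincount(assign, weights=part.sub_f, minlength=M)
            random_.append(ratio(totals))
        assert np.mean(greedy) < np.mean(random_)

    def test_too_many_groups_raises(self, rng):
        G = rng.standard_normal((100, 4))
        x = rng.standard_normal(100)
        with pytest.raises(InputError, match="M=9"):
            partition_sub_instruments(G, x, 9)


def _sub_instrument_dataset(seed, n=4000, M=30, beta4=0.0, prop=0.0):
    b4 = np.zeros((M, 1))
    b4[: int(round(prop * M)), 0] = beta4
    dgp = DGPParams(n=n, K=1, M=M, gamma_1=0.1, gamma_2=1.0, gamma_3=0.2,
                    beta_2=0.05, beta_4=b4)
    return simulate_dataset(dgp, np.random.default_rng(seed))


class TestSargan:
    def test_statistic_invariant_to_group_label_permutation(self):
        ds = _sub_instrument_dataset(SEED)
        part = partition_sub_instruments(ds.g_matrix, ds.x, 3, seed=SEED)
        res = sargan_gxe(ds, 0, partition=part, per_group=False)
        perm = [2, 0, 1]
        part2 = SubInstrumentPartition(
            assignment=np.array([perm[a] for a in part.assignment]),
            M=3,
            group_scores=part.group_scores[:, np.argsort(perm)],
            group_f=part.group_f[np.argsort(perm)],
            sub_f=part.sub_f,
            group_strength=part.group_strength[np.argsort(perm)],
        )
        res2 = sargan_gxe(ds, 0, partition=part2, per_group=False)
        assert res.statistic == pytest.approx(res2.statistic, rel=1e-8)
        assert res.df == res2.df == 2

    def test_single_group_untestable(self):
        ds = _sub_instrument_dataset(SEED)
        part = partition_sub_instruments(ds.g_matrix, ds.x, 2, seed=SEED)
        part.M = 1
        part.group_scores = part.group_scores[:, :1]
        with pytest.raises(InputError, match="just-identified"):
            sargan_gxe(ds, 0, partition=part)

    def test_partial_violation_detected(self):
        """10% of sub-instruments with a second-stage interaction: the
        over-identification test rejects."""
        ds = _sub_instrument_dataset(SEED, n=20_000, M=30, beta4=0.2, prop=0.1)
        res = sargan_gxe(ds, 0, m_groups=3, seed=SEED, per_group=False)
        assert res.pvalue < 0.01

    def test_agrees_with_cochran_q_decision(self):
        """Sargan and Q test the same over-identifying structure: their
        5%-level decisions agree on the vast majority of datasets."""
        agree = 0
        reps = 60
        for i in range(reps):
            prop = 0.0 if i % 2 == 0 else 0.2
            ds = _sub_instrument_dataset(1000 + i, n=4000, M=30,
                                         beta4=0.3, prop=prop)
            res = sargan_gxe(ds, 0, m_groups=3, seed=i)
            q = cochran_q(res.per_group_estimates["beta1"],
                          res.per_group_estimates["se"])
            agree += (res.pvalue < 0.05) == (q.pvalue < 0.05)
        assert agree / reps >= 0.9


class TestCochranQ:
    def test_identical_estimates_give_zero(self):
        res = cochran_q([1.2, 1.2, 1.2], [0.1, 0.2, 0.3])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_computed_two_group_value(self):
        """(1.0, se 0.1) vs (2.0, se 0.1): weights 100 each, IVW mean 1.5,
        Q = 100*0.25 + 100*0.25 = 50."""
        res = cochran_q([1.0, 2.0], [0.1, 0.1])
        assert res.statistic == pytest.approx(50.0, rel=1e-12)
        assert res.df == 1
        assert res.ivw_estimate == pytest.approx(1.5)

    def test_null_distribution_mean_matches_df(self, rng):
        """Homogeneous true effects: Q ~ chi-square(M-1), so its mean over
        replicates is close to M - 1."""
        M, reps = 5, 800
        qs = [
            cochran_q(1.0 + 0.1 * rng.standard_normal(M), np.full(M, 0.1)).statistic
            for _ in range(reps)
        ]
        assert np.mean(qs) == pytest.approx(M - 1, abs=0.35)

    def test_nonpositive_se_raises(self):
        with pytest.raises(InputError):
            cochran_q([1.0, 2.0], [0.1, 0.0])


class TestBuildPRS:
    def test_unit_weights_give_row_sums(self, rng):
        G = rng.integers(0, 3, size=(50, 6)).astype(float)
        np.testing.assert_allclose(build_prs(G), G.sum(axis=1))

    def test_standardized_score_is_zscored(self, rng):
        G = rng.standard_normal((200, 5))
        w = rng.random(5)
        s = build_prs(G, w, standardize=True)
        assert s.mean() == pytest.approx(0.0, abs=1e-10)
        assert s.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_weight_rescaling_invariant_after_standardization(self, rng):
        G = rng.standard_normal((100, 4))
        w = rng.random(4)
        np.testing.assert_allclose(
            build_prs(G, w, standardize=True),
            build_prs(G, 2.0 * w, standardize=True),
            atol=1e-10,
        )

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(InputError, match="weights length"):
            build_prs(rng.standard_normal((10, 3)), [1.0, 2.0])

    def test_missing_dosages_require_impute_flag(self, rng):
        G = rng.standard_normal((20, 3))
        G[0, 0] = np.nan
        with pytest.raises(InputError, match="missing"):
            build_prs(G)
        s = build_prs(G, mean_impute=True)
        assert np.isfinite(s).all()
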