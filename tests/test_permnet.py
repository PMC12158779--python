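"""Permutation machinery: conservation, hand-checked statistics, oracles."""

import numpy as np
import pandas as pd
import pytest

from starhelp.permnet import (
    _BlockShuffler,
    adjusted_help_scores,
    bootstrap_group_mean,
    double_permutation_pipeline,
    dyadic_cv,
    empirical_p,
    mantel_test,
    mrqap_dsp,
    permute_nonkin_help,
)


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "helper_id", "nest_id", "day", "help_minutes", "exposure_minutes",
            "kinship_r", "group", "season", "mother_id", "father_id",
        ],
    )


class TestEmpiricalP:
    def test_minimum_with_5000_draws(self):
        null = np.zeros(5000)
        p = empirical_p(1.0, null, tail="upper")
        assert p == pytest.approx(1 / 5001)
        assert p <= 0.0002

    def test_observed_below_all_nulls_upper_tail(self):
        assert empirical_p(-1.0, np.zeros(100), tail="upper") == 1.0

    def test_tiny_case_by_hand(self):
        # nulls {1, 2, 3, 4}, observed 2.5, upper tail: k = 2 -> p = 3/5
        assert empirical_p(2.5, [1, 2, 3, 4], tail="upper") == pytest.approx(0.6)

    def test_never_zero(self):
        assert empirical_p(99.0, np.zeros(10), tail="upper") == pytest.approx(1 / 11)


class TestDyadicCV:
    def test_equal_rates_zero_cv(self):
        rows = [
            ("H1", "N1", 1, 5, 100.0, 0.0, "G", 1, "M", "F"),
            ("H2", "N1", 1, 5, 100.0, 0.0, "G", 1, "M", "F"),
        ]
        assert dyadic_cv(_table(rows)) == pytest.approx(0.0)

    def test_sample_sd_convention(self):
        # rates {0, 0, 1} with the n-1 convention: sd/mean = sqrt(1/3)/(1/3)
        assert np.std([0, 0, 1], ddof=1) / np.mean([0, 0, 1]) == pytest.approx(
            np.sqrt(3.0), rel=1e-9
        )

    def test_hand_computed_cv(self):
        # three helpers at distinct nests; each row feeds the helper->mother
        # and helper->father dyads, so the dyad-rate multiset is {0,0,0,0,1,1}
        rows = [
            ("H1", "N1", 1, 0, 100.0, 0.0, "G", 1, "M1", "M1b"),
            ("H2", "N2", 1, 0, 100.0, 0.0, "G", 1, "M2", "M2b"),
            ("H3", "N3", 1, 100, 100.0, 0.0, "G", 1, "M3", "M3b"),
        ]
        expected = np.std([0, 0, 0, 0, 1, 1], ddof=1) / np.mean([0, 0, 0, 0, 1, 1])
        assert dyadic_cv(_table(rows)) == pytest.approx(expected)

    def test_all_zero_is_nan(self):
        rows = [("H1", "N1", 1, 0, 100.0, 0.0, "G", 1, "M", "F")]
        assert np.isnan(dyadic_cv(_table(rows)))


class TestPermuteNonkinHelp:
    def test_conservation_per_nest_day(self, small_table):
        nonkin = small_table[small_table["kinship_r"] <= 0.125].reset_index(drop=True)
        block = pd.factorize(nonkin["nest_id"].astype(str) + "@" + nonkin["day"].astype(str))[0]
        sh = _BlockShuffler(block, nonkin["help_minutes"].to_numpy(float))
        rng = np.random.default_rng(0)
        for _ in range(10):
            permuted = sh.draw(rng)
            # totals per block and the multiset of amounts are conserved
            np.testing.assert_allclose(
                np.bincount(sh.block, weights=permuted),
                np.bincount(sh.block, weights=sh.help),
            )
            assert sorted(permuted) == sorted(sh.help)

    def test_planted_extreme_dyad_detected(self):
        # one helper always helping one breeder far above the group norm
        rows = []
        for day in range(15):
            rows.append(("H1", f"N{day}", day, 60, 120.0, 0.0, "G", 1, "B1", "B2"))
            for h in ("H2", "H3", "H4", "H5"):
                rows.append((h, f"N{day}", day, 0, 120.0, 0.0, "G", 1, "B1", "B2"))
        res = permute_nonkin_help(_table(rows), n_perm=300, seed=1)
        assert res.p == pytest.approx(1 / 301)
        assert res.observed > res.null_draws.max()

    def test_determinism(self, small_table):
        a = permute_nonkin_help(small_table, n_perm=50, seed=12)
        b = permute_nonkin_help(small_table, n_perm=50, seed=12)
        np.testing.assert_array_equal(a.null_draws, b.null_draws)
        assert a.p == b.p


class TestAdjustedScores:
    def test_self_null_centres_scores(self):
        # data generated by the null itself -> entries centred near zero
        rng = np.random.default_rng(8)
        rows = []
        for day in range(30):
            helpers = [f"H{k}" for k in range(6)]
            amounts = rng.permutation([12, 4, 0, 0, 0, 0])
            for h, a in zip(helpers, amounts):
                rows.append((h, f"N{day % 3}", day, a, 120.0, 0.0, "G", 1, "B1", "B2"))
        mats = adjusted_help_scores(_table(rows), n_perm=400, seed=3)
        entries = mats["G"].values[mats["G"].values != 0]
        assert abs(np.mean(entries)) < 0.02

    def test_planted_signal_positive_entry(self):
        rows = []
        for day in range(12):
            rows.append(("H1", f"N{day}", day, 80, 120.0, 0.0, "G", 1, "B1", "B2"))
            for h in ("H2", "H3", "H4"):
                rows.append((h, f"N{day}", day, 0, 120.0, 0.0, "G", 1, "B1", "B2"))
        mats = adjusted_help_scores(_table(rows), n_perm=200, seed=5)
        ids = mats["G"].ids
        M = mats["G"].values
        assert M[ids.index("H1"), ids.index("B1")] > 0.2

    def test_seeded_determinism(self, small_table):
        a = adjusted_help_scores(small_table, n_perm=60, seed=4)
        b = adjusted_help_scores(small_table, n_perm=60, seed=4)
        for g in a:
            np.testing.assert_array_equal(a[g].values, b[g].values)

    def test_zero_diagonal(self, small_table):
        for mat in adjusted_help_scores(small_table, n_perm=40, seed=2).values():
            assert np.all(np.diag(mat.values) == 0)


class TestMantel:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 8))
        r, p = mantel_test(A, A, n_perm=200, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 8))
        r, _ = mantel_test(A, -A, n_perm=50, seed=1)
        assert r == pytest.approx(-1.0)

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(300):
            A = rng.normal(size=(7, 7))
            B = rng.normal(size=(7, 7))
            _, p = mantel_test(A, B, n_perm=99, seed=int(rng.integers(2**31)))
            ps.append(p)
        assert np.mean(np.array(ps) <= 0.05) == pytest.approx(0.05, abs=0.035)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mantel_test(np.eye(3), np.eye(4), n_perm=10)


class TestMrqapDsp:
    def test_perfect_single_predictor(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(9, 9))
        res = mrqap_dsp(Y, [Y], n_perm=150, seed=0)
        assert res.loc[0, "coefficient"] == pytest.approx(1.0)
        assert res.loc[0, "p"] == pytest.approx(1 / 151)

    def test_coefficients_equal_offdiagonal_ols(self):
        rng = np.random.default_rng(4)
        n = 10
        X1, X2 = rng.normal(size=(n, n)), rng.normal(size=(n, n))
        Y = 0.5 * X1 - 0.3 * X2 + rng.normal(size=(n, n))
        res = mrqap_dsp(Y, [X1, X2], n_perm=20, seed=0)
        # independent oracle: normal equations on the off-diagonal cells
        mask = ~np.eye(n, dtype=bool)
        D = np.column_stack([np.ones(mask.sum()), X1[mask], X2[mask]])
        beta = np.linalg.solve(D.T @ D, D.T @ Y[mask])
        assert res["coefficient"].to_numpy() == pytest.approx(beta[1:], abs=1e-10)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        rejections = []
        for _ in range(200):
            X = rng.normal(size=(7, 7))
            Y = rng.normal(size=(7, 7))
            res = mrqap_dsp(Y, [X], n_perm=99, seed=int(rng.integers(2**31)))
            rejections.append(res.loc[0, "p"] <= 0.05)
        assert np.mean(rejections) == pytest.approx(0.05, abs=0.04)

    def test_collinear_predictors_error(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 6))
        with pytest.raises(ValueError, match="collinear"):
            mrqap_dsp(rng.normal(size=(6, 6)), [X, 2 * X], n_perm=10)


class TestBootstrapGroupMean:
    def test_identical_stats_degenerate(self):
        mean, lo, hi = bootstrap_group_mean([0.3] * 9, B=200, seed=0)
        assert mean == lo == hi == pytest.approx(0.3)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_group_mean([0.3], B=10, seed=0)

    def test_determinism(self):
        vals = np.random.default_rng(1).normal(size=9)
        assert bootstrap_group_mean(vals, B=500, seed=7) == bootstrap_group_mean(
            vals, B=500, seed=7
        )


class TestDoublePermutationPipeline:
    def test_planted_reciprocity_detected_in_majority(self):
        """With a strong generative reciprocity effect the group-mean
        give-receive statistic should reject in most replicates."""
        from starhelp import datamodel
        from starhelp.synthpop import SimConfig, simulate_population

        hits = 0
        reps = 6
        for rep in range(reps):
            ds = simulate_population(
                SimConfig(seed=1200 + rep, n_seasons=12, n_groups=4, beta_recip=2.0,
                          beta_kin=0.0, sd_helper=0.0, sd_nest=0.0, sd_dyad=0.0)
            )
            presence = datamodel.presence_from_individuals(ds.individuals)
            table, _ = datamodel.build_analysis_table(
                ds.ledger, presence, ds.nests, ds.individuals, relatedness=ds.relatedness
            )
            dp = double_permutation_pipeline(
                table, ds.relatedness, n_perm_adjust=300, n_perm_test=300,
                n_boot=300, seed=rep, n_perm_mrqap=100,
            )
            hits += dp["mean_mantel_p"] <= 0.05
        assert hits > reps / 2

    def test_result_structure(self, small_dataset, small_table):
        dp = double_permutation_pipeline(
            small_table, small_dataset.relatedness, n_perm_adjust=100,
            n_perm_test=100, n_boot=100, seed=3, n_perm_mrqap=50,
        )
        assert set(dp) >= {
            "per_group", "mean_mantel_r", "mean_mantel_p", "bootstrap_ci",
            "mrqap", "mrqap_mean_coef_give", "mrqap_mean_coef_p",
        }
        assert 0 < dp["mean_mantel_p"] <= 1
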