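"""Size factors, dispersion, NB Wald test, BH adjustment, classification
and pool ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import denovopool as dp


def _frame(arr, prefix="s"):
    arr = np.asarray(arr)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def _counts_from_truth(truth, depth, rng, timepoints=None):
    """Multinomial read counts per sample drawn from true frequencies."""
    tps = timepoints or [1, truth.config.n_timepoints]
    cols, meta = {}, []
    for r in range(truth.config.n_replicates):
        for t in tps:
            name = truth.sample_name(r, t - 1)
            cols[name] = pd.Series(
                rng.multinomial(depth, truth.frequencies(r, t - 1)),
                index=truth.clone_ids,
            )
            meta.append({"sample": name, "replicate": r + 1, "timepoint": t})
    return dp.assemble_count_matrix(
        cols, pd.DataFrame(meta).set_index("sample")
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = _frame(np.tile([[4], [10], [7]], (1, 4)))
        sf = dp.size_factors(df)
        assert np.allclose(sf, 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = np.tile(rng.poisson(50, size=(100, 1)) + 1, (1, 4))
        doubled = base.copy()
        doubled[:, 2] *= 2
        sf = dp.size_factors(_frame(doubled))
        # the scaled column's factor is exactly twice each of the others
        others = np.delete(sf.to_numpy(), 2)
        assert np.allclose(sf.iloc[2], 2 * others, rtol=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        # odd clone count: the median is an order statistic, so the
        # ratio-scale and log-scale medians agree exactly
        rng = np.random.default_rng(42)
        counts = rng.poisson(60, size=(51, 6)) + 1
        sf = dp.size_factors(_frame(counts))
        geo = np.exp(np.mean(np.log(counts), axis=1))
        expected = [np.median(counts[:, j] / geo) for j in range(6)]
        assert np.allclose(sf, expected, atol=1e-12)

    def test_single_clone_median_is_the_ratio(self):
        df = _frame([[4, 9]])
        sf = dp.size_factors(df)
        geomean = np.sqrt(4 * 9)
        assert np.allclose(sf, [4 / geomean, 9 / geomean])

    def test_no_all_positive_clone_raises(self):
        with pytest.raises(ValueError, match="size factors undefined"):
            dp.size_factors(_frame([[0, 5], [5, 0]]))


class TestEstimateDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(1)
        counts = _frame(rng.poisson(100, size=(1000, 10)))
        cond = np.array([0] * 5 + [1] * 5)
        sf = dp.size_factors(counts)
        disp = dp.estimate_dispersion(counts, sf, cond, shrinkage_weight=0.0)
        assert disp.median() < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(2)
        alpha, mu = 0.5, 200.0
        r = 1 / alpha
        counts = _frame(rng.negative_binomial(r, r / (r + mu), size=(500, 20)))
        cond = np.array([0] * 10 + [1] * 10)
        sf = dp.size_factors(counts)
        disp = dp.estimate_dispersion(counts, sf, cond, shrinkage_weight=0.0)
        assert 0.3 < disp.mean() < 0.7

    def test_constant_counts_give_zero(self):
        counts = _frame(np.full((3, 6), 50))
        cond = np.array([0] * 3 + [1] * 3)
        disp = dp.estimate_dispersion(counts, dp.size_factors(counts), cond,
                                      shrinkage_weight=0.0)
        assert (disp == 0).all()

    def test_all_zero_clone_flagged_untestable(self):
        counts = _frame([[5, 5, 5, 5], [0, 0, 0, 0]])
        cond = np.array([0, 0, 1, 1])
        disp = dp.estimate_dispersion(counts, dp.size_factors(counts), cond)
        assert np.isnan(disp.iloc[1])


class TestWaldTest:
    def test_identical_conditions_give_null_result(self):
        counts = _frame(np.tile([[100], [40]], (1, 8)))
        cond = np.array([0] * 4 + [1] * 4)
        res = dp.wald_test(counts, condition=cond)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-8)
        assert (res["wald_p"] > 0.99).all()

    def test_fourfold_shift_recovered(self):
        rng = np.random.default_rng(3)
        mu0, alpha = 2500.0, 0.01
        r = 1 / alpha
        a = rng.negative_binomial(r, r / (r + mu0), size=(300, 5))
        b = rng.negative_binomial(r, r / (r + 4 * mu0), size=(300, 5))
        counts = _frame(np.hstack([a, b]))
        cond = np.array([0] * 5 + [1] * 5)
        sf = pd.Series(1.0, index=counts.columns)
        res = dp.wald_test(counts, sf=sf, condition=cond)
        assert abs(res["log2fc"].mean() - 2.0) < 0.2
        assert (res["wald_p"] < 1e-6).mean() > 0.99

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(4)
        mu = rng.lognormal(5, 1, 10_000)
        alpha = 0.05
        r = 1 / alpha
        counts = _frame(
            rng.negative_binomial(r, r / (r + mu[:, None]), size=(10_000, 10))
        )
        cond = np.array([0] * 5 + [1] * 5)
        res = dp.wald_test(counts, condition=cond)
        p = res["wald_p"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.001

    def test_scale_invariance_of_fold_change_and_p(self):
        # a depth change in one sample is absorbed by its size factor:
        # with the scaled factors the normalized matrix is identical, so
        # fold changes and p-values do not move
        rng = np.random.default_rng(5)
        counts = rng.poisson(80, size=(200, 10)) + 1
        cond = np.array([0] * 5 + [1] * 5)
        sf = dp.size_factors(_frame(counts))
        disp = dp.estimate_dispersion(_frame(counts), sf, cond)
        res1 = dp.wald_test(_frame(counts), sf=sf, dispersions=disp,
                            condition=cond)
        scaled = counts.copy()
        scaled[:, 3] *= 2  # integer rescale of one sample
        sf_scaled = sf.copy()
        sf_scaled.iloc[3] *= 2
        res2 = dp.wald_test(_frame(scaled), sf=sf_scaled, dispersions=disp,
                            condition=cond)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=1e-8)
        assert np.allclose(res1["wald_p"], res2["wald_p"], atol=1e-8)

    def test_fold_change_invariant_under_recomputed_size_factors(self):
        # even when the size factors are recomputed from the scaled matrix,
        # the log fold change depends only on ratios and does not move
        rng = np.random.default_rng(15)
        counts = rng.poisson(80, size=(200, 10)) + 1
        cond = np.array([0] * 5 + [1] * 5)
        res1 = dp.wald_test(_frame(counts), condition=cond)
        scaled = counts.copy()
        scaled[:, 3] *= 2
        res2 = dp.wald_test(_frame(scaled), condition=cond)
        assert np.allclose(res1["log2fc"], res2["log2fc"], atol=1e-8)

    def test_too_few_samples_rejected(self):
        counts = _frame([[1, 2, 3]])
        with pytest.raises(ValueError, match="at least 2 samples"):
            dp.wald_test(counts, condition=np.array([0, 0, 1]))


class TestAdjustBH:
    def test_degenerate_cases(self):
        assert np.allclose(dp.adjust_bh([1.0, 1.0, 1.0]), 1.0)
        assert dp.adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_step_up_arithmetic(self):
        adj = dp.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_missing_values_pass_through(self):
        adj = dp.adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and np.isfinite(adj[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.adjust_bh([0.5, 1.5])

    def test_matches_brute_force_step_up(self):
        def brute_force_bh(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            adj = [None] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(dp.adjust_bh(p), brute_force_bh(list(p)),
                               atol=1e-12)


class TestClassifyClones:
    def test_rule_on_constructed_rows(self):
        res = pd.DataFrame(
            {
                "log2fc": [1.2, -0.8, 0.4, np.nan],
                "wald_p": [0.001, 0.001, 0.5, np.nan],
                "padj": [0.01, 0.01, 0.2, np.nan],
            },
            index=["a", "b", "c", "d"],
        )
        out, counts = dp.classify_clones(res)
        assert list(out["class"]) == ["UP", "DOWN", "NS", "NS"]
        assert counts.sum() == 4  # the three groups partition the clones

    def test_recovery_of_known_class_proportions(self):
        rng = np.random.default_rng(7)
        n = 600
        s = np.zeros(n)
        s[:60] = 0.15
        s[60:180] = -0.15
        cfg = dp.GrowthSimConfig(n_replicates=5, n_timepoints=10,
                                 cells_per_passage=500_000)
        truth = dp.simulate_growth(n, s, cfg, seed=8)
        cm = _counts_from_truth(truth, depth=200_000, rng=rng)
        res = dp.run_differential_abundance(cm, contrast_timepoint=10)
        merged = res.join(truth.true_class)
        for label, frac in [("UP", 0.10), ("DOWN", 0.20), ("NS", 0.70)]:
            got = (merged["class"] == label).mean()
            assert abs(got - frac) < 0.03, (label, got)

    def test_strong_effects_recovered_with_correct_sign(self):
        # |s| = 0.05 per doubling over 10 passages at depth 1e6
        rng = np.random.default_rng(9)
        n = 1000
        s = np.zeros(n)
        s[:100] = 0.05
        s[100:300] = -0.05
        cfg = dp.GrowthSimConfig(n_replicates=5, n_timepoints=11,
                                 cells_per_passage=3_000_000)
        truth = dp.simulate_growth(n, s, cfg, seed=10)
        cm = _counts_from_truth(truth, depth=1_000_000, rng=rng,
                                timepoints=[1, 11])
        res = dp.run_differential_abundance(cm, contrast_timepoint=11)
        merged = res.join(truth.true_class)
        non_neutral = merged[merged["true_class"] != "NS"]
        correct = (non_neutral["class"] == non_neutral["true_class"]).mean()
        assert correct >= 0.90

    def test_fdr_controlled_on_full_null(self):
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mu = rng.lognormal(5.5, 0.8, 10_000)
            r = 1 / 0.02
            counts = _frame(
                rng.negative_binomial(r, r / (r + mu[:, None]), size=(10_000, 10))
            )
            cond = np.array([0] * 5 + [1] * 5)
            res = dp.wald_test(counts, condition=cond)
            res["padj"] = dp.adjust_bh(res["wald_p"])
            out, cts = dp.classify_clones(res, alpha=0.05)
            rates.append((cts["UP"] + cts["DOWN"]) / cts.sum())
        assert np.mean(rates) <= 0.07


class TestRankPoolGrowth:
    def _pool_matrix(self, truth, depth, rng):
        return _counts_from_truth(truth, depth, rng,
                                  timepoints=[1, truth.config.n_timepoints])

    def test_neutral_deterministic_pool_ranks_by_tie_break(self):
        truth = dp.make_mdng_pool(np.zeros(14), seed=0, deterministic=True)
        rng = np.random.default_rng(11)
        cm = self._pool_matrix(truth, 10**6, rng)
        res = dp.rank_pool_growth(cm)
        assert sorted(res["rank"].dropna()) == list(range(1, 15))

    def test_rank_order_tracks_fitness(self):
        s = np.linspace(0.12, -0.12, 14)
        concordant = total = 0
        for seed in range(100):
            truth = dp.make_mdng_pool(s, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            cm = self._pool_matrix(truth, 300_000, rng)
            res = dp.rank_pool_growth(cm)
            rank = res["rank"].to_numpy(float)
            for i, j in itertools.combinations(range(14), 2):
                total += 1
                concordant += int((s[i] - s[j]) * (rank[j] - rank[i]) > 0)
        assert concordant / total >= 0.90

    def test_failed_to_grow_clone_is_flagged_and_unranked(self):
        truth = dp.make_mdng_pool(np.zeros(14), seed=1, deterministic=True)
        rng = np.random.default_rng(12)
        cm = self._pool_matrix(truth, 10**5, rng)
        cm.counts.iloc[2, cm.condition_mask(truth.config.n_timepoints)] = 0
        res = dp.rank_pool_growth(cm)
        assert bool(res["failed_to_grow"].iloc[2])
        assert pd.isna(res["rank"].iloc[2])
        assert sorted(res["rank"].dropna()) == list(range(1, 14))
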