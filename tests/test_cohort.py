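import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsrnakit.cohort import (
    chi_square,
    cox_fit,
    differential_expression,
    fit_variance_prior,
    km_estimate,
    logrank_test,
    median_split,
    spearman_top_k,
)


def _two_group(n_sig, n1, n2, lfc=0.0, sigma=1.0, seed=0, n_affected=None):
    rng = np.random.default_rng(seed)
    x = rng.normal(5.0, sigma, size=(n_sig, n1 + n2))
    n_affected = n_sig if n_affected is None else n_affected
    x[:n_affected, :n1] += lfc
    expr = pd.DataFrame(
        x,
        index=[f"sig{i}" for i in range(n_sig)],
        columns=[f"T{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)],
    )
    design = pd.DataFrame(
        {"group": ["tumor"] * n1 + ["normal"] * n2}, index=expr.columns
    )
    return expr, design


class TestDifferentialExpression:
    def test_identical_group_means_not_significant(self):
        expr, design = _two_group(50, 8, 8, lfc=0.0, seed=1)
        res = differential_expression(expr, design)
        assert np.allclose(res["log2fc"].mean(), 0, atol=0.1)
        assert res["significant"].sum() <= 5

    def test_fold_change_gate_is_strict(self):
        # an effect of exactly 1.0 with p ~ 0 must NOT pass ("more than one")
        expr, design = _two_group(30, 10, 10, lfc=0.0, sigma=0.01, seed=2)
        expr.iloc[0, :10] = 6.0  # noise-free: log2FC exactly 1.0
        expr.iloc[0, 10:] = 5.0
        res = differential_expression(expr, design)
        assert res.iloc[0]["p"] < 1e-6
        assert res.iloc[0]["log2fc"] == 1.0
        assert not res.iloc[0]["significant"]
        # nudging past the gate flips it
        expr.iloc[0, :10] = 6.01
        res2 = differential_expression(expr, design)
        assert res2.iloc[0]["significant"]

    def test_planted_effect_detected(self):
        detected = 0
        for seed in range(20):
            expr, design = _two_group(
                100, 20, 20, lfc=2.0, sigma=0.3, seed=seed, n_affected=1
            )
            res = differential_expression(expr, design)
            detected += bool(res.iloc[0]["significant"])
        assert detected == 20

    def test_paired_contrast_uses_pair_differences(self):
        rng = np.random.default_rng(3)
        n = 8
        sample_effect = rng.normal(0, 5, size=n)  # huge pair-level noise
        tumor = sample_effect + 2.0 + rng.normal(0, 0.1, size=n)
        normal = sample_effect + rng.normal(0, 0.1, size=n)
        expr = pd.DataFrame(
            [np.concatenate([tumor, normal])],
            index=["sig0"],
            columns=[f"T{i}" for i in range(n)] + [f"N{i}" for i in range(n)],
        )
        design = pd.DataFrame(
            {
                "group": ["tumor"] * n + ["normal"] * n,
                "pair_id": [f"P{i}" for i in range(n)] * 2,
            },
            index=expr.columns,
        )
        res = differential_expression(pd.concat([expr] * 30), design, method="welch")
        assert res.attrs["paired"]
        assert res.iloc[0]["p"] < 1e-4  # pairing removes the sample effect

    def test_incomplete_pairing_degrades_to_unpaired(self, caplog):
        expr, design = _two_group(20, 6, 4, seed=4)
        design["pair_id"] = ["P1", "P2", "P3", "P4", "P5", "P6",
                             "P1", "P2", "P3", "P4"]
        res = differential_expression(expr, design, paired=True)
        assert not res.attrs["paired"]

    def test_null_pvalues_uniform(self):
        expr, design = _two_group(2000, 16, 9, lfc=0.0, seed=5)
        res = differential_expression(expr, design)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_welch_and_moderated_agree_at_large_n(self):
        expr, design = _two_group(200, 50, 50, lfc=1.0, seed=6, n_affected=50)
        mod = differential_expression(expr, design)
        welch = differential_expression(expr, design, method="welch")
        assert np.corrcoef(mod["t"], welch["t"])[0, 1] > 0.99

    def test_shrinkage_limits(self):
        # homogeneous variances: prior dominates, d0 large
        rng = np.random.default_rng(7)
        s2 = stats.chi2.rvs(10, size=500, random_state=rng) / 10
        d0, s0 = fit_variance_prior(s2, 10)
        assert d0 > 50 or np.isinf(d0)
        assert s0 == pytest.approx(1.0, rel=0.15)
        # wildly heterogeneous variances: little shrinkage, d0 small
        s2_het = np.exp(rng.normal(0, 3, size=500))
        d0_het, _ = fit_variance_prior(s2_het, 10)
        assert d0_het < 2.0

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: the reference empirical-Bayes implementation."""
        expr, design = _two_group(60, 5, 4, lfc=2.0, seed=8, n_affected=10)
        expr.to_csv(tmp_path / "expr.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))\n'
            'design <- cbind(Intercept=1, tumor=c(rep(1,5), rep(0,4)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(lfc=fit$coefficients[,"tumor"],'
            ' t=fit$t[,"tumor"], p=fit$p.value[,"tumor"])\n'
            f'write.table(out, "{tmp_path}/limma_out.tsv", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t")
        res = differential_expression(expr, design, paired=False)
        np.testing.assert_allclose(res["t"], oracle["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p"], oracle["p"], rtol=1e-8)


class TestMedianSplit:
    def test_even_split(self):
        values = pd.Series(range(1, 11), index=[f"s{i}" for i in range(10)])
        groups = median_split(values)
        assert list(groups[values <= 5]) == ["low"] * 5
        assert list(groups[values > 5]) == ["high"] * 5

    def test_median_value_goes_low(self):
        groups = median_split(pd.Series([1.0, 2.0, 3.0]))
        assert list(groups) == ["low", "low", "high"]

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate|>= 2"):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate([3, 5, 7], [0, 0, 0])
        assert curve.survival_at(10) == 1.0
        assert len(curve.times) == 0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=40)
        curve = km_estimate(times, np.ones(40, int))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean())

    def test_survival_non_increasing_starts_at_one(self):
        rng = np.random.default_rng(10)
        times = rng.exponential(10, size=50)
        events = rng.integers(0, 2, size=50)
        curve = km_estimate(times, events)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival[0] <= 1.0

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        times = np.round(rng.exponential(10, size=80), 1) + 0.1
        events = rng.integers(0, 2, size=80)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        curve = km_estimate(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )


class TestLogRank:
    def test_toy_hand_tabulation(self):
        """Group A dies at 1,2,3; group B at 4,5,6 — tabulated by hand."""
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        groups = list("AAABBB")
        res = logrank_test(times, events, groups)
        # hand hypergeometric sums: E_A = 1/2 + 2/5 + 1/4 = 1.15
        # V = 0.25 + 0.24 + 0.1875 = 0.6775; U = 3 - 1.15
        assert res.observed[0] == 3
        assert res.expected[0] == pytest.approx(1.15)
        assert res.variance == pytest.approx(0.6775)
        assert res.statistic == pytest.approx((3 - 1.15) ** 2 / 0.6775)
        assert res.p_value < 0.05
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 0, 1, 1, 0, 1]
        res = logrank_test(times, events, list("AAABBB"))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_under_relabeling(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(5, size=30)
        events = rng.integers(0, 2, size=30)
        groups = rng.choice(["x", "y"], size=30)
        a = logrank_test(times, events, groups)
        flipped = np.where(groups == "x", "y", "x")
        b = logrank_test(times, events, flipped)
        assert a.statistic == pytest.approx(b.statistic)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], ["a", "b"])

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(13)
        times = rng.exponential(5, size=60)
        events = rng.integers(0, 2, size=60)
        groups = rng.choice(["x", "y"], size=60)
        mine = logrank_test(times, events, groups)
        theirs = lifelines_stats.logrank_test(
            times[groups == "x"], times[groups == "y"],
            events[groups == "x"], events[groups == "y"],
        )
        assert mine.statistic == pytest.approx(theirs.test_statistic)
        assert mine.p_value == pytest.approx(theirs.p_value)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(2000):
            times = rng.exponential(5, size=24)
            events = (rng.random(24) < 0.8).astype(int)
            groups = np.repeat(["a", "b"], 12)
            if events.sum() == 0:
                continue
            pvals.append(logrank_test(times, events, groups).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _cox_sim(n, beta, censor_frac=0.2, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    t_event = rng.exponential(1.0 / np.exp(beta * z))
    c = np.quantile(t_event, 1 - censor_frac) * rng.uniform(0.5, 2.0, size=n)
    times = np.minimum(t_event, c)
    events = (t_event <= c).astype(int)
    return times, events, pd.DataFrame({"z": z})


class TestCox:
    def test_toy_brute_force_partial_likelihood(self):
        """n=4, binary covariate, no ties/censoring: grid-search oracle."""
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def neg_log_pl(beta):
            order = np.argsort(times)
            ll = 0.0
            for i, idx in enumerate(order):
                risk = order[i:]
                ll += beta * x[idx] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        grid = np.arange(-3, 3, 1e-4)
        beta_grid = grid[np.argmin([neg_log_pl(b) for b in grid])]
        model = cox_fit(times, events, pd.DataFrame({"x": x}))
        beta_hat = model.table.loc["x", "beta"]
        assert beta_hat == pytest.approx(beta_grid, abs=1e-4)
        assert model.log_likelihood == pytest.approx(-neg_log_pl(beta_hat))
        assert model.table.loc["x", "hr"] == pytest.approx(np.exp(beta_hat))

    def test_parameter_recovery_single_seed(self):
        times, events, cov = _cox_sim(500, beta=1.0, seed=15)
        model = cox_fit(times, events, cov)
        assert model.converged
        assert 0.8 <= model.table.loc["z", "beta"] <= 1.2

    def test_null_covariate_beta_near_zero(self):
        betas = []
        for seed in range(30):
            times, events, cov = _cox_sim(200, beta=0.0, seed=100 + seed)
            model = cox_fit(times, events, cov)
            betas.append(model.table.loc["z", "beta"])
        assert abs(np.median(betas)) < 0.1

    def test_matches_lifelines_without_ties(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(16)
        n = 120
        df = pd.DataFrame(
            {
                "z": rng.normal(size=n),
                "w": rng.integers(0, 2, size=n).astype(float),
            }
        )
        t_event = rng.exponential(1.0 / np.exp(0.8 * df["z"] - 0.5 * df["w"]))
        c = rng.exponential(3.0, size=n)
        times = np.minimum(t_event, c)  # continuous: no ties, Breslow == Efron
        events = (t_event <= c).astype(int)
        mine = cox_fit(times, events, df)
        ldf = df.assign(T=times, E=events)
        cph = lifelines.CoxPHFitter().fit(ldf, "T", "E")
        np.testing.assert_allclose(
            mine.table["beta"], cph.params_[["z", "w"]], rtol=1e-4
        )
        np.testing.assert_allclose(
            mine.table["se"], cph.standard_errors_[["z", "w"]], rtol=1e-3
        )

    def test_categorical_dummy_encoding_reference_level(self):
        rng = np.random.default_rng(17)
        n = 100
        stage = rng.choice(["I", "II", "III"], size=n)
        times = rng.exponential(1.0 / np.exp((stage == "III") * 1.0))
        events = np.ones(n, int)
        model = cox_fit(times, events, pd.DataFrame({"stage": stage}),
                        reference_levels={"stage": "I"})
        assert set(model.table.index) == {"stage[II vs I]", "stage[III vs I]"}
        assert model.table.loc["stage[III vs I]", "beta"] > 0.3

    def test_univariate_sweep_mode(self):
        times, events, cov = _cox_sim(150, beta=0.8, seed=18)
        cov["noise"] = np.random.default_rng(19).normal(size=len(cov))
        models = cox_fit(times, events, cov, mode="univariate")
        assert set(models) == {"z", "noise"}
        assert models["z"].table.shape[0] == 1

    def test_separation_flagged_not_estimated(self):
        # perfectly separating covariate: monotone likelihood
        times = np.arange(1.0, 11.0)
        events = np.ones(10, int)
        x = (times > 5).astype(float)  # all late deaths have x=1
        model = cox_fit(times, events, pd.DataFrame({"x": x}))
        assert not model.converged
        assert model.table is None

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


class TestChiSquare:
    def test_perfect_association_2x2(self):
        stat, df, p = chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert df == 1

    def test_independence_gives_zero(self):
        stat, df, p = chi_square([[10, 20], [20, 40]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_df_3x4(self):
        table = np.ones((3, 4)) * 5
        _, df, _ = chi_square(table)
        assert df == 6

    def test_zero_expected_advises_merge(self):
        with pytest.raises(ValueError, match="merge"):
            chi_square([[0, 0], [5, 5]])


class TestSpearman:
    def _matrix(self, rows, samples):
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))], columns=samples
        )

    def test_monotone_pairs(self):
        samples = [f"s{i}" for i in range(6)]
        target = pd.Series([1.0, 2, 3, 4, 5, 6], index=samples)
        mrna = self._matrix(
            [[2, 4, 6, 8, 10, 12], [12, 10, 8, 6, 4, 2]], samples
        )
        res = spearman_top_k(target, mrna, k=2).set_index("gene")
        assert res.loc["g0", "rho"] == pytest.approx(1.0)
        assert res.loc["g1", "rho"] == pytest.approx(-1.0)

    def test_tie_handling_matches_scipy(self):
        samples = [f"s{i}" for i in range(6)]
        target = pd.Series([1.0, 2, 2, 3, 4, 5], index=samples)
        gene = [3.0, 1, 4, 4, 5, 9]
        res = spearman_top_k(target, self._matrix([gene], samples), k=1)
        rho_ref, p_ref = stats.spearmanr(target, gene)
        assert res.iloc[0]["rho"] == pytest.approx(rho_ref)
        assert res.iloc[0]["p"] == pytest.approx(p_ref)

    def test_zero_variance_genes_skipped_and_k_capped(self, caplog):
        samples = [f"s{i}" for i in range(5)]
        target = pd.Series(np.arange(5.0), index=samples)
        mrna = self._matrix([[1, 2, 3, 4, 5], [2, 2, 2, 2, 2]], samples)
        res = spearman_top_k(target, mrna, k=10)
        assert list(res["gene"]) == ["g0"]

    def test_needs_four_shared_samples(self):
        samples = ["a", "b", "c"]
        with pytest.raises(ValueError, match="4 shared"):
            spearman_top_k(
                pd.Series([1.0, 2, 3], index=samples),
                self._matrix([[1, 2, 3]], samples),
            )

    def test_ranked_by_absolute_rho(self):
        rng = np.random.default_rng(20)
        samples = [f"s{i}" for i in range(20)]
        target = pd.Series(rng.normal(size=20), index=samples)
        mrna = self._matrix(rng.normal(size=(30, 20)), samples)
        res = spearman_top_k(target, mrna, k=30)
        assert (np.diff(res["rho"].abs()) <= 1e-12).all()
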