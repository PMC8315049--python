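import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cartisec as cs
from cartisec.data_model import CANONICAL_CONTRASTS, ContrastSpec, Treatment
from cartisec.diffstats import (
    EBHyperparams,
    bh_adjust,
    fit_eb_hyperparams,
    heatmap_order,
    moderated_t_test,
    pca,
    per_animal_log2fc,
)
from cartisec.preprocess import impute_half_min, sum_over_timepoints, zscore

C_VS_N = CANONICAL_CONTRASTS[0]


def sample_scaled_f_variances(rng, d0, s0_sq, d_g, size):
    """Variances from the moderated-t generative model:
    true sg^2 ~ s0^2 * d0 / chi2(d0), observed s^2 ~ sg^2 * chi2(d_g)/d_g."""
    sg2 = s0_sq * d0 / rng.chisquare(d0, size)
    return sg2 * rng.chisquare(d_g, size) / d_g


class TestLog2FoldChanges:
    def test_identical_columns_give_zero(self, processed):
        summed = processed["summed"].copy()
        for a in ("A1", "A2", "A3"):
            summed[(a, "C")] = summed[(a, "N")]
        fc = per_animal_log2fc(summed, C_VS_N)
        assert np.allclose(fc.to_numpy(), 0.0)

    def test_doubling_gives_unit_fold_change(self, processed):
        summed = processed["summed"].copy()
        for a in ("A1", "A2", "A3"):
            summed[(a, "C")] = summed[(a, "N")] + 1.0  # 2x on raw scale
        fc = per_animal_log2fc(summed, C_VS_N)
        assert np.allclose(fc.to_numpy(), 1.0)

    def test_antisymmetry(self, processed):
        summed = processed["summed"]
        reverse = ContrastSpec(Treatment.N, Treatment.C)
        fc = per_animal_log2fc(summed, C_VS_N)
        fc_rev = per_animal_log2fc(summed, reverse)
        np.testing.assert_allclose(fc.to_numpy(), -fc_rev.to_numpy())


class TestHyperparameterFit:
    def test_parameter_recovery_from_generative_model(self):
        d0_est, s0_est = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s2 = sample_scaled_f_variances(rng, d0=4.0, s0_sq=0.09, d_g=2.0, size=5000)
            h = fit_eb_hyperparams(s2, d_g=2.0)
            d0_est.append(h.d0)
            s0_est.append(h.s0_sq)
        assert abs(np.mean(d0_est) - 4.0) < 1.0
        assert abs(np.mean(s0_est) - 0.09) < 0.01

    def test_identical_variances_give_complete_shrinkage(self):
        h = fit_eb_hyperparams(np.full(100, 0.25), d_g=2.0)
        assert np.isinf(h.d0)
        assert h.s0_sq > 0

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        s2 = sample_scaled_f_variances(rng, 4.0, 0.09, 2.0, 2000)
        h1 = fit_eb_hyperparams(s2, 2.0)
        h2 = fit_eb_hyperparams(2.0 * s2, 2.0)
        assert h2.d0 == pytest.approx(h1.d0, rel=1e-9)
        assert h2.s0_sq == pytest.approx(2.0 * h1.s0_sq, rel=1e-9)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(cs.ValidationError):
            fit_eb_hyperparams(np.zeros(10), 2.0)

    def test_matches_limma_squeezevar(self, tmp_path):
        """Independent oracle: the reference empirical-Bayes implementation
        in R reproduces our prior fit and moderated statistics."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript is required for the cross-check")
        rng = np.random.default_rng(42)
        signal = rng.choice([0.0, 1.0], 200, p=[0.7, 0.3])
        fc = rng.normal(0.2, 0.5, (200, 3)) * signal[:, None]
        fc = fc + rng.normal(0, 0.3, (200, 3))
        np.savetxt(tmp_path / "fc.tsv", fc, delimiter="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            fc <- as.matrix(read.table("fc.tsv", sep="\\t"))
            fit <- lmFit(fc, design = matrix(1, ncol(fc), 1))
            eb <- eBayes(fit)
            out <- data.frame(d0 = eb$df.prior, s0 = eb$s2.prior,
                              t = eb$t[, 1], p = eb$p.value[, 1])
            write.table(format(out, digits = 12), "ref.tsv",
                        sep = "\\t", row.names = FALSE, quote = FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", "check.R"], cwd=tmp_path, check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        s2 = fc.var(axis=1, ddof=1)
        h = fit_eb_hyperparams(s2, d_g=2.0)
        assert h.d0 == pytest.approx(ref["d0"][0], rel=1e-8)
        assert h.s0_sq == pytest.approx(ref["s0"][0], rel=1e-8)
        for i in range(len(fc)):
            t_mod, _, p = moderated_t_test(fc[i], s2[i], h)
            assert t_mod == pytest.approx(ref["t"][i], rel=1e-6)
            assert p == pytest.approx(ref["p"][i], rel=1e-6)


class TestModeratedT:
    def test_worked_example(self):
        # s~2 = (4*0.09 + 2*0.04) / 6 = 0.07333...; t = 1 / sqrt(s~2/3)
        h = EBHyperparams(d0=4.0, s0_sq=0.09, n_proteins_used=100)
        t_mod, df_total, p = moderated_t_test([1.0, 1.2, 0.8], 0.04, h)
        s_post = (4 * 0.09 + 2 * 0.04) / 6
        assert s_post == pytest.approx(0.0733333333, rel=1e-8)
        assert t_mod == pytest.approx(1.0 / np.sqrt(s_post / 3), rel=1e-10)
        assert t_mod == pytest.approx(6.396, abs=5e-4)
        assert df_total == 6
        assert p == pytest.approx(2 * stats.t.sf(6.39602, 6), rel=1e-4)

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        """d0 = 0 reduces exactly to the one-sample t on the ratios."""
        rng = np.random.default_rng(0)
        h = EBHyperparams(d0=0.0, s0_sq=1.0, n_proteins_used=10)
        for _ in range(1000):
            fc = rng.normal(0, 1, 3)
            s2 = fc.var(ddof=1)
            t_mod, df_total, p = moderated_t_test(fc, s2, h)
            t_ref, p_ref = stats.ttest_1samp(fc, 0.0)
            assert abs(t_mod - t_ref) < 1e-10
            assert abs(p - p_ref) < 1e-10
            assert df_total == 2

    def test_zero_mean_gives_unit_p(self):
        h = EBHyperparams(d0=4.0, s0_sq=0.09, n_proteins_used=10)
        t_mod, _, p = moderated_t_test([-1.0, 0.0, 1.0], 1.0, h)
        assert t_mod == 0.0
        assert p == 1.0

    def test_complete_shrinkage_uses_normal_reference(self):
        h = EBHyperparams(d0=np.inf, s0_sq=0.09, n_proteins_used=10)
        t_mod, df_total, p = moderated_t_test([0.5, 0.5, 0.5], 0.0, h)
        assert np.isinf(df_total)
        assert p == pytest.approx(2 * stats.norm.sf(abs(t_mod)), rel=1e-12)

    def test_shrinkage_brackets_variances(self):
        rng = np.random.default_rng(1)
        h = EBHyperparams(d0=3.0, s0_sq=0.09, n_proteins_used=10)
        for _ in range(200):
            s2 = float(rng.gamma(2.0, 0.1))
            s_post = (h.d0 * h.s0_sq + 2 * s2) / (h.d0 + 2)
            assert min(s2, h.s0_sq) - 1e-15 <= s_post <= max(s2, h.s0_sq) + 1e-15

    def test_p_monotone_in_statistic_magnitude(self):
        h = EBHyperparams(d0=4.0, s0_sq=0.09, n_proteins_used=10)
        results = [
            moderated_t_test([m, m, m], 0.0, h) for m in (0.1, 0.3, 0.6, 1.2)
        ]
        t_values = [abs(r[0]) for r in results]
        p_values = [r[2] for r in results]
        assert t_values == sorted(t_values)
        assert p_values == sorted(p_values, reverse=True)


class TestBHAdjustment:
    def test_monotone_chain_collapses(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(200)
        perm = rng.permutation(200)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(5):
            p = rng.random(137)
            mine = bh_adjust(p)
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(mine, ref, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(cs.ValidationError):
            bh_adjust([0.5, 1.5])


class TestRunContrasts:
    def test_swapping_flips_direction_keeps_p(self, processed):
        summed = processed["summed"]
        fwd = cs.run_contrasts(summed, [C_VS_N])
        rev = cs.run_contrasts(
            summed, [ContrastSpec(Treatment.N, Treatment.C)]
        )
        for a, b in zip(fwd, rev):
            assert a.mean_log2fc == pytest.approx(-b.mean_log2fc)
            assert a.p == pytest.approx(b.p, rel=1e-12)
            if abs(a.mean_log2fc) > 0:
                assert a.direction != b.direction

    def test_power_on_planted_group_iii(self):
        """Nearly all strongly induced proteins are detected (adjusted
        p < 0.05) in both cytokine contrasts."""
        hits, total = 0, 0
        for seed in (11, 12, 13):
            table, truth, _ = cs.simulate_dataset(
                cs.GeneratorConfig(seed=seed, residual_sd=0.3)
            )
            from cartisec.preprocess import filter_all_replicates, filter_min_fraction

            table = filter_min_fraction(filter_all_replicates(table))
            summed = sum_over_timepoints(impute_half_min(table))
            records = cs.run_contrasts(summed, list(CANONICAL_CONTRASTS[:2]))
            df = cs.records_to_frame(records)
            iii = set(
                truth.df.loc[truth.df["planted_class"] == "group_III", "protein"]
            )
            sig = df[(df["p_adj"] < 0.05) & df["protein"].isin(iii)]
            both = sig.groupby("protein").size() == 2
            hits += int(both.sum())
            total += len(iii)
        assert hits / total >= 0.95

    def test_missing_treatment_rejected(self, processed):
        summed = processed["summed"].copy()
        summed = summed.drop(columns=[("A1", "C")])
        with pytest.raises((cs.ValidationError, KeyError)):
            cs.run_contrasts(summed, [C_VS_N])


class TestPCA:
    def test_perfectly_correlated_variables(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        X = pd.DataFrame({"v1": x, "v2": 2 * x + 1})
        res = pca(X)
        assert res.var_explained[0] == pytest.approx(100.0)

    def test_variance_sums_to_100(self, processed):
        from cartisec.pipeline import _pca_on_log2

        res = _pca_on_log2(processed["log2"])
        assert res.var_explained.sum() == pytest.approx(100.0, abs=1e-6)
        # score columns are mutually orthogonal
        S = res.scores.to_numpy()
        G = S.T @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_matches_correlation_eigendecomposition(self):
        """Brute-force oracle: eigenvalues of the correlation matrix."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(0, 1, (10, 10)))
        res = pca(X)
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(corr))[::-1]
        mine = res.var_explained / 100 * eig.sum()
        np.testing.assert_allclose(mine[: len(eig)], eig[: X.shape[0] - 1], atol=1e-8)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (25, 12))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        res = pca(pd.DataFrame(X))
        ref = SkPCA(n_components=5).fit(Z)
        np.testing.assert_allclose(
            res.var_explained[:5] / 100,
            ref.explained_variance_ratio_,
            rtol=1e-10,
        )
        scores_ref = ref.transform(Z)
        for k in range(5):  # equality up to component sign
            a, b = res.scores.to_numpy()[:, k], scores_ref[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_zero_variance_variable_rejected(self):
        X = pd.DataFrame({"v1": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(cs.ValidationError, match="flat"):
            pca(X)


class TestHeatmapOrder:
    def test_identical_rows_are_adjacent(self):
        rng = np.random.default_rng(5)
        M = pd.DataFrame(rng.normal(0, 1, (8, 6)), index=[f"p{i}" for i in range(8)])
        M.loc["p7"] = M.loc["p0"]
        order, _ = heatmap_order(M)
        assert abs(order.index("p0") - order.index("p7")) == 1

    def test_order_is_permutation(self, processed):
        summed = processed["summed"]
        six = summed.loc[:, summed.columns.get_level_values("treatment").isin(
            ["N", "C", "IC", "D", "CD", "ICD"]
        )]
        z = zscore(six, axis="rows")
        order, _ = heatmap_order(z)
        assert sorted(order) == sorted(str(p) for p in summed.index)

    def test_three_cut_recovers_planted_classes(self, processed):
        """The dendrogram's 3-cut aligns with the planted response classes
        (adjusted Rand index) among clearly affected proteins."""
        from scipy.cluster.hierarchy import fcluster
        from sklearn.metrics import adjusted_rand_score

        truth = processed["truth"]
        summed = processed["summed"]
        classes = truth.class_of()
        affected = classes[classes != "null"].index
        affected = [p for p in affected if p in summed.index]
        six = summed.loc[
            affected,
            summed.columns.get_level_values("treatment").isin(
                ["N", "C", "IC", "D", "CD", "ICD"]
            ),
        ]
        z = zscore(six, axis="rows")
        _, linkage = heatmap_order(z)
        cut = fcluster(linkage, t=3, criterion="maxclust")
        ari = adjusted_rand_score(classes.loc[affected], cut)
        assert ari > 0.8
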