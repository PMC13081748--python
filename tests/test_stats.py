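import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import stats as sps

import silacflux.stats as st
from silacflux.stats import ContrastSpec, SqueezeResult


def two_group_matrix(values_by_group, prefix="r"):
    """Protein x run matrix + run->group map from {group: {protein: [values]}}."""
    cols = {}
    run_groups = {}
    for g, (gname, rows) in enumerate(values_by_group.items()):
        n = max(len(v) for v in rows.values())
        for j in range(n):
            run = f"{prefix}{g}_{j}"
            run_groups[run] = gname
            cols[run] = {p: (v[j] if j < len(v) else np.nan) for p, v in rows.items()}
    return pd.DataFrame(cols), run_groups


class TestLog2AndCenter:
    def test_column_median_becomes_zero(self):
        mat = pd.DataFrame({"r1": [2.0, 8.0, 32.0]}, index=list("ABC"))
        out = st.log2_and_center(mat, center=True)
        np.testing.assert_allclose(out["r1"], [-2.0, 0.0, 2.0])

    def test_no_centering_is_pure_log2(self):
        mat = pd.DataFrame({"r1": [2.0, 8.0]}, index=list("AB"))
        out = st.log2_and_center(mat, center=False)
        np.testing.assert_allclose(out["r1"], [1.0, 3.0])

    def test_missing_cells_stay_missing(self):
        mat = pd.DataFrame({"r1": [4.0, np.nan], "r2": [np.nan, np.nan]}, index=list("AB"))
        out = st.log2_and_center(mat, center=True)
        assert np.isnan(out.at["B", "r1"]) and out["r2"].isna().all()
        assert out.at["A", "r1"] == 0.0

    def test_nonpositive_value_names_cell(self):
        mat = pd.DataFrame({"runX": [1.0, -3.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="B.*runX"):
            st.log2_and_center(mat)


class TestFilterMinObs:
    def test_complete_protein_retained_incomplete_dropped(self):
        mat, rg = two_group_matrix({
            "g1": {"A": [1, 1, 1], "B": [1, 1, np.nan]},
            "g2": {"A": [2, 2, 2], "B": [2, 2, 2]},
        })
        kept, dropped = st.filter_min_obs(mat, rg, min_per_group=3)
        assert list(kept.index) == ["A"] and dropped == ["B"]

    def test_relaxed_threshold_keeps_everything(self):
        mat, rg = two_group_matrix({
            "g1": {"A": [1, 1, 1], "B": [1, np.nan, np.nan]},
            "g2": {"A": [2, 2, 2], "B": [2, 2, 2]},
        })
        kept, dropped = st.filter_min_obs(mat, rg, min_per_group=1)
        assert len(kept) == 2 and dropped == []

    def test_group_smaller_than_threshold_is_config_error(self):
        mat, rg = two_group_matrix({"g1": {"A": [1, 1]}, "g2": {"A": [2, 2, 2]}})
        with pytest.raises(ValueError, match="g1"):
            st.filter_min_obs(mat, rg, min_per_group=3)

    def test_groups_argument_restricts_requirement(self):
        mat, rg = two_group_matrix({
            "g1": {"A": [1, 1, 1]},
            "g2": {"A": [np.nan, np.nan, np.nan]},
        })
        kept, _ = st.filter_min_obs(mat, rg, min_per_group=3, groups=["g1"])
        assert list(kept.index) == ["A"]


class TestFitGroupModel:
    def test_no_within_group_variance(self):
        mat, rg = two_group_matrix({"g1": {"A": [1, 1, 1]}, "g2": {"A": [2, 2, 2]}})
        fit = st.fit_group_model(mat, rg)
        assert fit.means.loc["A"].tolist() == [1.0, 2.0]
        assert fit.s2["A"] == 0.0 and fit.df["A"] == 4

    def test_known_rss(self):
        mat, rg = two_group_matrix({"g1": {"A": [0, 2]}, "g2": {"A": [4, 6]}})
        fit = st.fit_group_model(mat, rg)
        assert fit.means.loc["A"].tolist() == [1.0, 5.0]
        assert fit.s2["A"] == pytest.approx(2.0)  # RSS=4 over df=2
        assert fit.df["A"] == 2

    def test_unbalanced_df_counts(self):
        mat, rg = two_group_matrix({"g1": {"A": [1, 2, 3]}, "g2": {"A": [4, 5, np.nan]}})
        fit = st.fit_group_model(mat, rg)
        assert fit.df["A"] == 3  # 5 obs - 2 groups

    def test_matches_ols_per_protein(self):
        """Cell means and s2 agree with an explicit per-protein OLS fit."""
        rng = np.random.default_rng(0)
        mat, rg = two_group_matrix({
            "g1": {f"P{i}": rng.normal(0, 1, 3).tolist() for i in range(5)},
            "g2": {f"P{i}": rng.normal(1, 1, 3).tolist() for i in range(5)},
            "g3": {f"P{i}": rng.normal(2, 1, 3).tolist() for i in range(5)},
        })
        fit = st.fit_group_model(mat, rg)
        groups = np.array([rg[c] for c in mat.columns])
        for p in mat.index:
            y = mat.loc[p].to_numpy()
            X = np.column_stack([(groups == g).astype(float) for g in fit.groups])
            beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            np.testing.assert_allclose(fit.means.loc[p], beta, rtol=1e-10)
            assert fit.s2[p] == pytest.approx(float(res[0]) / (len(y) - 3), rel=1e-10)


class TestSqueezeVariances:
    def test_identical_variances_unchanged(self):
        s2 = pd.Series([0.3] * 20)
        df = pd.Series([4.0] * 20)
        sq = st.squeeze_variances(s2, df, None, trend=False, robust=False)
        assert np.isinf(sq.df_prior)
        np.testing.assert_allclose(sq.s2_post, 0.3, rtol=1e-12)

    def test_identical_variances_unchanged_with_flags(self):
        s2 = pd.Series([0.3] * 20)
        df = pd.Series([4.0] * 20)
        amean = pd.Series(np.linspace(8, 12, 20))
        sq = st.squeeze_variances(s2, df, amean, trend=True, robust=True)
        np.testing.assert_allclose(sq.s2_post, 0.3, rtol=1e-12)

    def test_infinite_prior_limit_formula(self):
        """d0 -> inf makes s2_post = s0^2 regardless of individual s2."""
        rng = np.random.default_rng(1)
        # homoscedastic data: observed spread is pure sampling noise
        s2 = pd.Series(0.2 * sps.chi2.rvs(4, size=400, random_state=rng) / 4)
        df = pd.Series([4.0] * 400)
        sq = st.squeeze_variances(s2, df, None, trend=False, robust=False)
        if np.isinf(sq.df_prior):
            assert sq.s2_post.nunique() == 1
        else:  # moments may resolve a large finite d0; shrinkage must be strong
            assert sq.df_prior > 20

    def test_parameter_recovery_from_hierarchical_model(self):
        """Method-of-moments recovers the generating (d0, s0^2)."""
        d0_true, s0_true, df = 4.0, 0.05, 4
        rng = np.random.default_rng(7)
        d0s, s0s = [], []
        for _ in range(100):
            sigma2 = d0_true * s0_true / sps.chi2.rvs(d0_true, size=200, random_state=rng)
            s2 = sigma2 * sps.chi2.rvs(df, size=200, random_state=rng) / df
            sq = st.squeeze_variances(
                pd.Series(s2), pd.Series([float(df)] * 200), None, trend=False, robust=False
            )
            d0s.append(sq.df_prior)
            s0s.append(sq.s2_prior.iloc[0])
        assert abs(np.median(d0s) - d0_true) / d0_true < 0.25
        assert abs(np.median(s0s) - s0_true) / s0_true < 0.25

    def test_all_zero_variances_skips_moderation(self):
        s2 = pd.Series([0.0] * 10)
        df = pd.Series([4.0] * 10)
        with pytest.warns(UserWarning, match="skipped"):
            sq = st.squeeze_variances(s2, df, None)
        assert sq.moderation_skipped
        np.testing.assert_allclose(sq.s2_post, 0.0)

    def test_robust_resists_variance_outliers(self):
        rng = np.random.default_rng(3)
        d0_true, s0_true, df = 6.0, 0.1, 4
        sigma2 = d0_true * s0_true / sps.chi2.rvs(d0_true, size=300, random_state=rng)
        s2 = sigma2 * sps.chi2.rvs(df, size=300, random_state=rng) / df
        s2[:6] *= 400.0  # hypervariable outliers
        series = pd.Series(s2)
        dfs = pd.Series([float(df)] * 300)
        plain = st.squeeze_variances(series, dfs, None, trend=False, robust=False)
        robust = st.squeeze_variances(series, dfs, None, trend=False, robust=True)
        assert abs(np.log(robust.s2_prior.iloc[-1] / s0_true)) < abs(
            np.log(plain.s2_prior.iloc[-1] / s0_true)
        )

    def test_trend_tracks_intensity_dependent_variance(self):
        rng = np.random.default_rng(4)
        n, df = 400, 4
        amean = pd.Series(np.linspace(6, 14, n))
        s0 = 0.4 * np.exp(-0.3 * (amean - 6))  # variance falls with intensity
        sigma2 = 8 * s0 / sps.chi2.rvs(8, size=n, random_state=rng)
        s2 = pd.Series(sigma2 * sps.chi2.rvs(df, size=n, random_state=rng) / df)
        sq = st.squeeze_variances(s2, pd.Series([float(df)] * n), amean, trend=True, robust=False)
        assert sq.trend_used
        low, high = sq.s2_prior.iloc[:50].median(), sq.s2_prior.iloc[-50:].median()
        assert low > 2 * high  # prior follows the decreasing trend


class TestModeratedT:
    def test_null_contrast(self):
        mat, rg = two_group_matrix({
            "g1": {"A": [1.0, 1.1, 0.9]}, "g2": {"A": [1.1, 0.9, 1.0]},
        })
        fit = st.fit_group_model(mat, rg)
        sq = SqueezeResult(df_prior=0.0, s2_prior=fit.s2 * np.nan, s2_post=fit.s2.copy())
        res = st.moderated_t(fit, sq, "g2", "g1")
        assert res["log2fc"]["A"] == pytest.approx(0.0)
        assert res["t_mod"]["A"] == pytest.approx(0.0)
        assert res["p"]["A"] == pytest.approx(1.0)

    def test_no_moderation_limit_is_ordinary_t(self):
        """df_prior = 0 reproduces the pooled two-sample t exactly."""
        rng = np.random.default_rng(12)
        mat, rg = two_group_matrix({
            "g1": {f"P{i}": rng.normal(0, 1, 3).tolist() for i in range(30)},
            "g2": {f"P{i}": rng.normal(0.5, 1, 3).tolist() for i in range(30)},
        })
        fit = st.fit_group_model(mat, rg)
        sq = SqueezeResult(df_prior=0.0, s2_prior=fit.s2 * np.nan, s2_post=fit.s2.copy())
        res = st.moderated_t(fit, sq, "g2", "g1")
        g1_cols = [c for c in mat.columns if rg[c] == "g1"]
        g2_cols = [c for c in mat.columns if rg[c] == "g2"]
        t_ref, p_ref = sps.ttest_ind(mat[g2_cols], mat[g1_cols], axis=1)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-9)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-9)

    def test_hand_computed_fixture(self):
        """Statistic matches a step-by-step computation against a 10-protein backdrop."""
        backdrop = {f"B{i}": [1.0, 1.0 + 0.05 * (i + 1), 1.0 - 0.05 * (i + 1)] for i in range(9)}
        g1 = dict(backdrop, A=[1.0, 1.2, 0.8])
        g2 = {k: [v_ + 1.0 for v_ in v] for k, v in backdrop.items()}
        g2["A"] = [2.0, 2.2, 1.8]
        mat, rg = two_group_matrix({"g1": g1, "g2": g2})
        fit = st.fit_group_model(mat, rg)
        sq = st.squeeze_variances(fit.s2, fit.df, None, trend=False, robust=False)
        res = st.moderated_t(fit, sq, "g2", "g1")
        # independent recomputation of the same quantities
        s2_a = float(np.var([1.0, 1.2, 0.8], ddof=1) + np.var([2.0, 2.2, 1.8], ddof=1)) / 2
        d0, s0 = sq.df_prior, sq.s2_prior["A"]
        s2_post = (d0 * s0 + 4 * s2_a) / (d0 + 4) if np.isfinite(d0) else s0
        t_expected = 1.0 / np.sqrt(s2_post * (2 / 3))
        df_tot = 4 + d0
        p_expected = (
            2 * sps.t.sf(abs(t_expected), df_tot)
            if np.isfinite(d0)
            else 2 * sps.norm.sf(abs(t_expected))
        )
        assert res["log2fc"]["A"] == pytest.approx(1.0, rel=1e-12)
        assert res["t_mod"]["A"] == pytest.approx(t_expected, rel=1e-10)
        assert res["p"]["A"] == pytest.approx(p_expected, rel=1e-10)

    def test_unknown_group_rejected(self):
        mat, rg = two_group_matrix({"g1": {"A": [1, 2, 3]}, "g2": {"A": [1, 2, 3]}})
        fit = st.fit_group_model(mat, rg)
        sq = SqueezeResult(df_prior=0.0, s2_prior=fit.s2, s2_post=fit.s2)
        with pytest.raises(ValueError, match="g9"):
            st.moderated_t(fit, sq, "g9", "g1")


class TestModeratedF:
    def test_equal_group_means_give_zero_F(self):
        mat, rg = two_group_matrix({
            "g1": {"A": [1.0, 1.2, 0.8]}, "g2": {"A": [0.8, 1.0, 1.2]},
            "g3": {"A": [1.2, 0.8, 1.0]},
        })
        fit = st.fit_group_model(mat, rg)
        sq = SqueezeResult(df_prior=0.0, s2_prior=fit.s2 * np.nan, s2_post=fit.s2.copy())
        res = st.moderated_F(fit, sq)
        assert res["F"]["A"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_F"]["A"] == pytest.approx(1.0)

    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(8)
        mat, rg = two_group_matrix({
            "g1": {f"P{i}": rng.normal(0, 1, 3).tolist() for i in range(20)},
            "g2": {f"P{i}": rng.normal(1, 1, 3).tolist() for i in range(20)},
        })
        fit = st.fit_group_model(mat, rg)
        sq = st.squeeze_variances(fit.s2, fit.df, None, trend=False, robust=False)
        t_res = st.moderated_t(fit, sq, "g2", "g1")
        f_res = st.moderated_F(fit, sq)
        np.testing.assert_allclose(f_res["F"], t_res["t_mod"] ** 2, rtol=1e-9)
        np.testing.assert_allclose(f_res["p_F"], t_res["p"], rtol=1e-9)

    def test_three_group_hand_computation(self):
        mat, rg = two_group_matrix({
            "g1": {"A": [0.0, 0.2, -0.2]},
            "g2": {"A": [1.0, 1.2, 0.8]},
            "g3": {"A": [2.0, 2.2, 1.8]},
        })
        fit = st.fit_group_model(mat, rg)
        sq = SqueezeResult(df_prior=0.0, s2_prior=fit.s2 * np.nan, s2_post=fit.s2.copy())
        res = st.moderated_F(fit, sq)
        # between-group MS = 3*var of means*(3-1)/(3-1): direct formula
        means = np.array([0.0, 1.0, 2.0])
        between = 3 * np.sum((means - 1.0) ** 2) / 2
        s2 = fit.s2["A"]
        assert res["F"]["A"] == pytest.approx(between / s2, rel=1e-10)
        assert res["df1"]["A"] == 2 and res["df2"]["A"] == 6
        assert res["p_F"]["A"] == pytest.approx(sps.f.sf(between / s2, 2, 6), rel=1e-10)


class TestBHAdjust:
    def test_single_p(self):
        assert st.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_ladder(self):
        np.testing.assert_allclose(
            st.bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.5])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st_.lists(st_.floats(0, 1), min_size=1, max_size=40))
    def test_agrees_with_definition(self, pvals):
        """Property: matches adj_p(i) = min_{p(j)>=p(i)} min(1, m p(j)/rank(j))."""
        got = st.bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        ranked = np.array(pvals)[order]
        brute_sorted = np.minimum(1.0, m * ranked / np.arange(1, m + 1))
        brute_sorted = np.minimum.accumulate(brute_sorted[::-1])[::-1]
        brute = np.empty(m)
        brute[order] = brute_sorted
        np.testing.assert_allclose(got, brute, atol=1e-12)
        assert np.all(got >= np.asarray(pvals) - 1e-15)  # adj_p >= p


class TestClassifyTurnover:
    @pytest.mark.parametrize(
        "channel,mode,fc,adj,expected",
        [
            ("light", "turnover", -1.2, 0.01, "degraded"),
            ("heavy", "turnover", 0.8, 0.049, "synthesized"),
            ("light", "turnover", -1.2, 0.05, "not_significant"),  # strict threshold
            ("light", "turnover", 1.2, 0.01, "not_significant"),   # wrong sign
            ("heavy", "turnover", -0.8, 0.01, "not_significant"),
            ("light", "accumulation", 0.9, 0.02, "accumulated"),
            ("light", "accumulation", -0.9, 0.02, "not_significant"),
            ("light", "turnover", np.nan, np.nan, "not_tested"),
        ],
    )
    def test_rules(self, channel, mode, fc, adj, expected):
        res = pd.DataFrame({"log2fc": [fc], "adj_p": [adj]}, index=["A"])
        assert st.classify_turnover(res, channel, mode)["A"] == expected

    def test_invalid_channel_mode_combinations(self):
        res = pd.DataFrame({"log2fc": [1.0], "adj_p": [0.01]}, index=["A"])
        with pytest.raises(ValueError):
            st.classify_turnover(res, "heavy", "accumulation")
        with pytest.raises(ValueError):
            st.classify_turnover(res, "total", "turnover")


@pytest.fixture()
def fixture_matrix():
    rng = np.random.default_rng(321)
    n = 60
    sigma2 = 4 * 0.04 / sps.chi2.rvs(4, size=n, random_state=rng)
    mat = rng.normal(0, 1, (n, 6)) * np.sqrt(sigma2)[:, None] + 8
    mat[:8, 3:] += 0.8
    return pd.DataFrame(
        mat, index=[f"P{i}" for i in range(n)], columns=[f"s{j}" for j in range(6)]
    )


class TestLimmaParity:
    """The moderation chain is cross-checked against R limma on a fixture."""

    def test_matches_limma_ebayes(self, fixture_matrix, tmp_path):
        csv = tmp_path / "fix.csv"
        fixture_matrix.to_csv(csv)
        rscript = tmp_path / "oracle.R"
        rscript.write_text(textwrap.dedent("""
            suppressMessages(library(limma))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.csv(args[1], row.names=1))
            group <- factor(c("g1","g1","g1","g2","g2","g2"))
            design <- model.matrix(~0+group)
            fit <- lmFit(x, design)
            ct <- makeContrasts(groupg2-groupg1, levels=design)
            fit2 <- eBayes(contrasts.fit(fit, ct), trend=FALSE, robust=FALSE)
            out <- data.frame(t=fit2$t[,1], p=fit2$p.value[,1], F=fit2$F,
                              pF=fit2$F.p.value, s2post=fit2$s2.post,
                              d0=fit2$df.prior, s02=fit2$s2.prior)
            write.csv(out, args[2])
        """))
        out_csv = tmp_path / "limma.csv"
        subprocess.run(
            ["Rscript", str(rscript), str(csv), str(out_csv)],
            check=True, capture_output=True, timeout=300,
        )
        ref = pd.read_csv(out_csv, index_col=0)

        rg = {f"s{j}": ("g1" if j < 3 else "g2") for j in range(6)}
        fit = st.fit_group_model(fixture_matrix, rg)
        sq = st.squeeze_variances(fit.s2, fit.df, fit.amean, trend=False, robust=False)
        res = st.moderated_t(fit, sq, "g2", "g1")
        fres = st.moderated_F(fit, sq)

        assert sq.df_prior == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert sq.s2_prior.iloc[0] == pytest.approx(ref["s02"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(sq.s2_post, ref["s2post"], rtol=1e-6)
        np.testing.assert_allclose(res["t_mod"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(fres["F"], ref["F"], rtol=1e-6)
        np.testing.assert_allclose(fres["p_F"], ref["pF"], rtol=1e-6, atol=1e-12)


class TestRunContrasts:
    def test_standard_contrast_set_runs(self, noisy_run, full_design):
        import silacflux as sf

        truths, report = noisy_run
        m = sf.build_channel_matrices(report, full_design)
        specs = st.standard_contrasts(include_inhibitors=True)
        results = st.run_contrasts(
            {"heavy": m.heavy, "light": m.light, "total": m.total}, full_design, specs
        )
        assert set(results) == {s.name for s in specs}
        res = results["H72_vs_H24_light"]
        assert {"log2fc", "t_mod", "p", "adj_p", "F", "p_F", "call"} <= set(res.columns)
        tested = res["adj_p"].notna()
        assert (res.loc[tested, "adj_p"] >= res.loc[tested, "p"] - 1e-15).all()

    def test_alpha_monotonicity(self, noisy_run, full_design):
        import silacflux as sf

        truths, report = noisy_run
        m = sf.build_channel_matrices(report, full_design)
        specs = [ContrastSpec("deg", "light", "H72_none", "H24_none", "turnover")]
        mats = {"light": m.light}
        strict = st.run_contrasts(mats, full_design, specs, alpha=0.01)["deg"]
        loose = st.run_contrasts(mats, full_design, specs, alpha=0.05)["deg"]
        assert (strict["call"] == "degraded").sum() <= (loose["call"] == "degraded").sum()

    def test_unknown_group_lists_valid_ones(self, noisy_run, full_design):
        import silacflux as sf

        truths, report = noisy_run
        m = sf.build_channel_matrices(report, full_design)
        specs = [ContrastSpec("bad", "light", "H96_none", "H24_none")]
        with pytest.raises(ValueError, match="H96_none"):
            st.run_contrasts({"light": m.light}, full_design, specs)
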