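"""Longitudinal statistics: normalization contracts, REML mixed model vs
OLS / nlme oracles, Tukey contrasts, bivariate fits, correlation matrix."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from redoxtrack.stats import (
    DesignError,
    ORGANOID_LEVEL,
    WELL_LEVEL,
    bivariate_fit,
    correlation_matrix,
    estimated_marginal_means,
    fit_lmm,
    fit_pooled,
    lsmeans_contrasts,
    normalize,
    simulate_normalized_series,
    simulate_raw_longitudinal,
)


def _toy_table():
    rows = []
    for oid, well, pre, post in [(1, "w1", 0.5, 0.6), (2, "w1", 0.3, 0.3),
                                 (3, "w2", 0.4, 0.5)]:
        rows.append({"organoid_id": oid, "well": well, "treatment": "control",
                     "time_h": 0.0, "mean_orr": pre, "area": 100.0})
        rows.append({"organoid_id": oid, "well": well, "treatment": "control",
                     "time_h": 48.0, "mean_orr": post, "area": 110.0})
    return pd.DataFrame(rows)


class TestNormalize:
    def test_organoid_level_ratio(self):
        out = normalize(_toy_table(), "mean_orr", ORGANOID_LEVEL)
        row = out.query("organoid_id == 1 and time_h == 48.0")
        assert row["Y"].iloc[0] == pytest.approx(0.6 / 0.5)
        pre = out.query("organoid_id == 1 and time_h == 0.0")
        assert pre["Y"].iloc[0] == pytest.approx(1.0)
        assert pre["pretreatment"].iloc[0]

    def test_well_level_ratio(self):
        out = normalize(_toy_table(), "mean_orr", WELL_LEVEL)
        # w1 pretreatment mean = 0.4
        row = out.query("organoid_id == 1 and time_h == 48.0")
        assert row["Y"].iloc[0] == pytest.approx(0.6 / 0.4)

    def test_missing_pretreatment_organoid_dropped(self, caplog):
        table = _toy_table()
        table = table[~((table["organoid_id"] == 2) & (table["time_h"] == 0.0))]
        with caplog.at_level("INFO", logger="redoxtrack.stats"):
            out = normalize(table, "mean_orr", ORGANOID_LEVEL)
        assert 2 not in set(out["organoid_id"])
        assert any("no pretreatment row" in r.message for r in caplog.records)

    def test_zero_denominator_dropped(self):
        table = _toy_table()
        table.loc[(table["organoid_id"] == 3) & (table["time_h"] == 0.0), "mean_orr"] = 0.0
        out = normalize(table, "mean_orr", ORGANOID_LEVEL)
        assert 3 not in set(out["organoid_id"])

    def test_idempotence(self):
        """Normalizing an already organoid-normalized series leaves it unchanged."""
        out1 = normalize(_toy_table(), "mean_orr", ORGANOID_LEVEL)
        relabeled = out1.rename(columns={"Y": "mean_orr"}).drop(columns="pretreatment")
        out2 = normalize(relabeled, "mean_orr", ORGANOID_LEVEL)
        assert np.allclose(out1["Y"], out2["Y"])


class TestFitLmm:
    def test_gls_equals_ols_without_heterogeneity(self):
        """With no random intercept and no autocorrelation in truth, fixed
        effects agree with the closed-form OLS solution."""
        rng = np.random.default_rng(4)
        df = simulate_normalized_series(rng, intercept_sd=0.0, rho=0.0, sigma=0.05)
        fit = fit_lmm(df)
        # OLS oracle: cell means of the saturated two-way layout
        post = df[~df["pretreatment"]]
        cell = post.groupby(["treatment", "time_h"])["Y"].mean()
        for g in fit.groups:
            for t in fit.times:
                assert fit.cell_mean(g, t) == pytest.approx(cell[(g, t)], abs=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        eff = {("treated", t): -0.2 for t in (12.0, 24.0, 36.0, 48.0)}
        rhos, sbs = [], []
        for _ in range(10):
            df = simulate_normalized_series(
                rng, n_per_group=25, effects=eff, intercept_sd=0.1, rho=0.5, sigma=0.05
            )
            fit = fit_lmm(df)
            rhos.append(fit.rho)
            sbs.append(np.sqrt(fit.sigma_b2))
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.1)
        assert np.mean(sbs) == pytest.approx(0.1, abs=0.02)

    def test_pooled_variance_exceeds_mixed_when_heterogeneous(self):
        rng = np.random.default_rng(2)
        df = simulate_normalized_series(rng, intercept_sd=0.15)
        assert fit_pooled(df).sigma2 >= fit_lmm(df).sigma2

    def test_mixed_detects_more_timepoints_than_pooled(self):
        """With organoid heterogeneity, organoid-level tracking flags the true
        effect at at least as many time points as the pooled analysis."""
        rng = np.random.default_rng(9)
        eff = {("treated", t): -0.12 for t in (12.0, 24.0, 36.0, 48.0)}
        wins = 0
        reps = 10
        for _ in range(reps):
            raw = simulate_raw_longitudinal(rng, effects=eff, intercept_sd=0.15)
            org = normalize(raw, "mean_orr", ORGANOID_LEVEL)
            pool = normalize(raw, "mean_orr", WELL_LEVEL)
            c_org = lsmeans_contrasts(fit_lmm(org[~org["pretreatment"]].assign(pretreatment=False)))
            c_pool = lsmeans_contrasts(fit_pooled(pool[~pool["pretreatment"]].assign(pretreatment=False)))
            n_org = int(c_org["significant"].sum())
            n_pool = int(c_pool["significant"].sum())
            wins += n_org >= n_pool
        assert wins >= 8

    def test_empty_cell_is_design_error(self):
        rng = np.random.default_rng(0)
        df = simulate_normalized_series(rng)
        df = df[~((df["treatment"] == "treated") & (df["time_h"] == 48.0))]
        with pytest.raises(DesignError, match="treated"):
            fit_lmm(df)

    def test_single_group_is_design_error(self):
        rng = np.random.default_rng(0)
        df = simulate_normalized_series(rng, groups=("control",))
        with pytest.raises(DesignError):
            fit_lmm(df)

    def test_agrees_with_nlme_reference(self, tmp_path):
        """Independent cross-check: fixed effects, variance components and
        AR(1) coefficient against R's nlme::lme on the same data."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the nlme cross-check")
        rng = np.random.default_rng(7)
        eff = {("treated", t): -0.15 for t in (24.0, 36.0, 48.0)}
        df = simulate_normalized_series(rng, effects=eff, n_per_group=12)
        fit = fit_lmm(df)
        csv = tmp_path / "data.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(nlme))
            d <- read.csv("{csv}")
            d$time <- factor(d$time_h)
            d$treatment <- factor(d$treatment, levels=c("control","treated"))
            m <- lme(Y ~ time*treatment, random=~1|organoid_id,
                     correlation=corAR1(form=~1|organoid_id), data=d, method="REML")
            cat(fixef(m), "\\n")
            vc <- VarCorr(m)
            cat(as.numeric(vc[1,1]), as.numeric(vc[2,1]), "\\n")
            cat(coef(m$modelStruct$corStruct, unconstrained=FALSE), "\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        r_fixef = np.array([float(v) for v in lines[0].split()])
        r_sb2, r_s2 = (float(v) for v in lines[1].split())
        r_rho = float(lines[2].split()[0])
        assert np.allclose(fit.beta.to_numpy(), r_fixef, atol=1e-4)
        assert fit.sigma_b2 == pytest.approx(r_sb2, rel=1e-3)
        assert fit.sigma2 == pytest.approx(r_s2, rel=1e-3)
        assert fit.rho == pytest.approx(r_rho, abs=1e-3)


class TestLsmeansContrasts:
    @pytest.fixture(scope="class")
    def five_group_fit(self):
        rng = np.random.default_rng(15)
        groups = ("control", "cyanide", "2DG", "cisplatin", "paclitaxel")
        df = simulate_normalized_series(rng, groups=groups, n_per_group=8)
        return fit_lmm(df)

    def test_ten_contrasts_per_time(self, five_group_fit):
        ct = lsmeans_contrasts(five_group_fit)
        assert all(len(g) == 10 for _, g in ct.groupby("time_h"))

    def test_adjusted_p_at_least_unadjusted(self, five_group_fit):
        ct = lsmeans_contrasts(five_group_fit)
        assert (ct["p_adjusted"] >= ct["p_unadjusted"] - 1e-12).all()

    def test_lsmeans_equal_cell_means_balanced(self):
        rng = np.random.default_rng(1)
        df = simulate_normalized_series(rng, intercept_sd=0.0, rho=0.0)
        fit = fit_lmm(df)
        emm = estimated_marginal_means(fit)
        cell = df[~df["pretreatment"]].groupby(["treatment", "time_h"])["Y"].mean()
        for _, row in emm.iterrows():
            assert row["emmean"] == pytest.approx(
                cell[(row["treatment"], row["time_h"])], abs=1e-6
            )

    def test_contrast_antisymmetry(self, five_group_fit):
        ct = lsmeans_contrasts(five_group_fit).set_index(["time_h", "group_a", "group_b"])
        fit = five_group_fit
        for (t, a, b), row in ct.iterrows():
            la = fit._emm_row(a, t) - fit._emm_row(b, t)
            lb = fit._emm_row(b, t) - fit._emm_row(a, t)
            assert np.allclose(la, -lb)


class TestBivariateAndCorrelation:
    def test_exact_line(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": 2 * np.arange(10.0)})
        slope, r, p = bivariate_fit(df, "x", "y")
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_variables_uncorrelated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
            _, r, _ = bivariate_fit(df, "x", "y")
            hits += abs(r) < 0.1
        assert hits >= 19

    def test_constant_x_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            bivariate_fit(df, "x", "y")

    def test_matrix_symmetric_unit_diagonal(self, mixed_phenotype_features):
        pre = mixed_phenotype_features.query("time_h == 0.0")
        r, sig = correlation_matrix(pre)
        arr = r.to_numpy(float)
        assert np.allclose(arr, arr.T, equal_nan=True)
        assert np.allclose(np.diag(arr)[np.isfinite(np.diag(arr))], 1.0)

    def test_duplicate_column_perfectly_correlated(self, mixed_phenotype_features):
        pre = mixed_phenotype_features.query("time_h == 0.0").copy()
        r, sig = correlation_matrix(pre, columns=["area", "convex_area"])
        assert r.loc["area", "convex_area"] > 0.9
        assert bool(sig.loc["area", "convex_area"])

    def test_constant_column_masked(self, caplog):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10),
                           "c": np.ones(10)})
        with caplog.at_level("INFO", logger="redoxtrack.stats"):
            r, sig = correlation_matrix(df, columns=["a", "b", "c"])
        assert np.isnan(r.loc["a", "c"])
        assert not sig.loc["a", "c"]
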