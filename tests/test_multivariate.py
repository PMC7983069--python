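"""PCA protocol: standardization, analytic eigenvector checks, projection,
coverage ellipses, top loadings, and phenotype separation on phantoms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from redoxtrack.multivariate import (
    EllipseSpec,
    biplot_scale,
    ellipse_95,
    fit_pca,
    point_in_ellipse,
    project,
    standardize_within_time,
    top_loadings,
)


def _table(rng, n=40, times=(0.0, 24.0), cols=("a", "b", "c")):
    rows = []
    for t in times:
        X = rng.normal(size=(n, len(cols))) * np.array([3.0, 1.0, 0.5])
        for i in range(n):
            rows.append({"organoid_id": i, "time_h": t,
                         **{c: X[i, j] for j, c in enumerate(cols)}})
    return pd.DataFrame(rows)


class TestStandardizeWithinTime:
    def test_zero_mean_unit_sd_per_time(self):
        rng = np.random.default_rng(0)
        table = _table(rng)
        std, keep = standardize_within_time(table, ["a", "b", "c"])
        for t, grp in std.groupby("time_h"):
            assert np.allclose(grp[keep].mean(), 0, atol=1e-12)
            assert np.allclose(grp[keep].std(ddof=0), 1, atol=1e-12)

    def test_single_timepoint_is_global_zscore(self):
        rng = np.random.default_rng(1)
        table = _table(rng, times=(0.0,))
        std, keep = standardize_within_time(table, ["a", "b", "c"])
        z = (table["a"] - table["a"].mean()) / table["a"].std(ddof=0)
        assert np.allclose(std["a"], z)

    def test_constant_column_dropped(self, caplog):
        rng = np.random.default_rng(2)
        table = _table(rng)
        table["c"] = 7.0
        with caplog.at_level("INFO", logger="redoxtrack.multivariate"):
            _, keep = standardize_within_time(table, ["a", "b", "c"])
        assert keep == ["a", "b"]


class TestFitPca:
    def test_two_variable_analytic_axes(self):
        """Independent variables with variance ratio 4:1: after z-scoring the
        correlation matrix is ~identity, so each PC explains ~half; on the
        raw scale PC1 aligns with the high-variance variable."""
        rng = np.random.default_rng(3)
        n = 4000
        raw = pd.DataFrame({"hi": 2 * rng.normal(size=n), "lo": rng.normal(size=n),
                            "time_h": 0.0, "organoid_id": np.arange(n)})
        std, keep = standardize_within_time(raw, ["hi", "lo"])
        model = fit_pca(std, keep)
        assert np.allclose(model.explained_variance_ratio[:2], [0.5, 0.5], atol=0.05)
        # raw-scale (unstandardized) PCA oracle: eigenvector of diag(4,1)
        cov = np.cov(raw[["hi", "lo"]].T)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        assert abs(lead[0]) > 0.99  # axis-aligned with the high-variance variable

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(5, 5))
        cov = A @ A.T + np.eye(5)
        X = rng.multivariate_normal(np.zeros(5), cov, size=600)
        df = pd.DataFrame(X, columns=list("abcde"))
        df["time_h"] = 0.0
        std, keep = standardize_within_time(df, list("abcde"))
        model = fit_pca(std, keep)
        corr = np.corrcoef(df[keep].to_numpy().T)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        for k in range(3):
            v = evecs[:, order[k]]
            cos = abs(v @ model.loadings.iloc[:, k].to_numpy())
            assert cos > 0.999

    def test_correlated_pair_parallel_loadings(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=500)
        df = pd.DataFrame({"a": base, "b": base * 1.0, "c": rng.normal(size=500),
                           "time_h": 0.0})
        std, keep = standardize_within_time(df, ["a", "b", "c"])
        model = fit_pca(std, keep)
        # restrict to informative components; the duplicated pair spans a
        # zero-variance direction whose loadings are arbitrary
        real = model.explained_variance_ratio > 1e-8
        la = model.loadings.loc["a"].to_numpy()[real]
        lb = model.loadings.loc["b"].to_numpy()[real]
        cos = la @ lb / (np.linalg.norm(la) * np.linalg.norm(lb))
        assert cos > 0.999

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        df = _table(rng, times=(0.0,))
        std, keep = standardize_within_time(df, ["a", "b", "c"])
        model = fit_pca(std, keep)
        L = model.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0], "time_h": 0.0,
                           "organoid_id": [0, 1]})
        with pytest.raises(ValueError, match="at least 3"):
            fit_pca(df, ["a", "b"])


class TestProject:
    def test_projecting_fit_data_reproduces_scores(self):
        rng = np.random.default_rng(7)
        df = _table(rng, times=(0.0,))
        std, keep = standardize_within_time(df, ["a", "b", "c"])
        model = fit_pca(std, keep)
        Zc = std[keep].to_numpy() - std[keep].to_numpy().mean(axis=0)
        fit_scores = Zc @ model.loadings.to_numpy()
        proj = project(model, std)
        centered_proj = proj[model.loadings.columns].to_numpy() - (
            std[keep].to_numpy().mean(axis=0) @ model.loadings.to_numpy()
        )
        assert np.allclose(centered_proj, fit_scores, atol=1e-10)

    def test_projection_linearity(self):
        rng = np.random.default_rng(8)
        df = _table(rng, times=(0.0,))
        std, keep = standardize_within_time(df, ["a", "b", "c"])
        model = fit_pca(std, keep)
        X = std.copy()
        Y = std.copy()
        Y[keep] = std[keep].to_numpy()[::-1]
        combo = std.copy()
        combo[keep] = 0.3 * X[keep].to_numpy() + 0.7 * Y[keep].to_numpy()
        pX = project(model, X)[model.loadings.columns].to_numpy()
        pY = project(model, Y)[model.loadings.columns].to_numpy()
        pC = project(model, combo)[model.loadings.columns].to_numpy()
        assert np.allclose(pC, 0.3 * pX + 0.7 * pY, atol=1e-10)

    def test_missing_variable_is_schema_error(self):
        rng = np.random.default_rng(9)
        df = _table(rng, times=(0.0,))
        std, keep = standardize_within_time(df, ["a", "b", "c"])
        model = fit_pca(std, keep)
        with pytest.raises(KeyError, match="missing"):
            project(model, std.drop(columns="b"))

    def test_phenotype_subpopulations_separate(self, mixed_phenotype_features):
        """Solid and hollow organoids form separated clusters in the
        pretreatment PC1-PC2 plane (silhouette > 0.2)."""
        from sklearn.metrics import silhouette_score

        pre = mixed_phenotype_features.query("time_h == 0.0").copy()
        std, keep = standardize_within_time(pre)
        model = fit_pca(std, keep)
        scores = project(model, std)
        pts = scores[["PC1", "PC2"]].to_numpy()
        labels = (pre["phenotype"] == "hollow").to_numpy()
        assert silhouette_score(pts, labels) > 0.2


class TestEllipse:
    def test_empirical_coverage_95(self):
        rng = np.random.default_rng(10)
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], size=10_000)
        df = pd.DataFrame(pts, columns=["PC1", "PC2"])
        df["group"] = "g"
        spec = ellipse_95(df, "g")
        frac = point_in_ellipse(spec, pts).mean()
        assert abs(frac - 0.95) <= 0.015

    def test_isotropic_axes_equal(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(20_000, 2))
        df = pd.DataFrame(pts, columns=["PC1", "PC2"])
        df["group"] = "g"
        spec = ellipse_95(df, "g")
        r1, r2 = spec.radii
        assert abs(r1 / r2 - 1) < 0.05

    def test_two_point_group_skipped(self):
        df = pd.DataFrame({"PC1": [0.0, 1.0], "PC2": [0.0, 1.0], "group": "g"})
        assert ellipse_95(df, "g") is None


class TestTopLoadings:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(12)
        cols = [f"v{i:02d}" for i in range(24)]
        df = pd.DataFrame(rng.normal(size=(60, 24)), columns=cols)
        df["time_h"] = 0.0
        std, keep = standardize_within_time(df, cols)
        return fit_pca(std, keep)

    def test_top_12_entries(self, model):
        top = top_loadings(model, 12)
        assert len(top) == 12
        assert set(top["kind"]) <= {"metabolic", "morphological"}

    def test_k_24_is_full_ranking(self, model):
        top = top_loadings(model, 24)
        assert len(top) == 24
        assert (np.diff(top["norm"]) <= 1e-12).all()

    def test_oversized_k_clipped(self, model):
        assert len(top_loadings(model, 99)) == 24

    def test_biplot_scale_positive(self, model):
        rng = np.random.default_rng(13)
        scores = pd.DataFrame(rng.normal(size=(10, 2)), columns=["PC1", "PC2"])
        assert biplot_scale(model, scores) > 0
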