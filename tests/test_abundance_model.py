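"""Correlation screens, partial correlations, GLM, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dielomix.abundance_model import (
    cross_validate,
    feature_mrna_correlations,
    feature_protein_partial_correlations,
    fit_glm,
    fit_protein_models,
    make_folds,
    partial_correlation,
)
from dielomix.mars import MarsRegressor


def _tp_frame(values, genes):
    return pd.DataFrame(
        values, index=genes, columns=["T1", "T2", "T3", "T4"]
    )


class TestFeatureMrnaCorrelations:
    def test_perfect_and_inverted(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        m = _tp_frame(rng.normal(size=(50, 4)), genes)
        feats = pd.DataFrame({"same": m["T1"], "neg": -m["T1"]}, index=genes)
        rho = feature_mrna_correlations(feats, m)
        assert rho.loc["same", "T1"] == pytest.approx(1.0)
        assert rho.loc["neg", "T1"] == pytest.approx(-1.0)

    def test_independent_feature_is_near_zero(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(1000)]
        m = _tp_frame(rng.normal(size=(1000, 4)), genes)
        feats = pd.DataFrame({"noise": rng.normal(size=1000)}, index=genes)
        rho = feature_mrna_correlations(feats, m)
        assert rho.abs().to_numpy().max() < 0.1

    def test_constant_feature_warns(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        m = _tp_frame(rng.normal(size=(30, 4)), genes)
        feats = pd.DataFrame({"flat": np.ones(30)}, index=genes)
        with pytest.warns(UserWarning, match="constant"):
            rho = feature_mrna_correlations(feats, m)
        assert rho.isna().all().all()


class TestPartialCorrelation:
    def test_formula_value(self):
        # construct x, y, z with pairwise Pearson r exactly 0.5 each
        cov = np.array([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(3)
        raw = rng.normal(size=(2000, 3)) @ L.T
        # enforce the exact sample correlation by whitening then recoloring
        raw -= raw.mean(0)
        emp = np.cov(raw.T)
        raw = raw @ np.linalg.inv(np.linalg.cholesky(emp)).T @ L.T
        x, y, z = raw.T
        got = partial_correlation(x, y, z, method="pearson")
        assert got == pytest.approx(1 / 3, abs=1e-9)

    def test_residual_correlation_oracle(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=300)
        x = 0.6 * z + rng.normal(size=300)
        y = -0.3 * z + 0.4 * x + rng.normal(size=300)
        got = partial_correlation(x, y, z, method="pearson")
        # oracle: correlation of OLS residuals of x|z and y|z
        rx = x - np.polyval(np.polyfit(z, x, 1), z)
        ry = y - np.polyval(np.polyfit(z, y, 1), z)
        assert got == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-10)

    def test_spearman_variant_matches_rank_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=200)
        x = np.exp(z) + rng.normal(size=200)
        y = z + rng.normal(size=200)
        got = partial_correlation(x, y, z, method="spearman")
        oracle = partial_correlation(
            stats.rankdata(x), stats.rankdata(y), stats.rankdata(z), method="pearson"
        )
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_collinear_inputs_error(self):
        z = np.arange(50, dtype=float)
        y = np.random.default_rng(6).normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(z, y, z)

    def test_feature_equal_to_protein_with_independent_mrna(self):
        rng = np.random.default_rng(7)
        p = rng.normal(size=500)
        z = rng.normal(size=500)
        got = partial_correlation(p, p + 1e-9 * rng.normal(size=500), z)
        assert got == pytest.approx(1.0, abs=1e-3)


class TestBootstrap:
    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(120)]
        m = _tp_frame(rng.normal(size=(120, 4)), genes)
        p = _tp_frame(rng.normal(size=(120, 4)), genes)
        feats = pd.DataFrame(
            {f"f{j}": rng.normal(size=120) for j in range(12)}, index=genes
        )
        res = feature_protein_partial_correlations(feats, m, p, n_boot=200, seed=0)
        pvals = res.p_partial.to_numpy().ravel()
        pvals = pvals[np.isfinite(pvals)]
        assert (pvals > 0).all() and (pvals <= 1).all()
        # under the null, small p should not be grossly enriched
        assert (pvals < 0.05).mean() < 0.15

    def test_planted_effect_is_significant(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(300)]
        mvals = rng.normal(size=(300, 4))
        f = rng.normal(size=300)
        pvals = mvals + f[:, None]
        m, p = _tp_frame(mvals, genes), _tp_frame(pvals, genes)
        feats = pd.DataFrame({"planted": f}, index=genes)
        res = feature_protein_partial_correlations(feats, m, p, n_boot=500, seed=1)
        assert (res.partial.loc["planted"] > 0.5).all()
        assert (res.p_partial.loc["planted"] < 0.01).all()


class TestGlm:
    def test_exact_linear_fit(self):
        x = np.linspace(0, 10, 50)
        df = pd.DataFrame({"x": x})
        fit = fit_glm(df, pd.Series(2 * x + 1))
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.rsquared == pytest.approx(1.0)

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=60)
        df = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_glm(df, pd.Series(x + rng.normal(0, 0.1, 60)))
        assert "x2" not in fit.params.index

    def test_null_r2_is_small(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=400)})
        fit = fit_glm(df, pd.Series(rng.normal(size=400)))
        assert fit.rsquared < 0.05


class TestCrossValidation:
    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"x": rng.normal(size=100)})
        y = pd.Series(X["x"] + 0.2 * rng.normal(size=100))
        r1, oof1 = cross_validate(MarsRegressor, X, y, folds=5, seed=3)
        r2, oof2 = cross_validate(MarsRegressor, X, y, folds=5, seed=3)
        assert r1 == r2
        np.testing.assert_array_equal(oof1, oof2)

    def test_pure_noise_does_not_generalize(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(200, 3)))
        y = pd.Series(rng.normal(size=200))
        r2, _ = cross_validate(MarsRegressor, X, y, folds=5, seed=0)
        assert r2 <= 0.1

    def test_strong_signal_generalizes(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"x": rng.uniform(0, 4, 300)})
        y = pd.Series(np.maximum(0, X["x"] - 2) + 0.01 * rng.normal(size=300))
        r2, _ = cross_validate(MarsRegressor, X, y, folds=10, seed=0)
        assert r2 >= 0.95

    def test_fold_assignment_stratified(self):
        y = np.arange(100, dtype=float)
        folds = make_folds(y, folds=10, seed=0)
        assert np.bincount(folds).min() >= 9
        with pytest.raises(ValueError):
            make_folds(y, folds=1)


class TestProteinModels:
    def test_resubstitution_beats_cv_and_residual_convention(self, small_bundle):
        from dielomix.seqfeatures import assemble_feature_table

        ft = assemble_feature_table(small_bundle.records, mrna=small_bundle.mrna)
        ev = fit_protein_models(
            ft, small_bundle.mrna, small_bundle.protein, folds=5, seed=0
        )
        for tp, model in ev.models.items():
            assert ev.r2_resub[tp] >= ev.r2_cv[tp] - 0.05
            # residual = predicted - observed
            X_genes = model.genes
            obs = small_bundle.protein.timepoint_means().loc[X_genes, tp]
            assert np.isfinite(model.residuals).all()
            assert model.residuals.index.equals(obs.index)
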