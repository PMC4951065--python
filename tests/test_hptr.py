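"""Residual-quantile HPTR calling, CSD balancing, BSR, classifiers."""

import numpy as np
import pandas as pd
import pytest

from dielomix.hptr import (
    balance_with_csd,
    balanced_success_rate,
    bsr_from_predictions,
    feature_distribution_tests,
    identify_hptr,
    train_hptr_classifiers,
)


def _residuals(n=1060, seed=0, n_models=4):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, n_models)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"T{i+1}" for i in range(n_models)],
    )


class TestIdentify:
    def test_gene_above_q95_in_three_models_is_hptr_plus(self):
        res = _residuals()
        res.loc["g0", ["T1", "T2", "T3"]] = 10.0
        out = identify_hptr(res)
        assert "g0" in out.hptr_plus

    def test_single_model_extreme_is_not_hptr(self):
        res = _residuals(seed=1)
        out = identify_hptr(res)
        single = out.n_models_flagged == 1
        assert not (set(res.index[single]) & out.hptr_genes)

    def test_tail_sizes_match_quantile_arithmetic(self):
        res = _residuals(n=1060, seed=2)
        out = identify_hptr(res)
        for tp in res.columns:
            n_hi = (res[tp] > out.thresholds.loc[tp, "q_high"]).sum()
            n_lo = (res[tp] < out.thresholds.loc[tp, "q_low"]).sum()
            assert 50 <= n_hi <= 53  # ~5% of 1060 per tail
            assert 50 <= n_lo <= 53

    def test_under_estimated_goes_to_minus_tail(self):
        res = _residuals(seed=3)
        res.loc["g1", :] = -10.0  # observed far above prediction
        out = identify_hptr(res)
        assert "g1" in out.hptr_minus

    def test_monotone_in_min_models(self):
        res = _residuals(n=400, seed=4)
        sets = [identify_hptr(res, min_models=m).hptr_genes for m in (2, 3, 4)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_min_models_validation(self):
        with pytest.raises(ValueError):
            identify_hptr(_residuals(n=50), min_models=9)

    def test_opposite_tail_tie_excluded(self):
        res = _residuals(n=300, seed=5)
        res.loc["g2", ["T1", "T2"]] = 10.0
        res.loc["g2", ["T3", "T4"]] = -10.0
        out = identify_hptr(res)
        assert "g2" not in out.hptr_genes
        assert out.n_models_flagged["g2"] == 4


class TestBsr:
    @pytest.mark.parametrize(
        "counts, expected",
        [((8, 2, 6, 4), 0.7), ((5, 0, 7, 0), 1.0), ((3, 1, 1, 3), 0.5)],
    )
    def test_formula(self, counts, expected):
        assert balanced_success_rate(*counts) == pytest.approx(expected)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_success_rate(0, 0, 3, 1)

    def test_imbalance_invariance(self):
        y = np.array([0] * 10 + [1] * 10)
        pred = np.array([0] * 8 + [1] * 2 + [1] * 9 + [0] * 1)
        base = bsr_from_predictions(y, pred)
        y2 = np.concatenate([y, np.zeros(10, int)])
        pred2 = np.concatenate([pred, np.array([0] * 8 + [1] * 2)])
        assert bsr_from_predictions(y2, pred2) == pytest.approx(base)


class TestCsd:
    def test_midpoint_interpolation(self):
        a = np.array([[0.0, 0.0], [2.0, 2.0]])
        out = balance_with_csd(a, 3, seed=0)
        assert out.shape == (3, 2)
        pseudo = out[2]
        assert np.allclose(pseudo[0], pseudo[1])  # on the segment
        assert 0 <= pseudo[0] <= 2

    def test_balancing_count(self):
        minority = np.random.default_rng(0).normal(size=(4, 3))
        out = balance_with_csd(minority, 10, seed=1)
        assert out.shape == (10, 3)

    def test_pseudo_samples_respect_bounding_box(self):
        rng = np.random.default_rng(2)
        minority = rng.normal(size=(6, 5))
        out = balance_with_csd(minority, 30, seed=3)
        lo, hi = minority.min(0), minority.max(0)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_shrinking_target_warns_and_noops(self):
        minority = np.zeros((5, 2))
        with pytest.warns(UserWarning):
            out = balance_with_csd(minority, 3, seed=0)
        assert out.shape == (5, 2)


class TestFeatureTests:
    def test_shifted_feature_detected(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(1000)]
        feats = pd.DataFrame({"f": rng.normal(size=1000), "g": rng.normal(size=1000)}, index=idx)
        labels = pd.Series(False, index=idx)
        labels.iloc[:50] = True
        feats.loc[labels, "f"] += 3.0
        out = feature_distribution_tests(feats, labels)
        assert out.loc["f", "p_bonferroni"] < 0.01
        assert out.loc["g", "p_bonferroni"] > 0.05

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        idx = [f"g{i}" for i in range(200)]
        feats = pd.DataFrame({f"f{j}": rng.normal(size=200) for j in range(5)}, index=idx)
        labels = pd.Series(rng.permutation([True] * 20 + [False] * 180), index=idx)
        out = feature_distribution_tests(feats, labels)
        assert (out["p_bonferroni"] > 0.05).all()

    def test_empty_group_rejected(self):
        feats = pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            feature_distribution_tests(feats, pd.Series([True, True], index=["a", "b"]))


class TestClassifiers:
    def test_separable_classes_reach_high_bsr(self):
        rng = np.random.default_rng(0)
        idx = [f"g{i}" for i in range(230)]
        X = np.vstack([rng.normal(0, 1, (200, 15)), rng.normal(3, 1, (30, 15))])
        F = pd.DataFrame(X, index=idx)
        y = pd.Series(["non-HPTR"] * 200 + ["HPTR+"] * 30, index=idx)
        out = train_hptr_classifiers(F, y, seed=1, n_permutations=15)
        assert out.bsr >= 0.95
        assert out.p_permutation <= 0.2

    def test_uninformative_features_are_not_significant(self):
        rng = np.random.default_rng(1)
        idx = [f"g{i}" for i in range(220)]
        F = pd.DataFrame(rng.normal(size=(220, 15)), index=idx)
        y = pd.Series(["non-HPTR"] * 190 + ["HPTR+"] * 30, index=idx)
        out = train_hptr_classifiers(F, y, seed=2, n_permutations=30)
        assert out.p_permutation > 0.05

    def test_single_class_rejected(self):
        F = pd.DataFrame(np.zeros((10, 2)), index=[f"g{i}" for i in range(10)])
        y = pd.Series(["a"] * 10, index=F.index)
        with pytest.raises(ValueError):
            train_hptr_classifiers(F, y)


class TestRefitGuards:
    def _fake_evaluation(self, genes):
        from dielomix.abundance_model import RegressionEvaluation, TimepointModel
        from dielomix.mars import MarsRegressor

        models = {}
        rng = np.random.default_rng(0)
        for tp in ("T1", "T2"):
            models[tp] = TimepointModel(
                timepoint=tp,
                model=MarsRegressor(),
                genes=pd.Index(genes),
                r2_resub=0.5,
                r2_cv=0.4,
                residuals=pd.Series(rng.normal(size=len(genes)), index=genes),
            )
        return RegressionEvaluation(models=models)

    def test_heldout_overlap_with_training_rejected(self):
        from dielomix.hptr import HptrResult, refit_excluding_hptr

        genes = [f"g{i}" for i in range(80)]
        evaluation = self._fake_evaluation(genes)
        hptr = HptrResult(
            thresholds=pd.DataFrame(),
            hptr_plus={"g0"},
            hptr_minus=set(),
            n_models_flagged=pd.Series(0, index=genes),
            min_models=2,
        )
        with pytest.raises(ValueError, match="overlap"):
            refit_excluding_hptr(
                None, None, None, evaluation, hptr, heldout_genes=["g5"]
            )

    def test_empty_hptr_set_is_identity(self):
        from dielomix.hptr import HptrResult, refit_excluding_hptr

        genes = [f"g{i}" for i in range(40)]
        evaluation = self._fake_evaluation(genes)
        empty = HptrResult(
            thresholds=pd.DataFrame(),
            hptr_plus=set(),
            hptr_minus=set(),
            n_models_flagged=pd.Series(0, index=genes),
            min_models=99,
        )
        out = refit_excluding_hptr(None, None, None, evaluation, empty)
        assert out.delta_r2_cv == {"T1": 0.0, "T2": 0.0}
        assert out.mean_relative_improvement == 0.0
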