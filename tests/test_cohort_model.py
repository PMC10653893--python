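"""Shannon features, CV logistic ROC machinery, McNemar comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm as normal
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from _oracles import irls_logistic
from magenes import cohort_model, synth_fixtures as sf
from magenes.cohort_model import (
    FeatureTable,
    build_features,
    cv_roc,
    fit_logistic,
    mcnemar,
    shannon_by_type,
    shannon_index,
)
from magenes.quant import getmm


def _table(x, y):
    ids = [f"s{i}" for i in range(len(y))]
    return FeatureTable(
        X=pd.DataFrame(np.atleast_2d(x).T if np.ndim(x) == 1 else x, index=ids),
        y=pd.Series(y, index=ids),
        variant=1,
    )


class TestShannon:
    def test_uniform_four_genes_gives_ln4(self):
        assert shannon_index([3.0, 3.0, 3.0, 3.0]) == pytest.approx(math.log(4))

    def test_single_nonzero_gene_gives_zero(self):
        assert shannon_index([0.0, 7.5, 0.0]) == 0.0

    def test_all_zero_gives_zero(self):
        assert shannon_index([0.0, 0.0]) == 0.0

    def test_scale_invariant_within_type(self, rng):
        a = rng.uniform(0, 5, size=6)
        assert shannon_index(a) == pytest.approx(shannon_index(10.0 * a))

    def test_bounded_by_log_gene_count(self, rng):
        vals = pd.DataFrame(
            rng.uniform(0, 10, size=(5, 4)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{j}" for j in range(4)],
        )
        types = {f"g{i}": "cutC" for i in range(5)}
        h = shannon_by_type(vals, types)
        assert (h["cutC"] <= math.log(5) + 1e-12).all()

    def test_per_type_renormalization(self):
        vals = pd.DataFrame(
            {"s0": [1.0, 1.0, 8.0]}, index=["a1", "a2", "b1"]
        )
        types = {"a1": "cutC", "a2": "cutC", "b1": "mttB"}
        h = shannon_by_type(vals, types)
        assert h.loc["s0", "cutC"] == pytest.approx(math.log(2))
        assert h.loc["s0", "mttB"] == 0.0


@pytest.fixture(scope="module")
def cohort():
    cm, meta, types = sf.simulate_cohort(
        sf.SimCohortSpec(n_case=15, n_control=15, genes_per_type=3, seed=5)
    )
    return getmm(cm), meta, types


class TestBuildFeatures:
    @pytest.mark.parametrize(
        "variant,n_cols",
        [
            (1, 8),   # 7 per-type diversities + gender
            (2, 4),   # 3 blood markers + gender
            (3, 3),   # cutC + cntA_yeaW sums + gender
            (5, 8),   # 7 per-type sums + gender
            (6, 3),   # 2 role sums + gender
            (7, 7),   # variant 1 without gender
        ],
    )
    def test_variant_column_counts(self, cohort, variant, n_cols):
        norm, meta, types = cohort
        t = build_features(norm, meta, types, variant=variant)
        assert t.X.shape[1] == n_cols

    def test_variant7_equals_variant1_minus_gender(self, cohort):
        norm, meta, types = cohort
        t1 = build_features(norm, meta, types, variant=1)
        t7 = build_features(norm, meta, types, variant=7)
        assert list(t1.X.columns) == list(t7.X.columns) + ["gender"]
        assert np.allclose(t1.X[t7.X.columns].values, t7.X.values)

    def test_variant4_uses_every_gene(self, cohort):
        norm, meta, types = cohort
        t = build_features(norm, meta, types, variant=4)
        assert t.X.shape[1] == norm.values.shape[0] + 1

    def test_missing_blood_markers_error_names_variant(self, cohort):
        norm, meta, types = cohort
        with pytest.raises(ValueError, match="variant 2"):
            build_features(norm, meta.drop(columns=["ldl_mmol_l"]), types, variant=2)

    def test_unknown_variant_rejected(self, cohort):
        norm, meta, types = cohort
        with pytest.raises(ValueError):
            build_features(norm, meta, types, variant=8)


class TestFitLogistic:
    def test_weights_match_irls_oracle(self, rng):
        X = rng.normal(size=(50, 2))
        logits = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(50) < 1 / (1 + np.exp(-logits))).astype(int)
        Xs = (X - X.mean(0)) / X.std(0)
        w, b = fit_logistic(X, y, l2_strength=1.0, tol=1e-10)
        w_o, b_o = irls_logistic(Xs, y, l2=1.0)
        assert np.allclose(w, w_o, atol=1e-5)
        assert b == pytest.approx(b_o, abs=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((5, 1)), np.ones(5))


class TestCVROC:
    def test_perfectly_separable_scores_auc_one(self):
        y = np.array([0] * 20 + [1] * 20)
        res = cv_roc(_table(y.astype(float), y), k=10, seed=0)
        assert res.auc == pytest.approx(1.0)

    def test_feature_equal_to_label_gives_cv_auc_one(self):
        y = np.array([0, 1] * 25)
        res = cv_roc(_table(y.astype(float), y), k=10, seed=1)
        assert res.auc == 1.0

    def test_mean_curve_auc_within_fold_auc_range(self, rng):
        x = rng.normal(size=200) + 0.8 * np.array([0] * 100 + [1] * 100)
        y = np.array([0] * 100 + [1] * 100)
        res = cv_roc(_table(x, y), k=10, seed=2)
        assert min(res.fold_aucs) - 1e-9 <= res.auc <= max(res.fold_aucs) + 1e-9

    def test_binormal_calibration(self):
        delta = 1.2415
        aucs = []
        for seed in range(1, 6):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(delta, 1, 218), rng.normal(0, 1, 187)])
            y = np.array([1] * 218 + [0] * 187)
            aucs.append(cv_roc(_table(x, y), k=10, seed=seed).auc)
        assert np.mean(aucs) == pytest.approx(normal.cdf(delta / math.sqrt(2)), abs=0.03)

    def test_null_labels_give_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            x = rng.normal(size=400)
            y = np.array([0, 1] * 200)
            aucs.append(cv_roc(_table(x, y), k=10, seed=seed).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)

    def test_stratification_balances_positives_across_folds(self, rng):
        x = rng.normal(size=105)
        y = (rng.random(105) < 0.4).astype(int)
        y[:10] = 1  # ensure enough positives
        res = cv_roc(_table(x, y), k=5, seed=3)
        n_pos = y.sum()
        for fold in range(5):
            fold_pos = y[res.fold_assignments == fold].sum()
            assert abs(fold_pos - n_pos / 5) <= 1

    def test_auc_invariant_under_monotone_score_transform(self, rng):
        # AUC depends on score ranks only; logistic's sigmoid is monotone in
        # the linear predictor, so scaling a single feature leaves ranks alone
        x = rng.normal(size=100) + np.array([0] * 50 + [1] * 50)
        y = np.array([0] * 50 + [1] * 50)
        a1 = cv_roc(_table(x, y), k=5, seed=4).auc
        a2 = cv_roc(_table(100.0 * x, y), k=5, seed=4).auc
        assert a1 == pytest.approx(a2, abs=1e-9)

    def test_class_smaller_than_k_rejected(self, rng):
        x = rng.normal(size=12)
        y = np.array([1] * 3 + [0] * 9)
        with pytest.raises(ValueError):
            cv_roc(_table(x, y), k=10)


class TestMcNemar:
    def test_identical_predictions_give_p_one(self):
        r = mcnemar([True, False, True], [True, False, True])
        assert r.b == r.c == 0 and r.p_value == 1.0

    def test_ten_zero_discordance_exact_p(self):
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        r = mcnemar(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 * 0.5**10)

    def test_symmetric_under_model_swap(self, rng):
        a = rng.random(60) < 0.7
        b = rng.random(60) < 0.6
        assert mcnemar(a, b).p_value == pytest.approx(mcnemar(b, a).p_value)

    def test_chi2_branch_used_for_large_discordance(self, rng):
        a = np.array([True] * 100)
        b = rng.random(100) < 0.6
        r = mcnemar(a, b)
        if r.b + r.c >= 25:
            assert r.method == "chi2_cc"

    @pytest.mark.parametrize("n_flip_a,n_flip_b", [(3, 1), (10, 0), (20, 15), (30, 5)])
    def test_matches_statsmodels(self, n_flip_a, n_flip_b):
        n = 80
        a = np.ones(n, dtype=bool)
        b = np.ones(n, dtype=bool)
        a[:n_flip_b] = False  # b-only-correct positions
        b[n_flip_b : n_flip_b + n_flip_a] = False  # a-only-correct
        r = mcnemar(a, b)
        table = [[0, r.b], [r.c, 0]]
        sm = sm_mcnemar(table, exact=(r.b + r.c) < 25, correction=True)
        assert r.p_value == pytest.approx(float(sm.pvalue), abs=1e-9)


class TestEffectMonotonicity:
    def test_auc_increases_with_planted_effect_size(self):
        aucs = []
        for effect in (0.0, 0.8, 2.0):
            spec = sf.SimCohortSpec(
                n_case=60,
                n_control=60,
                genes_per_type=3,
                role_log2_effects={"proatherogenic": effect, "mttB": -effect},
                seed=11,
            )
            cm, meta, types = sf.simulate_cohort(spec)
            t = build_features(getmm(cm), meta, types, variant=6)
            aucs.append(cv_roc(t, k=10, seed=11).auc)
        assert aucs[0] < aucs[1] < aucs[2]
        assert aucs[2] > 0.95
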