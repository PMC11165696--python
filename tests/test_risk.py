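import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutsem import (
    LogisticRiskModel,
    MeasurementModel,
    cv_risk_model,
    estimate_risk,
    fit_logistic,
    roc_auc,
    smote,
)


class TestSmote:
    def test_two_point_minority_interpolates_on_segment(self, rng):
        x = np.vstack([rng.normal(size=(20, 2)) + 5, [[0.0, 0.0], [2.0, 4.0]]])
        y = np.r_[np.zeros(20, dtype=int), 1, 1]
        xa, ya = smote(x, y, k=5, ratio=1.0, seed=1)
        synth = xa[len(x):]
        assert (ya[len(x):] == 1).all()
        # every synthetic point is on the segment between the two minority points
        t = synth[:, 0] / 2.0
        assert np.allclose(synth[:, 1], 4.0 * t, atol=1e-9)
        assert ((t >= 0) & (t <= 1)).all()

    def test_counts_balanced_to_ratio(self, rng):
        x = rng.normal(size=(120, 3))
        y = np.r_[np.zeros(100, dtype=int), np.ones(20, dtype=int)]
        xa, ya = smote(x, y, ratio=1.0, seed=2)
        assert (ya == 1).sum() == 100 and (ya == 0).sum() == 100

    def test_originals_preserved_verbatim(self, rng):
        x = rng.normal(size=(40, 2))
        y = np.r_[np.zeros(30, dtype=int), np.ones(10, dtype=int)]
        xa, ya = smote(x, y, seed=3)
        assert np.array_equal(xa[:40], x)
        assert np.array_equal(ya[:40], y)

    def test_synthetic_points_inside_convex_hull(self, rng):
        from scipy.spatial import Delaunay

        minority = rng.normal(size=(15, 2))
        majority = rng.normal(size=(60, 2)) + 10
        x = np.vstack([majority, minority])
        y = np.r_[np.zeros(60, dtype=int), np.ones(15, dtype=int)]
        xa, _ = smote(x, y, k=4, seed=4)
        hull = Delaunay(minority)
        assert (hull.find_simplex(xa[len(x):]) >= 0).all()

    def test_k_reduced_with_warning_and_tiny_minority_rejected(self, rng):
        x = rng.normal(size=(13, 2))
        y = np.r_[np.zeros(10, dtype=int), np.ones(3, dtype=int)]
        with pytest.warns(RuntimeWarning, match="reduced"):
            smote(x, y, k=5, seed=5)
        with pytest.raises(ValueError):
            smote(x[:11], np.r_[np.zeros(10, dtype=int), 1], seed=6)


class TestFitLogistic:
    def test_mirrored_classes_give_zero_intercept(self, rng):
        x = rng.normal(size=(200, 1))
        feats = np.vstack([x, -x])
        labels = np.r_[np.ones(200, dtype=int), np.zeros(200, dtype=int)]
        beta = fit_logistic(feats, labels)
        assert abs(beta[0]) < 1e-6

    def test_generative_recovery(self, rng):
        x = rng.normal(size=5000)
        p = 1 / (1 + np.exp(-(-1 + 2 * x)))
        y = (rng.uniform(size=5000) < p).astype(int)
        beta = fit_logistic(x, y)
        assert beta[0] == pytest.approx(-1, abs=0.15)
        assert beta[1] == pytest.approx(2, abs=0.15)

    def test_matches_reference_implementation(self, rng):
        from sklearn.linear_model import LogisticRegression

        x = rng.normal(size=(300, 3))
        y = (x @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=300) > 0).astype(int)
        ours = fit_logistic(x, y, l2=1e-4)
        ref = LogisticRegression(C=1e4, tol=1e-10, max_iter=2000).fit(x, y)
        assert ours[0] == pytest.approx(ref.intercept_[0], abs=1e-3)
        assert ours[1:] == pytest.approx(ref.coef_[0], abs=1e-3)

    def test_separable_data_stays_finite_and_ordered(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        beta = fit_logistic(x, y)
        assert np.isfinite(beta).all()
        assert beta[1] > 0


class TestRocAuc:
    def test_perfect_and_worked_example(self):
        assert roc_auc([0.1, 0.2, 0.9, 0.8], [0, 0, 1, 1]).auc == pytest.approx(1.0)
        res = roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)
        assert res.fpr[0] == 0 and res.tpr[-1] == 1

    def test_label_flip_complements_auc(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[0], y[1] = 0, 1
        assert roc_auc(s, y).auc == pytest.approx(1 - roc_auc(s, 1 - y).auc)

    def test_equals_pairwise_concordance_and_monotone_invariance(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 60))
            s = np.round(rng.normal(size=n), 1)  # ties likely
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            case, ctrl = s[y == 1], s[y == 0]
            gt = (case[:, None] > ctrl[None, :]).sum()
            eq = (case[:, None] == ctrl[None, :]).sum()
            oracle = (gt + 0.5 * eq) / (len(case) * len(ctrl))
            assert roc_auc(s, y).auc == pytest.approx(oracle, abs=1e-12)
            assert roc_auc(np.exp(3 * s), y).auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        scores=st.lists(st.integers(-5, 5), min_size=4, max_size=30),
        seed=st.integers(0, 1000),
    )
    def test_auc_bounds_and_complement_property(self, scores, seed):
        labels = np.random.default_rng(seed).integers(0, 2, size=len(scores))
        if len(np.unique(labels)) < 2:
            return
        scores = np.asarray(scores, dtype=float)
        auc = roc_auc(scores, labels).auc
        assert 0.0 <= auc <= 1.0
        assert roc_auc(-scores, labels).auc == pytest.approx(1 - auc, abs=1e-12)


class TestCvRiskModel:
    def test_signal_limit_and_determinism(self, rng):
        y = rng.integers(0, 2, size=120)
        x = y + rng.normal(0, 0.01, size=120)
        res1, preds1 = cv_risk_model(x, y, folds=5, seed=4)
        res2, preds2 = cv_risk_model(x, y, folds=5, seed=4)
        assert res1.cv_auc_pooled > 0.99
        assert np.array_equal(preds1, preds2)

    def test_null_features_stay_near_chance(self, rng):
        aucs = []
        for seed in range(5):
            local = np.random.default_rng(seed)
            x = local.normal(size=(100, 2))
            y = np.r_[np.ones(15, dtype=int), np.zeros(85, dtype=int)]
            res, _ = cv_risk_model(x, y, folds=5, seed=seed)
            aucs.append(res.cv_auc_pooled)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_class_smaller_than_folds_rejected(self, rng):
        x = rng.normal(size=(30, 1))
        y = np.r_[np.ones(5, dtype=int), np.zeros(25, dtype=int)]
        with pytest.raises(ValueError, match="folds"):
            cv_risk_model(x, y, folds=10, seed=0)

    def test_results_round_trip(self, rng):
        from gutsem.risk import RiskResults

        y = np.r_[np.ones(20, dtype=int), np.zeros(60, dtype=int)]
        x = y[:, None] + rng.normal(0, 1.0, size=(80, 1))
        res, _ = cv_risk_model(x, y, folds=5, seed=1)
        back = RiskResults.from_dict(res.to_dict())
        assert back.intercept == res.intercept
        assert np.array_equal(back.coef, res.coef)
        assert back.cv_auc_pooled == res.cv_auc_pooled


class TestEstimateRisk:
    def _bundle(self):
        meas = MeasurementModel(
            latents={"lv1": {"taxa": ["A", "B"], "loadings": [0.8, 0.7],
                             "residual_variances": [0.36, 0.51]}},
            latent_corr=[[1.0]],
            direct=[],
            means={"A": 0.0, "B": 0.0},
            sds={"A": 1.0, "B": 1.0},
        )
        from gutsem.risk import RiskResults, RocResult

        risk = RiskResults(
            feature_names=["lv1"], intercept=-0.4, coef=np.array([1.5]),
            folds=2, seed=0, smote_k=1, smote_ratio=1.0,
            cv_predictions=np.array([]), cv_auc_pooled=0.8, fold_aucs=[0.8],
            auc_resubstitution=0.8,
            roc=RocResult(np.array([0.0]), np.array([0.0]), np.array([0.0]), 0.8),
        )
        return risk, meas

    def test_average_sample_scores_at_intercept(self):
        risk, meas = self._bundle()
        clr = pd.DataFrame({"A": [0.0], "B": [0.0]}, index=["new"])
        prob = estimate_risk(risk, meas, clr)
        assert prob.iloc[0] == pytest.approx(1 / (1 + np.exp(0.4)))

    def test_monotone_in_latent_score_and_blind_to_outcome(self):
        risk, meas = self._bundle()
        clr = pd.DataFrame(
            {"A": [-2.0, 0.0, 2.0], "B": [-2.0, 0.0, 2.0], "depression": [1, 0, 1]}
        )
        probs = estimate_risk(risk, meas, clr)
        assert probs.is_monotonic_increasing
        probs_blind = estimate_risk(risk, meas, clr.drop(columns="depression"))
        assert np.array_equal(probs.to_numpy(), probs_blind.to_numpy())

    def test_missing_taxon_rejected(self):
        risk, meas = self._bundle()
        with pytest.raises(ValueError, match="B"):
            estimate_risk(risk, meas, pd.DataFrame({"A": [0.0]}))
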