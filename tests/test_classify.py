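import numpy as np
import pandas as pd
import pytest

from pgdvoc import (
    FeatureTable,
    SplitPlan,
    VOCLinearClassifier,
    auroc,
    evaluate_late_samples,
    evaluate_scores,
    fit_and_evaluate,
    grouped_split,
    implied_prevalence_npv,
    prevalence_filter,
    scale_importance,
    select_features,
    train_linear_model,
)
from conftest import make_meta


class TestGroupedSplit:
    def test_two_per_class_forced_one_each_side(self):
        rows = [[f"s{i}", f"p{i}", "BALF", "early", g]
                for i, g in enumerate([3, 3, 0, 1])]
        meta = make_meta(rows)
        plan = grouped_split(meta, ratio=0.5, seed=0)
        assert len(plan.train_patients) == 2 and len(plan.test_patients) == 2
        train_g = {p[-1] for p in plan.train_patients}  # p0..p3 digits encode class
        assert len(set(plan.train_patients) & {"p0", "p1"}) == 1  # one PGD3 each side

    def test_patient_never_split(self, cohort17):
        _, meta, _ = cohort17
        early = meta[meta["time_window"] == "early"]
        for seed in range(20):
            plan = grouped_split(early, seed=seed)
            train_p = set(early.loc[list(plan.train_samples), "patient_id"])
            test_p = set(early.loc[list(plan.test_samples), "patient_id"])
            assert not train_p & test_p
            assert train_p | test_p == set(early["patient_id"])

    def test_splitplan_rejects_overlap(self):
        with pytest.raises(ValueError, match="both sides"):
            SplitPlan(("p1",), ("p1",), (), (), 0)

    def test_small_class_rejected(self):
        meta = make_meta([["s1", "p1", "BALF", "early", 3],
                          ["s2", "p2", "BALF", "early", 0],
                          ["s3", "p3", "BALF", "early", 0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            grouped_split(meta)


class TestScaleImportance:
    def test_max_scaling(self):
        np.testing.assert_allclose(scale_importance([1, -2, 4]), [25, 50, 100])

    def test_equal_weights_all_100(self):
        np.testing.assert_allclose(scale_importance([0.3, -0.3, 0.3]), [100, 100, 100])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            out = scale_importance([0.0, 0.0])
        np.testing.assert_allclose(out, 0.0)

    def test_order_preservation(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=50)
        imp = scale_importance(w)
        assert np.argmax(imp) == np.argmax(np.abs(w))
        assert (np.argsort(imp) == np.argsort(np.abs(w))).all()


class TestPrevalenceFilter:
    def _table(self, pos_hits, neg_hits, n_pos=8, n_neg=20):
        rows = []
        meta_rows = []
        for i in range(n_pos):
            rows.append([1.0 if i < pos_hits else 0.0])
            meta_rows.append([f"a{i}", f"pa{i}", "BALF", "early", 3])
        for i in range(n_neg):
            rows.append([1.0 if i < neg_hits else 0.0])
            meta_rows.append([f"b{i}", f"pb{i}", "BALF", "early", 0])
        meta = make_meta(meta_rows)
        areas = pd.DataFrame(rows, index=meta.index, columns=["f"])
        return FeatureTable(areas), meta

    def test_fully_present_kept(self):
        t, m = self._table(8, 0)
        assert prevalence_filter(t, m)["f"]

    def test_boundary_25_percent_inclusive(self):
        t, m = self._table(2, 0)  # 2 of 8 = exactly 25 %
        assert prevalence_filter(t, m)["f"]

    def test_below_threshold_dropped(self):
        t, m = self._table(1, 2)  # 12.5 % and 10 %
        assert not prevalence_filter(t, m)["f"]


def _brute_force_svm_2point(C=1.0):
    """Grid-search the C-SVM objective for pos x=+1, neg x=-1."""
    best, best_obj = None, np.inf
    for w in np.arange(-3, 3.001, 0.01):
        for b in np.arange(-2, 2.001, 0.01):
            obj = 0.5 * w * w + C * (
                max(0, 1 - (w * 1 + b)) + max(0, 1 + (w * -1 + b))
            )
            if obj < best_obj - 1e-12:
                best, best_obj = (w, b), obj
    return best


class TestLinearModel:
    def test_separable_one_dimensional(self):
        X = pd.DataFrame({"f": [1.0, 1.2, 0.1, 0.2]})
        y = pd.Series(["PGD3", "PGD3", "PGD0-2", "PGD0-2"])
        m = train_linear_model(X, y, log_transform=False)
        assert m.coef_[0] > 0
        assert list(m.predict(X.to_numpy())) == list(y)

    def test_matches_brute_force_grid_and_duplication_invariant(self):
        # raw +-1 points standardize to themselves, so the fitted (w, b)
        # should match the brute-force minimizer of the hinge+L2 objective
        w_star, b_star = _brute_force_svm_2point()
        X = np.array([[1.0], [0.0]])  # standardizes to +1, -1
        y = np.array(["PGD3", "PGD0-2"])
        m = VOCLinearClassifier(log_transform=False).fit(X, y)
        assert m.coef_[0] == pytest.approx(w_star, abs=0.02)
        assert m.intercept_ == pytest.approx(b_star, abs=0.02)
        m2 = VOCLinearClassifier(log_transform=False).fit(np.vstack([X, X]),
                                                          np.concatenate([y, y]))
        assert m2.coef_[0] == pytest.approx(m.coef_[0], abs=1e-6)
        assert m2.intercept_ == pytest.approx(m.intercept_, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            VOCLinearClassifier().fit(np.ones((3, 2)), np.array(["PGD3"] * 3))

    def test_training_beats_test_accuracy_on_average(self):
        from pgdvoc import SyntheticSpec, generate_cohort, normalize_areas

        diffs = []
        for seed in range(1, 21):
            table, meta, _ = generate_cohort(SyntheticSpec(seed=seed))
            norm = normalize_areas(table)
            early = meta[meta["time_window"] == "early"]
            plan = grouped_split(early, seed=seed)
            train = list(plan.train_samples)
            test = list(plan.test_samples)
            m = train_linear_model(norm.areas.loc[train], early.loc[train, "label"])
            acc = lambda s: (m.predict(norm.areas.loc[s].to_numpy())
                             == early.loc[s, "label"].to_numpy()).mean()
            diffs.append(acc(train) - acc(test))
        assert np.mean(diffs) >= 0


class TestAuroc:
    def test_hand_counted_example(self):
        # pairs: (.9,.85)+ (.9,.7)+ (.8,.85)- (.8,.7)+ -> 3/4
        assert auroc([0.9, 0.8], [0.85, 0.7]) == pytest.approx(0.75)

    def test_ties_count_half(self):
        assert auroc([1.0], [1.0]) == pytest.approx(0.5)

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            pos = rng.normal(0.5, 1, rng.integers(2, 8))
            neg = rng.normal(0, 1, rng.integers(2, 8))
            y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
            assert auroc(pos, neg) == pytest.approx(
                roc_auc_score(y, np.r_[pos, neg])
            )


class TestSelectFeatures:
    def _toy(self):
        rng = np.random.default_rng(0)
        meta_rows, rows = [], []
        for i in range(6):
            grade = 3 if i < 3 else 0
            # feature A separates classes; feature B is identical noise
            rows.append([5.0 + (2.0 if grade == 3 else 0.0) + rng.normal(0, 0.1),
                         3.0 + rng.normal(0, 0.1)])
            meta_rows.append([f"s{i}", f"p{i}", "BALF", "early", grade])
        meta = make_meta(meta_rows)
        areas = pd.DataFrame(rows, index=meta.index, columns=["A", "B"])
        return FeatureTable(areas), meta

    def test_only_discriminative_feature_retained(self):
        t, m = self._toy()
        plan = SplitPlan(tuple(m["patient_id"]), ("px",), tuple(m.index), (), 0)
        sel = select_features(t, m, plan, log_transform=False)
        assert sel.retained == ["A"]

    def test_empty_selection_advises(self, norm17):
        norm, meta, _ = norm17
        early = meta[meta["time_window"] == "early"]
        plan = grouped_split(early, seed=1)
        with pytest.raises(ValueError, match="relax"):
            select_features(norm, early, plan, importance_cut=101)

    def test_deterministic_given_inputs(self, norm17):
        norm, meta, _ = norm17
        early = meta[meta["time_window"] == "early"]
        plan = grouped_split(early, seed=3)
        s1 = select_features(norm, early, plan)
        s2 = select_features(norm, early, plan)
        assert s1.retained == s2.retained
        pd.testing.assert_series_equal(s1.importance, s2.importance)


class TestFitAndEvaluate:
    def test_perfect_separation_all_metrics_one(self, norm17):
        norm, meta, _ = norm17
        scores = pd.Series([2.0, 1.5, -1.0, -2.0], index=list("abcd"))
        proba = pd.Series([0.9, 0.8, 0.2, 0.1], index=list("abcd"))
        y = pd.Series(["PGD3", "PGD3", "PGD0-2", "PGD0-2"], index=list("abcd"))
        rep = evaluate_scores(scores, proba, y, n_boot=50)
        assert rep.auroc == 1.0
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv,
                rep.accuracy) == (1, 1, 1, 1, 1)

    def test_confusion_identities(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(6, 25))
            idx = [f"s{i}" for i in range(n)]
            y = pd.Series(rng.choice(["PGD3", "PGD0-2"], n), index=idx)
            if y.nunique() < 2:
                continue
            scores = pd.Series(rng.normal(size=n), index=idx)
            proba = pd.Series(rng.random(n), index=idx)
            r = evaluate_scores(scores, proba, y, n_boot=20)
            assert r.accuracy == pytest.approx((r.tp + r.tn) / r.n)
            if r.tp + r.fn:
                assert r.sensitivity == pytest.approx(r.tp / (r.tp + r.fn))
            if r.tn + r.fp:
                assert r.specificity == pytest.approx(r.tn / (r.tn + r.fp))
            assert r.ci95[0] <= r.auroc <= r.ci95[1]

    def test_end_to_end_on_planted_cohort(self, norm17):
        norm, meta, _ = norm17
        early = meta[meta["time_window"] == "early"]
        plan = grouped_split(early, seed=17)
        sel = select_features(norm, early, plan)
        model, rep = fit_and_evaluate(norm, early, sel, plan, n_boot=100, seed=17)
        assert rep.auroc > 0.6  # planted 2-fold effect must beat chance
        assert set(rep.y_true.index) <= set(plan.test_samples)

    def test_late_identical_to_test_reproduces_report(self, norm17):
        norm, meta, _ = norm17
        early = meta[meta["time_window"] == "early"]
        plan = grouped_split(early, seed=17)
        sel = select_features(norm, early, plan)
        model, rep = fit_and_evaluate(norm, early, sel, plan, n_boot=50, seed=5)
        # rebadge the held-out early samples as the late window
        meta2 = early.copy()
        meta2.loc[list(plan.test_samples), "time_window"] = "late"
        late_rep = evaluate_late_samples(model, norm, meta2, sel, plan,
                                         n_boot=50, seed=5)
        assert late_rep.auroc == pytest.approx(rep.auroc)
        assert (late_rep.tp, late_rep.fp, late_rep.tn, late_rep.fn) == \
            (rep.tp, rep.fp, rep.tn, rep.fn)

    def test_late_excludes_training_patients(self, norm17):
        norm, meta, _ = norm17
        early = meta[meta["time_window"] == "early"]
        plan = grouped_split(early, seed=17)
        sel = select_features(norm, early, plan)
        model, _ = fit_and_evaluate(norm, early, sel, plan, n_boot=20, seed=0)
        rep = evaluate_late_samples(model, norm, meta, sel, plan, n_boot=20, seed=0)
        pats = set(meta.loc[rep.y_true.index, "patient_id"])
        assert not pats & set(plan.train_patients)


class TestMetricIdentities:
    def test_implied_prevalence_round_trip(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pi, se, sp = rng.uniform(0.1, 0.9, 3)
            ppv = se * pi / (se * pi + (1 - sp) * (1 - pi))
            pi_hat, npv_hat = implied_prevalence_npv(se, sp, ppv)
            assert pi_hat == pytest.approx(pi)
            npv = sp * (1 - pi) / (sp * (1 - pi) + (1 - se) * pi)
            assert npv_hat == pytest.approx(npv)
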