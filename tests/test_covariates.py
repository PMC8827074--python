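import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway, rankdata

from pgdvoc import (
    bmi_classify,
    chi_squared,
    cohort_table,
    ischemia_stratify,
    lung_function_correlation,
    manova_screen,
    recipient_risk,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def chi2_oracle(table):
    """Textbook sum((O-E)^2/E) with chi-square(1 df for 2x2) tail."""
    from scipy.stats import chi2

    t = np.asarray(table, dtype=float)
    rows, cols = t.sum(1), t.sum(0)
    e = np.outer(rows, cols) / t.sum()
    stat = ((t - e) ** 2 / e).sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return stat, chi2.sf(stat, df)


def wilcoxon_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    m, n = len(a), len(b)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    ext_obs = min(u_obs, m * n - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(m + n), m):
        u = ranks[list(idx)].sum() - m * (m + 1) / 2
        if min(u, m * n - u) <= ext_obs + 1e-9:
            count += 1
        total += 1
    return count / total


class TestChiSquared:
    def test_ocs_contingency_hand_computed(self):
        # chi2 = 35*(24*3 - 1*7)^2 / (25*10*31*4) = 4.770...
        stat, p = chi_squared([[24, 1], [7, 3]])
        assert stat == pytest.approx(35 * 65 ** 2 / 31000, abs=1e-9)
        assert round(p, 2) == 0.03

    def test_identical_proportions_p_one(self):
        stat, p = chi_squared([[10, 5], [10, 5]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_oracle_on_small_tables(self):
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            stat, p = chi_squared([[a, b], [c, d]])
            stat_o, p_o = chi2_oracle([[a, b], [c, d]])
            assert stat == pytest.approx(stat_o)
            assert p == pytest.approx(p_o)


class TestWilcoxon:
    def test_disjoint_small_groups(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(3, 7), rng.integers(3, 7)
        vals = rng.permutation(60)[: m + n].astype(float)  # distinct values
        a, b = vals[:m], vals[m:]
        assert wilcoxon_rank_sum(a, b) == pytest.approx(wilcoxon_oracle(a, b))


class TestCohortTable:
    def _records(self):
        rec = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(10)],
            "age": [40, 42, 44, 46, 48, 50, 52, 54, 56, 58],
            "ocs": [False] * 5 + [True] * 5,
        }).set_index("patient_id", drop=False)
        group = pd.Series(["PGD0-2"] * 5 + ["PGD3"] * 5, index=rec.index)
        return rec, group

    def test_variable_typing_and_tests(self):
        rec, group = self._records()
        out = cohort_table(rec, group)
        assert out.loc["age", "test"] == "wilcoxon"
        assert out.loc["ocs", "test"] == "chi-squared"

    def test_continuous_toy_exact_p(self):
        rec = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(6)],
            "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        }).set_index("patient_id", drop=False)
        group = pd.Series(["PGD0-2"] * 3 + ["PGD3"] * 3, index=rec.index)
        out = cohort_table(rec, group)
        assert out.loc["x", "p_raw"] == pytest.approx(0.1)

    def test_all_missing_variable_omitted(self):
        rec, group = self._records()
        rec["ghost"] = np.nan
        out = cohort_table(rec, group)
        assert "ghost" not in out.index

    def test_too_small_group_rejected(self):
        rec, _ = self._records()
        group = pd.Series(["PGD3"] + ["PGD0-2"] * 9, index=rec.index)
        with pytest.raises(ValueError, match="at least 2"):
            cohort_table(rec, group)


def pillai_oracle(Y, labels):
    """Manual Pillai trace from the hypothesis/error cross-product matrices."""
    Y = np.asarray(Y, float)
    grand = Y.mean(0)
    H = np.zeros((Y.shape[1], Y.shape[1]))
    E = np.zeros_like(H)
    for lev in np.unique(labels):
        sub = Y[labels == lev]
        d = (sub.mean(0) - grand)[:, None]
        H += len(sub) * d @ d.T
        E += (sub - sub.mean(0)).T @ (sub - sub.mean(0))
    return np.trace(H @ np.linalg.inv(H + E))


class TestManova:
    def test_single_response_equals_anova(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        fac = pd.Series(rng.choice(["a", "b", "c"], 30))
        resp = pd.DataFrame({"y": y}, index=fac.index)
        res = manova_screen(resp, fac)
        groups = [y[(fac == lev).to_numpy()] for lev in "abc"]
        f_ref = f_oneway(*groups)
        assert res.f_value == pytest.approx(f_ref.statistic)
        assert res.p_value == pytest.approx(f_ref.pvalue)

    def test_pillai_matches_manual_cross_products(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(40, 3))
        fac = pd.Series(rng.choice(["a", "b"], 40))
        resp = pd.DataFrame(Y, index=fac.index)
        res = manova_screen(resp, fac)
        assert res.pillai == pytest.approx(pillai_oracle(Y, fac.to_numpy()), abs=1e-8)

    def test_high_dimension_projected(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 30))  # p >= n - g forces PCA reduction
        fac = pd.Series(rng.choice(["a", "b"], 20))
        resp = pd.DataFrame(Y, index=fac.index)
        res = manova_screen(resp, fac)
        assert res.n_response == 20 - 2 - 1
        assert 0 <= res.p_value <= 1

    def test_single_level_rejected(self):
        resp = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="2 levels"):
            manova_screen(resp, pd.Series(["a", "a", "a"]))

    def test_power_against_planted_class_effect(self):
        from pgdvoc import SyntheticSpec, generate_cohort, normalize_areas

        hits = 0
        for seed in range(1, 21):
            table, meta, _ = generate_cohort(SyntheticSpec(seed=seed))
            norm = normalize_areas(table)
            early = meta[meta["time_window"] == "early"]
            feats = np.log(norm.areas.loc[early.index, table.informative_features]
                           + 1e-9)
            res = manova_screen(feats, early["label"])
            hits += res.p_value < 0.05
        assert hits >= 16  # >= 80 % of seeds


class TestStratifiers:
    @pytest.mark.parametrize("bmi,expected", [
        (24, "normal"), (18.5, "normal"), (25.0, "normal"),
        (18.4, "low"), (26, "high"),
    ])
    def test_bmi(self, bmi, expected):
        assert bmi_classify(bmi) == expected

    @pytest.mark.parametrize("h,expected", [
        (5, "short"), (6, "medium"), (8, "medium"), (10, "medium"), (11, "long"),
    ])
    def test_ischemia(self, h, expected):
        assert ischemia_stratify(h) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bmi_classify(0)
        with pytest.raises(ValueError):
            ischemia_stratify(-1)

    def test_total_on_grid_no_gaps(self):
        for x in np.arange(0.1, 60, 0.1):
            assert bmi_classify(round(float(x), 1)) in {"low", "normal", "high"}
            assert ischemia_stratify(round(float(x), 1)) in {"short", "medium", "long"}


class TestRecipientRisk:
    def _rec(self, bmi=22.0, dx="COPD-Emphysema", ph="absent/mild"):
        return pd.Series({"patient_id": "p", "recipient_bmi": bmi,
                          "underlying_disease": dx, "pulmonary_hypertension": ph})

    def test_all_three_conditions_low(self):
        assert recipient_risk(self._rec()) == "low"

    def test_high_bmi_high(self):
        assert recipient_risk(self._rec(bmi=27)) == "high"

    def test_other_diagnosis_high(self):
        assert recipient_risk(self._rec(dx="Other")) == "high"

    def test_missing_field_conservative_high(self):
        assert recipient_risk(self._rec(bmi=np.nan)) == "high"


class TestLungFunctionCorrelation:
    def test_identical_vectors_r_one(self):
        idx = [f"p{i}" for i in range(8)]
        f = pd.DataFrame({"feat": np.arange(8.0)}, index=idx)
        s = pd.DataFrame({"fev1_pct": np.arange(8.0)}, index=idx)
        out = lung_function_correlation(f, s)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_null_grid_calibration(self):
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(30)]
        f = pd.DataFrame(rng.normal(size=(30, 20)), index=idx,
                         columns=[f"f{i}" for i in range(20)])
        s = pd.DataFrame(rng.normal(size=(30, 8)), index=idx,
                         columns=[f"m{i}" for i in range(8)])
        out = lung_function_correlation(f, s)
        frac = (out["p_raw"] < 0.05).mean()
        assert 0.0 <= frac <= 0.12  # 160 tests, expect ~5 %

    def test_planted_strong_correlation_detected(self):
        detected = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            idx = [f"p{i}" for i in range(30)]
            x = rng.normal(size=30)
            y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=30)
            f = pd.DataFrame({"f0": x}, index=idx)
            f[[f"f{i}" for i in range(1, 20)]] = rng.normal(size=(30, 19))
            s = pd.DataFrame({"m0": y}, index=idx)
            s[[f"m{i}" for i in range(1, 8)]] = rng.normal(size=(30, 7))
            out = lung_function_correlation(f, s).set_index(["feature_id", "measure"])
            detected += bool(out.loc[("f0", "m0"), "significant"])
        assert detected >= 8

    def test_constant_vector_nan_sentinel(self):
        idx = [f"p{i}" for i in range(6)]
        f = pd.DataFrame({"feat": [1.0] * 6}, index=idx)
        s = pd.DataFrame({"m": np.arange(6.0)}, index=idx)
        out = lung_function_correlation(f, s)
        assert np.isnan(out.loc[0, "r"])
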