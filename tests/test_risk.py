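import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from oracles import logistic_mle_oracle, mannwhitney_exact_two_sided
from qctlung.risk import (
    RankDeficiencyError,
    RiskModelSpec,
    SeparationError,
    backward_select_lr,
    brock_probability,
    compare_groups,
    extend_with_qct,
    fit_logistic,
    load_model_spec,
    lr_test,
    mayo_probability,
    roc_auc,
)


class TestCompareGroups:
    def test_tiny_sample_exact_mannwhitney(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0], "malignant": [1, 1, 0, 0]})
        c = compare_groups(df, "v", kind="continuous")
        assert c.statistic == 0.0
        assert c.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_near_one(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"v": x, "malignant": np.r_[np.zeros(100), np.ones(100)]})
        df["v"] = np.r_[x[:100], x[:100]]
        c = compare_groups(df, "v", kind="continuous")
        assert c.p_value > 0.9

    def test_balanced_contingency_chi2_zero(self):
        df = pd.DataFrame(
            {"g": ["a"] * 20 + ["b"] * 20, "malignant": ([0] * 10 + [1] * 10) * 2}
        )
        c = compare_groups(df, "g", kind="categorical")
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(500 + seed)
        x = rng.permutation(np.arange(12, dtype=float))
        g = np.r_[np.zeros(6), np.ones(6)]
        df = pd.DataFrame({"v": x, "malignant": g})
        c = compare_groups(df, "v", kind="continuous")
        assert c.p_value == pytest.approx(
            mannwhitney_exact_two_sided(x[g == 1], x[g == 0]), abs=1e-12
        )

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"v": [1.0] * 10, "malignant": [0] * 5 + [1] * 5})
        with pytest.raises(ValueError, match="constant"):
            compare_groups(df, "v", kind="continuous")


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(20), np.zeros(80)]
        f = fit_logistic(np.empty((100, 0)), y)
        assert f.params[0] == pytest.approx(np.log(0.2 / 0.8), abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_likelihood_maximization(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 120, 3
        X = rng.normal(size=(n, p))
        beta_true = rng.normal(0, 0.7, size=p)
        y = (rng.random(n) < expit(X @ beta_true - 0.2)).astype(float)
        if y.min() == y.max():
            pytest.skip("degenerate draw")
        mine = fit_logistic(X, y)
        Xd = np.column_stack([np.ones(n), X])
        ref = logistic_mle_oracle(Xd, y)
        np.testing.assert_allclose(mine.params, ref, atol=1e-6)

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(400, 2))
        y = (rng.random(400) < expit(0.8 * X[:, 0] - 0.5)).astype(float)
        mine = fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(mine.params, ref.params, atol=1e-8)
        np.testing.assert_allclose(mine.bse, ref.bse, atol=1e-6)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_perfect_separation_raises(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            fit_logistic(x[:, None], x)

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = 2 * X["a"]
        y = (rng.random(50) < 0.4).astype(float)
        with pytest.raises(RankDeficiencyError, match="a|b"):
            fit_logistic(X, y)

    def test_odds_ratio_exp_of_coef(self, rng):
        X = rng.normal(size=(300, 1))
        y = (rng.random(300) < expit(0.5 * X[:, 0])).astype(float)
        f = fit_logistic(X, y, names=["x"])
        tab = f.odds_ratios()
        assert tab.loc["x", "or"] == pytest.approx(np.exp(f.coef("x")))
        assert tab.loc["x", "or_ci_low"] < tab.loc["x", "or"] < tab.loc["x", "or_ci_high"]


class TestLrTest:
    def test_lr_invariant_to_affine_covariate_rescaling(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        y = (rng.random(300) < expit(0.6 * X["a"])).astype(float)
        full = fit_logistic(X, y)
        red = fit_logistic(X[["b"]], y)
        lr1 = lr_test(full, red).lr_statistic
        X2 = X.copy()
        X2["a"] = 100.0 * X2["a"] - 7.0
        lr2 = lr_test(fit_logistic(X2, y), fit_logistic(X2[["b"]], y)).lr_statistic
        assert lr1 == pytest.approx(lr2, rel=1e-6)


class TestBackwardSelection:
    def _data(self, rng, n=600):
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = (rng.random(n) < expit(1.5 * X["a"] - 1.0)).astype(float)
        return X, y

    def test_strong_single_candidate_retained(self, rng):
        X, y = self._data(rng)
        sel = backward_select_lr(X[["a"]], y, p_remove=0.10)
        assert sel.selected == ("a",)
        assert sel.path == ()

    def test_p_remove_zero_drops_everything(self, rng):
        X, y = self._data(rng)
        sel = backward_select_lr(X, y, p_remove=0.0)
        assert sel.selected == ()
        assert len(sel.path) == 4

    def test_p_remove_above_one_retains_all(self, rng):
        X, y = self._data(rng)
        sel = backward_select_lr(X, y, p_remove=1.01)
        assert set(sel.selected) == set("abcd")

    def test_signal_survives_noise_candidates(self, rng):
        X, y = self._data(rng)
        sel = backward_select_lr(X, y, p_remove=0.10)
        assert "a" in sel.selected


class TestRiskModels:
    def test_logistic_of_zero_linear_predictor(self):
        spec = RiskModelSpec(
            name="test", citation="-", intercept=0.0,
            terms=({"covariate": "x", "coefficient": 1.0, "transform": "linear"},),
        )
        assert spec.probability({"x": 0.0}) == pytest.approx(0.5)

    def test_mayo_monotone_in_diameter(self):
        rec = dict(age_years=60, ever_smoker=1, prior_extrathoracic_cancer=0,
                   spiculation=0, upper_lobe=0)
        probs = [mayo_probability({**rec, "diameter_mm": d}) for d in (5, 10, 20, 30)]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_probability_forms_agree(self):
        spec = load_model_spec("mayo")
        rec = dict(age_years=70, ever_smoker=1, prior_extrathoracic_cancer=1,
                   diameter_mm=14.0, spiculation=1, upper_lobe=1)
        x = spec.linear_predictor(rec)
        assert spec.probability(rec) == pytest.approx(
            np.exp(x) / (1 + np.exp(x)), abs=1e-12
        )

    def test_missing_covariate_strict_error(self):
        with pytest.raises(ValueError, match="ever_smoker"):
            mayo_probability({"age_years": 60, "diameter_mm": 8})

    @pytest.mark.parametrize(
        "rec",
        [
            dict(sex="female", diameter_mm=8.0, nodule_type="solid",
                 upper_lobe=1, nodule_count=1, spiculation=0),
            dict(sex="male", diameter_mm=22.0, nodule_type="part_solid",
                 upper_lobe=0, nodule_count=3, spiculation=1),
            dict(sex="male", diameter_mm=5.0, nodule_type="ggo",
                 upper_lobe=1, nodule_count=6, spiculation=0),
        ],
    )
    def test_brock_matches_hand_computed_linear_predictor(self, rec):
        spec = load_model_spec("brock")
        coefs = {
            (t["covariate"], t.get("level")): t["coefficient"] for t in spec.terms
        }
        lp = spec.intercept
        lp += coefs[("sex", "female")] * (rec["sex"] == "female")
        lp += coefs[("diameter_mm", None)] * (
            (rec["diameter_mm"] / 10.0) ** -0.5 - 1.58113883
        )
        lp += coefs[("nodule_type", "part_solid")] * (rec["nodule_type"] == "part_solid")
        lp += coefs[("nodule_type", "ggo")] * (rec["nodule_type"] == "ggo")
        lp += coefs[("upper_lobe", None)] * rec["upper_lobe"]
        lp += coefs[("nodule_count", None)] * (rec["nodule_count"] - 4)
        lp += coefs[("spiculation", None)] * rec["spiculation"]
        assert brock_probability(rec) == pytest.approx(float(expit(lp)), abs=1e-12)
        assert 0.0 < brock_probability(rec) < 1.0


class TestExtension:
    def _base(self, rng, n=500):
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(1.2 * x - 1.0)).astype(float)
        base_probs = expit(1.0 * x - 0.8)  # informative but miscalibrated
        return base_probs, y

    def test_duplicated_logit_column_rejected(self, rng):
        base_probs, y = self._base(rng)
        from scipy.special import logit

        qct = pd.DataFrame({"dup": logit(base_probs)})
        with pytest.raises(RankDeficiencyError):
            extend_with_qct(base_probs, qct, y)

    def test_degenerate_base_probabilities_rejected(self, rng):
        y = (rng.random(100) < 0.3).astype(float)
        with pytest.raises(ValueError, match="degenerate|strictly"):
            extend_with_qct(np.full(100, 0.3), pd.DataFrame({"q": rng.normal(size=100)}), y)

    def test_informative_qct_improves_fit_and_auc(self, rng):
        n = 2000
        x = rng.normal(size=n)
        q = rng.normal(size=n)
        y = (rng.random(n) < expit(1.0 * x + 0.8 * q - 1.0)).astype(float)
        base_probs = expit(1.0 * x - 1.0)
        res = extend_with_qct(base_probs, pd.DataFrame({"q": q}), y)
        assert res.comparison.p_value < 1e-6
        assert res.auc_extended.auc > res.auc_base.auc

    def test_null_qct_lr_statistic_modest(self, rng):
        base_probs, y = self._base(rng, n=800)
        qct = pd.DataFrame({"q1": rng.normal(size=800), "q2": rng.normal(size=800)})
        res = extend_with_qct(base_probs, qct, y)
        assert res.comparison.df == 2
        assert res.comparison.lr_statistic < 15  # generous chi2(2) bound

    def test_offset_mode_runs_and_nests(self, rng):
        base_probs, y = self._base(rng)
        qct = pd.DataFrame({"q": rng.normal(size=len(y))})
        res = extend_with_qct(base_probs, qct, y, mode="offset")
        assert res.comparison.lr_statistic >= 0


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.ci_high <= 1.0

    def test_pairwise_enumeration_example(self):
        # pairs (pos, neg): (2,1)+, (2,3)-, (4,1)+, (4,3)+ -> 3/4
        r = roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_ties_get_half_credit(self):
        r = roc_auc([1.0, 2.0, 2.0, 3.0], [0, 0, 1, 1])
        assert r.auc == pytest.approx((1.0 + 0.5 + 1.0 + 1.0) / 4)

    def test_invariant_under_monotone_transform(self, rng):
        s = rng.normal(size=200)
        y = (rng.random(200) < expit(s)).astype(int)
        a1 = roc_auc(s, y).auc
        a2 = roc_auc(np.exp(3 * s), y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_delong_ci_width_agrees_with_bootstrap(self, rng):
        n = 200
        s = rng.normal(size=n) + np.r_[np.zeros(n // 2), np.ones(n // 2)]
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        r = roc_auc(s, y)
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            if y[idx].min() == y[idx].max():
                continue
            boots.append(roc_auc(s[idx], y[idx]).auc)
        b_lo, b_hi = np.percentile(boots, [2.5, 97.5])
        delong_width = r.ci_high - r.ci_low
        boot_width = b_hi - b_lo
        assert delong_width == pytest.approx(boot_width, rel=0.20)

    def test_delong_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.normal(size=300)
        y = (rng.random(300) < expit(0.7 * s)).astype(int)
        assert roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)
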